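"""Posterior summaries and log-file I/O.

Highest-posterior-density intervals (shortest interval on sorted samples),
credible sets for categorical quantities (descending-frequency
construction), autocorrelation-based effective sample sizes, the
Table-2-shaped coverage table of the well-calibrated study, and clade
support comparison between posterior tree sets.  Trace logs are
tab-separated with a leading ``Sample`` column; tree logs are NEXUS with a
translate block (dendropy-backed).
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd

from .priors import yule_log_density
from .tree import TimeTree

__all__ = [
    "hpd_interval",
    "credible_set",
    "ess",
    "coverage_table",
    "clade_support",
    "max_support_difference",
    "read_trace",
    "write_trace",
    "read_nexus_trees",
    "write_nexus_trees",
]


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(level * n) of the sorted samples.

    Ties between equally short windows resolve to the earliest (lowest
    lower bound), making the estimator deterministic.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(samples, float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    m = int(math.ceil(level * n))
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: earliest window
    return float(x[i]), float(x[i + m - 1])


def credible_set(samples, level: float = 0.95) -> set:
    """Smallest set of categorical values reaching cumulative mass >= level.

    Values enter in order of decreasing posterior frequency; ties break
    toward the smaller value (registry order for model indicators).
    """
    arr = np.asarray(samples)
    if arr.size == 0:
        raise ValueError("need at least one sample")
    values, counts = np.unique(arr, return_counts=True)
    order = np.lexsort((values, -counts))
    freq = counts[order] / arr.size
    cum = np.cumsum(freq)
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    return set(values[order][:min(k, len(values))].tolist())


def ess(samples) -> float:
    """Effective sample size from the autocorrelation function.

    n / (1 + 2 sum rho_k) with the sum truncated by the initial positive
    sequence rule (stop when a consecutive pair of autocorrelations turns
    non-positive), the convention of the standard trace analyzers.
    Zero-variance input is defined to have ESS n.
    """
    x = np.asarray(samples, float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0:
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    total = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0.0:
            break
        total += pair
        k += 2
    return float(n / (1.0 + 2.0 * total))


# ---------------------------------------------------------------------------
# coverage

_CONTINUOUS_ROWS = [
    ("gamma Shape", "gammaShape"),
    ("Proportion Invariable", "proportionInvariable"),
    ("Tree Height", "treeHeight"),
    ("Yule Model", "yuleDensity"),
    ("birth Rate", "birthRate"),
    ("ucldStdev", "ucldStdev"),
]


def _truth_value(row_name: str, truth) -> float | None:
    """True value for a coverage row, or None when the truth lacks it ('x')."""
    site = truth.site
    if row_name == "gamma Shape":
        return site.alpha if site.has_gamma else None
    if row_name == "Proportion Invariable":
        return site.p_inv if site.has_inv else None
    if row_name == "Tree Height":
        return truth.tree.root_height()
    if row_name == "Yule Model":
        return yule_log_density(truth.tree, truth.yule)
    if row_name == "birth Rate":
        return truth.yule.birth_rate
    if row_name == "ucldStdev":
        return truth.clock.ucld_stdev if truth.clock.kind == "ucln" else None
    raise KeyError(row_name)


def coverage_table(records, level: float = 0.95, burnin: float = 0.1) -> pd.DataFrame:
    """Aggregate replicate records into the coverage percentage table.

    Rows are the monitored quantities; columns are the study conditions.
    An entry is the percentage of replicates whose truth fell inside the
    95% HPD interval (continuous rows) or 95% credible set (indicator and
    flags); NaN marks rows the true model does not parameterize.  Errored
    replicates are excluded from denominators.
    """
    rows = (["Model Indicator", "has Invariable Sites", "has Gamma Rates",
             "use External Freqs"]
            + [name for name, _ in _CONTINUOUS_ROWS]
            + [f"frequencies.{i + 1}" for i in range(20)])
    by_cond: dict[str, list] = {}
    for rec in records:
        by_cond.setdefault(rec.condition.label, []).append(rec)
    table = pd.DataFrame(index=rows, columns=list(by_cond), dtype=float)
    for label, recs in by_cond.items():
        hits: dict[str, list[int]] = {r: [] for r in rows}
        for rec in recs:
            if rec.error is not None or rec.trace is None or len(rec.trace) == 0:
                continue
            trace = rec.trace.iloc[int(burnin * len(rec.trace)):]
            truth = rec.truth
            hits["Model Indicator"].append(
                truth.site.model_indicator in credible_set(
                    trace["modelIndicator"], level))
            hits["has Invariable Sites"].append(
                int(truth.site.has_inv) in credible_set(
                    trace["hasInvariableSites"], level))
            hits["has Gamma Rates"].append(
                int(truth.site.has_gamma) in credible_set(
                    trace["hasGammaRates"], level))
            hits["use External Freqs"].append(
                int(truth.site.use_estimated_freqs) in credible_set(
                    trace["useEstimatedFreqs"], level))
            for row_name, column in _CONTINUOUS_ROWS:
                tv = _truth_value(row_name, truth)
                if tv is None:
                    continue
                samples = trace[column].dropna().to_numpy()
                if samples.size < 2:
                    hits[row_name].append(0)
                    continue
                lo, hi = hpd_interval(samples, level)
                hits[row_name].append(int(lo <= tv <= hi))
            if truth.site.use_estimated_freqs:
                for i in range(20):
                    lo, hi = hpd_interval(trace[f"frequencies.{i + 1}"], level)
                    tv = truth.site.estimated_freqs[i]
                    hits[f"frequencies.{i + 1}"].append(int(lo <= tv <= hi))
        for row_name in rows:
            h = hits[row_name]
            table.loc[row_name, label] = 100.0 * np.mean(h) if h else np.nan
    return table


def write_coverage_table(table: pd.DataFrame, path) -> None:
    """Tab-separated coverage table; 'x' marks unparameterized entries."""
    out = table.map(lambda v: "x" if pd.isna(v) else f"{v:.0f}")
    out.index.name = "True model:"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# clade support

def clade_support(trees: list[TimeTree]) -> dict[frozenset, float]:
    """Posterior support (fraction of trees) for every non-trivial clade."""
    if not trees:
        raise ValueError("empty tree log")
    taxa = frozenset(trees[0].labels)
    counts: dict[frozenset, int] = {}
    for tree in trees:
        if frozenset(tree.labels) != taxa:
            raise ValueError("tree logs must share one taxon set")
        for clade in set(tree.clade_bitsets().values()):
            counts[clade] = counts.get(clade, 0) + 1
    return {clade: c / len(trees) for clade, c in counts.items()}


def max_support_difference(a: dict[frozenset, float],
                           b: dict[frozenset, float]) -> float:
    """Largest clade-support difference between two analyses, in percent.

    Scans the union of clades (the root clade, supported 1.0 in both, is
    excluded by dropping the full taxon set).
    """
    taxa_a = frozenset().union(*a) if a else frozenset()
    taxa_b = frozenset().union(*b) if b else frozenset()
    if taxa_a != taxa_b:
        raise ValueError("clade tables are over different taxon sets")
    best = 0.0
    for clade in set(a) | set(b):
        if clade == taxa_a:
            continue
        best = max(best, abs(a.get(clade, 0.0) - b.get(clade, 0.0)))
    return 100.0 * best


# ---------------------------------------------------------------------------
# I/O

def write_trace(trace: pd.DataFrame, path) -> None:
    cols = ["Sample"] + [c for c in trace.columns if c != "Sample"]
    trace[cols].to_csv(path, sep="\t", index=False)


def read_trace(path) -> pd.DataFrame:
    trace = pd.read_csv(path, sep="\t")
    if "Sample" not in trace.columns:
        raise ValueError(f"{path}: not a trace log (no Sample column)")
    return trace


def write_nexus_trees(trees: list[TimeTree], path) -> None:
    """NEXUS tree log with a translate block, one tree per sample."""
    if not trees:
        raise ValueError("no trees to write")
    labels = trees[0].labels
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBegin trees;\n\tTranslate\n")
        for i, lb in enumerate(labels, start=1):
            sep = "," if i < len(labels) else ""
            fh.write(f"\t\t{i} {lb}{sep}\n")
        fh.write("\t\t;\n")
        index = {lb: str(i) for i, lb in enumerate(labels, start=1)}
        for k, tree in enumerate(trees):
            nwk = tree.to_newick()
            for lb in sorted(index, key=len, reverse=True):
                nwk = _replace_label(nwk, lb, index[lb])
            fh.write(f"tree STATE_{k} = {nwk}\n")
        fh.write("End;\n")


def _replace_label(newick: str, label: str, repl: str) -> str:
    out = []
    i = 0
    while i < len(newick):
        if newick.startswith(label, i) and newick[i - 1] in "(," and \
                newick[i + len(label)] in ":,)":
            out.append(repl)
            i += len(label)
        else:
            out.append(newick[i])
            i += 1
    return "".join(out)


def read_nexus_trees(path) -> list[TimeTree]:
    tl = dendropy.TreeList.get(path=str(path), schema="nexus")
    return [TimeTree.from_dendropy(t) for t in tl]
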