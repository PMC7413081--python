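"""Amino-acid alignments and FASTA I/O.

Sequences are stored as integer codes over the fixed 20-letter alphabet;
gap ``-``, ambiguity ``X`` and any unrecognised letter are encoded as -1
and treated as fully ambiguous (all-ones tip partials) by the likelihood.
"""

from __future__ import annotations

import numpy as np

from .empirical import ALPHABET, AMINO_ACIDS

__all__ = ["AminoAlignment", "read_fasta", "write_fasta"]


class AminoAlignment:
    """A labelled amino-acid multiple alignment."""

    def __init__(self, labels: list[str], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int64)
        if codes.ndim != 2 or codes.shape[0] != len(labels):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if codes.shape[1] == 0:
            raise ValueError("alignment has no sites")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels")
        self.labels = list(labels)
        self.codes = codes

    @classmethod
    def from_sequences(cls, labels: list[str], sequences: list[str]) -> "AminoAlignment":
        if len({len(s) for s in sequences}) != 1:
            raise ValueError("sequences must all have equal length")
        return cls(labels, np.stack([ALPHABET.encode(s) for s in sequences]))

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return int(self.codes.shape[1])

    def sequence(self, i: int) -> str:
        return "".join(AMINO_ACIDS[c] if c >= 0 else "-" for c in self.codes[i])

    def reordered(self, labels: list[str]) -> "AminoAlignment":
        """Rows permuted into the given label order (e.g. a tree's tip order)."""
        pos = {lb: i for i, lb in enumerate(self.labels)}
        missing = [lb for lb in labels if lb not in pos]
        if missing or len(labels) != len(self.labels):
            raise ValueError(f"label mismatch with alignment: {missing}")
        return AminoAlignment(labels, self.codes[[pos[lb] for lb in labels]])


def read_fasta(path) -> AminoAlignment:
    """Parse a FASTA alignment (mixed case tolerated, gaps kept as '-')."""
    labels: list[str] = []
    chunks: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip()
                if not name:
                    raise ValueError(f"{path}: empty sequence name on line {lineno}")
                labels.append(name)
                chunks.append([])
            else:
                if not labels:
                    raise ValueError(f"{path}: sequence data before header on line {lineno}")
                chunks[-1].append(line)
    if not labels:
        raise ValueError(f"{path}: no sequences found")
    return AminoAlignment.from_sequences(labels, ["".join(c) for c in chunks])


def write_fasta(aln: AminoAlignment, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for i, label in enumerate(aln.labels):
            fh.write(f">{label}\n")
            seq = aln.sequence(i)
            for start in range(0, len(seq), width):
                fh.write(seq[start:start + width] + "\n")
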