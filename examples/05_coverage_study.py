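"""A miniature well-calibrated coverage study.

Runs the study driver in oracle mode (posterior replaced by fresh prior
draws) where the 95% intervals must cover the truth ~95% of the time by
construction — the calibration identity — and then one real MCMC
replicate at smoke scale.  The full-size study is
scripts/full_coverage_study.py.
"""

import aamava as am

cfg = am.StudyConfig(
    n_replicates=25,
    conditions=[am.StudyCondition(True, True, True)],
    n_taxa=8, n_sites=5, inference="prior-oracle", oracle_samples=1000)
table, _ = am.run_well_calibrated_study(cfg, rng_seed=3, keep_records=False)
print("oracle-mode coverage (should hover around 95):")
print(table.dropna().to_string(float_format=lambda v: f"{v:5.1f}"))

mcmc_cfg = am.StudyConfig(
    n_replicates=1, conditions=[am.StudyCondition(with_gamma=True)],
    n_taxa=5, n_sites=60, clock_kind="strict",
    chain_length=4000, log_every=20)
table2, records = am.run_well_calibrated_study(mcmc_cfg, rng_seed=4)
print("\none real MCMC replicate (+G condition), covered=100 / missed=0 / x=absent:")
print(table2.to_string(float_format=lambda v: f"{v:3.0f}", na_rep="x"))
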