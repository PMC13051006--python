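"""End-to-end report bundle: simulate a three-experiment study, analyse it.

``run_full`` applies the exclusion rules, computes per-participant SDT
measures, figure data (accuracy, d'/C, quarter trajectories, per-pair CIC),
correlation tables with split-half diagonals, and the ANOVA/t-test panel,
then writes everything as CSVs plus a machine-readable run log.
"""

import afrmatch as am

params = am.GeneratorParams(n_participants=30, seed=1)
trials, participants, _ = am.simulate_study(params, seed=1)

cfg = am.RunConfig(out_dir="scratch/example_report", seed=1,
                   split_half_n_splits=50)
bundle = am.run_full(trials, participants, cfg)

print("tables written:", ", ".join(sorted(bundle)))
print("\nmean unaided criterion per experiment (fig5):")
print(bundle["fig5_criterion"].to_string(index=False))
print("\nCIC-vs-similarity regressions (fig4):")
print(bundle["fig4_regressions"].to_string(index=False))
print("\nTrust scale:", bundle["trust_scale"].iloc[0].to_dict())
print("\nexp1a (graded) keeps the criterion nearest zero; exp1b (binary) and")
print("exp2 (no aid) drift liberal, and only the graded regime shows a")
print("strong positive match-pair CIC regression.")
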