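"""Phenome-wide MR of one protein across many disease outcomes.

Fixes one protein's selected cis instruments and tests them against 150
simulated binary outcomes whose case counts straddle the 50-case filter
(outcomes below 50 cases are excluded before any fitting, as in
FinnGen-style PheWAS). All outcomes here are null, so after BH adjustment
nothing should survive.
"""

from pqtlmr import (
    EstimatorConfig,
    PhewasConfig,
    SimulationConfig,
    manhattan_frame,
    run_phewas,
    select_instruments,
    simulate_exposure,
    simulate_phewas_outcomes,
)

cfg = SimulationConfig(n_proteins=1, seed=13)
exposures, genes, ld, truth = simulate_exposure(cfg)
instruments, counts = select_instruments(exposures["PROT0000"], genes["PROT0000"], ld)
print(f"protein PROT0000: {counts['kept']} instruments selected")

outcomes = simulate_phewas_outcomes(truth, 150, case_count_range=(10, 500))
rows, summary = run_phewas(
    instruments, outcomes,
    PhewasConfig(min_cases=50),
    estimation=EstimatorConfig(seed=1),
)
print(f"{summary['n_outcomes']} outcomes, "
      f"{summary['n_excluded_small_case_count']} excluded below 50 cases, "
      f"{summary['n_tested']} tested")
print(f"{summary['n_nominal']} nominal (p < 0.05), "
      f"{summary['n_fdr_significant']} FDR-significant\n")

m = manhattan_frame(rows).sort_values("minus_log10_p", ascending=False)
print(m.head(5).to_string(index=False, float_format=lambda x: f"{x:.3f}"))
# Under the null ~5% of outcomes are nominally significant by chance;
# the BH-adjusted q-values absorb that multiplicity.
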