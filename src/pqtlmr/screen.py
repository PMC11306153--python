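"""Proteome-wide and phenome-wide MR screening drivers.

``run_protein`` performs one full protein-to-outcome analysis: instrument
selection, outcome-overlap exclusion, harmonization, the estimator suite
and sensitivity diagnostics.  ``run_proteome`` maps it across many
proteins and applies Benjamini-Hochberg FDR control to the primary
(IVW multiplicative-random-effects) p-values; ``run_phewas`` fixes one
protein's instruments and screens many disease outcomes, excluding
outcomes with too few cases before any fitting.

The FDR family is the set of proteins (or outcomes) with a successful
primary fit in the current run.  Per-analysis randomness is derived from
the run seed and the analysis identifier, so results are invariant under
reordering of the inputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from .estimators import EstimatorConfig, MRResult, SensitivityResult
from .harmonize import HarmonizationConfig, InstrumentSet, harmonize
from .instruments import LDMatrix, SelectionConfig, select_instruments
from .sumstats import GeneAnnotation, SummaryStats

log = logging.getLogger(__name__)

ALL_METHODS = ("ivw_mre", "ivw_fe", "egger", "weighted_median", "weighted_mode")

PRIMARY_METHOD = "ivw_mre"


@dataclass(frozen=True)
class PhewasConfig:
    """Outcome filter for the phenome-wide screen."""

    min_cases: int = 50
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


@dataclass
class ScreenRow:
    """One exposure-outcome analysis within a screen."""

    exposure_id: str
    outcome_id: str
    status: str  # ok | no_instruments | skipped_small_L
    results: dict[str, MRResult] = field(default_factory=dict)
    sensitivity: SensitivityResult | None = None
    instruments: InstrumentSet | None = None
    selection_log: dict[str, int] = field(default_factory=dict)
    p_fdr: float | None = None

    @property
    def primary(self) -> MRResult | None:
        return self.results.get(PRIMARY_METHOD)


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are excluded from the family size m and returned as NaN;
    any finite value outside (0, 1] raises.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if np.any((p[mask] <= 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _derive_seed(base_seed: int | None, analysis_id: str) -> int:
    """Deterministic per-analysis seed, stable under input reordering."""
    base = 0 if base_seed is None else int(base_seed)
    return (base ^ zlib.crc32(analysis_id.encode())) % (2**31 - 1)


def run_protein(
    exposure: SummaryStats,
    gene: GeneAnnotation,
    outcome: SummaryStats,
    ld: LDMatrix,
    selection: SelectionConfig | None = None,
    harmonization: HarmonizationConfig | None = None,
    estimation: EstimatorConfig | None = None,
    methods: Sequence[str] = ALL_METHODS,
    run_presso: bool = True,
    run_sensitivity: bool = True,
    min_instruments: int = 1,
) -> ScreenRow:
    """One protein-to-outcome MR analysis, end to end.

    Deterministic given the estimator seed.  ``methods`` restricts the
    estimator suite (the primary IVW-MRE is always computed); methods whose
    minimum instrument count is not met are skipped with a log entry.
    """
    selection = selection or SelectionConfig()
    harmonization = harmonization or HarmonizationConfig()
    estimation = estimation or EstimatorConfig(seed=0)

    selected, counts = select_instruments(exposure, gene, ld, selection, outcome=outcome)
    if len(selected) == 0:
        log.info("%s: no instruments survive selection", exposure.trait_id)
        return ScreenRow(exposure.trait_id, outcome.trait_id, "no_instruments", selection_log=counts)

    instruments = harmonize(selected, outcome, harmonization)
    L = len(instruments)
    if L == 0:
        return ScreenRow(
            exposure.trait_id, outcome.trait_id, "no_instruments",
            instruments=instruments, selection_log=counts,
        )
    if L < min_instruments:
        return ScreenRow(
            exposure.trait_id, outcome.trait_id, "skipped_small_L",
            instruments=instruments, selection_log=counts,
        )

    results: dict[str, MRResult] = {}
    results[PRIMARY_METHOD] = est.ivw(instruments, "mre", estimation)
    if "ivw_fe" in methods:
        results["ivw_fe"] = est.ivw(instruments, "fe", estimation)
    if "egger" in methods and L >= 3:
        egger_res, _ = est.mr_egger(instruments, estimation)
        results["egger"] = egger_res
    if "weighted_median" in methods and L >= 3:
        results["weighted_median"] = est.weighted_median(instruments, estimation)
    if "weighted_mode" in methods and L >= 3:
        results["weighted_mode"] = est.weighted_mode(instruments, estimation)

    sensitivity = None
    corrected = None
    if run_sensitivity:
        sensitivity, corrected = est.sensitivity_suite(
            instruments, estimation, run_presso=run_presso and L >= 4
        )
    if corrected is not None:
        results["presso_corrected"] = corrected

    return ScreenRow(
        exposure.trait_id,
        outcome.trait_id,
        "ok",
        results=results,
        sensitivity=sensitivity,
        instruments=instruments,
        selection_log=counts,
    )


def _apply_fdr(rows: list[ScreenRow]) -> None:
    ok = [r for r in rows if r.status == "ok" and r.primary is not None]
    if not ok:
        return
    q = bh_fdr([r.primary.pvalue for r in ok])
    for row, qv in zip(ok, q):
        row.p_fdr = float(qv)


def run_proteome(
    exposures: Mapping[str, SummaryStats] | Sequence[SummaryStats],
    genes: Mapping[str, GeneAnnotation],
    outcome: SummaryStats,
    ld: LDMatrix,
    selection: SelectionConfig | None = None,
    harmonization: HarmonizationConfig | None = None,
    estimation: EstimatorConfig | None = None,
    methods: Sequence[str] = ALL_METHODS,
    run_presso: bool = True,
    run_sensitivity: bool = True,
) -> tuple[list[ScreenRow], dict]:
    """One MR analysis per protein, with BH-FDR over the primary p-values.

    Returns the rows (one per protein, input order) and a run summary with
    the FDR family size and the counts of nominal (p < 0.05) and
    FDR-significant (q < 0.05) proteins.
    """
    if isinstance(exposures, Mapping):
        items = list(exposures.values())
    else:
        items = list(exposures)
    if not items:
        raise ValueError("run_proteome requires at least one exposure")
    estimation = estimation or EstimatorConfig(seed=0)

    rows: list[ScreenRow] = []
    for exposure in items:
        gene = genes[exposure.trait_id]
        per_cfg = EstimatorConfig(
            bootstrap_iterations=estimation.bootstrap_iterations,
            presso_simulations=estimation.presso_simulations,
            mode_bandwidth_multiplier=estimation.mode_bandwidth_multiplier,
            seed=_derive_seed(estimation.seed, exposure.trait_id),
            ci_level=estimation.ci_level,
            mre_variance_floor=estimation.mre_variance_floor,
        )
        rows.append(
            run_protein(
                exposure, gene, outcome, ld,
                selection, harmonization, per_cfg,
                methods=methods, run_presso=run_presso, run_sensitivity=run_sensitivity,
            )
        )
        if log.isEnabledFor(logging.INFO):
            log.info("screen %s: %s", exposure.trait_id, rows[-1].status)

    _apply_fdr(rows)
    ok = [r for r in rows if r.status == "ok"]
    summary = {
        "n_proteins": len(rows),
        "n_ok": len(ok),
        "fdr_family_size": len(ok),
        "n_nominal": sum(r.primary.pvalue < 0.05 for r in ok),
        "n_fdr_significant": sum(r.p_fdr < 0.05 for r in ok),
    }
    return rows, summary


def run_phewas(
    instruments_source: SummaryStats,
    outcomes: Iterable[SummaryStats],
    cfg: PhewasConfig | None = None,
    harmonization: HarmonizationConfig | None = None,
    estimation: EstimatorConfig | None = None,
    selection: SelectionConfig | None = None,
    methods: Sequence[str] = ("ivw_mre",),
) -> tuple[list[ScreenRow], dict]:
    """Screen one protein's instruments against many disease outcomes.

    ``instruments_source`` is the protein's already-selected instrument
    table.  Outcomes with fewer than ``min_cases`` cases are excluded
    before any fitting; each retained outcome is re-harmonized and fitted
    independently, then BH-FDR is applied across the retained family.
    """
    cfg = cfg or PhewasConfig()
    selection = selection or SelectionConfig()
    estimation = estimation or EstimatorConfig(seed=0)
    outcomes = list(outcomes)
    ids = [o.trait_id for o in outcomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate outcome ids in PheWAS input")

    rows: list[ScreenRow] = []
    n_excluded = 0
    for outcome in outcomes:
        if outcome.n_cases is None or outcome.n_cases < cfg.min_cases:
            n_excluded += 1
            continue
        from .instruments import exclude_outcome_associated

        kept = exclude_outcome_associated(instruments_source, outcome, selection)
        instruments = harmonize(kept, outcome, harmonization or HarmonizationConfig())
        if len(instruments) == 0:
            rows.append(
                ScreenRow(instruments_source.trait_id, outcome.trait_id, "no_instruments")
            )
            continue
        per_cfg = EstimatorConfig(
            bootstrap_iterations=estimation.bootstrap_iterations,
            presso_simulations=estimation.presso_simulations,
            mode_bandwidth_multiplier=estimation.mode_bandwidth_multiplier,
            seed=_derive_seed(estimation.seed, outcome.trait_id),
            ci_level=estimation.ci_level,
            mre_variance_floor=estimation.mre_variance_floor,
        )
        results = {PRIMARY_METHOD: est.ivw(instruments, "mre", per_cfg)}
        L = len(instruments)
        if "egger" in methods and L >= 3:
            results["egger"] = est.mr_egger(instruments, per_cfg)[0]
        if "weighted_median" in methods and L >= 3:
            results["weighted_median"] = est.weighted_median(instruments, per_cfg)
        sens = est.cochran_q(instruments) if L >= 2 else None
        rows.append(
            ScreenRow(
                instruments_source.trait_id, outcome.trait_id, "ok",
                results=results, sensitivity=sens, instruments=instruments,
            )
        )

    _apply_fdr(rows)
    ok = [r for r in rows if r.status == "ok"]
    summary = {
        "n_outcomes": len(outcomes),
        "n_excluded_small_case_count": n_excluded,
        "n_tested": len(ok),
        "n_nominal": sum(r.primary.pvalue < 0.05 for r in ok),
        "n_fdr_significant": sum(r.p_fdr < 0.05 for r in ok),
    }
    return rows, summary


# ---------------------------------------------------------------------------
# tabular outputs


def results_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """One row per (exposure, outcome, method): n_snp, beta, se, OR, CI, p, q."""
    records = []
    for row in rows:
        for method, res in row.results.items():
            records.append(
                {
                    "exposure_id": row.exposure_id,
                    "outcome_id": row.outcome_id,
                    "method": method,
                    "n_snp": res.n_snp,
                    "beta": res.beta,
                    "se": res.se,
                    "or": res.or_point,
                    "or_lcl": res.or_lcl,
                    "or_ucl": res.or_ucl,
                    "pvalue": res.pvalue,
                    "p_fdr": row.p_fdr if method == PRIMARY_METHOD else np.nan,
                    "status": row.status,
                }
            )
        if not row.results:
            records.append(
                {
                    "exposure_id": row.exposure_id,
                    "outcome_id": row.outcome_id,
                    "method": None,
                    "n_snp": 0,
                    "beta": np.nan,
                    "se": np.nan,
                    "or": np.nan,
                    "or_lcl": np.nan,
                    "or_ucl": np.nan,
                    "pvalue": np.nan,
                    "p_fdr": np.nan,
                    "status": row.status,
                }
            )
    return pd.DataFrame.from_records(records)


def sensitivity_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    records = []
    for row in rows:
        s = row.sensitivity or SensitivityResult()
        records.append(
            {
                "exposure_id": row.exposure_id,
                "outcome_id": row.outcome_id,
                "q": s.q,
                "q_df": s.q_df,
                "q_pvalue": s.q_pvalue,
                "egger_intercept": s.egger_intercept,
                "egger_intercept_se": s.egger_intercept_se,
                "egger_intercept_p": s.egger_intercept_p,
                "presso_global_p": s.presso_global_p,
                "presso_outliers": ",".join(s.presso_outliers),
            }
        )
    return pd.DataFrame.from_records(records)


def volcano_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Per-protein (beta, -log10 p) table for volcano plotting."""
    ok = [r for r in rows if r.status == "ok"]
    return pd.DataFrame(
        {
            "exposure_id": [r.exposure_id for r in ok],
            "beta": [r.primary.beta for r in ok],
            "or": [r.primary.or_point for r in ok],
            "minus_log10_p": [-np.log10(r.primary.pvalue) for r in ok],
            "p_fdr": [r.p_fdr for r in ok],
        }
    )


def manhattan_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Per-outcome -log10 p table for Manhattan plotting of a PheWAS."""
    ok = [r for r in rows if r.status == "ok"]
    return pd.DataFrame(
        {
            "outcome_id": [r.outcome_id for r in ok],
            "beta": [r.primary.beta for r in ok],
            "minus_log10_p": [-np.log10(r.primary.pvalue) for r in ok],
            "p_fdr": [r.p_fdr for r in ok],
        }
    )


def write_run_log(path: str | Path, entries: Iterable[Mapping]) -> None:
    """Append structured JSON-lines records (thresholds, seeds, statuses)."""
    with open(path, "a") as fh:
        for entry in entries:
            fh.write(json.dumps(entry, default=str) + "\n")
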