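"""Per-analysis reports and run summaries; the single place numbers are formatted.

Stored values keep full precision everywhere; rounding happens only here,
at the text layer: odds ratios and CI bounds to 2 decimals, p-values in
scientific notation with the mantissa to 2 decimals (e.g. ``3.96E-05``).
Formatting is locale-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonize import InstrumentSet
from .instruments import f_statistic
from .screen import ScreenRow

METHOD_LABELS = {
    "ivw_mre": "IVW",
    "ivw_fe": "IVW (fixed effects)",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "weighted_mode": "Weighted mode",
    "presso_corrected": "MR-PRESSO (outlier-corrected)",
    "wald": "Wald ratio",
}


def format_or(value: float) -> str:
    return f"{value:.2f}"


def format_p(value: float) -> str:
    return f"{value:.2E}"


@dataclass
class AnalysisReport:
    """A formatted per-analysis table: one row per method, plus diagnostics."""

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame  # method, n_snp, or, lcl, ucl, p (all strings except n_snp)
    heterogeneity_p: str | None
    pleiotropy_p: str | None
    f_range: tuple[float, float] | None
    status: str = "ok"

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(Path(path), sep="\t", index=False)

    def __str__(self) -> str:
        lines = [f"# {self.exposure_id} -> {self.outcome_id} [{self.status}]"]
        lines.append(self.rows.to_string(index=False))
        if self.heterogeneity_p is not None:
            lines.append(f"P for heterogeneity: {self.heterogeneity_p}")
        if self.pleiotropy_p is not None:
            lines.append(f"P for pleiotropy (Egger intercept): {self.pleiotropy_p}")
        if self.f_range is not None:
            lines.append(f"Instrument F range: {self.f_range[0]:.2f} - {self.f_range[1]:.2f}")
        return "\n".join(lines)


def build_report(row: ScreenRow, instruments: InstrumentSet | None = None) -> AnalysisReport:
    """Assemble the formatted method-by-method report for one analysis."""
    if row.status != "ok":
        return AnalysisReport(
            row.exposure_id,
            row.outcome_id,
            pd.DataFrame(columns=["method", "n_snp", "or", "lcl", "ucl", "p"]),
            None,
            None,
            None,
            status=row.status,
        )
    instruments = instruments if instruments is not None else row.instruments
    records = []
    for method in ("ivw_mre", "egger", "weighted_median", "weighted_mode", "ivw_fe",
                   "presso_corrected", "wald"):
        res = row.results.get(method)
        if res is None:
            continue
        records.append(
            {
                "method": METHOD_LABELS[method],
                "n_snp": res.n_snp,
                "or": format_or(res.or_point),
                "lcl": format_or(res.or_lcl),
                "ucl": format_or(res.or_ucl),
                "p": format_p(res.pvalue),
            }
        )
    het_p = None
    pleio_p = None
    if row.sensitivity is not None:
        if row.sensitivity.q_pvalue is not None:
            het_p = f"{row.sensitivity.q_pvalue:.3f}"
        if row.sensitivity.egger_intercept_p is not None:
            pleio_p = f"{row.sensitivity.egger_intercept_p:.3f}"
    f_range = None
    if instruments is not None and len(instruments) > 0:
        f = f_statistic(instruments.beta_x, instruments.se_x)
        f_range = (float(np.min(f)), float(np.max(f)))
    return AnalysisReport(
        row.exposure_id, row.outcome_id, pd.DataFrame.from_records(records),
        het_p, pleio_p, f_range,
    )


def summary_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Run-level one-row-per-analysis summary (primary method, formatted)."""
    records = []
    for row in rows:
        primary = row.primary
        records.append(
            {
                "exposure_id": row.exposure_id,
                "outcome_id": row.outcome_id,
                "status": row.status,
                "n_snp": primary.n_snp if primary else 0,
                "or": format_or(primary.or_point) if primary else "",
                "lcl": format_or(primary.or_lcl) if primary else "",
                "ucl": format_or(primary.or_ucl) if primary else "",
                "p": format_p(primary.pvalue) if primary else "",
                "p_fdr": format_p(row.p_fdr) if row.p_fdr is not None else "",
            }
        )
    return pd.DataFrame.from_records(records)
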