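"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs both effect estimates per variant expressed for the
*same* effect allele.  For each variant matched by id between the exposure
and outcome tables, the outcome record is aligned to the exposure's effect
allele:

* identical allele labels -> kept as-is;
* swapped labels (effect/other exchanged) -> outcome beta negated, outcome
  frequency complemented;
* complementary-strand labels (A<->T, C<->G) -> resolved to one of the two
  cases above when strand flipping is allowed;
* palindromic variants (A/T or C/G pairs), whose strand cannot be inferred
  from labels, are kept only when both allele frequencies are available,
  lie outside a configurable ambiguity zone around 0.5, and fall on the
  same side of 0.5 after alignment — otherwise they are dropped;
* anything else is dropped as incompatible; variants missing from the
  outcome are dropped as unmatched.

Every per-variant decision is recorded in a harmonization log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .sumstats import SummaryStats

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns of the harmonized pair table.
PAIR_COLUMNS = [
    "variant_id",
    "beta_x",
    "se_x",
    "beta_y",
    "se_y",
    "eaf_x",
    "eaf_y",
    "p_x",
    "p_y",
]

ACTIONS = (
    "kept",
    "sign_flipped",
    "strand_flipped",
    "dropped_palindromic",
    "dropped_incompatible",
    "dropped_missing",
)


@dataclass(frozen=True)
class HarmonizationConfig:
    """Palindrome policy.

    ``palindromic_eaf_tolerance`` is the half-width of the frequency
    ambiguity zone around 0.5: a palindromic variant with either aligned
    frequency inside (0.5 - tol, 0.5 + tol) is dropped.  Setting
    ``allow_strand_flip`` to False drops all complementary-strand matches
    as incompatible instead of resolving them.
    """

    palindromic_eaf_tolerance: float = 0.08
    allow_strand_flip: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.palindromic_eaf_tolerance < 0.5:
            raise ValueError("palindromic_eaf_tolerance must lie in [0, 0.5)")


@dataclass(frozen=True)
class InstrumentPair:
    """One harmonized instrument: exposure and outcome effects on a shared allele."""

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None = None
    eaf_y: float | None = None
    p_x: float | None = None
    p_y: float | None = None


@dataclass
class InstrumentSet:
    """Harmonized per-SNP effect pairs for one exposure-outcome analysis.

    ``table`` holds the kept pairs (:data:`PAIR_COLUMNS`); ``actions`` maps
    every matched-or-attempted variant_id to its harmonization action.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    actions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def __post_init__(self) -> None:
        if self.table["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_id in instrument set")

    @property
    def pairs(self) -> Iterator[InstrumentPair]:
        for row in self.table.itertuples(index=False):
            yield InstrumentPair(
                variant_id=row.variant_id,
                beta_x=float(row.beta_x),
                se_x=float(row.se_x),
                beta_y=float(row.beta_y),
                se_y=float(row.se_y),
                eaf_x=None if pd.isna(row.eaf_x) else float(row.eaf_x),
                eaf_y=None if pd.isna(row.eaf_y) else float(row.eaf_y),
                p_x=None if pd.isna(row.p_x) else float(row.p_x),
                p_y=None if pd.isna(row.p_y) else float(row.p_y),
            )

    # array accessors used throughout the estimators
    @property
    def beta_x(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy(dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(dtype=float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy(dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(dtype=float)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["variant_id"].to_numpy()

    @classmethod
    def from_arrays(
        cls,
        beta_x,
        se_x,
        beta_y,
        se_y,
        *,
        variant_ids=None,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
        p_x=None,
        p_y=None,
        eaf_x=None,
        eaf_y=None,
    ) -> "InstrumentSet":
        """Build a set directly from effect arrays (simulation and testing aid)."""
        beta_x = np.asarray(beta_x, dtype=float)
        n = beta_x.size
        if variant_ids is None:
            variant_ids = [f"snp{i:04d}" for i in range(n)]
        table = pd.DataFrame(
            {
                "variant_id": list(variant_ids),
                "beta_x": beta_x,
                "se_x": np.asarray(se_x, dtype=float),
                "beta_y": np.asarray(beta_y, dtype=float),
                "se_y": np.asarray(se_y, dtype=float),
                "eaf_x": np.nan if eaf_x is None else np.asarray(eaf_x, dtype=float),
                "eaf_y": np.nan if eaf_y is None else np.asarray(eaf_y, dtype=float),
                "p_x": np.nan if p_x is None else np.asarray(p_x, dtype=float),
                "p_y": np.nan if p_y is None else np.asarray(p_y, dtype=float),
            }
        )
        return cls(exposure_id, outcome_id, table, {v: "kept" for v in table["variant_id"]})


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    cfg: HarmonizationConfig | None = None,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect alleles, variant by variant.

    Matching is by ``variant_id`` only.  Returns an :class:`InstrumentSet`
    whose ``actions`` log partitions all exposure variants into kept /
    flipped / dropped categories.
    """
    cfg = cfg or HarmonizationConfig()
    exp = exposure.table
    out = outcome.indexed().reindex(exp["variant_id"])

    n = len(exp)
    action = np.full(n, "", dtype=object)
    flip = np.zeros(n, dtype=bool)

    beta_y_raw = out["beta"].to_numpy(dtype=float)
    se_y = out["se"].to_numpy(dtype=float)
    p_y = out["pvalue"].to_numpy(dtype=float)
    matched = ~np.isnan(beta_y_raw)
    action[~matched] = "dropped_missing"

    ea_x = exp["effect_allele"].to_numpy(dtype=object)
    oa_x = exp["other_allele"].to_numpy(dtype=object)
    ea_y = out["effect_allele"].to_numpy(dtype=object)
    oa_y = out["other_allele"].to_numpy(dtype=object)

    comp = np.vectorize(lambda a: COMPLEMENT.get(a, "N"), otypes=[object])
    cea_y = comp(np.where(matched, ea_y, "N"))
    coa_y = comp(np.where(matched, oa_y, "N"))

    palindromic = comp(ea_x) == oa_x
    same = matched & (ea_y == ea_x) & (oa_y == oa_x)
    swapped = matched & (ea_y == oa_x) & (oa_y == ea_x)
    strand_same = matched & (cea_y == ea_x) & (coa_y == oa_x)
    strand_swapped = matched & (cea_y == oa_x) & (coa_y == ea_x)

    eaf_x = exp["eaf"].to_numpy(dtype=float)
    eaf_y = out["eaf"].to_numpy(dtype=float)

    # palindromic variants: label alignment is strand-ambiguous; use frequencies
    pal = matched & palindromic & (same | swapped)
    pal_flip = pal & swapped
    with np.errstate(invalid="ignore"):
        eaf_y_aligned = np.where(pal_flip, 1.0 - eaf_y, eaf_y)
        outside = (
            (np.abs(eaf_x - 0.5) >= cfg.palindromic_eaf_tolerance)
            & (np.abs(eaf_y_aligned - 0.5) >= cfg.palindromic_eaf_tolerance)
        )
        same_side = (eaf_x - 0.5) * (eaf_y_aligned - 0.5) > 0
    resolvable = (
        pal
        & ~np.isnan(eaf_x)
        & ~np.isnan(eaf_y)
        & np.where(np.isnan(eaf_x) | np.isnan(eaf_y), False, outside & same_side)
    )
    action[pal & ~resolvable] = "dropped_palindromic"
    action[resolvable & ~pal_flip] = "kept"
    action[resolvable & pal_flip] = "sign_flipped"
    flip |= resolvable & pal_flip

    # non-palindromic variants
    npal = matched & ~palindromic
    action[npal & same] = "kept"
    action[npal & swapped] = "sign_flipped"
    flip |= npal & swapped
    if cfg.allow_strand_flip:
        sflip = npal & ~same & ~swapped & (strand_same | strand_swapped)
        action[sflip] = "strand_flipped"
        flip |= sflip & strand_swapped
    incompatible = matched & (action == "")
    action[incompatible] = "dropped_incompatible"
    # palindromic exposure variants whose outcome labels are neither identical
    # nor swapped carry a genuinely different allele pair
    action[matched & palindromic & ~(same | swapped)] = "dropped_incompatible"

    keep = np.isin(action, ("kept", "sign_flipped", "strand_flipped"))
    beta_y = np.where(flip, -beta_y_raw, beta_y_raw)
    with np.errstate(invalid="ignore"):
        eaf_y_out = np.where(flip, 1.0 - eaf_y, eaf_y)

    variant_ids = exp["variant_id"].to_numpy()
    table = pd.DataFrame(
        {
            "variant_id": variant_ids[keep],
            "beta_x": exp["beta"].to_numpy(dtype=float)[keep],
            "se_x": exp["se"].to_numpy(dtype=float)[keep],
            "beta_y": beta_y[keep],
            "se_y": se_y[keep],
            "eaf_x": eaf_x[keep],
            "eaf_y": eaf_y_out[keep],
            "p_x": exp["pvalue"].to_numpy(dtype=float)[keep],
            "p_y": p_y[keep],
        }
    )

    actions = dict(zip(variant_ids, action))
    if log.isEnabledFor(logging.INFO):
        counts = pd.Series(list(actions.values())).value_counts().to_dict()
        log.info("harmonize %s vs %s: %s", exposure.trait_id, outcome.trait_id, counts)
    return InstrumentSet(exposure.trait_id, outcome.trait_id, table, actions)


def orient_positive_exposure(instruments: InstrumentSet) -> InstrumentSet:
    """Re-express every pair so the exposure effect is non-negative.

    Jointly negates (beta_x, beta_y) — an allele relabelling — wherever
    beta_x < 0, and complements the aligned frequencies accordingly.
    Ratio-based estimators (Wald, IVW, median) are invariant under this;
    the Egger intercept is not, which is why Egger applies it internally.
    """
    t = instruments.table
    neg = t["beta_x"].to_numpy() < 0
    if not neg.any():
        return InstrumentSet(
            instruments.exposure_id, instruments.outcome_id, t.copy(), dict(instruments.actions)
        )
    sign = np.where(neg, -1.0, 1.0)
    with np.errstate(invalid="ignore"):
        flipped = pd.DataFrame(
            {
                "variant_id": t["variant_id"].to_numpy(),
                "beta_x": t["beta_x"].to_numpy() * sign,
                "se_x": t["se_x"].to_numpy(dtype=float),
                "beta_y": t["beta_y"].to_numpy() * sign,
                "se_y": t["se_y"].to_numpy(dtype=float),
                "eaf_x": np.where(neg, 1.0 - t["eaf_x"].to_numpy(dtype=float), t["eaf_x"].to_numpy(dtype=float)),
                "eaf_y": np.where(neg, 1.0 - t["eaf_y"].to_numpy(dtype=float), t["eaf_y"].to_numpy(dtype=float)),
                "p_x": t["p_x"].to_numpy(dtype=float),
                "p_y": t["p_y"].to_numpy(dtype=float),
            }
        )
    return InstrumentSet(
        instruments.exposure_id, instruments.outcome_id, flipped, dict(instruments.actions)
    )


def write_harmonization_log(instruments: InstrumentSet, path: str | Path) -> None:
    """Emit the per-variant action log as a two-column TSV."""
    frame = pd.DataFrame(
        sorted(instruments.actions.items()), columns=["variant_id", "action"]
    )
    frame.to_csv(Path(path), sep="\t", index=False)
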