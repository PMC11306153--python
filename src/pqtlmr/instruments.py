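"""cis-pQTL instrument selection.

Instruments for one protein are chosen from its pQTL summary statistics by
composing, in order:

1. genome-wide significance (p strictly below 5e-8 by default);
2. exclusion of the extended MHC region (chr6:28,477,897-33,448,354),
   whose extreme LD makes instruments there untrustworthy;
3. the cis filter — within 1 Mb of the gene body encoding the protein;
4. greedy LD clumping at r^2 > 0.001 within 10,000 kb;
5. a per-variant instrument-strength filter, F = (beta/se)^2 > 10.

Exclusion of variants genome-wide significant for the *outcome* is applied
by the screening driver after instruments are matched to the outcome table.

All filters are idempotent and (1)-(3) mutually commute; clumping is
order-sensitive and always runs after them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .sumstats import SummaryStats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the instrument-selection pipeline.

    Defaults are the conventional values for cis-pQTL two-sample MR:
    genome-wide significance 5e-8, 1 Mb cis-window around the gene body,
    extended MHC on chromosome 6, clumping at r^2 0.001 within 10,000 kb,
    outcome-overlap exclusion at 5e-8, and minimum per-variant F of 10.
    """

    p_threshold: float = 5e-8
    cis_window: int = 1_000_000
    mhc_chromosome: str = "6"
    mhc_start: int = 28_477_897
    mhc_end: int = 33_448_354
    clump_r2: float = 0.001
    clump_window: int = 10_000_000
    outcome_p_exclusion: float = 5e-8
    f_min: float = 10.0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "cis_window", "clump_window", "outcome_p_exclusion", "f_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.clump_r2 < 1:
            raise ValueError("clump_r2 must lie in (0, 1)")
        if self.mhc_start > self.mhc_end:
            raise ValueError("mhc_start must be <= mhc_end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class LDMatrixError(ValueError):
    """The LD input violates symmetry / range invariants."""


class LDMatrix:
    """Pairwise squared correlations between variants.

    Stored sparsely as (i, j) -> r^2 pairs; any pair not recorded is
    uncorrelated (r^2 = 0) and every variant has r^2 = 1 with itself.
    Construct from a dense matrix, a pair table, or LD blocks.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._pairs: dict[tuple[str, str], float] = {}
        self._ids: set[str] = set()
        if pairs:
            for (a, b), r2 in pairs.items():
                self._set(a, b, float(r2))

    def _set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise LDMatrixError(f"r2 out of [0,1] for ({a},{b}): {r2}")
        self._ids.update((a, b))
        if a == b:
            if not np.isclose(r2, 1.0):
                raise LDMatrixError(f"diagonal r2 must be 1, got {r2} for {a}")
            return
        key = (a, b) if a < b else (b, a)
        existing = self._pairs.get(key)
        if existing is not None and not np.isclose(existing, r2):
            raise LDMatrixError(f"conflicting r2 for pair {key}: {existing} vs {r2}")
        self._pairs[key] = r2

    @classmethod
    def from_dense(cls, variant_ids: Sequence[str], r2: np.ndarray) -> "LDMatrix":
        r2 = np.asarray(r2, dtype=float)
        k = len(variant_ids)
        if r2.shape != (k, k):
            raise LDMatrixError(f"matrix shape {r2.shape} does not match {k} ids")
        if not np.allclose(r2, r2.T):
            raise LDMatrixError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise LDMatrixError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise LDMatrixError("LD r2 values must lie in [0,1]")
        obj = cls()
        ii, jj = np.nonzero(np.triu(r2, k=1))
        for i, j in zip(ii, jj):
            obj._set(variant_ids[i], variant_ids[j], float(np.clip(r2[i, j], 0, 1)))
        return obj

    @classmethod
    def from_pairs_tsv(cls, path: str | Path) -> "LDMatrix":
        """Read a TSV of (id_i, id_j, r2) pairs."""
        frame = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "r2"], comment="#")
        obj = cls()
        for row in frame.itertuples(index=False):
            obj._set(str(row.a), str(row.b), float(row.r2))
        return obj

    @classmethod
    def from_blocks(
        cls, blocks: Mapping[str, Sequence[str]], within_r2: float | Mapping[str, float]
    ) -> "LDMatrix":
        """Build block-diagonal LD: every within-block pair shares one r^2."""
        obj = cls()
        for block_id, members in blocks.items():
            r2 = within_r2[block_id] if isinstance(within_r2, Mapping) else within_r2
            members = list(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    obj._set(members[i], members[j], float(r2))
        return obj

    @classmethod
    def from_blocks_tsv(cls, path: str | Path) -> "LDMatrix":
        """Read a block file: TSV of (block_id, variant_id, within_block_r2)."""
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["block", "variant", "r2"], comment="#"
        )
        blocks: dict[str, list[str]] = {}
        r2s: dict[str, float] = {}
        for row in frame.itertuples(index=False):
            blocks.setdefault(str(row.block), []).append(str(row.variant))
            r2s[str(row.block)] = float(row.r2)
        return cls.from_blocks(blocks, r2s)

    def r2_between(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        return self._pairs.get(key, 0.0)

    def submatrix(self, variant_ids: Sequence[str]) -> np.ndarray:
        ids = list(variant_ids)
        k = len(ids)
        out = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                out[i, j] = out[j, i] = self.r2_between(ids[i], ids[j])
        return out

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._ids

    def to_pairs_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            [(a, b, r2) for (a, b), r2 in sorted(self._pairs.items())],
            columns=["a", "b", "r2"],
        )
        frame.to_csv(Path(path), sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# individual filters


def select_significant(stats: SummaryStats, cfg: SelectionConfig) -> SummaryStats:
    """Keep variants with p strictly below the genome-wide threshold."""
    return stats.subset(stats.table["pvalue"].to_numpy() < cfg.p_threshold)


def exclude_mhc(stats: SummaryStats, cfg: SelectionConfig) -> SummaryStats:
    """Drop variants inside the extended MHC interval (inclusive bounds)."""
    t = stats.table
    in_mhc = (
        (t["chromosome"].to_numpy() == cfg.mhc_chromosome)
        & (t["position"].to_numpy() >= cfg.mhc_start)
        & (t["position"].to_numpy() <= cfg.mhc_end)
    )
    return stats.subset(~in_mhc)


def filter_cis(stats: SummaryStats, gene, cfg: SelectionConfig) -> SummaryStats:
    """Keep variants within ``cis_window`` bp of the gene body, same chromosome."""
    t = stats.table
    in_cis = (
        (t["chromosome"].to_numpy() == gene.chromosome)
        & (t["position"].to_numpy() >= gene.start - cfg.cis_window)
        & (t["position"].to_numpy() <= gene.end + cfg.cis_window)
    )
    return stats.subset(in_cis)


def ld_clump(stats: SummaryStats, ld: LDMatrix, cfg: SelectionConfig) -> SummaryStats:
    """Greedy LD clumping.

    Variants are visited by ascending p-value (ties broken by variant_id);
    each visited variant is kept and all remaining variants on the same
    chromosome within ``clump_window`` bp with r^2 > ``clump_r2`` against it
    are removed.  Variants absent from ``ld`` are treated as uncorrelated.
    """
    t = stats.table
    if t.empty:
        return stats.subset(np.zeros(0, dtype=bool))
    order = t.sort_values(["pvalue", "variant_id"], kind="mergesort").index.to_numpy()
    ids = t["variant_id"].to_numpy()
    chrom = t["chromosome"].to_numpy()
    pos = t["position"].to_numpy()

    missing = [v for v in ids if v not in ld]
    if missing:
        log.info("ld_clump: %d variant(s) absent from LD input, treated as uncorrelated", len(missing))

    alive = dict.fromkeys(order.tolist())
    kept: set[str] = set()
    while alive:
        i = next(iter(alive))
        del alive[i]
        kept.add(ids[i])
        for j in list(alive):
            if (
                chrom[j] == chrom[i]
                and abs(int(pos[j]) - int(pos[i])) <= cfg.clump_window
                and ld.r2_between(ids[i], ids[j]) > cfg.clump_r2
            ):
                del alive[j]
    return stats.subset(np.isin(ids, list(kept)))


def exclude_outcome_associated(
    instruments: SummaryStats, outcome: SummaryStats, cfg: SelectionConfig
) -> SummaryStats:
    """Drop instruments genome-wide significant for (or absent from) the outcome.

    Instruments strongly associated with the outcome could act through
    pathways other than the exposure; instruments missing from the outcome
    table cannot be harmonized and are dropped with a logged count.
    """
    out_p = outcome.indexed()["pvalue"]
    matched_p = out_p.reindex(instruments.table["variant_id"]).to_numpy()
    missing = np.isnan(matched_p)
    if missing.any():
        log.info(
            "exclude_outcome_associated: %d instrument(s) absent from outcome, dropped",
            int(missing.sum()),
        )
    with np.errstate(invalid="ignore"):
        keep = ~missing & ~(matched_p < cfg.outcome_p_exclusion)
    return instruments.subset(keep)


def f_statistic(beta: np.ndarray | float, se: np.ndarray | float) -> np.ndarray | float:
    """Per-variant instrument-strength F statistic, (beta/se)^2 (the squared z-ratio)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be strictly positive")
    f = (beta / se) ** 2
    return float(f) if f.ndim == 0 else f


def filter_f(stats: SummaryStats, cfg: SelectionConfig) -> SummaryStats:
    """Keep variants with F strictly greater than ``f_min``."""
    t = stats.table
    if t.empty:
        return stats.subset(np.zeros(0, dtype=bool))
    f = f_statistic(t["beta"].to_numpy(), t["se"].to_numpy())
    return stats.subset(np.asarray(f) > cfg.f_min)


def select_instruments(
    exposure: SummaryStats,
    gene,
    ld: LDMatrix,
    cfg: SelectionConfig | None = None,
    outcome: SummaryStats | None = None,
) -> tuple[SummaryStats, dict[str, int]]:
    """Run the full selection pipeline for one protein.

    Returns the surviving instruments and a per-step drop-count log.
    When ``outcome`` is given, instruments genome-wide significant for the
    outcome (or absent from it) are additionally excluded; the exclusion
    predicate depends only on outcome p-values, so applying it here or after
    harmonization yields the same instrument set.
    """
    cfg = cfg or SelectionConfig()
    counts: dict[str, int] = {"input": len(exposure)}

    # significance, MHC and cis are independent row predicates (they commute);
    # evaluate them in one pass, counting drops in the sequential order
    t = exposure.table
    p = t["pvalue"].to_numpy()
    chrom = t["chromosome"].to_numpy()
    pos = t["position"].to_numpy()
    m_sig = p < cfg.p_threshold
    m_mhc = ~((chrom == cfg.mhc_chromosome) & (pos >= cfg.mhc_start) & (pos <= cfg.mhc_end))
    m_cis = (
        (chrom == gene.chromosome)
        & (pos >= gene.start - cfg.cis_window)
        & (pos <= gene.end + cfg.cis_window)
    )
    counts["dropped_significance"] = int((~m_sig).sum())
    counts["dropped_mhc"] = int((m_sig & ~m_mhc).sum())
    counts["dropped_cis"] = int((m_sig & m_mhc & ~m_cis).sum())
    current = exposure.subset(m_sig & m_mhc & m_cis)

    clumped = ld_clump(current, ld, cfg)
    counts["dropped_clump"] = len(current) - len(clumped)
    current = filter_f(clumped, cfg)
    counts["dropped_f_filter"] = len(clumped) - len(current)
    if outcome is not None:
        kept = exclude_outcome_associated(current, outcome, cfg)
        counts["dropped_outcome_overlap"] = len(current) - len(kept)
        current = kept
    counts["kept"] = len(current)
    if log.isEnabledFor(logging.INFO):
        log.info("select_instruments %s: %s", exposure.trait_id, counts)
    return current, counts
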