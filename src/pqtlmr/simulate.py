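"""Synthetic GWAS summary-statistics studies with known ground truth.

The generator emulates the structure of a cis-pQTL exposure study paired
with a binary-outcome GWAS: per protein, a gene interval and a handful of
genuinely associated cis variants organised in LD blocks, surrounded by
null cis variants and genome-wide-significant decoys inside the MHC; one
binary outcome whose per-variant effects follow the linear structural
model

    beta_y_j = theta * beta_x_j + alpha_j,

where theta is the causal log-odds effect per SD of protein level and
alpha_j an optional direct (pleiotropic) effect.

Effects live on the standardized-genotype scale, so standard errors follow
the closed forms

    se_x = (2 * maf * (1-maf) * n_exposure)^(-1/2)
    se_y = (2 * maf * (1-maf) * n_eff)^(-1/2),   n_eff = n_ca*n_co/(n_ca+n_co)

which make instrument strength and power analytically controllable.  LD is
simulated at the z-score level (block-correlated noise), sufficient to
exercise clumping deterministically, and outcome allele labels can be
scrambled (swapped / strand-complemented) at configured rates to exercise
harmonization.  Everything is reproducible from (config, seed).

Default dimensions mirror a typical large-scale plasma-proteome MR study:
35,559 exposure samples, a 1,543-case / 391,037-control outcome, and 5
instruments per protein.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import COMPLEMENT, InstrumentSet
from .instruments import LDMatrix
from .sumstats import CANONICAL_COLUMNS, GeneAnnotation, SummaryStats

log = logging.getLogger(__name__)

#: |z| needed for two-sided p = 5e-8
Z_GENOME_WIDE = float(sps.norm.isf(5e-8 / 2))

MHC_START, MHC_END = 28_477_897, 33_448_354

_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and COMPLEMENT[a] != b
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic study.

    ``theta`` may be a scalar (shared by all proteins) or a per-protein
    sequence; 0 makes a protein null.  ``effect_size_range`` gives the
    instrument strength of causal lead variants as a multiple of the
    genome-wide-significance z threshold, guaranteeing detectable
    instruments.  ``invalid_fraction`` is the fraction of instruments per
    protein receiving the pleiotropic effect when ``pleiotropy_mode`` is
    not "none".
    """

    n_proteins: int = 1
    instruments_per_protein: int = 5
    n_exposure: int = 35_559
    n_cases: int = 1_543
    n_controls: int = 391_037
    theta: float | tuple[float, ...] = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    tau: float = 0.0
    mu: float = 0.0
    invalid_fraction: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 3
    ld_block_r2: float = 0.9
    n_null_variants: int = 8
    decoy_fraction_mhc: float = 0.1
    palindrome_fraction: float = 0.0
    allele_swap_rate: float = 0.3
    strand_flip_rate: float = 0.1
    positive_effects: bool = False
    effect_size_range: tuple[float, float] = (1.2, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.instruments_per_protein < 1:
            raise ValueError("instruments_per_protein must be >= 1")
        if self.n_exposure < 2 or self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes too small")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must lie in [0,1]")
        if not 0 < self.ld_block_r2 < 1:
            raise ValueError("ld_block_r2 must lie in (0,1)")
        self.thetas()  # validates per-protein theta length

    def thetas(self) -> np.ndarray:
        if np.isscalar(self.theta):
            return np.full(self.n_proteins, float(self.theta))
        theta = np.asarray(self.theta, dtype=float)
        if theta.size != self.n_proteins:
            raise ValueError("per-protein theta length must equal n_proteins")
        return theta


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study.

    ``variants`` has one row per generated variant: protein, genomic
    placement, MAF, LD block, true exposure effect, pleiotropic effect and
    role (lead / shadow / null / mhc_decoy).
    """

    config: SimulationConfig
    theta: dict[str, float]
    variants: pd.DataFrame
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "theta": self.theta,
            "seed": self.seed,
            "variants": self.variants.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        cfg_dict = payload["config"]
        for key in ("maf_range", "effect_size_range"):
            cfg_dict[key] = tuple(cfg_dict[key])
        if isinstance(cfg_dict["theta"], list):
            cfg_dict["theta"] = tuple(cfg_dict["theta"])
        return cls(
            SimulationConfig(**cfg_dict),
            payload["theta"],
            pd.DataFrame(payload["variants"]),
            payload["seed"],
        )


def se_exposure(maf: np.ndarray, n: int) -> np.ndarray:
    """Standard error of a standardized-trait per-allele effect."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def effective_n(n_cases: int, n_controls: int) -> float:
    return n_cases * n_controls / (n_cases + n_controls)


def _draw_alleles(rng: np.random.Generator, n: int, palindrome_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    pal = rng.random(n) < palindrome_fraction
    pairs = np.empty((n, 2), dtype=object)
    idx_np = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    for i in range(n):
        pairs[i] = _PALINDROMIC_PAIRS[idx_p[i]] if pal[i] else _NONPALINDROMIC_PAIRS[idx_np[i]]
    return pairs[:, 0], pairs[:, 1]


def _block_noise(rng: np.random.Generator, blocks: np.ndarray, r2: float) -> np.ndarray:
    """Unit-variance noise, correlated r = sqrt(r2) within each LD block."""
    n = len(blocks)
    r = np.sqrt(r2)
    shared = {b: rng.standard_normal() for b in pd.unique(blocks)}
    own = rng.standard_normal(n)
    shared_arr = np.array([shared[b] for b in blocks])
    sizes = pd.Series(blocks).map(pd.Series(blocks).value_counts()).to_numpy()
    singleton = sizes == 1
    out = np.where(singleton, own, r * shared_arr + np.sqrt(1 - r2) * own)
    return out


def simulate_exposure(
    cfg: SimulationConfig,
) -> tuple[dict[str, SummaryStats], dict[str, GeneAnnotation], LDMatrix, SimulationTruth]:
    """Generate per-protein exposure tables, gene annotations, LD and truth.

    Each protein receives L causal LD blocks inside its cis window (lead
    variants drawn strong enough to pass genome-wide significance with
    near-certainty), ``n_null_variants`` null cis variants, and
    genome-wide-significant decoy variants inside the MHC on chromosome 6.
    Genes cycle over chromosomes 1-22; genes landing on chromosome 6 are
    placed adjacent to the MHC so the decoys fall inside their cis window
    and the MHC filter does real work.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    thetas = cfg.thetas()
    L = cfg.instruments_per_protein
    bsize = cfg.ld_block_size

    genes: dict[str, GeneAnnotation] = {}
    theta_map: dict[str, float] = {}

    # layout of all variants across all proteins, column-wise
    col_protein: list[str] = []
    col_chrom: list[str] = []
    col_pos: list[int] = []
    col_block: list[str] = []
    col_role: list[str] = []
    col_vid: list[str] = []

    n_core = L * bsize + cfg.n_null_variants
    n_mhc = int(round(cfg.decoy_fraction_mhc * n_core))

    for i in range(cfg.n_proteins):
        protein = f"PROT{i:04d}"
        theta_map[protein] = float(thetas[i])
        chrom = str((i % 22) + 1)
        if chrom == "6":
            gene_start = MHC_END + 200_000
        else:
            gene_start = 50_000_000 + (i // 22) * 3_000_000
        gene_end = gene_start + 10_000
        genes[protein] = GeneAnnotation(protein, chrom, gene_start, gene_end)

        k_var = 0
        # causal blocks (lead + shadows) spread across the cis window
        for b in range(L):
            base = gene_start - 800_000 + b * (1_600_000 // max(L, 1))
            for k in range(bsize):
                col_protein.append(protein)
                col_chrom.append(chrom)
                col_pos.append(base + k * 500)
                col_block.append(f"{protein}_B{b}")
                col_role.append("lead" if k == 0 else "shadow")
                col_vid.append(f"{protein}_V{k_var:04d}")
                k_var += 1
        # null cis variants, each its own block
        null_pos = rng.integers(gene_start - 950_000, gene_end + 950_000, size=cfg.n_null_variants)
        for k in range(cfg.n_null_variants):
            col_protein.append(protein)
            col_chrom.append(chrom)
            col_pos.append(int(null_pos[k]))
            col_block.append(f"{protein}_N{k}")
            col_role.append("null")
            col_vid.append(f"{protein}_V{k_var:04d}")
            k_var += 1
        # MHC decoys: strong associations inside the excluded region
        mhc_pos = rng.integers(MHC_START, MHC_END + 1, size=n_mhc)
        for k in range(n_mhc):
            col_protein.append(protein)
            col_chrom.append("6")
            col_pos.append(int(mhc_pos[k]))
            col_block.append(f"{protein}_M{k}")
            col_role.append("mhc_decoy")
            col_vid.append(f"{protein}_V{k_var:04d}")
            k_var += 1

    n_var = len(col_vid)
    blocks = np.asarray(col_block, dtype=object)
    role = np.asarray(col_role, dtype=object)
    maf = rng.uniform(*cfg.maf_range, size=n_var)
    ea, oa = _draw_alleles(rng, n_var, cfg.palindrome_fraction)
    se_x = se_exposure(maf, cfg.n_exposure)

    # true z-scores: leads strong, shadows attenuated by r, others null/decoy
    lead_mask = role == "lead"
    shadow_mask = role == "shadow"
    decoy_mask = role == "mhc_decoy"
    sign = np.ones(n_var) if cfg.positive_effects else rng.choice([-1.0, 1.0], size=n_var)
    mult = rng.uniform(*cfg.effect_size_range, size=n_var)
    true_z = np.zeros(n_var)
    true_z[lead_mask] = sign[lead_mask] * mult[lead_mask] * Z_GENOME_WIDE
    z_by_block = pd.Series(true_z[lead_mask], index=blocks[lead_mask])
    r = np.sqrt(cfg.ld_block_r2)
    true_z[shadow_mask] = r * z_by_block.reindex(blocks[shadow_mask]).to_numpy()
    true_z[decoy_mask] = sign[decoy_mask] * 2.0 * Z_GENOME_WIDE

    noise = _block_noise(rng, blocks, cfg.ld_block_r2)
    z_obs = true_z + noise
    beta_obs = z_obs * se_x
    pvals = np.maximum(2.0 * sps.norm.sf(np.abs(z_obs)), np.finfo(float).tiny)

    variants = pd.DataFrame(
        {
            "protein": col_protein,
            "chromosome": col_chrom,
            "position": np.asarray(col_pos, dtype=np.int64),
            "block": blocks,
            "role": role,
            "variant_id": col_vid,
            "maf": maf,
            "effect_allele": ea,
            "other_allele": oa,
            "se_x": se_x,
            "true_z_x": true_z,
            "true_beta_x": true_z * se_x,
        }
    )

    full = pd.DataFrame(
        {
            "variant_id": col_vid,
            "chromosome": col_chrom,
            "position": np.asarray(col_pos, dtype=np.int64),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta_obs,
            "se": se_x,
            "pvalue": pvals,
            "n": float(cfg.n_exposure),
            "protein": col_protein,
        }
    )
    exposures: dict[str, SummaryStats] = {}
    for protein, group in full.groupby("protein", sort=False):
        exposures[protein] = SummaryStats(
            protein, group[CANONICAL_COLUMNS].reset_index(drop=True)
        )

    blocks_for_ld: dict[str, list[str]] = {
        block_id: list(members)
        for block_id, members in variants.groupby("block")["variant_id"]
        if len(members) > 1
    }
    ld = LDMatrix.from_blocks(blocks_for_ld, cfg.ld_block_r2)
    # pleiotropic effects are drawn here so the outcome generator is a pure
    # function of the truth; alpha applies to instrument (lead) variants
    variants["alpha"] = _draw_pleiotropy(
        np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 3])), variants, cfg
    )
    truth = SimulationTruth(cfg, theta_map, variants, cfg.seed)
    return exposures, genes, ld, truth


def _draw_pleiotropy(
    rng: np.random.Generator, variants: pd.DataFrame, cfg: SimulationConfig
) -> np.ndarray:
    """Direct (horizontal) effects alpha_j for lead variants, per pleiotropy mode.

    Shadows inherit r * alpha of their lead (LD propagates direct effects);
    null and decoy variants carry none.
    """
    n = len(variants)
    alpha = np.zeros(n)
    if cfg.pleiotropy_mode == "none":
        return alpha
    role = variants["role"].to_numpy()
    lead_idx = np.flatnonzero(role == "lead")
    for protein, group in variants.loc[lead_idx].groupby("protein"):
        idx = group.index.to_numpy()
        n_invalid = int(round(cfg.invalid_fraction * len(idx)))
        chosen = rng.choice(idx, size=n_invalid, replace=False)
        center = cfg.mu if cfg.pleiotropy_mode == "directional" else 0.0
        alpha[chosen] = rng.normal(center, cfg.tau, size=n_invalid)
    # propagate to shadows
    alpha_by_block = dict(zip(variants.loc[lead_idx, "block"], alpha[lead_idx]))
    shadow = np.flatnonzero(role == "shadow")
    r = np.sqrt(cfg.ld_block_r2)
    for j in shadow:
        alpha[j] = r * alpha_by_block.get(variants.at[j, "block"], 0.0)
    return alpha


def simulate_outcome(
    truth: SimulationTruth,
    cfg: SimulationConfig | None = None,
    *,
    outcome_id: str = "outcome",
    scramble: bool | None = None,
) -> SummaryStats:
    """Generate the binary-outcome GWAS over all variants in the truth table.

    True outcome effects follow beta_y = theta * beta_x + alpha; standard
    errors use the effective sample size of the case/control design.
    Allele labels are scrambled (swap and/or strand-complement) at the
    configured rates unless ``scramble=False``.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    v = truth.variants
    n = len(v)
    maf = v["maf"].to_numpy()
    n_eff = effective_n(cfg.n_cases, cfg.n_controls)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)

    theta_per_variant = v["protein"].map(truth.theta).to_numpy(dtype=float)
    true_beta_y = theta_per_variant * v["true_beta_x"].to_numpy() + v["alpha"].to_numpy()
    noise = _block_noise(rng, v["block"].to_numpy(), cfg.ld_block_r2)
    beta_obs = true_beta_y + noise * se_y
    z_obs = beta_obs / se_y
    pvals = np.maximum(2.0 * sps.norm.sf(np.abs(z_obs)), np.finfo(float).tiny)

    ea = v["effect_allele"].to_numpy(dtype=object).copy()
    oa = v["other_allele"].to_numpy(dtype=object).copy()
    eaf = maf.copy()
    beta = beta_obs.copy()

    do_scramble = scramble if scramble is not None else True
    if do_scramble:
        swap = rng.random(n) < cfg.allele_swap_rate
        strand = rng.random(n) < cfg.strand_flip_rate
        ea[swap], oa[swap] = oa[swap], ea[swap]
        beta[swap] *= -1.0
        eaf[swap] = 1.0 - eaf[swap]
        comp = np.vectorize(COMPLEMENT.get, otypes=[object])
        ea[strand] = comp(ea[strand])
        oa[strand] = comp(oa[strand])

    frame = pd.DataFrame(
        {
            "variant_id": v["variant_id"],
            "chromosome": v["chromosome"],
            "position": v["position"],
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se_y,
            "pvalue": pvals,
            "n": float(cfg.n_cases + cfg.n_controls),
        }
    )
    stats = SummaryStats.from_frame(
        outcome_id,
        frame,
        trait_type="binary",
        n_cases=cfg.n_cases,
        n_controls=cfg.n_controls,
        validate=False,
    )
    stats.table["position"] = stats.table["position"].astype(np.int64)
    return stats


def simulate_phewas_outcomes(
    truth: SimulationTruth,
    n_outcomes: int,
    case_count_range: tuple[int, int] = (10, 500),
    cfg: SimulationConfig | None = None,
    spiked_theta: Mapping[str, float] | None = None,
) -> list[SummaryStats]:
    """Independent (null by default) binary outcomes spanning the case filter.

    Case counts are drawn uniformly over ``case_count_range``; outcomes
    listed in ``spiked_theta`` receive that causal effect instead of 0.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    v = truth.variants
    maf = v["maf"].to_numpy()
    out: list[SummaryStats] = []
    for k in range(n_outcomes):
        outcome_id = f"PHE{k:04d}"
        n_cases = int(rng.integers(case_count_range[0], case_count_range[1] + 1))
        n_eff = effective_n(n_cases, cfg.n_controls)
        se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)
        theta_k = float(spiked_theta.get(outcome_id, 0.0)) if spiked_theta else 0.0
        true_beta_y = theta_k * v["true_beta_x"].to_numpy()
        beta_obs = true_beta_y + _block_noise(rng, v["block"].to_numpy(), cfg.ld_block_r2) * se_y
        pvals = np.maximum(
            2.0 * sps.norm.sf(np.abs(beta_obs / se_y)), np.finfo(float).tiny
        )
        frame = pd.DataFrame(
            {
                "variant_id": v["variant_id"],
                "chromosome": v["chromosome"],
                "position": v["position"],
                "effect_allele": v["effect_allele"],
                "other_allele": v["other_allele"],
                "eaf": maf,
                "beta": beta_obs,
                "se": se_y,
                "pvalue": pvals,
                "n": float(n_cases + cfg.n_controls),
            }
        )
        stats = SummaryStats.from_frame(
            outcome_id, frame, trait_type="binary",
            n_cases=n_cases, n_controls=cfg.n_controls, validate=False,
        )
        stats.table["position"] = stats.table["position"].astype(np.int64)
        out.append(stats)
    return out


def quick_instrument_set(
    rng: np.random.Generator,
    L: int = 5,
    theta: float = 0.0,
    n_exposure: int = 35_559,
    n_cases: int = 1_543,
    n_controls: int = 391_037,
    maf_range: tuple[float, float] = (0.05, 0.5),
    effect_size_range: tuple[float, float] = (1.2, 10.0),
    alpha: np.ndarray | None = None,
    positive_effects: bool = False,
) -> InstrumentSet:
    """One harmonized instrument set drawn directly from the generating model.

    A fast path for estimator-level Monte Carlo: the same closed forms as
    :func:`simulate_exposure` / :func:`simulate_outcome` (independent
    instruments, no decoys or label scrambling), skipping table plumbing.
    ``alpha`` supplies per-instrument direct effects (default none).
    """
    maf = rng.uniform(*maf_range, size=L)
    se_x = se_exposure(maf, n_exposure)
    sign = np.ones(L) if positive_effects else rng.choice([-1.0, 1.0], size=L)
    true_bx = sign * rng.uniform(*effect_size_range, size=L) * Z_GENOME_WIDE * se_x
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * effective_n(n_cases, n_controls))
    if alpha is None:
        alpha = np.zeros(L)
    true_by = theta * true_bx + np.asarray(alpha, dtype=float)
    bx = rng.normal(true_bx, se_x)
    by = rng.normal(true_by, se_y)
    return InstrumentSet.from_arrays(bx, se_x, by, se_y)
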