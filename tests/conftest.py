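"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pqtlmr.harmonize import InstrumentSet
from pqtlmr.sumstats import CANONICAL_COLUMNS, SummaryStats

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_sumstats(
    trait_id: str = "trait",
    *,
    variant_id,
    beta,
    se,
    pvalue,
    chromosome=None,
    position=None,
    effect_allele=None,
    other_allele=None,
    eaf=None,
    n=None,
    trait_type="quantitative",
    n_cases=None,
    n_controls=None,
    validate=True,
) -> SummaryStats:
    """Build a SummaryStats from column arrays, filling unspecified fields."""
    k = len(variant_id)
    frame = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chromosome": chromosome if chromosome is not None else ["1"] * k,
            "position": position if position is not None else np.arange(1, k + 1) * 1000,
            "effect_allele": effect_allele if effect_allele is not None else ["A"] * k,
            "other_allele": other_allele if other_allele is not None else ["G"] * k,
            "eaf": eaf if eaf is not None else [0.3] * k,
            "beta": beta,
            "se": se,
            "pvalue": pvalue,
            "n": n if n is not None else [10000.0] * k,
        }
    )
    return SummaryStats.from_frame(
        trait_id, frame, trait_type=trait_type, n_cases=n_cases,
        n_controls=n_controls, validate=validate,
    )


def random_sumstats(rng: np.random.Generator, k: int, trait_id: str = "trait") -> SummaryStats:
    """A valid random summary-statistics table with k variants."""
    alleles = np.array(list("ACGT"))
    ea = rng.choice(alleles, size=k)
    oa = np.array([rng.choice([a for a in "ACGT" if a != e]) for e in ea])
    return make_sumstats(
        trait_id,
        variant_id=[f"rs{i}" for i in range(k)],
        chromosome=rng.choice([str(c) for c in range(1, 23)], size=k),
        position=rng.integers(1, 2_000_000_00, size=k),
        effect_allele=ea,
        other_allele=oa,
        eaf=rng.uniform(0.01, 0.99, size=k),
        beta=rng.normal(0, 0.2, size=k),
        se=rng.uniform(0.01, 0.1, size=k),
        pvalue=rng.uniform(1e-12, 1.0, size=k),
    )


def random_instrument_set(rng: np.random.Generator, L: int) -> InstrumentSet:
    """A random harmonized instrument set for algebraic estimator checks."""
    return InstrumentSet.from_arrays(
        beta_x=rng.uniform(0.05, 0.6, size=L) * rng.choice([-1, 1], size=L),
        se_x=rng.uniform(0.005, 0.05, size=L),
        beta_y=rng.normal(0, 0.1, size=L),
        se_y=rng.uniform(0.01, 0.08, size=L),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240725)


@pytest.fixture
def small_study():
    """A 4-protein study (1 causal), fully simulated with defaults."""
    from pqtlmr.simulate import SimulationConfig, simulate_exposure, simulate_outcome

    cfg = SimulationConfig(n_proteins=4, theta=(0.336, 0.0, 0.0, 0.0), seed=99)
    exposures, genes, ld, truth = simulate_exposure(cfg)
    outcome = simulate_outcome(truth, cfg)
    return cfg, exposures, genes, ld, truth, outcome
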