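"""GWAS summary-statistics tables, gene annotations, and their I/O.

This module houses the variant-level data model shared by the whole
pipeline.  A summary-statistics table holds, per variant, the estimated
per-allele effect on one trait (log-odds for binary traits, SD units for
rank-normalised quantitative traits such as plasma protein levels),
its standard error, p-value, allele labels and effect-allele frequency.

Conventions enforced here, once, for everything downstream:

* genomic positions are **1-based inclusive** (the usual GWAS
  summary-statistic convention); BED gene annotations are converted on read;
* alleles are single-nucleotide A/C/G/T, upper-cased; indels and other
  non-SNV rows are dropped with a logged count;
* a missing effect-allele frequency is permitted (written as ``.``) but
  marks the variant as unresolvable if it turns out to be palindromic
  during harmonization.

Validation is total: no operation downstream of :func:`read_sumstats` /
:meth:`SummaryStats.from_frame` ever sees a record violating the
invariants (positive SE, p in (0, 1], distinct alleles, position >= 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical column order of every summary-statistics table in memory and on disk.
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Default on-disk column names, overridable per file via a dialect mapping.
DEFAULT_DIALECT = {
    "variant_id": "variant_id",
    "chromosome": "chr",
    "position": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

MANDATORY_FIELDS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
]

VALID_ALLELES = frozenset("ACGT")

MISSING = "."


class ConfigurationError(ValueError):
    """A column mapping or configuration value cannot be resolved."""


class EmptyInputError(ValueError):
    """An input file contains no data rows."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval anchoring the cis-window (1-based inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class SummaryStats:
    """A validated summary-statistics table for one trait.

    ``table`` always has :data:`CANONICAL_COLUMNS`; ``eaf`` / ``n`` may be NaN.
    ``dropped`` counts rows removed during validation, keyed by reason.
    """

    trait_id: str
    table: pd.DataFrame
    trait_type: str = "quantitative"
    n_cases: int | None = None
    n_controls: int | None = None
    dropped: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_frame(
        cls,
        trait_id: str,
        frame: pd.DataFrame,
        *,
        trait_type: str = "quantitative",
        n_cases: int | None = None,
        n_controls: int | None = None,
        validate: bool = True,
    ) -> "SummaryStats":
        if trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        if n_cases is not None and n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        table = frame.reindex(columns=CANONICAL_COLUMNS).copy()
        dropped: dict[str, int] = {}
        if validate:
            table, dropped = _validate_table(table)
            if dropped:
                log.info("trait %s: dropped rows during validation: %s", trait_id, dropped)
        return cls(trait_id, table.reset_index(drop=True), trait_type, n_cases, n_controls, dropped)

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> Iterator[VariantAssociation]:
        for row in self.table.itertuples(index=False):
            yield VariantAssociation(
                variant_id=row.variant_id,
                chromosome=row.chromosome,
                position=int(row.position),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            )

    def subset(self, mask: np.ndarray | pd.Series) -> "SummaryStats":
        """A new SummaryStats sharing metadata, keeping rows where mask is True."""
        return SummaryStats(
            self.trait_id,
            self.table.loc[np.asarray(mask)].reset_index(drop=True),
            self.trait_type,
            self.n_cases,
            self.n_controls,
            dict(self.dropped),
        )

    def indexed(self) -> pd.DataFrame:
        """The table indexed by variant_id (cached; valid because ids are unique)."""
        cached = getattr(self, "_indexed", None)
        if cached is None:
            cached = self.table.set_index("variant_id")
            self._indexed = cached
        return cached


def _validate_table(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Coerce dtypes, enforce record invariants, drop (and count) offenders."""
    dropped: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal table
        n = int(mask.sum())
        if n:
            dropped[reason] = dropped.get(reason, 0) + n
            table = table.loc[~mask]

    table = table.copy()
    table["variant_id"] = table["variant_id"].astype(str)
    table["chromosome"] = table["chromosome"].astype(str).str.replace("^chr", "", regex=True)
    for col in ("position", "eaf", "beta", "se", "pvalue", "n"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        table[col] = table[col].astype(str).str.upper().str.strip()

    core = ["position", "beta", "se", "pvalue"]
    drop(table[core].isna().any(axis=1), "missing_value")
    snv = table["effect_allele"].isin(VALID_ALLELES) & table["other_allele"].isin(VALID_ALLELES)
    drop(~snv, "non_snv_allele")
    drop(table["effect_allele"] == table["other_allele"], "identical_alleles")
    drop(table["se"] <= 0, "nonpositive_se")
    drop(~((table["pvalue"] > 0) & (table["pvalue"] <= 1)), "pvalue_out_of_range")
    drop(table["position"] < 1, "bad_position")
    eaf_bad = table["eaf"].notna() & ~table["eaf"].between(0.0, 1.0)
    drop(eaf_bad, "eaf_out_of_range")
    drop(table["variant_id"].duplicated(keep="first"), "duplicate_variant_id")

    table["position"] = table["position"].astype(np.int64)
    return table, dropped


# ---------------------------------------------------------------------------
# summary-statistics I/O


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    n_cases: int | None = None,
    n_controls: int | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics table into a validated :class:`SummaryStats`.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`) to
    the column names used in the file; unspecified fields fall back to the
    defaults.  Rows violating record invariants are dropped and counted in
    ``SummaryStats.dropped``.

    Raises
    ------
    ConfigurationError
        if a mandatory column cannot be resolved through the dialect.
    EmptyInputError
        if the file has no data rows.
    """
    path = Path(path)
    names = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect fields: {sorted(unknown)}")
        names.update(dialect)

    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=[MISSING, ""], comment="#")
    if raw.empty:
        raise EmptyInputError(f"{path}: no data rows")

    # the dialect name wins; a canonical header (as written by write_sumstats)
    # is always accepted as fallback
    resolved = {
        canon: col if col in raw.columns else canon
        for canon, col in names.items()
    }
    for fieldname in MANDATORY_FIELDS:
        if resolved[fieldname] not in raw.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {names[fieldname]!r} (field {fieldname!r}) not found"
            )

    frame = pd.DataFrame(
        {canon: raw[col] if col in raw.columns else np.nan for canon, col in resolved.items()}
    )
    return SummaryStats.from_frame(
        trait_id or path.stem,
        frame,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write ``stats`` as a canonical TSV (fixed column order, ``.`` for missing).

    ``read_sumstats(write_sumstats(s))`` is the identity on valid records;
    numeric fields are serialised to 10 significant digits.
    """
    out = stats.table.reindex(columns=CANONICAL_COLUMNS)
    out.to_csv(
        Path(path),
        sep="\t",
        index=False,
        na_rep=MISSING,
        float_format="%.10g",
    )


# ---------------------------------------------------------------------------
# gene annotations


def read_gene_annotations(
    path: str | Path, *, zero_based: bool | None = None
) -> list[GeneAnnotation]:
    """Read a gene table: 4 columns (gene, chr, start, end), TSV, 1-based inclusive.

    A ``.bed`` file (or ``zero_based=True``) is interpreted as BED
    (0-based half-open, columns chrom/start/end/name) and converted.
    Rows with start > end are rejected with a warning.
    """
    path = Path(path)
    if zero_based is None:
        zero_based = path.suffix.lower() == ".bed"
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 4:
        raise ConfigurationError(f"{path}: expected 4 columns, found {raw.shape[1]}")
    if zero_based:
        cols = {"chromosome": 0, "start": 1, "end": 2, "gene_id": 3}
    else:
        cols = {"gene_id": 0, "chromosome": 1, "start": 2, "end": 3}
    # tolerate a header row on the TSV form
    first = raw.iloc[0, cols["start"]]
    try:
        int(first)
    except (TypeError, ValueError):
        raw = raw.iloc[1:]

    annotations: list[GeneAnnotation] = []
    for _, row in raw.iterrows():
        start = int(row[cols["start"]])
        end = int(row[cols["end"]])
        if zero_based:
            start += 1  # BED start is 0-based; end is exclusive == 1-based inclusive end
        gene = str(row[cols["gene_id"]])
        chrom = str(row[cols["chromosome"]]).removeprefix("chr")
        if start > end:
            log.warning("gene %s: start > end, row rejected", gene)
            continue
        annotations.append(GeneAnnotation(gene, chrom, start, end))
    return annotations


def write_gene_annotations(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write genes as the 4-column 1-based TSV accepted by :func:`read_gene_annotations`."""
    frame = pd.DataFrame(
        [(g.gene_id, g.chromosome, g.start, g.end) for g in genes],
        columns=["gene_id", "chromosome", "start", "end"],
    )
    frame.to_csv(Path(path), sep="\t", index=False, header=False)
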