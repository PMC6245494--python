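"""Readers, writers and validated containers for the external file formats.

Four formats cross the package boundary: a genes x samples expression TSV,
a clinical survival TSV (sample_id, time_days, event), a GDC-dialect MAF of
somatic mutations, and a GMT gene-set collection.  Everything is parsed into
small validated containers; intermediate artifacts are written back as TSV
with a ``#`` schema comment so any stage can be swapped for an external
tool's output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("survsig")

VALID_BASES = frozenset("ACGT")

#: Required columns of the GDC MAF dialect.
MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Type",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix.

    ``unit_tag`` records the scale of ``values``: raw ``counts``, ``fpkm``,
    or ``log2`` (meaning log2(x+1) of an FPKM-like quantity, the scale the
    downstream risk model operates on).
    """

    frame: pd.DataFrame  # index = gene ids, columns = sample ids
    unit_tag: str = "fpkm"

    def __post_init__(self) -> None:
        if self.unit_tag not in {"counts", "fpkm", "log2"}:
            raise ValueError(f"unknown unit_tag {self.unit_tag!r}")
        idx, cols = self.frame.index, self.frame.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        if np.isnan(values).any():
            raise FormatError("expression matrix contains missing values")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise FormatError(
                f"negative expression value at gene {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def log2(self) -> "ExpressionMatrix":
        """Return a log2(x+1) copy; a no-op if already on the log scale."""
        if self.unit_tag == "log2":
            return self
        return ExpressionMatrix(np.log2(self.frame + 1.0), unit_tag="log2")

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.frame.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.frame.loc[list(genes)], unit_tag=self.unit_tag)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame[list(samples)], unit_tag=self.unit_tag)


@dataclass
class SurvivalTable:
    """Per-sample right-censored follow-up: time in days and event indicator."""

    frame: pd.DataFrame  # columns: sample_id, time_days, event

    def __post_init__(self) -> None:
        required = {"sample_id", "time_days", "event"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[
                self.frame["sample_id"].duplicated(), "sample_id"
            ].tolist()
            raise FormatError(f"duplicate sample ids in clinical table: {dups}")
        if (self.frame["time_days"] < 0).any():
            raise FormatError("negative follow-up time")
        if not self.frame["event"].isin([0, 1]).all():
            raise FormatError("event indicator must be 0 or 1")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_days"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def n(self) -> int:
        return len(self.frame)

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        sub = self.frame.set_index("sample_id").loc[list(samples)].reset_index()
        return SurvivalTable(sub)


@dataclass
class MutationRecord:
    """A single somatic mutation call (one MAF row)."""

    sample_id: str
    gene: str
    variant_type: str  # SNP / INS / DEL / other
    ref_allele: str
    alt_allele: str
    dbsnp_id: Optional[str] = None


@dataclass
class GeneSet:
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); duplicates within a set are removed."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, name: str) -> list[str]:
        return self.sets[name].genes

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if not deduped:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(description, deduped)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, unit_tag: str = "fpkm") -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV (header = sample ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression cell in {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.index.name = None
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(frame, unit_tag=unit_tag)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# expression matrix, unit={matrix.unit_tag}, genes x samples\n")
        matrix.frame.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# clinical TSV
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> SurvivalTable:
    """Read a clinical TSV with columns sample_id, time_days, event.

    Rows with missing time or event are excluded with a logged count rather
    than imputed.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "time_days", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    complete = frame.dropna(subset=["time_days", "event"])
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        logger.warning("excluded %d samples with missing survival data", n_dropped)
    complete = complete.assign(event=complete["event"].astype(int))
    return SurvivalTable(complete[["sample_id", "time_days", "event"]])


def write_clinical(table: SurvivalTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# clinical survival table: sample_id, time_days, event\n")
        table.frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def read_maf(
    path: str | Path, barcode_prefix_len: Optional[int] = None
) -> list[MutationRecord]:
    """Parse a GDC-dialect MAF into mutation records.

    ``barcode_prefix_len`` optionally truncates Tumor_Sample_Barcode so that
    aliquot-level mutation barcodes can be joined with patient-level
    expression sample ids.  SNP rows whose ref/alt alleles are not a valid
    substitution are rejected with a warning rather than silently kept.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"MAF missing required columns: {missing}")
    if frame.empty:
        warnings.warn(f"MAF file {path} contains no data rows")
        return []
    records: list[MutationRecord] = []
    n_rejected = 0
    for row in frame.itertuples(index=False):
        sample = str(row.Tumor_Sample_Barcode)
        if barcode_prefix_len is not None:
            sample = sample[:barcode_prefix_len]
        variant_type = str(row.Variant_Type).upper()
        ref = str(row.Reference_Allele)
        alt = str(row.Tumor_Seq_Allele2)
        if variant_type == "SNP":
            ok = (
                len(ref) == 1
                and len(alt) == 1
                and ref in VALID_BASES
                and alt in VALID_BASES
                and ref != alt
            )
            if not ok:
                n_rejected += 1
                continue
        dbsnp = getattr(row, "dbSNP_RS", None)
        if dbsnp is not None and (pd.isna(dbsnp) or dbsnp in {"novel", "."}):
            dbsnp = None
        records.append(
            MutationRecord(
                sample_id=sample,
                gene=str(row.Hugo_Symbol),
                variant_type=variant_type,
                ref_allele=ref,
                alt_allele=alt,
                dbsnp_id=dbsnp,
            )
        )
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} SNP rows with invalid ref/alt alleles")
    return records


def write_maf(records: Sequence[MutationRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#version gdc-dialect\n")
        cols = list(MAF_REQUIRED_COLUMNS) + ["dbSNP_RS"]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.gene,
                        r.sample_id,
                        r.variant_type,
                        r.ref_allele,
                        r.alt_allele,
                        r.dbsnp_id or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...``"""
    collection = GeneSetCollection()
    path = Path(path)
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"GMT file {path} is empty")
        return collection
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, description, genes = fields[0], fields[1], fields[2:]
        genes = [g for g in genes if g]
        if len(set(genes)) < len(genes):
            warnings.warn(f"gene set {name!r} lists duplicate genes; deduplicated")
        collection.add(name, description, genes)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, gs in collection.sets.items():
            fh.write("\t".join([name, gs.description] + list(gs.genes)) + "\n")


# ---------------------------------------------------------------------------
# cohort joining
# ---------------------------------------------------------------------------

@dataclass
class JoinReport:
    common_samples: list[str]
    n_expression_only: int
    n_clinical_only: int
    n_mutation_only: int


def join_cohort(
    expression: ExpressionMatrix,
    survival: SurvivalTable,
    mutations: Optional[Sequence[MutationRecord]] = None,
) -> tuple[ExpressionMatrix, SurvivalTable, list[MutationRecord], JoinReport]:
    """Intersect expression/clinical(/mutation) samples, reporting drops.

    The intersection keeps the expression matrix's sample order.  Mutation
    records for samples outside the intersection are dropped (mutation data
    typically covers a subset of the expression cohort).
    """
    expr_ids = set(expression.sample_ids)
    clin_ids = set(survival.sample_ids)
    common = [s for s in expression.sample_ids if s in clin_ids]
    if not common:
        raise FormatError("no samples shared between expression and clinical tables")
    mut_ids = {m.sample_id for m in mutations} if mutations else set()
    kept_mut = [m for m in (mutations or []) if m.sample_id in set(common)]
    report = JoinReport(
        common_samples=common,
        n_expression_only=len(expr_ids - clin_ids),
        n_clinical_only=len(clin_ids - expr_ids),
        n_mutation_only=len(mut_ids - set(common)),
    )
    logger.info(
        "cohort join: %d common samples (%d expression-only, %d clinical-only dropped)",
        len(common),
        report.n_expression_only,
        report.n_clinical_only,
    )
    return expression.subset_samples(common), survival.subset(common), kept_mut, report
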