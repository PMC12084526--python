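"""Readers and writers for the tabular inputs of the enrichment pipeline.

Dialects
--------
* GWAS summary statistics: TSV with header, 1-based positions (the field
  convention for association files).
* Gene models: BED4, 0-based half-open; an optional fifth column carries the
  gene's pLI (probability of loss-of-function intolerance, in [0, 1]).
* Drug targets / indications / cis-eQTL: TSV with header.
* Chromatin loops: six-column BEDPE, no header, 0-based half-open anchors.

All internal interval arithmetic is 0-based half-open; a SNP's 1-based
position is converted where used (``pos0 = pos - 1``). Alleles are carried
through but never interpreted: the mapping method is purely positional.

Rows violating record invariants are rejected, not silently kept; readers
return the number of rejected rows alongside the validated records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import pandas as pd


class ValidationError(ValueError):
    """An input table or row violates the documented dialect."""


#: regulomeDB evidence categories, strongest ("1a") to weakest ("7").
REGULOME_CATEGORIES = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c", "3a", "3b",
    "4", "5", "6", "7",
)


@dataclass
class SummaryStatRecord:
    """One variant's association statistics plus optional annotations.

    ``beta`` is the per-allele effect (log-odds scale for case-control
    GWAS), ``se`` its standard error, ``z`` the Wald statistic, ``p`` the
    association p-value and ``n`` the sample size. ``cadd`` is PHRED-scaled;
    ``regulome`` is a regulomeDB category string; ``exonic`` flags variants
    inside coding sequence.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    cadd: Optional[float] = None
    regulome: Optional[str] = None
    exonic: Optional[bool] = None

    @property
    def pos0(self) -> int:
        """0-based position for interval arithmetic."""
        return self.pos - 1

    def validate(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.variant_id}: p must be in (0, 1], got {self.p}")
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if abs(self.z - self.beta / self.se) >= 1e-3:
            raise ValidationError(
                f"{self.variant_id}: z={self.z} inconsistent with beta/se={self.beta / self.se}"
            )
        if self.regulome is not None and self.regulome not in REGULOME_CATEGORIES:
            raise ValidationError(
                f"{self.variant_id}: unknown regulomeDB category {self.regulome!r}"
            )
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"{self.variant_id}: CADD must be >= 0, got {self.cadd}")


@dataclass
class GeneModel:
    """A named genomic interval (BED dialect, 0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    pli: Optional[float] = None

    def validate(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValidationError(f"{self.gene_id}: pLI must be in [0, 1], got {self.pli}")


@dataclass
class DrugRecord:
    """A drug, its target-gene set, per-disorder indication flags and class."""

    drug_id: str
    target_genes: frozenset[str]
    indications: dict[str, bool]
    class_label: Optional[str] = None

    def validate(self) -> None:
        if not self.target_genes:
            raise ValidationError(f"{self.drug_id}: empty target-gene set")


@dataclass
class EqtlRecord:
    """A variant-to-gene expression association (cis-eQTL) link."""

    variant_id: str
    gene_id: str
    p: float

    def validate(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.variant_id}/{self.gene_id}: p must be in (0, 1]")


@dataclass
class LoopRecord:
    """A chromatin contact between two anchors (BEDPE, 0-based half-open)."""

    chromA: str
    startA: int
    endA: int
    chromB: str
    startB: int
    endB: int

    def validate(self) -> None:
        if not self.startA < self.endA:
            raise ValidationError(f"loop anchor A degenerate: [{self.startA}, {self.endA})")
        if not self.startB < self.endB:
            raise ValidationError(f"loop anchor B degenerate: [{self.startB}, {self.endB})")


@dataclass
class ReadResult:
    """Validated records plus per-row rejection bookkeeping."""

    records: list
    n_rejected: int = 0
    errors: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


SUMSTAT_MANDATORY = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p", "n",
)
SUMSTAT_OPTIONAL = ("z", "cadd", "regulome", "exonic")

_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


def _parse_bool(value: str) -> Optional[bool]:
    if value is None or value == "" or value.lower() == "nan":
        return None
    low = value.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean flag: {value!r}")


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def read_sumstats(path, column_map: Optional[Mapping[str, str]] = None) -> ReadResult:
    """Read GWAS summary statistics from a headered TSV.

    ``column_map`` maps canonical field names (``variant_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``z``,
    ``p``, ``n``, ``cadd``, ``regulome``, ``exonic``) to the file's column
    names. A blank ``z`` is backfilled as ``beta / se``. Rows violating the
    record invariants are rejected and counted, never silently kept; a
    missing mandatory column raises :class:`ValidationError` naming it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    colmap = {name: name for name in SUMSTAT_MANDATORY + SUMSTAT_OPTIONAL}
    if column_map:
        colmap.update(column_map)
    for canon in SUMSTAT_MANDATORY:
        if colmap[canon] not in df.columns:
            raise ValidationError(f"missing mandatory column {colmap[canon]!r} (for {canon})")

    records: list[SummaryStatRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        lineno = i + 2  # header is line 1
        try:
            p_raw = row[colmap["p"]]
            try:
                p = float(p_raw)
            except ValueError:
                raise ValidationError(f"line {lineno}: non-numeric p {p_raw!r}")
            beta = float(row[colmap["beta"]])
            se = float(row[colmap["se"]])
            z_raw = row.get(colmap["z"], "")
            z = beta / se if _blank(z_raw) else float(z_raw)
            cadd_raw = row.get(colmap["cadd"], "")
            regulome_raw = row.get(colmap["regulome"], "")
            exonic_raw = row.get(colmap["exonic"], "")
            rec = SummaryStatRecord(
                variant_id=str(row[colmap["variant_id"]]),
                chrom=str(row[colmap["chrom"]]),
                pos=int(row[colmap["pos"]]),
                effect_allele=str(row[colmap["effect_allele"]]),
                other_allele=str(row[colmap["other_allele"]]),
                beta=beta,
                se=se,
                z=z,
                p=p,
                n=int(float(row[colmap["n"]])),
                cadd=None if _blank(cadd_raw) else float(cadd_raw),
                regulome=None if _blank(regulome_raw) else str(regulome_raw),
                exonic=_parse_bool(exonic_raw) if colmap["exonic"] in row else None,
            )
            rec.validate()
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        records.append(rec)
    return ReadResult(records=records, n_rejected=len(errors), errors=errors)


def write_sumstats(records: Sequence[SummaryStatRecord], path, comment: Optional[str] = None) -> None:
    rows = []
    for r in records:
        rows.append({
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "effect_allele": r.effect_allele, "other_allele": r.other_allele,
            "beta": repr(r.beta), "se": repr(r.se), "z": repr(r.z), "p": repr(r.p), "n": r.n,
            "cadd": "" if r.cadd is None else repr(r.cadd),
            "regulome": "" if r.regulome is None else r.regulome,
            "exonic": "" if r.exonic is None else int(r.exonic),
        })
    _write_tsv(pd.DataFrame(rows, columns=list(SUMSTAT_MANDATORY[:5]) + [
        "beta", "se", "z", "p", "n", "cadd", "regulome", "exonic"]), path, comment)


def read_gene_bed(path) -> ReadResult:
    """Read gene models from BED4(+pLI); duplicate gene ids are a hard error."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                         keep_default_na=False,
                         names=["chrom", "start", "end", "gene_id", "pli"])
    except pd.errors.EmptyDataError:
        return ReadResult(records=[])
    if df["gene_id"].isna().any() or (df["gene_id"] == "").any():
        raise ValidationError("BED file needs >= 4 columns (chrom, start, end, gene_id)")
    records: list[GeneModel] = []
    errors: list[str] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 1
        gene_id = str(row[3])
        if gene_id in seen:
            raise ValidationError(f"line {lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            pli = None
            if df.shape[1] >= 5 and not _blank(row[4]):
                pli = float(row[4])
            gene = GeneModel(gene_id=gene_id, chrom=str(row[0]),
                             start=int(row[1]), end=int(row[2]), pli=pli)
            gene.validate()
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        records.append(gene)
    return ReadResult(records=records, n_rejected=len(errors), errors=errors)


def write_gene_bed(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            pli = "" if g.pli is None else repr(g.pli)
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{pli}\n")


@dataclass
class DrugTableResult:
    """Drugs assembled from the target and indication tables.

    Drugs with no recorded targets can never overlap a GWAS-implicated gene,
    so they are excluded from the analysis denominator and counted in
    ``n_excluded_no_targets``.
    """

    drugs: list[DrugRecord]
    disorders: tuple[str, ...]
    n_excluded_no_targets: int = 0
    errors: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[DrugRecord]:
        return iter(self.drugs)

    def __len__(self) -> int:
        return len(self.drugs)


def read_drug_tables(targets_path, indications_path) -> DrugTableResult:
    """Assemble one :class:`DrugRecord` per drug with recorded targets.

    The targets table is a headered TSV (``drug_id``, ``gene_id``); the
    indications table (``drug_id``, ``disorder_id``, ``treats`` in {0, 1},
    optional ``class_label``). Drugs absent from the indications table get
    ``treats=0`` for every disorder; drugs with zero targets are excluded
    and counted. Output is sorted by drug id, hence independent of input
    row order.
    """
    tdf = pd.read_csv(targets_path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    idf = pd.read_csv(indications_path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("drug_id", "gene_id"):
        if col not in tdf.columns:
            raise ValidationError(f"targets table missing column {col!r}")
    for col in ("drug_id", "disorder_id", "treats"):
        if col not in idf.columns:
            raise ValidationError(f"indications table missing column {col!r}")

    targets: dict[str, set[str]] = {}
    for row in tdf.itertuples(index=False):
        gene = str(row.gene_id)
        if gene:
            targets.setdefault(str(row.drug_id), set()).add(gene)

    disorders = tuple(sorted(idf["disorder_id"].unique()))
    treats: dict[str, dict[str, bool]] = {}
    classes: dict[str, str] = {}
    errors: list[str] = []
    for i, row in enumerate(idf.itertuples(index=False)):
        lineno = i + 2
        if str(row.treats) not in {"0", "1"}:
            raise ValidationError(f"indications line {lineno}: treats must be 0 or 1, got {row.treats!r}")
        drug = str(row.drug_id)
        treats.setdefault(drug, {})[str(row.disorder_id)] = str(row.treats) == "1"
        if "class_label" in idf.columns and not _blank(getattr(row, "class_label", "")):
            classes[drug] = str(row.class_label)

    n_excluded = 0
    for drug in treats:
        if drug not in targets or not targets[drug]:
            n_excluded += 1
            errors.append(f"drug {drug!r} has indications but no recorded targets; excluded")

    drugs = []
    for drug_id in sorted(targets):
        indic = {d: treats.get(drug_id, {}).get(d, False) for d in disorders}
        rec = DrugRecord(drug_id=drug_id, target_genes=frozenset(targets[drug_id]),
                         indications=indic, class_label=classes.get(drug_id))
        rec.validate()
        drugs.append(rec)
    return DrugTableResult(drugs=drugs, disorders=disorders,
                           n_excluded_no_targets=n_excluded, errors=errors)


def write_drug_tables(drugs: Sequence[DrugRecord], targets_path, indications_path) -> None:
    with open(targets_path, "w") as fh:
        fh.write("drug_id\tgene_id\n")
        for d in drugs:
            for g in sorted(d.target_genes):
                fh.write(f"{d.drug_id}\t{g}\n")
    with open(indications_path, "w") as fh:
        fh.write("drug_id\tdisorder_id\ttreats\tclass_label\n")
        for d in drugs:
            cls = d.class_label or ""
            for disorder, flag in sorted(d.indications.items()):
                fh.write(f"{d.drug_id}\t{disorder}\t{int(flag)}\t{cls}\n")


def read_eqtl(path) -> ReadResult:
    """Read a pre-filtered cis-eQTL table (variant_id, gene_id, p)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("variant_id", "gene_id", "p"):
        if col not in df.columns:
            raise ValidationError(f"eQTL table missing column {col!r}")
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = EqtlRecord(variant_id=str(row.variant_id), gene_id=str(row.gene_id),
                             p=float(row.p))
            rec.validate()
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {i + 2}: {exc}")
            continue
        records.append(rec)
    return ReadResult(records=records, n_rejected=len(errors), errors=errors)


def write_eqtl(records: Sequence[EqtlRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tgene_id\tp\n")
        for r in records:
            fh.write(f"{r.variant_id}\t{r.gene_id}\t{r.p!r}\n")


def read_loops(path) -> ReadResult:
    """Read chromatin loops from 6-column BEDPE (no header)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                         keep_default_na=False, usecols=range(6),
                         names=["chromA", "startA", "endA", "chromB", "startB", "endB"])
    except pd.errors.EmptyDataError:
        return ReadResult(records=[])
    if df.isna().any().any():
        raise ValidationError("BEDPE needs >= 6 columns")
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = LoopRecord(chromA=str(row[0]), startA=int(row[1]), endA=int(row[2]),
                             chromB=str(row[3]), startB=int(row[4]), endB=int(row[5]))
            rec.validate()
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {i + 1}: {exc}")
            continue
        records.append(rec)
    return ReadResult(records=records, n_rejected=len(errors), errors=errors)


def write_loops(records: Sequence[LoopRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chromA}\t{r.startA}\t{r.endA}\t{r.chromB}\t{r.startB}\t{r.endB}\n")


def _write_tsv(df: pd.DataFrame, path, comment: Optional[str] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
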