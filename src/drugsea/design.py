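"""Drug-level regression table for one disorder.

Each drug contributes one row: outcome Y (does the drug treat the
disorder), covariate X1 (total number of target genes — the competitive
adjustment, so merely having many targets cannot drive enrichment), and
predictor X2 under the active coding.

X2 codings
----------
binary        1 iff any target gene is implicated by the GWAS (the primary
              coding), else 0
count         number of implicated target genes
annotation    a per-gene annotation aggregate (|beta|, |z|, CADD,
              regulomeDB, pLI, exonic flag) combined across the drug's
              implicated targets by ``max`` (default) or ``mean``; 0 when
              no target is implicated
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from statistics import fmean, pstdev
from typing import Iterable, Optional, Sequence

from .io import DrugRecord
from .mapping import GeneHit

#: Annotation-mode name -> per-gene aggregate field.
MODE_AGG_KEY = {
    "max_abs_beta": "max_abs_beta",
    "mean_abs_beta": "mean_abs_beta",
    "max_z": "max_z",
    "mean_z": "mean_z",
    "max_cadd": "max_cadd",
    "mean_cadd": "mean_cadd",
    "regulome_best": "regulome_best",
    "pli_max": "pli",
    "any_exonic": "any_exonic",
}

MODE_NAMES = ("binary", "count") + tuple(MODE_AGG_KEY)


@dataclass(frozen=True)
class PredictorMode:
    """X2 coding: a mode name plus how per-gene values combine across a
    drug's implicated targets (ignored by binary/count)."""

    name: str = "binary"
    gene_aggregator: str = "max"

    def __post_init__(self):
        if self.name not in MODE_NAMES:
            raise ValueError(f"unknown predictor mode {self.name!r}; "
                             f"expected one of {MODE_NAMES}")
        if self.gene_aggregator not in ("max", "mean"):
            raise ValueError(f"gene_aggregator must be 'max' or 'mean', "
                             f"got {self.gene_aggregator!r}")

    @classmethod
    def parse(cls, text: str) -> "PredictorMode":
        """Parse "name" or "name:aggregator" (e.g. "max_cadd:mean")."""
        name, _, agg = text.partition(":")
        return cls(name=name, gene_aggregator=agg or "max")

    def __str__(self) -> str:
        if self.name in ("binary", "count"):
            return self.name
        return f"{self.name}:{self.gene_aggregator}"


@dataclass
class DesignRow:
    drug_id: str
    y: int
    x1: int
    x2: float
    implicated_targets: frozenset[str]
    class_label: Optional[str] = None


def build_design(drugs: Iterable[DrugRecord],
                 hits: Sequence[GeneHit],
                 disorder_id: str,
                 mode: PredictorMode = PredictorMode("binary"),
                 standardize: bool = False) -> list[DesignRow]:
    """One row per drug; rows are sorted by drug id (order-independent).

    ``standardize`` optionally z-scores X2 across rows (sensitivity
    analysis); by default the raw scale is kept so coefficients are
    comparable across codings.
    """
    hit_by_gene = {h.gene_id: h for h in hits}
    rows: list[DesignRow] = []
    for drug in sorted(drugs, key=lambda d: d.drug_id):
        if disorder_id not in drug.indications:
            raise ValueError(f"disorder {disorder_id!r} absent from indications "
                             f"of drug {drug.drug_id!r}")
        implicated = frozenset(g for g in drug.target_genes if g in hit_by_gene)
        if mode.name == "binary":
            x2 = 1.0 if implicated else 0.0
        elif mode.name == "count":
            x2 = float(len(implicated))
        else:
            key = MODE_AGG_KEY[mode.name]
            vals = [hit_by_gene[g].agg[key] for g in implicated]
            if not vals:
                x2 = 0.0
            elif mode.gene_aggregator == "max":
                x2 = max(vals)
            else:
                x2 = fmean(vals)
        rows.append(DesignRow(
            drug_id=drug.drug_id, y=int(drug.indications[disorder_id]),
            x1=len(drug.target_genes), x2=x2,
            implicated_targets=implicated, class_label=drug.class_label))
    if standardize:
        xs = [r.x2 for r in rows]
        mu, sd = fmean(xs), pstdev(xs)
        if sd > 0:
            for r in rows:
                r.x2 = (r.x2 - mu) / sd
    return rows


def summarize_pairings(rows: Iterable[DesignRow]) -> list[tuple[str, str]]:
    """Gene–drug pairing edges (gene_id, drug_id) for every implicated
    target of every treatment (y=1) drug — the positive enrichment cases."""
    edges = []
    for r in rows:
        if r.y == 1:
            for g in sorted(r.implicated_targets):
                edges.append((g, r.drug_id))
    return sorted(edges)


def exclude_gene(hits: Sequence[GeneHit], gene_id: str) -> list[GeneHit]:
    """Drop one gene's hit (post-hoc sensitivity, e.g. removing a single
    locus that drives many pairings); downstream design is rebuilt without it."""
    return [h for h in hits if h.gene_id != gene_id]


def write_design(rows: Sequence[DesignRow], path, comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("drug_id\ty\tx1\tx2\timplicated_targets\tclass_label\n")
        for r in rows:
            fh.write(f"{r.drug_id}\t{r.y}\t{r.x1}\t{r.x2!r}\t"
                     f"{';'.join(sorted(r.implicated_targets))}\t{r.class_label or ''}\n")


def write_sankey(edges: Sequence[tuple[str, str]], tsv_path, json_path=None,
                 comment: Optional[str] = None) -> None:
    """Pairing edge list for Sankey-style plotting: gene -> drug, value 1."""
    with open(tsv_path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("source\ttarget\tvalue\n")
        for gene, drug in edges:
            fh.write(f"{gene}\t{drug}\t1\n")
    if json_path is not None:
        nodes = sorted({g for g, _ in edges}) + sorted({d for _, d in edges})
        index = {name: i for i, name in enumerate(nodes)}
        payload = {
            "nodes": [{"name": n} for n in nodes],
            "links": [{"source": index[g], "target": index[d], "value": 1}
                      for g, d in edges],
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
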