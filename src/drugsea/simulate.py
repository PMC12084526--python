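"""Synthetic inputs with controlled ground truth, at two levels.

Full-stack
    Genome -> summary statistics -> drug tables: GWS loci are planted
    inside a chosen pool of genes, and treatment drugs' target sets are
    seeded with pool genes at a higher rate than non-treatment drugs'.
    The induced enrichment is *empirical* — measure it with
    :func:`empirical_log_or` by direct 2x2 enumeration, never assume it.

Design-level
    Y is drawn directly from the logistic model
    logit P(Y=1) = b0 + b1*X1 + b2*X2, so the fitted model exactly matches
    the generative one; used for parameter-recovery and type-I studies.

Default scale mirrors the study setting this emulates: 1,201 drugs with
right-skewed target counts (zero-truncated negative binomial, mean ~8),
a few dozen treatments per disorder, and a handful-to-hundreds of planted
GWS loci. Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .design import DesignRow
from .io import REGULOME_CATEGORIES, DrugRecord, GeneModel, SummaryStatRecord


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one generated dataset.

    For full-stack data the logistic coefficients are induced rather than
    parametric, so ``beta*_true`` are NaN there; the pi's record the
    target-seeding rates instead.
    """

    beta0_true: float = -2.0
    beta1_true: float = 0.04
    beta2_true: float = 0.0
    n_drugs: int = 1201
    n_genes: int = 1000
    n_gws_planted: int = 20
    pi_target_overlap_treat: float = 0.5
    pi_target_overlap_nontreat: float = 0.05
    seed: int = 0
    x2_rate: float = 0.1
    target_mean: float = 8.0
    target_shape: float = 2.0


@dataclass
class EnrichmentPlan:
    """How one disorder's treatments relate to the planted-GWS gene pool."""

    disorder_id: str
    planted_gene_ids: tuple[str, ...]
    n_treatments: int = 40
    pi_treat: float = 0.5
    pi_nontreat: float = 0.05


@dataclass
class SumstatsResult:
    """Generated summary statistics plus planted-variant bookkeeping."""

    records: list[SummaryStatRecord]
    planted_ids: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _ztnb(rng: np.random.Generator, mean: float, shape: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial draws (mean of the untruncated law
    is ``mean``; ``shape`` is the NB dispersion r)."""
    p = shape / (shape + mean)
    out = rng.negative_binomial(shape, p, size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(shape, p, int(zero.sum()))


def gen_genome(n_genes: int = 1000,
               n_chroms: int = 4,
               gene_len_range: tuple[int, int] = (10_000, 100_000),
               intergenic_range: tuple[int, int] = (50_000, 500_000),
               seed: int = 0) -> list[GeneModel]:
    """Non-overlapping genes laid left-to-right across chromosomes, with
    uniform lengths and gaps and pLI ~ Uniform(0, 1)."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0)
                 for c in range(n_chroms)]
    gid = 0
    for c, count in enumerate(per_chrom):
        pos = int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
        for _ in range(count):
            length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
            genes.append(GeneModel(
                gene_id=f"G{gid:05d}", chrom=f"chr{c + 1}",
                start=pos, end=pos + length, pli=float(rng.uniform())))
            pos += length + int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
            gid += 1
    return genes


def gen_sumstats(genes: Sequence[GeneModel],
                 n_snps: int = 10_000,
                 n_gws_planted: int = 20,
                 target_gene_ids: Optional[Sequence[str]] = None,
                 inside_fraction: float = 1.0,
                 gws_alpha: float = 5e-8,
                 n_samples: int = 300_000,
                 seed: int = 0) -> SumstatsResult:
    """Background SNPs (p ~ U(0,1), small effects) plus planted GWS SNPs.

    A fraction ``inside_fraction`` of the planted SNPs is placed uniformly
    inside ``target_gene_ids`` gene bodies, cycling through the (shuffled)
    pool so every pool gene carries a locus before any carries two; the rest land
    mid-intergap, at least 15 kb from any gene where the gap allows, so
    they cannot create proximity hits at the default flank. z and se are
    made mutually consistent with (beta, p) via z = sign(beta) * Phi^-1(1 - p/2).
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    if target_gene_ids is None:
        target_gene_ids = [g.gene_id for g in genes]
    chrom_span: dict[str, int] = {}
    chrom_genes: dict[str, list[GeneModel]] = {}
    for g in genes:
        chrom_span[g.chrom] = max(chrom_span.get(g.chrom, 0), g.end + 200_000)
        chrom_genes.setdefault(g.chrom, []).append(g)
    chroms = sorted(chrom_span)

    planted_ids: list[str] = []
    alleles = "ACGT"

    def _make(vid, chrom, pos0, p, abs_beta, sign, ea, oa, cadd, reg, exo):
        beta = sign * abs_beta
        z = sign * float(norm.isf(p / 2.0))
        se = abs_beta / abs(z) if z != 0 else 1.0
        return SummaryStatRecord(
            variant_id=vid, chrom=chrom, pos=int(pos0) + 1,
            effect_allele=ea, other_allele=oa,
            beta=float(beta), se=float(se), z=float(z), p=float(p), n=n_samples,
            cadd=float(cadd), regulome=reg, exonic=bool(exo))

    # background (all draws vectorized; z from p via the normal quantile)
    n_bg = n_snps - n_gws_planted
    ci = rng.integers(len(chroms), size=n_bg)
    pos0 = rng.integers(0, [chrom_span[chroms[c]] for c in ci])
    p_bg = rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=n_bg)
    abs_beta = np.maximum(np.abs(rng.normal(0.0, 0.01, size=n_bg)), 1e-6)
    sign = np.where(rng.uniform(size=n_bg) < 0.5, 1.0, -1.0)
    z_bg = sign * norm.isf(p_bg / 2.0)
    se_bg = abs_beta / np.abs(z_bg)
    ea_i = rng.integers(4, size=n_bg)
    oa_i = (ea_i + 1 + rng.integers(3, size=n_bg)) % 4
    cadd = rng.gamma(2.0, 3.0, size=n_bg)
    reg_i = rng.integers(len(REGULOME_CATEGORIES), size=n_bg)
    exo = rng.uniform(size=n_bg) < 0.05
    records = [
        SummaryStatRecord(
            variant_id=f"rs{i}", chrom=chroms[ci[i]], pos=int(pos0[i]) + 1,
            effect_allele=alleles[ea_i[i]], other_allele=alleles[oa_i[i]],
            beta=float(sign[i] * abs_beta[i]), se=float(se_bg[i]), z=float(z_bg[i]),
            p=float(p_bg[i]), n=n_samples, cadd=float(cadd[i]),
            regulome=REGULOME_CATEGORIES[reg_i[i]], exonic=bool(exo[i]))
        for i in range(n_bg)
    ]

    # planted GWS
    n_inside = int(round(inside_fraction * n_gws_planted))
    pool_order = list(target_gene_ids)
    rng.shuffle(pool_order)
    for i in range(n_gws_planted):
        vid = f"rsP{i}"
        p = float(rng.uniform(1e-12, gws_alpha * 0.99))
        ab = abs(float(rng.normal(0.05, 0.01))) or 1e-3
        if i < n_inside and target_gene_ids:
            gene = by_id[pool_order[i % len(pool_order)]]
            ppos = int(rng.integers(gene.start, gene.end))
            chrom = gene.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            gs = sorted(chrom_genes[chrom], key=lambda g: g.start)
            gaps = []
            prev = 0
            for g in gs:
                if g.start - prev > 40_000:
                    gaps.append((prev + 15_000, g.start - 15_000))
                prev = g.end
            lo, hi = gaps[int(rng.integers(len(gaps)))] if gaps else (prev + 15_000, prev + 40_000)
            ppos = int(rng.integers(lo, hi))
        sgn = 1.0 if rng.uniform() < 0.5 else -1.0
        eai = int(rng.integers(4))
        oai = (eai + 1 + int(rng.integers(3))) % 4
        records.append(_make(
            vid, chrom, ppos, p, ab, sgn, alleles[eai], alleles[oai],
            rng.gamma(2.0, 3.0), REGULOME_CATEGORIES[int(rng.integers(len(REGULOME_CATEGORIES)))],
            rng.uniform() < 0.05))
        planted_ids.append(vid)
    return SumstatsResult(records=records, planted_ids=planted_ids)


def gen_drug_tables(gene_ids: Sequence[str],
                    plans: Sequence[EnrichmentPlan],
                    n_drugs: int = 1201,
                    target_mean: float = 8.0,
                    target_shape: float = 2.0,
                    n_classes: int = 30,
                    seed: int = 0) -> tuple[list[DrugRecord], list[SyntheticTruth]]:
    """Drug-target and indication tables with planted enrichment.

    Target counts are zero-truncated NB (right-skewed, mean ~``target_mean``);
    targets are uniform draws from the gene universe. Per plan, treatment
    drugs get one target replaced by a planted-pool gene with probability
    ``pi_treat`` (``pi_nontreat`` for the rest) — replacement, not addition,
    keeps the X1 distribution identical across groups. Induced enrichment
    is empirical; the truth objects carry NaN coefficients and the pi's.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    counts = _ztnb(rng, target_mean, target_shape, n_drugs)
    counts = np.minimum(counts, len(gene_ids))
    targets = [set(np.array(gene_ids)[rng.choice(len(gene_ids), int(k), replace=False)])
               for k in counts]
    class_labels = [f"C{int(rng.integers(n_classes)):03d}" for _ in range(n_drugs)]

    indications: list[dict[str, bool]] = [
        {plan.disorder_id: False for plan in plans} for _ in range(n_drugs)]
    truths = []
    for plan in plans:
        treat_idx = set(rng.choice(n_drugs, size=plan.n_treatments, replace=False).tolist())
        pool = list(plan.planted_gene_ids)
        for i in range(n_drugs):
            is_treat = i in treat_idx
            indications[i][plan.disorder_id] = is_treat
            pi = plan.pi_treat if is_treat else plan.pi_nontreat
            if pool and rng.uniform() < pi:
                gene = pool[int(rng.integers(len(pool)))]
                if gene not in targets[i]:
                    drop = list(targets[i])[int(rng.integers(len(targets[i])))]
                    targets[i].discard(drop)
                    targets[i].add(gene)
        truths.append(SyntheticTruth(
            beta0_true=float("nan"), beta1_true=float("nan"), beta2_true=float("nan"),
            n_drugs=n_drugs, n_genes=len(gene_ids), n_gws_planted=len(pool),
            pi_target_overlap_treat=plan.pi_treat,
            pi_target_overlap_nontreat=plan.pi_nontreat,
            seed=seed, target_mean=target_mean, target_shape=target_shape))

    drugs = [DrugRecord(drug_id=f"D{i:05d}", target_genes=frozenset(targets[i]),
                        indications=indications[i], class_label=class_labels[i])
             for i in range(n_drugs)]
    return drugs, truths


def empirical_log_or(drugs: Sequence[DrugRecord], hit_gene_ids: set[str],
                     disorder_id: str) -> float:
    """Brute-force 2x2 log cross-product ratio of (treats, overlaps-hits):
    the induced enrichment of a full-stack dataset, measured, not assumed."""
    a = b = c = d = 0
    for drug in drugs:
        overlap = bool(drug.target_genes & hit_gene_ids)
        if drug.indications[disorder_id]:
            a, b = a + overlap, b + (not overlap)
        else:
            c, d = c + overlap, d + (not overlap)
    if min(a, b, c, d) == 0:
        return math.nan
    return math.log((a * d) / (b * c))


def gen_design_direct(truth: SyntheticTruth,
                      seed: Optional[int] = None) -> list[DesignRow]:
    """Draw a design table straight from the logistic model.

    x1 ~ zero-truncated NB, x2 ~ Bernoulli(x2_rate), then
    y ~ Bernoulli(expit(b0 + b1*x1 + b2*x2)): the generative law and the
    fitted model coincide exactly. Rows carry a placeholder implicated
    target when x2 = 1 so binary-coding invariants hold; class labels
    cycle through 25 synthetic classes.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.n_drugs
    x1 = _ztnb(rng, truth.target_mean, truth.target_shape, n)
    x2 = (rng.uniform(size=n) < truth.x2_rate).astype(float)
    eta = truth.beta0_true + truth.beta1_true * x1 + truth.beta2_true * x2
    y = (rng.uniform(size=n) < expit(eta)).astype(int)
    return [DesignRow(
        drug_id=f"D{i:05d}", y=int(y[i]), x1=int(x1[i]), x2=float(x2[i]),
        implicated_targets=frozenset({"SIM_HIT"}) if x2[i] else frozenset(),
        class_label=f"C{i % 25:03d}") for i in range(n)]


def write_truth(truths, path) -> None:
    """truth.json with every ground-truth field (NaN encoded as null)."""
    items = [truths] if isinstance(truths, SyntheticTruth) else list(truths)
    payload = []
    for t in items:
        d = asdict(t)
        payload.append({k: (None if isinstance(v, float) and math.isnan(v) else v)
                        for k, v in d.items()})
    with open(path, "w") as fh:
        json.dump(payload if len(payload) > 1 else payload[0], fh, indent=1)
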