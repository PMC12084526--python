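import numpy as np
import pytest

import drugsea as ds


@pytest.fixture
def small_genome():
    """Ten disjoint genes on two chromosomes, fixed layout."""
    return ds.gen_genome(n_genes=10, n_chroms=2, gene_len_range=(5_000, 20_000),
                         intergenic_range=(60_000, 120_000), seed=7)


@pytest.fixture
def tiny_drugs():
    """Three drugs, one disorder, hand-built."""
    return [
        ds.DrugRecord("aripip", frozenset({"GA", "GB"}), {"SCZ": True}, "antipsychotic"),
        ds.DrugRecord("metform", frozenset({"GC"}), {"SCZ": False}, "biguanide"),
        ds.DrugRecord("cloza", frozenset({"GB", "GC", "GD"}), {"SCZ": True}, "antipsychotic"),
    ]


def make_snp(variant_id="rs1", chrom="chr1", pos=1000, p=1e-9, beta=0.05,
             cadd=None, regulome=None, exonic=None, n=100_000):
    """A consistent summary-stat record: z derived from p, se from beta/z."""
    from scipy.stats import norm
    z = float(np.sign(beta) * norm.isf(p / 2.0))
    se = abs(beta) / abs(z) if z else 1.0
    return ds.SummaryStatRecord(variant_id=variant_id, chrom=chrom, pos=pos,
                                effect_allele="A", other_allele="G", beta=beta,
                                se=se, z=z, p=p, n=n, cadd=cadd,
                                regulome=regulome, exonic=exonic)


@pytest.fixture
def snp_factory():
    return make_snp
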