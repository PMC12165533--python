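import numpy as np
import pytest

from ctpet.quant import VariantCall


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


def make_variant(
    sample_id="P0001",
    timepoint="post",
    gene="TP53",
    vaf=0.01,
    vclass="mutation",
    pos=100,
    chrom="chr17",
    alt="T",
    **kw,
):
    return VariantCall(
        sample_id=sample_id,
        timepoint=timepoint,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref="C",
        alt=alt,
        vclass=vclass,
        vaf=vaf if vclass == "mutation" else None,
        **kw,
    )


@pytest.fixture
def paired_scores_n12():
    """Correlated paired marker scores on 6 positives / 6 negatives."""
    r = np.random.default_rng(42)
    labels = np.array([1] * 6 + [0] * 6)
    latent = r.normal(labels * 1.0, 1.0)
    a = latent + r.normal(0, 0.6, 12)
    b = latent + r.normal(0, 0.9, 12)
    return a, b, labels
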