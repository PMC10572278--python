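import numpy as np
import pytest

from sharedrisk import HarmonizedInstrument, VariantAssociation


def make_assoc(variant_id="rs1", chrom="1", pos=1_000_000, ea="A", oa="G",
               beta=0.3, se=0.05, pval=None, eaf=0.25, **kw):
    if pval is None:
        from sharedrisk import effect_transform
        pval = effect_transform(beta, se).p
    return VariantAssociation(variant_id=variant_id, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa, beta=beta,
                              se=se, pval=pval, eaf=eaf, **kw)


def make_instrument(variant_id="rs1", chrom="1", pos=1_000_000,
                    gamma=0.3, se_gamma=0.03, Gamma=0.15, se_Gamma=0.05,
                    pval_exposure=1e-10, **kw):
    return HarmonizedInstrument(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele="A", other_allele="G",
        gamma=gamma, se_gamma=se_gamma, Gamma=Gamma, se_Gamma=se_Gamma,
        pval_exposure=pval_exposure, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_instruments():
    """Five instruments lying near the line Gamma = 0.5 * gamma."""
    gammas = [0.10, 0.18, 0.25, 0.33, 0.40]
    Gammas = [0.052, 0.088, 0.127, 0.160, 0.205]
    return [make_instrument(variant_id=f"rs{i}", chrom=str(i + 1),
                            pos=1_000_000 + i, gamma=g, Gamma=G)
            for i, (g, G) in enumerate(zip(gammas, Gammas))]
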