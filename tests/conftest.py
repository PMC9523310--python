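import numpy as np
import pytest

from ferromr import HarmonizedInstrument, VariantAssociation, make_iron_fixture


def random_instruments(rng: np.random.Generator, n: int) -> list[HarmonizedInstrument]:
    """Random harmonized instrument sets for oracle-equivalence checks."""
    bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1.0, 1.0], n)
    by = rng.normal(0.0, 0.2, n)
    sx = rng.uniform(0.005, 0.05, n)
    sy = rng.uniform(0.01, 0.1, n)
    return [
        HarmonizedInstrument(
            rsid=f"rs{j}", effect_allele="A", other_allele="G",
            beta_exposure=float(bx[j]), se_exposure=float(sx[j]),
            beta_outcome=float(by[j]), se_outcome=float(sy[j]),
        )
        for j in range(n)
    ]


def make_assoc(rsid="rs1", ea="A", oa="G", beta=0.3, se=0.01, pvalue=1e-10,
               eaf=0.3, n=48972, **kw) -> VariantAssociation:
    return VariantAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=pvalue, eaf=eaf, n=n, **kw,
    )


@pytest.fixture
def iron_fixture():
    return make_iron_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20220916)
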