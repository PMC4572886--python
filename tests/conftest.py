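import numpy as np
import pytest

from summr.instrument_io import HarmonizedInstrument, InstrumentVariant, OutcomeAssociation


def make_harmonized(rsid="rs1", beta=0.05, se_b=0.01, logor=0.1, se_o=0.05, action="as_is"):
    return HarmonizedInstrument(
        rsid=rsid,
        beta_exposure=beta,
        se_exposure=se_b,
        logor_outcome=logor,
        se_outcome=se_o,
        harmonization_action=action,
    )


def random_harmonized_set(rng: np.random.Generator, n: int) -> list[HarmonizedInstrument]:
    """A random estimable instrument set (positive exposure effects)."""
    return [
        make_harmonized(
            rsid=f"rs{i}",
            beta=rng.uniform(0.01, 0.2),
            se_b=rng.uniform(0.002, 0.02),
            logor=rng.normal(0, 0.2),
            se_o=rng.uniform(0.01, 0.3),
        )
        for i in range(n)
    ]


def make_instrument(rsid="rs1", ea="A", oa="G", beta=0.05, se=0.01, locus=None):
    return InstrumentVariant(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta_exposure=beta, se_exposure=se, locus_label=locus
    )


def make_outcome(rsid="rs1", ea="A", oa="G", logor=0.1, se=0.05, cohort="UK"):
    return OutcomeAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, logor_outcome=logor, se_outcome=se, cohort=cohort
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
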