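import numpy as np
import pytest

from cismr.sumstats import VariantAssociation, harmonize


def make_assoc(**kw):
    """VariantAssociation with convenient defaults for tests."""
    defaults = dict(
        snp_id="rs1",
        effect_allele="T",
        other_allele="C",
        beta=0.3,
        se=0.05,
    )
    defaults.update(kw)
    return VariantAssociation(**defaults)


def make_pair(bx, sx, by, sy, outcome_type="quantitative", outcome_pval=None):
    """Harmonized instrument pair with given exposure/outcome summaries."""
    exp = make_assoc(beta=bx, se=sx, trait="exposure")
    out = make_assoc(
        beta=by, se=sy, trait="outcome", trait_type=outcome_type, pval=outcome_pval
    )
    return harmonize(exp, out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
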