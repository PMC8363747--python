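"""Auxiliary association statistics: effect-size comparison and LD summaries.

``compare_effects`` is the Z-test for whether two effect estimates differ
(e.g. fracture log-odds ratios at two skeletal sites); by default the
estimates are treated as independent, with an optional covariance term for
overlapping samples.

``ld_from_haplotype_freqs`` computes the classical two-locus linkage
disequilibrium summaries D, D′ and r² from the four haplotype frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import ValidationError

__all__ = ["EffectComparison", "LDStats", "compare_effects", "ld_from_haplotype_freqs"]


@dataclass
class EffectComparison:
    """Result of a two-effect Z-test."""

    z: float
    pval: float
    b1: float
    se1: float
    b2: float
    se2: float
    cov12: float = 0.0


@dataclass
class LDStats:
    """Two-locus LD summaries from haplotype frequencies.

    Alleles are labeled A/a at the first locus and B/b at the second;
    ``d = p_AB − p_A p_B`` is the raw disequilibrium, ``d_prime`` its
    magnitude normalized by the maximum attainable given the allele
    frequencies, and ``r2`` the squared allelic correlation.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    d: float
    d_prime: float
    r2: float


def compare_effects(
    b1: float,
    se1: float,
    b2: float,
    se2: float,
    cov12: float = 0.0,
) -> EffectComparison:
    """Z-test of the difference between two effect estimates.

    ``z = (b1 − b2) / sqrt(se1² + se2² − 2 cov12)`` with a two-sided normal
    p-value.  ``cov12`` defaults to 0 (independent estimates); supply the
    estimated covariance when both effects come from overlapping samples.
    """
    if not (se1 > 0 and se2 > 0):
        raise ValidationError("standard errors must be > 0")
    var_diff = se1**2 + se2**2 - 2.0 * cov12
    if not var_diff > 0:
        raise ValidationError(
            f"variance of the difference is not positive ({var_diff})"
        )
    z = (b1 - b2) / math.sqrt(var_diff)
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return EffectComparison(z=z, pval=pval, b1=b1, se1=se1, b2=b2, se2=se2, cov12=cov12)


def ld_from_haplotype_freqs(
    p_AB: float,
    p_Ab: float,
    p_aB: float,
    p_ab: float,
) -> LDStats:
    """LD summaries D, D′ and r² from the four haplotype frequencies.

    Frequencies must be non-negative and sum to 1 (within 1e-9), and both
    loci must be polymorphic.  ``d_prime = |d| / d_max`` where ``d_max`` is
    ``min(p_A p_b, p_a p_B)`` for positive d and ``min(p_A p_B, p_a p_b)``
    for negative d; ``r2 = d² / (p_A p_a p_B p_b)``.  Independence
    (``d = 0``) gives ``d_prime = r2 = 0``.
    """
    freqs = (p_AB, p_Ab, p_aB, p_ab)
    if any(f < 0 for f in freqs):
        raise ValidationError("haplotype frequencies must be non-negative")
    if abs(sum(freqs) - 1.0) > 1e-9:
        raise ValidationError(f"haplotype frequencies sum to {sum(freqs)}, not 1")
    p_A = p_AB + p_Ab
    p_B = p_AB + p_aB
    p_a, p_b = 1.0 - p_A, 1.0 - p_B
    if not (0 < p_A < 1 and 0 < p_B < 1):
        raise ValidationError("both loci must be polymorphic")
    d = p_AB - p_A * p_B
    if d > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    elif d < 0:
        d_max = min(p_A * p_B, p_a * p_b)
    else:
        d_max = None
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d**2 / (p_A * p_a * p_B * p_b)
    return LDStats(
        p_AB=p_AB, p_Ab=p_Ab, p_aB=p_aB, p_ab=p_ab, d=d, d_prime=d_prime, r2=r2
    )
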