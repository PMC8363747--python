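"""Bayesian colocalization of two traits at one locus.

Given per-SNP association summaries for two traits across the same set of
locus SNPs, and assuming at most one causal variant per trait, the method
computes posterior probabilities of five hypotheses:

- H0: neither trait has a causal variant in the region;
- H1 / H2: only trait 1 / only trait 2 has one;
- H3: both traits have one, at two distinct SNPs;
- H4: both traits share a single causal SNP.

Each SNP's evidence enters through the Wakefield approximate Bayes factor
against the null, computed from the estimated effect ``beta`` and its
variance ``varbeta`` under a N(0, W) effect prior:

    log ABF = ½ [ log(1 − r) + r z² ],   r = W / (W + varbeta),  z² = beta²/varbeta.

Hypothesis weights combine per-SNP ABFs with per-SNP prior probabilities
p1, p2 (causal for one trait) and p12 (causal for both); everything is
accumulated in log space for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .exceptions import ValidationError

__all__ = ["ColocTrait", "ColocResult", "log_abf", "coloc_abf"]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocTrait:
    """Per-SNP association summaries for one trait at the locus.

    ``prior_sd`` is the standard deviation W^{1/2} of the normal effect
    prior: 0.15 (SD units) for quantitative traits, 0.2 (log-odds) for
    case/control traits by convention.
    """

    snp_ids: list[str]
    beta: np.ndarray
    varbeta: np.ndarray
    trait_type: str = "quantitative"
    prior_sd: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.varbeta = np.asarray(self.varbeta, dtype=float)
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.prior_sd is None:
            self.prior_sd = 0.2 if self.trait_type == "case_control" else 0.15
        if not self.prior_sd > 0:
            raise ValidationError("prior_sd must be > 0")
        if len(self.snp_ids) != len(self.beta) or len(self.beta) != len(self.varbeta):
            raise ValidationError("snp_ids, beta and varbeta must have equal length")
        if len(self.snp_ids) < 1:
            raise ValidationError("at least one SNP required")
        if np.any(self.varbeta <= 0):
            raise ValidationError("all varbeta must be > 0")

    @classmethod
    def from_pval_maf(
        cls,
        snp_ids: list[str],
        pval: np.ndarray,
        maf: np.ndarray,
        n: int,
        trait_type: str = "quantitative",
        case_fraction: float | None = None,
        prior_sd: float | None = None,
    ) -> "ColocTrait":
        """Build a trait from p-values and allele frequencies.

        Approximates the per-SNP sampling variance from the study design:
        ``varbeta ≈ 1 / (2 n f (1−f))`` for a standardized quantitative
        trait, with an extra ``cf (1−cf)`` factor for case/control studies
        of case fraction ``cf``; the effect is then ``|z|·se`` signed
        arbitrarily positive (the ABF depends on z² only).
        """
        pval = np.asarray(pval, dtype=float)
        maf = np.asarray(maf, dtype=float)
        if np.any((maf <= 0) | (maf >= 1)):
            raise ValidationError("maf must be in (0, 1)")
        denom = 2.0 * n * maf * (1.0 - maf)
        if trait_type == "case_control":
            if case_fraction is None or not 0 < case_fraction < 1:
                raise ValidationError("case_control route needs case_fraction in (0,1)")
            denom = denom * case_fraction * (1.0 - case_fraction)
        varbeta = 1.0 / denom
        z = norm.isf(pval / 2.0)
        beta = z * np.sqrt(varbeta)
        return cls(snp_ids, beta, varbeta, trait_type=trait_type, prior_sd=prior_sd)


@dataclass
class ColocResult:
    """Posterior probabilities of H0–H4, per-SNP log-ABFs, and the priors
    used."""

    pp: dict[str, float]
    labf1: np.ndarray = field(repr=False)
    labf2: np.ndarray = field(repr=False)
    priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5)

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]


def log_abf(beta, varbeta, prior_sd: float):
    """Wakefield log approximate Bayes factor for one association.

    Vectorized over ``beta``/``varbeta``.  Positive values favor a real
    effect over the null; ``beta = 0`` gives ``½ log(1−r) < 0`` (the prior
    spreads mass over effects the data exclude), and the factor tends to 0
    as ``prior_sd → 0`` (the prior collapses onto the null).
    """
    beta = np.asarray(beta, dtype=float)
    varbeta = np.asarray(varbeta, dtype=float)
    if np.any(varbeta <= 0):
        raise ValidationError("varbeta must be > 0")
    if not prior_sd >= 0:
        raise ValidationError("prior_sd must be >= 0")
    w = prior_sd**2
    r = w / (w + varbeta)
    z2 = beta**2 / varbeta
    return 0.5 * (np.log1p(-r) + r * z2)


def coloc_abf(
    trait1: ColocTrait,
    trait2: ColocTrait,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Posterior probabilities of shared vs distinct causal variants.

    Both traits must cover the same SNPs in the same order.  Hypothesis
    weights are assembled in log space:

    - H0: 0 (reference)
    - H1: log p1 + logΣ exp(labf1)
    - H2: log p2 + logΣ exp(labf2)
    - H4: log p12 + logΣ exp(labf1 + labf2)
    - H3: log p1 p2 + log( Σ_i Σ_{j≠i} exp(labf1_i + labf2_j) ), computed as
      a stable log-space subtraction of the shared-SNP diagonal from the
      full product; if the subtraction underflows (as it must with a single
      SNP, where no i ≠ j pair exists) the H3 weight is −inf.

    Posteriors are the softmax of the five weights.
    """
    for p, name in ((p1, "p1"), (p2, "p2"), (p12, "p12")):
        if not 0 < p < 1:
            raise ValidationError(f"{name} must be in (0, 1)")
    if trait1.snp_ids != trait2.snp_ids:
        raise ValidationError(
            "trait SNP lists differ or are ordered differently — intersect "
            "and align them first"
        )
    l1 = log_abf(trait1.beta, trait1.varbeta, trait1.prior_sd)
    l2 = log_abf(trait2.beta, trait2.varbeta, trait2.prior_sd)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)

    h0 = 0.0
    h1 = np.log(p1) + s1
    h2 = np.log(p2) + s2
    h4 = np.log(p12) + s12
    # off-diagonal sum: exp(s1)exp(s2) − exp(s12), in log space
    total = s1 + s2
    if s12 >= total:
        h3 = -np.inf
    else:
        h3 = np.log(p1) + np.log(p2) + total + np.log1p(-np.exp(s12 - total))

    weights = np.array([h0, h1, h2, h3, h4])
    pp = np.exp(weights - logsumexp(weights))
    pp /= pp.sum()
    return ColocResult(
        pp=dict(zip(HYPOTHESES, pp.tolist())),
        labf1=l1,
        labf2=l2,
        priors=(p1, p2, p12),
    )
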