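"""Two-sample Mendelian randomization estimators.

Implements the single-instrument Wald ratio, the fixed-effect
inverse-variance-weighted (IVW) combination of Wald ratios with Cochran's Q
heterogeneity statistic, and a bidirectional wrapper that runs IVW in both
causal directions to probe reverse causation.

The Wald ratio divides the instrument's outcome association by its exposure
association: with a valid instrument the ratio estimates the causal effect
of one SD (or one unit) of exposure on the outcome.  Its first-order
standard error, ``se_out / |beta_exp|``, treats the exposure association as
known; it preserves the outcome association's Z-score (and hence p-value)
exactly, which is the convention used when instruments are strong cis-QTLs.
The second-order (delta-method) SE adds the exposure-uncertainty term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import CismrError, ScaleError, ValidationError
from .sumstats import InstrumentPair

__all__ = ["MRResult", "wald_ratio", "ivw", "bidirectional_mr", "to_or_scale"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """A causal-effect estimate from summary-statistics MR.

    ``beta_mr`` is on the outcome scale per SD of exposure: linear for
    quantitative outcomes, log-odds for binary outcomes (``outcome_scale``).
    ``q_stat``/``q_df``/``q_pval`` carry Cochran's heterogeneity test and
    are present only with two or more instruments.
    """

    beta_mr: float
    se_mr: float
    ci_low: float
    ci_high: float
    pval: float
    n_instruments: int
    method: str  # "wald_ratio" | "ivw"
    outcome_scale: str  # "linear" | "log_odds"
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None


def _two_sided_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _check_pair(pair: InstrumentPair) -> None:
    if not pair.harmonized:
        raise CismrError(
            f"{pair.exposure.snp_id}: pair not harmonized — call harmonize() first"
        )
    if pair.exposure.beta == 0:
        raise ValidationError(
            f"{pair.exposure.snp_id}: exposure beta is 0 — Wald ratio undefined"
        )
    if pair.exposure.se is None or pair.outcome.se is None:
        raise ValidationError(
            f"{pair.exposure.snp_id}: both associations need standard errors"
        )


def wald_ratio(
    pair: InstrumentPair,
    se_mode: str = "first_order",
    level: float = 0.95,
) -> MRResult:
    """Single-instrument Wald ratio: outcome effect / exposure effect.

    With ``se_mode="first_order"`` the SE is ``outcome.se / |exposure.beta|``
    and the outcome association's Z-score is preserved exactly; the result's
    p-value is therefore the outcome association's own p-value (taken from
    the outcome record when available, since a recorded p reflects the
    unrounded Z of the source GWAS).  ``"second_order"`` adds the
    delta-method term for exposure uncertainty:
    ``se² = se_out²/b_exp² + b_out²·se_exp²/b_exp⁴``.
    """
    _check_pair(pair)
    if se_mode not in ("first_order", "second_order"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    bx, sx = pair.exposure.beta, pair.exposure.se
    by, sy = pair.outcome.beta, pair.outcome.se
    beta = by / bx
    if se_mode == "first_order":
        se = sy / abs(bx)
        pval = pair.outcome.pval if pair.outcome.pval is not None else _two_sided_p(by, sy)
    else:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        pval = _two_sided_p(beta, se)
    z = stats.norm.ppf(0.5 + level / 2.0)
    scale = "log_odds" if pair.outcome.trait_type == "case_control" else "linear"
    return MRResult(
        beta_mr=beta,
        se_mr=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pval=pval,
        n_instruments=1,
        method="wald_ratio",
        outcome_scale=scale,
    )


def ivw(
    pairs: list[InstrumentPair],
    se_mode: str = "first_order",
    level: float = 0.95,
) -> MRResult:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios.

    Each instrument contributes its Wald ratio ``b_i`` with variance ``v_i``;
    the pooled estimate is ``Σ(b_i/v_i) / Σ(1/v_i)`` with variance
    ``1/Σ(1/v_i)``.  Cochran's Q, ``Σ (b_i − b̂)²/v_i`` on ``n−1`` degrees of
    freedom, quantifies between-instrument heterogeneity (reported for
    n ≥ 2).  A single instrument reduces to :func:`wald_ratio` exactly.
    """
    if not pairs:
        raise ValidationError("ivw requires at least one instrument")
    singles = [wald_ratio(p, se_mode=se_mode, level=level) for p in pairs]
    if len(singles) == 1:
        r = singles[0]
        return MRResult(**{**r.__dict__, "method": "ivw"})
    b = np.array([r.beta_mr for r in singles])
    v = np.array([r.se_mr**2 for r in singles])
    w = 1.0 / v
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    q = float(np.sum((b - beta) ** 2 / v))
    q_df = len(pairs) - 1
    z = stats.norm.ppf(0.5 + level / 2.0)
    scales = {r.outcome_scale for r in singles}
    if len(scales) != 1:
        raise ValidationError("instruments mix linear and log-odds outcomes")
    return MRResult(
        beta_mr=beta,
        se_mr=se,
        ci_low=beta - z * se,
        ci_high=beta + z * se,
        pval=_two_sided_p(beta, se),
        n_instruments=len(pairs),
        method="ivw",
        outcome_scale=scales.pop(),
        q_stat=q,
        q_df=q_df,
        q_pval=float(stats.chi2.sf(q, q_df)),
    )


def bidirectional_mr(
    forward_pairs: list[InstrumentPair],
    reverse_pairs: list[InstrumentPair],
    se_mode: str = "first_order",
) -> tuple[MRResult, MRResult]:
    """Run IVW in both causal directions.

    ``forward_pairs`` instrument the hypothesized exposure→outcome effect;
    ``reverse_pairs`` instrument the outcome as an exposure (using variants
    that affect it directly) to test for reverse causation.  A null reverse
    estimate supports the forward causal reading.
    """
    return ivw(forward_pairs, se_mode=se_mode), ivw(reverse_pairs, se_mode=se_mode)


def to_or_scale(
    result: MRResult, level: float = 0.95
) -> tuple[float, float, float]:
    """Present a log-odds MR result as (OR, CI low, CI high)."""
    if result.outcome_scale != "log_odds":
        raise ScaleError("result is on a linear scale; odds ratios undefined")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        math.exp(result.beta_mr),
        math.exp(result.beta_mr - z * result.se_mr),
        math.exp(result.beta_mr + z * result.se_mr),
    )
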