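"""Synthetic cis-locus cohorts with a protein → BMD → fracture causal chain.

The generator emulates the causal structure that summary-statistics MR of a
circulating protein assumes: a cis locus of correlated biallelic SNPs, one
of which raises the circulating protein level; the protein raises a
continuous bone-mineral-density (BMD) mediator; and BMD lowers the odds of
a binary fracture outcome through a logistic link.

LD between SNPs is induced by drawing each individual's two haplotypes
independently from an explicit haplotype pool, so every haplotype (and
therefore every pairwise LD coefficient) has an analytically known
frequency.  Per-SNP association summary statistics are then computed from
the simulated cohort — simple linear regression for the continuous traits
(standardized to unit SD first, so betas are in SD-per-allele units) and
logistic regression fitted by IRLS for fracture — emulating the lookup
tables a two-sample MR consumes.

Structural equations (per individual, ``g`` = causal-SNP allele count)::

    base    = Σ_j d_j g_j + ε_b            ε_b ~ N(0, bmd_noise_sd²)
    protein = β_gp g + β_bp base + ε_p     ε_p ~ N(0, protein_noise_sd²)
    bmd     = β_pb protein + base
    P(fracture) = logistic(α₀ + β_bf · bmd_std)

``base`` is the protein-independent component of BMD.  ``d_j``
(``direct_bmd_effects``) are optional direct genotype→BMD effects: a SNP
with a direct effect, unlinked to the protein SNP, is a valid instrument
for the reverse (BMD→protein) direction, mirroring the genome-wide BMD
instruments used in bidirectional MR.  ``β_bp`` (``reverse_beta_bp``)
injects true reverse causation when nonzero.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats
from scipy.special import expit

from .assoc_stats import LDStats, ld_from_haplotype_freqs
from .exceptions import ValidationError
from .mr import MRResult, ivw, wald_ratio
from .sumstats import VariantAssociation, harmonize

__all__ = [
    "SyntheticLocusConfig",
    "CohortData",
    "RecoveryReport",
    "simulate_cohort",
    "cohort_sumstats",
    "recovery_experiment",
    "default_haplotype_pool",
    "random_haplotype_pool",
    "cross_pools",
    "pool_allele_freq",
    "pool_ld",
    "standardized_mediation_effect",
]


def default_haplotype_pool() -> list[tuple[str, float]]:
    """Three-SNP pool mirroring the magnitudes of a real cis-pQTL locus.

    SNP 0 (the default causal SNP, allele frequency 0.50) and SNP 1
    (frequency 0.53) are in strong LD (r² ≈ 0.74, D′ ≈ 0.91), like the two
    cis-pQTL instruments of the RSPO3 locus; SNP 2 (frequency 0.30)
    segregates independently.
    """
    two_locus = [("11", 0.48), ("10", 0.02), ("01", 0.05), ("00", 0.45)]
    third = [("1", 0.30), ("0", 0.70)]
    return cross_pools(two_locus, third)


def cross_pools(
    pool_a: list[tuple[str, float]], pool_b: list[tuple[str, float]]
) -> list[tuple[str, float]]:
    """Product pool of two independent haplotype blocks (concatenated
    haplotypes, multiplied frequencies) — the blocks end up in linkage
    equilibrium with each other."""
    return [(ha + hb, fa * fb) for ha, fa in pool_a for hb, fb in pool_b]


def random_haplotype_pool(
    n_snps: int,
    n_haplotypes: int = 12,
    rng: np.random.Generator | None = None,
    copy_prob: float = 0.85,
) -> list[tuple[str, float]]:
    """Random pool of ``n_haplotypes`` founder haplotypes over ``n_snps``
    SNPs with LD along the locus.

    Alleles follow a two-state Markov chain along each haplotype (the next
    SNP copies the previous allele with probability ``copy_prob``), which
    induces the block-like decaying LD of a real locus.  Frequencies are
    Dirichlet(1); pools with monomorphic SNPs are resampled.
    """
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(200):
        haps = np.empty((n_haplotypes, n_snps), dtype=np.uint8)
        haps[:, 0] = rng.integers(0, 2, size=n_haplotypes)
        for j in range(1, n_snps):
            copy = rng.random(n_haplotypes) < copy_prob
            haps[:, j] = np.where(copy, haps[:, j - 1], rng.integers(0, 2, n_haplotypes))
        freqs = rng.dirichlet(np.ones(n_haplotypes))
        af = freqs @ haps
        if np.all((af > 0.05) & (af < 0.95)):
            return [
                ("".join(map(str, h)), float(f)) for h, f in zip(haps.tolist(), freqs)
            ]
    raise RuntimeError("could not sample a polymorphic haplotype pool")


@dataclass
class SyntheticLocusConfig:
    """Parameters of one simulated cohort.

    Defaults mirror the magnitudes of the motivating cis-pQTL study: an
    instrument→protein effect of ≈ 0.32 SD per allele, a protein→BMD effect
    of 0.3 SD per SD, and a BMD→fracture log-odds slope chosen so one SD of
    protein maps to a fracture OR ≈ 0.83 (for demonstration, not a target).
    """

    n_individuals: int
    haplotype_pool: list[tuple[str, float]] = field(
        default_factory=default_haplotype_pool
    )
    causal_snp_index: int = 0
    beta_gp: float = 0.32  # SNP → protein, SD units per allele
    beta_pb: float = 0.30  # protein → BMD, SD per SD (raw-scale coefficient)
    alpha0: float = -2.2  # logistic intercept (≈10% fracture prevalence)
    beta_bf: float = -0.62  # BMD → fracture, log-odds per SD of BMD
    reverse_beta_bp: float = 0.0  # true BMD → protein feedback
    direct_bmd_effects: dict[int, float] = field(default_factory=dict)
    protein_noise_sd: float = 1.0
    bmd_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValidationError("n_individuals must be >= 2")
        if len(self.haplotype_pool) < 2:
            raise ValidationError(
                "degenerate haplotype pool: at least two haplotypes required "
                "(one haplotype makes every SNP monomorphic)"
            )
        lengths = {len(h) for h, _ in self.haplotype_pool}
        if len(lengths) != 1:
            raise ValidationError("haplotypes must all have the same length")
        freqs = np.array([f for _, f in self.haplotype_pool])
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValidationError("haplotype frequencies must be >= 0 and sum to 1")
        m = lengths.pop()
        if not 0 <= self.causal_snp_index < m:
            raise ValidationError("causal_snp_index out of range")
        for j in self.direct_bmd_effects:
            if not 0 <= j < m:
                raise ValidationError(f"direct_bmd_effects index {j} out of range")
        for name in ("beta_gp", "beta_pb", "alpha0", "beta_bf", "reverse_beta_bp"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    @property
    def n_snps(self) -> int:
        return len(self.haplotype_pool[0][0])

    @classmethod
    def from_yaml(cls, path) -> "SyntheticLocusConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "haplotype_pool" in raw:
            raw["haplotype_pool"] = [(str(h), float(f)) for h, f in raw["haplotype_pool"]]
        if "direct_bmd_effects" in raw:
            raw["direct_bmd_effects"] = {
                int(k): float(v) for k, v in raw["direct_bmd_effects"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["haplotype_pool"] = [[h, f] for h, f in self.haplotype_pool]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class CohortData:
    """Simulated individual-level data: allele counts and the three traits.

    ``protein`` and ``bmd`` are standardized to zero mean / unit SD (so
    association betas are in SD-per-allele units); ``fracture`` is 0/1.
    """

    genotypes: np.ndarray  # (n, M) allele counts in {0, 1, 2}
    protein: np.ndarray
    bmd: np.ndarray
    fracture: np.ndarray
    snp_ids: list[str]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValidationError("trait has zero variance; cannot standardize")
    return (x - x.mean()) / sd


def simulate_cohort(config: SyntheticLocusConfig) -> CohortData:
    """Draw one cohort from the structural model (bit-reproducible from
    ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    haps = np.array(
        [[int(b) for b in h] for h, _ in config.haplotype_pool], dtype=np.uint8
    )
    freqs = np.array([f for _, f in config.haplotype_pool], dtype=float)
    freqs = freqs / freqs.sum()
    n = config.n_individuals
    idx = rng.choice(len(freqs), size=(2, n), p=freqs)
    genotypes = (haps[idx[0]] + haps[idx[1]]).astype(np.int8)

    g_causal = genotypes[:, config.causal_snp_index].astype(float)
    eps_b = rng.normal(0.0, config.bmd_noise_sd, size=n)
    eps_p = rng.normal(0.0, config.protein_noise_sd, size=n)

    base = eps_b.copy()
    for j, d in config.direct_bmd_effects.items():
        base += d * genotypes[:, j]
    protein_raw = config.beta_gp * g_causal + config.reverse_beta_bp * base + eps_p
    bmd_raw = config.beta_pb * protein_raw + base

    protein = _standardize(protein_raw)
    bmd = _standardize(bmd_raw)
    fracture = rng.binomial(
        1, expit(config.alpha0 + config.beta_bf * bmd)
    ).astype(np.int8)
    snp_ids = [f"snp{j}" for j in range(genotypes.shape[1])]
    return CohortData(
        genotypes=genotypes,
        protein=protein,
        bmd=bmd,
        fracture=fracture,
        snp_ids=snp_ids,
    )


# --- per-SNP association models -------------------------------------------

def _linear_assoc(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple linear regression of y on allele count: (beta, se, p).

    p from the t distribution on n−2 degrees of freedom.
    """
    n = len(g)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    beta = float(gc @ yc) / sxx
    rss = float(yc @ yc) - beta * float(gc @ yc)
    # rss can hit 0 (perfect fit); keep se strictly positive
    sigma2 = max(rss, 0.0) / (n - 2)
    se = math.sqrt(max(sigma2, np.finfo(float).tiny) / sxx)
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return beta, se, max(p, np.finfo(float).tiny)


def _logistic_irls(
    g: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[float, float | None]:
    """Intercept + allele-count logistic regression by IRLS.

    Returns (beta, se); se is None when the fit fails to converge or the
    data are separated (diverging coefficient).
    """
    X = np.column_stack([np.ones_like(g, dtype=float), g.astype(float)])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        if np.any(w < 1e-12) and np.max(np.abs(beta)) > 30:
            return float(beta[1]), None  # separation
        xtw = X.T * w
        try:
            delta = np.linalg.solve(xtw @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return float(beta[1]), None
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            info = (X.T * (expit(X @ beta) * (1 - expit(X @ beta)))) @ X
            se = math.sqrt(np.linalg.inv(info)[1, 1])
            return float(beta[1]), se
    return float(beta[1]), None  # not converged


def cohort_sumstats(cohort: CohortData, trait: str) -> list[VariantAssociation]:
    """Per-SNP GWAS-style summary statistics for one trait of the cohort.

    Continuous traits (``"protein"``, ``"bmd"``) use simple linear
    regression of the standardized trait on allele count; ``"fracture"``
    uses logistic regression (IRLS, tolerance 1e-8, ≤50 iterations) with
    betas on the log-odds scale.  Monomorphic SNPs are skipped with a
    warning; non-converged or separated logistic fits yield a row with
    ``se=None``.

    Every SNP's effect allele is reported as the alternate ('1') allele,
    labeled A (reference G).
    """
    if trait not in ("protein", "bmd", "fracture"):
        raise ValidationError(f"unknown trait {trait!r}")
    y = getattr(cohort, trait).astype(float)
    n = cohort.n_individuals
    out: list[VariantAssociation] = []
    for j in range(cohort.n_snps):
        g = cohort.genotypes[:, j].astype(float)
        if g.min() == g.max():
            warnings.warn(f"{cohort.snp_ids[j]} is monomorphic; skipped", stacklevel=2)
            continue
        eaf = float(g.mean() / 2.0)
        common = dict(
            snp_id=cohort.snp_ids[j],
            effect_allele="A",
            other_allele="G",
            eaf=eaf,
            trait=trait,
        )
        if trait == "fracture":
            beta, se = _logistic_irls(g, y)
            pval = None if se is None else max(
                float(2.0 * stats.norm.sf(abs(beta / se))), np.finfo(float).tiny
            )
            out.append(
                VariantAssociation(
                    beta=beta,
                    se=se,
                    pval=pval,
                    n_cases=int(y.sum()),
                    n_controls=int(n - y.sum()),
                    n=n,
                    trait_type="case_control",
                    **common,
                )
            )
        else:
            beta, se, pval = _linear_assoc(g, y)
            out.append(
                VariantAssociation(
                    beta=beta, se=se, pval=pval, n=n, trait_type="quantitative", **common
                )
            )
    return out


# --- analytic helpers ------------------------------------------------------

def pool_allele_freq(pool: list[tuple[str, float]], snp: int) -> float:
    """Alternate-allele frequency of one SNP implied by the pool."""
    return float(sum(f for h, f in pool if h[snp] == "1"))


def pool_ld(pool: list[tuple[str, float]], snp_a: int, snp_b: int) -> LDStats:
    """Exact LD between two pool SNPs (A/B = the '1' alleles)."""
    p = {"11": 0.0, "10": 0.0, "01": 0.0, "00": 0.0}
    for h, f in pool:
        p[h[snp_a] + h[snp_b]] += f
    return ld_from_haplotype_freqs(p["11"], p["10"], p["01"], p["00"])


def _pool_geno_cov(pool: list[tuple[str, float]], i: int, j: int) -> float:
    """Covariance of allele counts at SNPs i and j (two independent
    haplotype draws double the per-haplotype covariance)."""
    pi, pj = pool_allele_freq(pool, i), pool_allele_freq(pool, j)
    pij = sum(f for h, f in pool if h[i] == "1" and h[j] == "1")
    return 2.0 * (pij - pi * pj)


def standardized_mediation_effect(config: SyntheticLocusConfig) -> float:
    """Population protein→BMD effect on the standardized (per-SD) scale.

    The structural coefficient ``beta_pb`` acts on raw trait scales; after
    both traits are standardized, the per-SD effect is
    ``beta_pb · sd(protein_raw) / sd(bmd_raw)``, computed here in closed
    form from the pool frequencies and noise SDs.  This is the estimand the
    MR pipeline targets on synthetic data.
    """
    pool = config.haplotype_pool
    c = config.causal_snp_index
    var_g = _pool_geno_cov(pool, c, c)
    idx = sorted(config.direct_bmd_effects)
    var_base = config.bmd_noise_sd**2
    for a in idx:
        for b in idx:
            var_base += (
                config.direct_bmd_effects[a]
                * config.direct_bmd_effects[b]
                * _pool_geno_cov(pool, a, b)
            )
    cov_g_base = sum(
        config.direct_bmd_effects[j] * _pool_geno_cov(pool, c, j) for j in idx
    )
    var_p = (
        config.beta_gp**2 * var_g
        + config.reverse_beta_bp**2 * var_base
        + config.protein_noise_sd**2
        + 2.0 * config.beta_gp * config.reverse_beta_bp * cov_g_base
    )
    cov_p_base = config.reverse_beta_bp * var_base + config.beta_gp * cov_g_base
    var_b = config.beta_pb**2 * var_p + var_base + 2.0 * config.beta_pb * cov_p_base
    return config.beta_pb * math.sqrt(var_p / var_b)


# --- recovery harness ------------------------------------------------------

@dataclass
class RecoveryReport:
    """Monte-Carlo performance of the MR pipeline on synthetic cohorts."""

    true_effect: float
    estimates: np.ndarray = field(repr=False)
    mean_bias: float = 0.0
    rmse: float = 0.0
    coverage: float = 0.0
    n_replicates: int = 0
    estimator: str = "wald"


def recovery_experiment(
    config: SyntheticLocusConfig,
    n_replicates: int,
    estimator: str = "wald",
    se_mode: str = "first_order",
) -> RecoveryReport:
    """Repeatedly simulate, run MR at the causal SNP, and score recovery of
    the standardized protein→BMD effect.

    Per replicate: simulate a cohort, compute protein and BMD summary
    statistics at the causal SNP, harmonize, and estimate the causal effect
    with the Wald ratio (or single-instrument IVW).  Reports mean bias,
    RMSE, and 95% CI coverage against the closed-form standardized
    generative effect.  Replicate seeds derive from ``config.seed``.
    """
    if estimator not in ("wald", "ivw"):
        raise ValidationError(f"unknown estimator {estimator!r}")
    if config.beta_gp == 0:
        raise ValidationError("recovery_experiment needs a nonzero beta_gp")
    truth = standardized_mediation_effect(config)
    child_seeds = (
        np.random.SeedSequence(config.seed).generate_state(n_replicates) & 0x7FFFFFFF
    )
    estimates = np.empty(n_replicates)
    covered = 0
    c = config.causal_snp_index
    for i, s in enumerate(child_seeds):
        cohort = simulate_cohort(dataclasses.replace(config, seed=int(s)))
        g = cohort.genotypes[:, c].astype(float)
        bx, sx, px = _linear_assoc(g, cohort.protein)
        by, sy, py = _linear_assoc(g, cohort.bmd)
        exp_assoc = VariantAssociation(
            snp_id=cohort.snp_ids[c], effect_allele="A", other_allele="G",
            beta=bx, se=sx, pval=px, trait="protein",
        )
        out_assoc = VariantAssociation(
            snp_id=cohort.snp_ids[c], effect_allele="A", other_allele="G",
            beta=by, se=sy, pval=py, trait="bmd",
        )
        pair = harmonize(exp_assoc, out_assoc)
        res: MRResult = (
            wald_ratio(pair, se_mode=se_mode)
            if estimator == "wald"
            else ivw([pair], se_mode=se_mode)
        )
        estimates[i] = res.beta_mr
        covered += int(res.ci_low <= truth <= res.ci_high)
    bias = float(estimates.mean() - truth)
    rmse = float(np.sqrt(np.mean((estimates - truth) ** 2)))
    return RecoveryReport(
        true_effect=truth,
        estimates=estimates,
        mean_bias=bias,
        rmse=rmse,
        coverage=covered / n_replicates,
        n_replicates=n_replicates,
        estimator=estimator,
    )
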