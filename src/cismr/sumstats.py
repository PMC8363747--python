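"""GWAS summary-statistics data model, file I/O, and allele harmonization.

One row of a GWAS summary-statistics table is a :class:`VariantAssociation`:
the per-allele effect of one SNP on one trait, with its standard error and
supporting metadata.  Binary-trait effects are stored on the log-odds scale
internally; odds ratios are converted on the way in (``or_ci_to_beta_se``)
and are a presentation concern on the way out.

Two-sample Mendelian randomization needs the exposure and outcome effects of
an instrument expressed per copy of the *same* allele; :func:`harmonize`
aligns an exposure/outcome pair into an :class:`InstrumentPair`, flipping
the outcome effect sign (and EAF) when its effect allele is the exposure's
other allele, resolving strand flips by complementing, and refusing to
orient palindromic variants whose allele frequencies are uninformative.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .exceptions import (
    AmbiguousPalindromeError,
    HarmonizationError,
    SumstatsFormatError,
    ValidationError,
)

__all__ = [
    "VariantAssociation",
    "InstrumentPair",
    "or_ci_to_beta_se",
    "harmonize",
    "read_sumstats",
    "write_sumstats",
    "DEFAULT_COLUMNS",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Standard column names of the TSV dialect (tab- or whitespace-separated,
#: header row).  ``dialect`` maps these standard names to the names actually
#: present in a file.
DEFAULT_COLUMNS = (
    "snp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pval",
    "n",
    "n_cases",
    "n_controls",
    "trait",
    "trait_type",
)


def _complement(allele: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        raise ValidationError(f"cannot strand-complement allele {allele!r}") from None


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2


@dataclass
class VariantAssociation:
    """One variant-trait association from a GWAS summary-statistics table.

    ``beta`` is the effect per copy of ``effect_allele``: SD units for
    quantitative traits, log-odds for case/control traits.  ``se`` may be
    missing (e.g. normalized eQTL effect sizes published without one), in
    which case the row can be carried around but not used as an MR input.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float | None = None
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    trait: str = ""
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.snp_id}: effect and other allele are both {self.effect_allele!r}"
            )
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValidationError(
                f"{self.snp_id}: trait_type must be 'quantitative' or "
                f"'case_control', got {self.trait_type!r}"
            )
        if self.se is not None and not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.pval is not None and not 0.0 < self.pval <= 1.0:
            raise ValidationError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is unresolvable from
        allele labels alone."""
        return _is_palindromic(self.effect_allele, self.other_allele)

    def flipped(self) -> "VariantAssociation":
        """The same association expressed per copy of the other allele."""
        return dataclasses.replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def zscore(self) -> float:
        if self.se is None:
            raise ValidationError(f"{self.snp_id}: no standard error available")
        return self.beta / self.se


@dataclass
class InstrumentPair:
    """Exposure and outcome associations of one instrument, allele-aligned.

    ``harmonized`` is set by :func:`harmonize`; MR estimators refuse
    unharmonized pairs.
    """

    exposure: VariantAssociation
    outcome: VariantAssociation
    harmonized: bool = False


def or_ci_to_beta_se(
    or_value: float,
    ci_low: float,
    ci_high: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Convert an odds ratio with confidence interval to (log-odds, SE).

    The SE is recovered from the CI width on the log scale,
    ``se = (ln ci_high - ln ci_low) / (2 z)`` with ``z`` the two-sided
    standard-normal quantile for ``level`` (1.959964 at 95%).

    Raises
    ------
    ValidationError
        If the ordering ``0 < ci_low <= or_value <= ci_high`` is violated or
        the interval has zero width (SE would be 0).
    """
    if not (0 < ci_low <= or_value <= ci_high):
        raise ValidationError(
            f"CI ordering violated: need 0 < ci_low <= or <= ci_high, "
            f"got or={or_value}, ci=({ci_low}, {ci_high})"
        )
    if ci_low == ci_high:
        raise ValidationError("zero-width confidence interval: se would be 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    beta = math.log(or_value)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return beta, se


def harmonize(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindromic_eaf_window: float = 0.08,
) -> InstrumentPair:
    """Align an outcome association to the exposure's effect allele.

    Allele labels are matched directly, after swapping, or after strand
    complementation (or both).  When the outcome's effect allele matches the
    exposure's other allele, the outcome is flipped: beta negated, EAF
    reflected, alleles relabeled to the exposure's.  Harmonizing an already
    aligned pair returns it unchanged (idempotent).

    Palindromic variants (A/T, C/G) cannot be oriented from labels; they are
    oriented from allele frequencies instead, and rejected with
    :class:`AmbiguousPalindromeError` when both EAFs lie within
    ``palindromic_eaf_window`` of 0.5 (or either is missing).
    """
    if exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele

    if exposure.is_palindromic:
        if not _is_palindromic(outcome.effect_allele, outcome.other_allele) or {
            outcome.effect_allele,
            outcome.other_allele,
        } != {ea, oa}:
            raise HarmonizationError(
                f"{exposure.snp_id}: allele sets incompatible "
                f"({ea}/{oa} vs {outcome.effect_allele}/{outcome.other_allele})"
            )
        # Labels cannot distinguish strands; orient by EAF.
        if exposure.eaf is None or outcome.eaf is None:
            raise AmbiguousPalindromeError(
                f"{exposure.snp_id}: palindromic variant without both EAFs"
            )
        if (
            abs(exposure.eaf - 0.5) < palindromic_eaf_window
            and abs(outcome.eaf - 0.5) < palindromic_eaf_window
        ):
            raise AmbiguousPalindromeError(
                f"{exposure.snp_id}: palindromic variant with both EAFs within "
                f"{palindromic_eaf_window} of 0.5 — cannot orient"
            )
        same_orientation = (exposure.eaf - 0.5) * (outcome.eaf - 0.5) > 0
        aligned = outcome if same_orientation else outcome.flipped()
        # Relabel to the exposure's strand representation.
        aligned = dataclasses.replace(aligned, effect_allele=ea, other_allele=oa)
        return InstrumentPair(exposure, aligned, harmonized=True)

    out_alleles = (outcome.effect_allele, outcome.other_allele)
    if out_alleles == (ea, oa):
        aligned = outcome
    elif out_alleles == (oa, ea):
        aligned = outcome.flipped()
    elif (_complement(out_alleles[0]), _complement(out_alleles[1])) == (ea, oa):
        aligned = dataclasses.replace(outcome, effect_allele=ea, other_allele=oa)
    elif (_complement(out_alleles[0]), _complement(out_alleles[1])) == (oa, ea):
        aligned = dataclasses.replace(
            outcome.flipped(), effect_allele=ea, other_allele=oa
        )
    else:
        raise HarmonizationError(
            f"{exposure.snp_id}: allele sets incompatible "
            f"({ea}/{oa} vs {out_alleles[0]}/{out_alleles[1]})"
        )
    return InstrumentPair(exposure, aligned, harmonized=True)


def _get(row: pd.Series, col: str | None):
    if col is None or col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() in ("", "NA", "."):
        return None
    return v


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
) -> list[VariantAssociation]:
    """Read a summary-statistics table into :class:`VariantAssociation` rows.

    The file is tab- or whitespace-separated with a header row.  ``dialect``
    maps the standard column names (:data:`DEFAULT_COLUMNS`) to the file's
    column names; unmapped standard names default to themselves.  Rows that
    supply an odds ratio with a 95% CI instead of beta/SE are converted via
    :func:`or_ci_to_beta_se`.

    Raises
    ------
    SumstatsFormatError
        If mandatory columns (snp, effect_allele, other_allele) are absent,
        or a row supplies neither beta nor OR+CI; the message names the
        offending line.
    ValidationError
        If a row's values violate their contracts (message names the line).
    """
    colmap = {name: name for name in DEFAULT_COLUMNS}
    if dialect:
        colmap.update(dialect)
    # tab-separated when the header says so (empty fields stay aligned),
    # otherwise any-whitespace separation
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else r"\s+"
    df = pd.read_csv(path, sep=sep, dtype={colmap["snp"]: str})
    for mandatory in ("snp", "effect_allele", "other_allele"):
        if colmap[mandatory] not in df.columns:
            raise SumstatsFormatError(
                f"{path}: missing mandatory column {colmap[mandatory]!r}"
            )

    records: list[VariantAssociation] = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        beta = _get(row, colmap["beta"])
        se = _get(row, colmap["se"])
        or_value = _get(row, colmap["or"])
        try:
            if beta is None:
                if or_value is None:
                    raise SumstatsFormatError(
                        f"{path}:{line}: row has neither beta nor or/ci_low/ci_high"
                    )
                ci_low = _get(row, colmap["ci_low"])
                ci_high = _get(row, colmap["ci_high"])
                if ci_low is None or ci_high is None:
                    raise SumstatsFormatError(
                        f"{path}:{line}: or supplied without ci_low/ci_high"
                    )
                beta, se = or_ci_to_beta_se(float(or_value), float(ci_low), float(ci_high))
            n_cases = _get(row, colmap["n_cases"])
            n_controls = _get(row, colmap["n_controls"])
            n = _get(row, colmap["n"])
            if n is None and n_cases is not None and n_controls is not None:
                n = int(n_cases) + int(n_controls)
            records.append(
                VariantAssociation(
                    snp_id=str(_get(row, colmap["snp"])),
                    effect_allele=str(_get(row, colmap["effect_allele"])),
                    other_allele=str(_get(row, colmap["other_allele"])),
                    beta=float(beta),
                    se=None if se is None else float(se),
                    eaf=None if (v := _get(row, colmap["eaf"])) is None else float(v),
                    # GWAS p-values can underflow double precision
                    # (e.g. 5.6E-336); clamp to the smallest positive float
                    pval=None
                    if (v := _get(row, colmap["pval"])) is None
                    else (float(v) or 5e-324),
                    n=None if n is None else int(n),
                    n_cases=None if n_cases is None else int(n_cases),
                    n_controls=None if n_controls is None else int(n_controls),
                    trait=str(_get(row, colmap["trait"]) or ""),
                    trait_type=str(_get(row, colmap["trait_type"]) or "quantitative"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from exc
    return records


def write_sumstats(records: Sequence[VariantAssociation], path) -> None:
    """Write associations as a TSV in the standard dialect (beta/SE
    representation; lossless round trip with :func:`read_sumstats`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "snp": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "trait": r.trait,
                "trait_type": r.trait_type,
            }
        )
    df = pd.DataFrame(rows)
    # repr() of a float is its shortest round-tripping decimal form
    df.to_csv(
        path, sep="\t", index=False, na_rep="NA",
        float_format=lambda v: repr(float(v)),
    )
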