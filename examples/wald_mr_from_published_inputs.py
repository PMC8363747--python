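"""Single-instrument Wald-ratio MR from the packaged association fixture.

Estimates the causal effect of circulating RSPO3 (per SD) on trabecular
volumetric BMD, using the cis-pQTL rs3734626 as the instrument: the
outcome association (per T-allele) is divided by the exposure association
(per T-allele), so the allele drops out and the estimate is per SD of
protein.
"""

from cismr import harmonize, read_sumstats, wald_ratio
from cismr.rspo3 import fixture_path

records = {(r.snp_id, r.trait): r for r in read_sumstats(fixture_path())}
exposure = records[("rs3734626", "rspo3_circulating")]   # beta 0.325 SD/T-allele
outcome = records[("rs3734626", "trabecular_vbmd")]      # beta 0.092 SD/T-allele

result = wald_ratio(harmonize(exposure, outcome))
print(f"causal effect: {result.beta_mr:.3f} SD trabecular vBMD per SD RSPO3")
print(f"standard error: {result.se_mr:.3f}")
print(f"95% CI: ({result.ci_low:.3f}, {result.ci_high:.3f})")
print(f"p-value: {result.pval:.2g}")
# ~0.28 SD of trabecular vBMD per SD of circulating protein: the outcome
# association scaled by the instrument strength; p carries over from the
# outcome GWAS because the first-order ratio preserves its Z-score.
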