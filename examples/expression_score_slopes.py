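"""Gene-expression score and simple-slope moderation analysis.

Computes the per-subject gene-expression score (GES) from an eQTL
annotation (counting expression-increasing alleles), then asks how the
exposure-outcome slope differs between genetically low-expression and
high-expression children (slopes at GES mean -/+ 1 SD).
"""

import numpy as np
import pandas as pd

from mixge import EqtlAnnotation, compute_ges, simple_slopes
from mixge.simulate import (
    SimulationConfig,
    simulate_covariates,
    simulate_exposure,
    simulate_genotypes,
)

n = 400
cfg = SimulationConfig(n_subjects=n, n_snps=6, seed=11)
rng = np.random.default_rng(11)
gm = simulate_genotypes(cfg, rng)

# eQTL annotation: for every SNP the alt allele increases expression
annotation = [EqtlAnnotation(s.snp_id, s.alt_allele, "synthetic") for s in gm.snps]
ges = compute_ges(gm, annotation)
print(f"GES over {len(annotation)} annotated SNPs: mean {ges.mean():.2f}, SD {ges.std():.2f}")

# outcome with genuine moderation: exposure hurts at low GES, protects at high
e = simulate_exposure(cfg, rng)
cov = simulate_covariates(cfg, rng)
b_int = 40.0 / (2 * ges.std(ddof=1))
slope = b_int * (ges - ges.mean())  # -20 at -1 SD, +20 at +1 SD
y = 1500.0 + 60.0 * (cov["sex"] == "male") + slope * e + rng.normal(0, 120, n)
cohort = pd.DataFrame(
    {"subject_id": gm.subject_ids, "volume": y, "E_prenatal": e,
     **{c: cov[c] for c in cov.columns}, "timepoint": "birth"}
)

res = simple_slopes(cohort, ges, outcome="volume")
print(f"slope at low GES (mean - 1 SD):  {res.slope_low.slope:+.1f} mm^3 per "
      f"exposure point (p = {res.slope_low.p:.3g})")
print(f"slope at high GES (mean + 1 SD): {res.slope_high.slope:+.1f} mm^3 per "
      f"exposure point (p = {res.slope_high.p:.3g})")
print(f"exposure x GES interaction p = {res.interaction.p:.3g}")
print("\nOpposite-sign slopes recover the generated moderation: higher exposure")
print("predicts smaller volumes in low-expression children and larger in high.")
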