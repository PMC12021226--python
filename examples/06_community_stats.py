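"""Seasonal community statistics on the synthetic diet table.

Computes Bray-Curtis and Jaccard dissimilarities, a 3-D NMDS (stress
above 0.2 means the ordination should not be trusted), a PerMANOVA for
seasonal differences, coverage-based rarefaction/extrapolation of
Shannon diversity per season, and the Steel-Dwass all-pairs comparison
of per-sample richness.
"""

import numpy as np

from dietbarcode import (
    PipelineConfig,
    SimConfig,
    dissimilarity,
    nmds,
    permanova,
    run_synthetic_pipeline,
    shannon_re_curve,
    steel_dwass,
)
from dietbarcode.stats import significance_letters

sim, result = run_synthetic_pipeline(SimConfig(seed=1), PipelineConfig(seed=1))
presence = result.diet.presence.astype(int)
abundance = result.diet.abundance
seasons = np.array([result.diet.seasons[s] for s in presence.index])

d_bc = dissimilarity(abundance, "bray_curtis")  # relative read abundance
d_j = dissimilarity(presence, "jaccard")  # binary occurrence
for name, d in (("Bray-Curtis", d_bc), ("Jaccard", d_j)):
    perm = permanova(d, seasons, permutations=10000, seed=1)
    print(f"PerMANOVA ({name}): F = {perm.pseudo_f:.2f}, R2 = {perm.r2:.3f}, "
          f"P = {perm.p_value:.4f} ({perm.permutations} permutations)")
# the synthetic seasonal profiles overlap but differ, so a small P is
# expected here, unlike a diet that is constant across the year.

ordination = nmds(d_bc, k=3, restarts=20, seed=1)
flag = "ok" if ordination.stress <= 0.2 else "too high to interpret (> 0.2)"
print(f"3-D NMDS stress: {ordination.stress:.3f} ({flag})")

print("coverage-based Shannon diversity (Hill order 1) per season:")
for season in ("spring", "summer", "autumn", "winter"):
    counts = presence[seasons == season].sum(axis=0).to_numpy()
    curve = shannon_re_curve(counts[counts > 0], bootstrap_reps=200, seed=1)
    i = int(np.where(curve.sizes == curve.observed_size)[0][0])
    print(f"  {season:7s} coverage {curve.observed_coverage:.2f}, "
          f"diversity {curve.estimates[i]:.2f} "
          f"[{curve.lcl[i]:.2f}, {curve.ucl[i]:.2f}]")

richness = presence.sum(axis=1)
groups = {str(s): richness[seasons == s].to_numpy() for s in np.unique(seasons)}
sd = steel_dwass(groups)
letters = significance_letters(sd, sorted(groups), alpha=0.05)
print("Steel-Dwass letters (shared letter = no difference at alpha 0.05):",
      letters)
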