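"""Compare two treatment groups end to end.

Simulates two cohorts of six individuals whose rotation rhythms differ
only in dominant period (8 s vs 20 s, with noise), builds Bray-Curtis
dissimilarities between their spectral fingerprints, and tests the group
difference with ANOSIM plus a 2-D non-metric MDS ordination.
"""

from embryoflow import (
    MotionSpec,
    anosim,
    assemble_features,
    bray_curtis_matrix,
    nmds,
    pairwise_anosim,
    preset,
    synth_cohort,
)

groups = [
    ("fast_rhythm", MotionSpec(duration_s=600, fps=7.5,
                               oscillations=(("pos", 8.0, 1.0),),
                               noise_sd=0.3), 6),
    ("slow_rhythm", MotionSpec(duration_s=600, fps=7.5,
                               oscillations=(("pos", 20.0, 1.0),),
                               noise_sd=0.3), 6),
]
cohort = synth_cohort(groups, seed=0)
features = [assemble_features(rec, preset("DANIO_XENOPUS_18"))
            for _, _, rec in cohort]
labels = [group for group, _, _ in cohort]

dist = bray_curtis_matrix(features)
result = anosim(dist, labels, seed=0)
print(f"global ANOSIM: R = {result.R:.3f}, p = {result.p_value:.4f} "
      f"({'exact, ' if result.exact else ''}{result.n_permutations} permutations)")

table = pairwise_anosim(dist, labels, seed=0)
for a, b, r, p, code in table.rows:
    print(f"  {a} vs {b}: R = {r:.3f}, p = {p:.4f} [{code}]")

embedding = nmds(dist, seed=0)
print(f"nMDS stress-1 = {embedding.stress:.4f}")
for (group, indiv, _), (x, y) in zip(cohort, embedding.coordinates):
    print(f"  {indiv:16s} {group:12s} ({x:+.3f}, {y:+.3f})")
print()
print("R near 1 with a small exact p says between-group dissimilarities")
print("dominate within-group ones; the low stress means the 2-D map is a")
print("faithful picture of the 12 individuals' relative dissimilarities.")
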