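"""The eight-condition empirical-style pipeline on a synthetic play-group world.

Generates a scan-sampled preschool dataset (two age-segregated classrooms,
AM/PM/FULL schedules, one focal child per observed play group, and a planted
friendship network), then extracts the SDSM-EC backbone under every subset
of the three constraint families and compares each to the
maximally-constrained backbone.
"""

from backbones import generate_preschool, run_empirical_comparison_world

world = generate_preschool(
    n_children=16,
    n_groups=600,
    classroom_split=(8, 8),
    truth_density=0.15,
    assortativity=8.0,
    seed=7,
)
print(f"children x groups: {world.graph.shape}, observed memberships: {world.graph.n_edges}")

res = run_empirical_comparison_world(world, alpha=0.13)

print("\nEdge accounting per constraint condition (cells of the 16 x 600 matrix):")
print(res.table_characteristics().to_string(index=False))

print("\nAgreement with the all-constraints backbone:")
print(res.table_comparisons().round(3).to_string(index=False))

print(
    f"\naccuracy vs number of constrained cells (Pearson over the 7 "
    f"less-constrained conditions): {res.accuracy_constraints_correlation:.3f}"
)
print(
    "Rows with more constraint families imposed agree more closely with the\n"
    "reference backbone; false positives (FP) are edges a less-constrained\n"
    "model retains that the correctly-specified model does not."
)
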