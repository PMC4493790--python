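"""Cluster cultivars by their transposable-element profiles.

Simulates dosage calls for six cultivars over three insertion loci, encodes
each profile as a binary band ladder, computes Nei-Li (Dice) distances,
builds a UPGMA dendrogram and attaches locus-bootstrap support values.
Cultivars cv1/cv2 and cv3/cv4 are given nearly identical true profiles, so
they should pair at small heights.
"""

import numpy as np

from tedose import (
    PlateScenario,
    bootstrap_support,
    distance_matrix,
    encode_profile,
    profiles_from_calls,
    score_plate,
    simulate_plate,
    to_newick,
)

truth = {
    "cv1": {"L1": 2.1, "L2": 7.4, "L3": 4.6},
    "cv2": {"L1": 2.3, "L2": 7.2, "L3": 4.4},  # near-replicate of cv1
    "cv3": {"L1": 8.6, "L2": 1.2, "L3": 6.3},
    "cv4": {"L1": 8.4, "L2": 1.4, "L3": 6.1},  # near-replicate of cv3
    "cv5": {"L1": 5.2, "L2": 5.3, "L3": 9.4},
    "cv6": {"L1": 0.0, "L2": 3.3, "L3": 1.8},
}
scenario = PlateScenario(samples=tuple(truth.items()), seed=21)
calls = score_plate(simulate_plate(scenario))
profiles = profiles_from_calls(calls)

encodings = [encode_profile(p, bin_width=1) for p in profiles]
d, labels = distance_matrix(encodings)
print("Nei-Li distance matrix:")
with np.printoptions(precision=3, suppress=True):
    print(labels)
    print(d)

tree = bootstrap_support(profiles, n_replicates=500, seed=22)
print("\nUPGMA dendrogram (newick; internal labels = % bootstrap support):")
print(to_newick(tree))
print(
    "\nsmall heights join near-identical profiles; low support values on"
    " deeper nodes reflect how little signal three loci carry."
)
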