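"""Gene-desert tropism and viewpoint clustering.

Simulates viewpoints with opposite long-range preferences, measures the
split of their desert-directed signal (smoothed, cluster excluded), and
clusters the viewpoints by the Spearman correlation of their long-range
profiles.
"""

import dataclasses

from fourc import (
    SimulationModel,
    cluster_viewpoints,
    correct_by_random_library,
    cumulative_tropism,
    desert_annotation,
    normalize,
    signal_partition,
    simulate_biases,
    simulate_map,
    simulate_viewpoint,
    tropism,
)

model = SimulationModel()
fmap, _ = simulate_map(model, seed=0)
annotation = desert_annotation(model, fmap)
shared_biases = simulate_biases(model, seed=0)

profiles = {}
for i, (name, tau) in enumerate(
    [("cen_tropic_1", 0.2), ("cen_tropic_2", 0.2),
     ("tel_tropic_1", 0.8), ("tel_tropic_2", 0.8)]
):
    m = dataclasses.replace(model, tau=tau)
    raw, rnd, _ = simulate_viewpoint(
        m, fmap, bait_fragment=model.default_bait() + i, seed=10 + i,
        biases=shared_biases,
    )
    profiles[name] = normalize(correct_by_random_library(raw, rnd))

print("viewpoint        p_cen  p_tel   (true tau)")
for name, profile in profiles.items():
    t = tropism(profile, annotation)
    true_tau = 0.2 if "cen" in name else 0.8
    print(f"{name:<15} {t.p_cen:6.3f} {t.p_tel:6.3f}   ({true_tau})")

t3 = cumulative_tropism(profiles["tel_tropic_1"], annotation)
print(f"\ncumulative split for tel_tropic_1: cluster {t3.p_cluster:.2f}, "
      f"cen desert {t3.p_cen:.2f}, tel desert {t3.p_tel:.2f}")

fractions = signal_partition(
    profiles["tel_tropic_1"],
    {"cen_desert": annotation.centromeric, "cluster": annotation.cluster,
     "tel_desert": annotation.telomeric},
)
print("\nsignal partition:", fractions.round(3).to_dict())

dendrogram = cluster_viewpoints(profiles, annotation)
print("\npairwise Spearman rho over desert fragments:")
print(dendrogram.correlation.round(2))
print("newick:", dendrogram.to_newick())
# Like-tropism viewpoints correlate strongly and merge first in the tree.
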