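"""4C x ChIP rank-correlation table.

Assigns mean ChIP coverage to every restriction fragment of the cluster
region, then computes Spearman's rho between 4C profiles (one repressed
bait, one active bait) and the repressive-like/active-like marks. The
best-correlating mark per viewpoint is flagged — for a repressed bait it
should be the repressive mark, mirroring how H3K27me3 tracks the
inactive-compartment profile.
"""

from fourc import (
    SimulationModel,
    aggregate_chip,
    correct_by_random_library,
    correlation_table,
    desert_annotation,
    normalize,
    simulate_chip,
    simulate_map,
    simulate_viewpoint,
)

model = SimulationModel()
fmap, _ = simulate_map(model, seed=0)
annotation = desert_annotation(model, fmap)

repressive, active, domains = simulate_chip(model, fmap, seed=1)
chip = {
    "repressive_mark": aggregate_chip(repressive, fmap, annotation.cluster),
    "active_mark": aggregate_chip(active, fmap, annotation.cluster),
}

profiles = {}
for name, bait in (
    ("repressed_bait", model.default_bait()),
    ("active_bait", model.n_centromeric + 90),
):
    raw, rnd, _ = simulate_viewpoint(model, fmap, bait_fragment=bait, seed=2)
    profiles[name] = normalize(correct_by_random_library(raw, rnd))

table = correlation_table(profiles, chip)
print(table.rho.round(3))
print("\nbest-correlating mark per viewpoint:")
print(table.best.to_string())
# Rows are 4C viewpoints, columns ChIP tracks; each viewpoint's highest
# rho flags the chromatin mark whose domain its contacts track.
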