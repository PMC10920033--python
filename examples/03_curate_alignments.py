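"""Curate noisy pairwise alignments into a multi-species alignment.

Takes clean per-species pairwise alignments, injects typical curation
artefacts (edge N runs, over-long internal N runs, overlapping duplicate
blocks, missing species), then runs the cleaning chain: N-trim/split,
reference-overlap resolution (longer alignment wins), reference-anchored
merge, and the >=7-of-8 species filter.
"""

import conacc as cc

plan = cc.plan_windows(40, 0, 0, seed=21)
ds = cc.generate_dataset(plan, seed=21)
clean = cc.to_pairwise(ds.blocks, "A_carolinensis")

cfg = cc.ArtifactConfig(
    edge_n_fraction=0.3,
    internal_n_fraction=0.1,
    missing_species_fraction=0.05,
    duplicate_fraction=0.2,
)
noisy = cc.inject_artifacts(clean, cfg, seed=22)

n_noisy = sum(len(v) for v in noisy.values())
curated = cc.curate_pairwise(noisy, "A_carolinensis")

print(f"pairwise blocks in:     {n_noisy} (across {len(noisy)} species)")
print(f"curated multi blocks:   {len(curated)}")
print(f"species per block:      {sorted({len(b.rows) for b in curated})}")
covered = sum(len(b.ref_interval()) for b in curated)
print(f"reference bases kept:   {covered} of {plan.length}")
# Every surviving block carries >= 7 of the 8 species, covers a disjoint
# slice of the reference, and contains no over-long N runs; bases lost are
# those trimmed with the injected Ns or dropped with missing species.
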