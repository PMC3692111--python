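"""Annotate a membrane-protein template with its environment.

Builds a synthetic 4-helix transmembrane bundle, fits the membrane slab by
hydrophobic-contrast optimisation, and prints the per-residue environment
(lipid-tail / lipid-head / non-membrane layer, secondary structure, burial).
"""
from memoir.fixtures import BundleSpec, make_helical_bundle
from memoir.membrane_annotate import annotate_template

structure, true_slab = make_helical_bundle(BundleSpec(seed=0))
annotated = annotate_template(structure)

print(f"fitted slab normal:      {annotated.slab.normal.round(3).tolist()}")
print(f"fitted tail half-width:  {annotated.slab.tail_half_width:.1f} A "
      f"(construction value {true_slab.tail_half_width:.1f} A)")
print(f"layer track (T=tail, P=head, .=outside):")
print("  " + annotated.layer_track())

counts = {}
for ann in annotated.annotations:
    counts[(ann.layer, ann.ss)] = counts.get((ann.layer, ann.ss), 0) + 1
print("residues per (layer, secondary structure):")
for key in sorted(counts):
    print(f"  {key[0]:>12} {key[1]}: {counts[key]}")
# Most residues should be (tail, H): transmembrane helices dominate the
# bundle; the loops show up as non-membrane coil.
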