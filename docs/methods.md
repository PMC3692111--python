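# Methods

This note documents the models, parameter choices and numerical behaviour
of the pipeline, and what the synthetic fixtures do and do not show about
real data.

## Membrane annotation

**Label set.** Each template residue carries a three-part environment:
membrane layer ∈ {tail, head, non-membrane}, secondary structure ∈
{H, E, C}, accessibility ∈ {accessible, buried}. The layer vocabulary
mirrors lipid anatomy — hydrophobic tails, polar head groups — because the
local electrostatic environment of a residue is set by which part of the
lipid it contacts.

**Membrane positioning.** Annotation pipelines built on molecular-dynamics
contact databases are not reproducible from published material, so membrane
position is computed purely geometrically: the slab (unit normal n̂, centre
offset c, tail half-width w) maximising the hydrophobic contrast
Q = mean Kyte–Doolittle hydropathy (at Cα) of *exposed* residues inside the
tail layer minus the mean outside it. The search is exhaustive and
deterministic:

* normals on a spherical grid of ≤ 5° spacing (hemisphere; the slab is
  symmetric under n̂ → −n̂),
* centre offsets on a 1 Å grid spanning the Cα extent,
* half-widths 10–20 Å in 1 Å steps (the physical range of hydrophobic-core
  half-thicknesses),
* ties broken by the smallest (normal index, offset index, width index).

Q depends only on the discrete partition of residues into inside/outside,
so its optimum is typically a plateau: several adjacent grid slabs score
identically. Consequently the *value* of Q at the optimum is exactly
invariant under rigid motion of the structure, while the reported normal
may wander a few grid steps within the plateau; tests assert the former
tightly and the latter loosely. The head layer is a fixed 6 Å shell beyond
the tail layer (typical head-group extent).

**Secondary structure** comes from backbone dihedral regions (helix:
φ ∈ [−100, −30], ψ ∈ [−80, −5]; strand: φ ∈ [−180, −90], ψ ∈ [90, 180] ∪
[−180, −170]) with minimum run lengths 4 (H) and 3 (E); shorter runs are
demoted to coil, as are residues with undefined dihedrals (termini, chain
breaks with C–N > 2.5 Å, missing atoms). A dihedral-region assignment
avoids an external hydrogen-bond-based tool and is exact on the ideal
fixtures.

**Accessibility** is Shrake–Rupley accessible surface area (biotite
implementation, probe 1.4 Å, 384 sphere points per atom — at this density a
further doubling changes no residue's relative ASA by more than 0.02),
normalised by the Tien et al. theoretical maximum per residue type and
clamped to [0, 1]. Buried means relative ASA < 0.07, a conventional cutoff
in environment-annotation work; it is configurable.

## Homologue selection

The filters are implemented exactly as stated in their source: reject
candidates with < 15% identity to the query or length outside (2/3, 3/2) of
the query's (strict inequalities, so boundary values are kept); reduce to
80% non-redundancy; combine both sides in equal numbers; re-deduplicate;
cap at 125. Decisions the source leaves open, declared here:

* **Identity convention** — identical aligned pairs over a global
  affine-gap alignment (BLOSUM62, 11/1), divided by the shorter sequence
  length. The shorter-length denominator keeps the identity filter
  consistent with the 2/3–3/2 length filter.
* **Redundancy reduction** — greedy Hobohm-style selection visiting
  sequences by decreasing identity to the query (ties by id), accepting a
  sequence iff it is < 80% identical to everything already accepted.
  Deterministic and auditable; every decision lands in the audit log.
* **Random steps** (balanced sampling of the larger side, the 125-cap) are
  seeded; the seed is part of the pipeline config.

## Environment-guided alignment

The scoring model is a declared, transparent default — published
environment-specific substitution tables for this method live outside the
material reproduced here, so the model preserves the two qualitative
constraints with auditable numbers, all config-overridable:

* column score = BLOSUM62(a, b) + bonus(env_a, b) + bonus(env_b, a), with
  bonus +2 half-bits for {L, I, V, F, M, A} aligned into a (tail, H)
  environment and −2 for {D, E, K, R} there; zero for unknown environments,
  so with no annotation the DP reduces *exactly* to standard global affine
  alignment (verified against an independent Gotoh implementation);
* gap open 11, extend 1; the open cost is multiplied by 2.0 when the gap is
  placed against a lipid-tail residue (indels are rare in transmembrane
  elements). The tail multiplier ≥ 1 is enforced as a model invariant.

The DP is a three-state Gotoh with all inter-state transitions and a
deterministic traceback preference (match > gap-in-B > gap-in-A). Its
optimality is tested against exhaustive enumeration of all global
alignments on short pairs.

Annotation transfer aligns each homologue to the template with the
*annotation-free* model first, to avoid the circularity of annotations
steering the alignment that defines them; positions aligned to a template
residue inherit its environment, everything else stays unknown. The target
itself remains unannotated.

The guide tree is UPGMA on d = 1 − identity with lexicographic tiebreaks
(the source names no tree method; UPGMA is deterministic and sufficient for
clade selection). Only leaves under the MRCA of target and template enter
the consistency library: primary weight of an aligned residue pair is the
source alignment's percent identity × 100 (the standard T-Coffee choice),
extended over triplets by adding min(w_ik, w_kj). Progressive profile
alignment proceeds in tree post-order with column score = mean library
weight over constituent residue pairs, zero gap cost, frozen profile gaps
("once a gap, always a gap"). On toy triples the progressive result reaches
≥ 95% of the exhaustive optimum; the bound is asserted empirically.

## Core building

The local alignment-quality statistic is declared (its source describes the
criterion only qualitatively): per column, 1 for an identical pair, 0.5 for
a positive-scoring BLOSUM62 pair, 0 otherwise or on gaps, averaged over a
centred window of 11 columns (truncated windows renormalised by their
actual width); threshold 0.3. Both are configurable; the modelled-residue
count is monotone in the threshold, which the tests check.

Seeds are the maximal aligned runs in the lipid-tail layer, processed N→C;
with no tail run at all the longest aligned run is the single fallback
seed. Extension outward from each seed copies N, CA, C, O and Cβ (Cβ also
on substitutions — its position is nearly sequence-independent; never for
glycine targets), plus the full side chain where target and template
residue types are identical ("conserved" = identical type; the source does
not define conservation). Extension stops at quality < threshold, at a
target insertion (no template coordinates; `max_bridge` = 0 by default so
any insertion stops), at a template residue with incomplete backbone, or on
reaching another seed's territory. Target deletions are walked through.
Template residues with missing mid-chain backbone atoms are excluded from
copying — declared behaviour, not claimed to match any particular server.

## Loop filling

Fragment databases cut every contiguous window (loop length + 3 flanking
residues per side, consecutive Cα–Cα < 4.2 Å, complete backbones) from the
supplied structures; membrane vs soluble membership is a tag given at build
time. Candidates for a gap are filtered by propensity (summed BLOSUM62
score of the gap sequence against the fragment sequence) and ranked by
anchor RMSD — the Kabsch superposition residual of the fragment's six
anchor residues (24 backbone atoms; 12 for single-sided terminal gaps) onto
the modelled anchors — with ties broken by propensity then source id. The
best fragment's loop backbone is rigidly transformed and spliced in; the
top 10 alternatives are retained; the core is never touched.

The two-tier thresholds are declared values chosen so the Hiacc ⊆ Hicov
ordering is structural: Hiacc uses the membrane database only, anchor
RMSD ≤ 1.0 Å, propensity ≥ 25, no terminal gaps; Hicov adds the soluble
database, anchor RMSD ≤ 2.0 Å, propensity ≥ 0 and single-sided terminal
anchoring. Splices keep the fragment's own geometry; there is no closure
refinement or side-chain placement on loops.

## Assessment

* Backbone RMSD over residues common to both models (author numbering),
  optionally after a Kabsch fit. Implemented via SVD; the degenerate
  2-point case agrees with the closed form |d₁ − d₂|/2.
* GDT_TS: mean over cutoffs {1, 2, 4, 8} Å of the maximal fraction of
  common Cα within the cutoff, ×100. The superposition search seeds a
  Kabsch fit from every 3-residue window (plus the global fit) and refines
  three times on the residues currently within the cutoff. The heuristic is
  exact for identical structures (100.0) and rigid copies (±0.5 tolerance
  stated for the search).
* Traffic lights: identity green ≥ 30% (the conventional twilight-zone
  boundary), amber 15–30%, red < 15% (the same floor the homologue filter
  uses); coverage green ≥ 80%, amber 60–80%. Bands are inclusive upward and
  partition the input range (property-tested).
* Column summaries round half-up to 2 decimals (integers for percent
  columns), matching the presentation convention of the bundled benchmark
  table, whose means the tests reproduce (2.57 / 2.96 / 2.86 Å, 83%).

## Synthetic fixtures

The fixture generator builds ideal antiparallel helical bundles: helices
from exact internal coordinates (φ = −57°, ψ = −47°, standard bond
geometry; rise ≈ 1.55 Å/residue), placed on a circle (default 4 helices of
20 residues, radius 9 Å), joined by Bezier-arc coil loops with ~3.8 Å Cα
spacing and seed-jittered apexes. Sequences follow the construction slab:
hydrophobic letters (L/I/V/F) at |z| ≤ 15 Å, polar (S/N/D/K) outside — the
15 Å tail half-width is a typical bilayer core, the 6 Å head shell a
typical head-group extent. The generator returns that slab as ground truth,
and generation is byte-deterministic under the seed.

Mutant families use per-site substitutions (always changing the letter) and
indels of length uniform on {1, 2, 3} — the simplest model adequate for
exercising the selection filters.

What the fixtures do **not** emulate: real side-chain packing (only Cβ
stubs), β-barrels (the annotation supports E labels but the generator is
helical only), irregular helix geometry, membrane deformation, and realistic
loop conformations (arcs, not Ramachandran-sampled coil). Passing tests
therefore demonstrate the pipeline's internal correctness — exact
self-modelling, native-loop recovery, slab recovery under the fixtures'
idealised signal — not accuracy on experimental structures.

## Problem sizes and determinism

Tests and the acceptance script run on bundles of ~95 residues, homologue
families of up to 200 sequences, fragment databases of a few hundred
fragments, and 5 seeded slab fits — sizes chosen so the full suite
completes in well under a minute of compute while still exercising every
code path at realistic shape. All randomness flows from explicit seeds
(numpy Generator or config seeds); identical inputs, config and seed give
byte-identical output bundles.

## Known limitations

* The environment bonus table and gap multiplier are defaults, not fitted
  parameters; they preserve qualitative constraints, not published numbers.
* The slab fit assumes one planar membrane; polytopic proteins spanning
  curved or double membranes will mis-annotate.
* Loop splicing does not repair peptide geometry at the junctions.
* GDT_TS uses a heuristic superposition search; its score can undershoot an
  exhaustive search by a small margin on pathological decoys.
* Chain selection takes exactly one chain; oligomeric interfaces are
  invisible to the annotation.
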