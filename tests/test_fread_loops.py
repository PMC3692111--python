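import numpy as np
import pytest
from Bio.Align import substitution_matrices

from memoir.fixtures import BundleSpec, make_helical_bundle, make_ideal_helix
from memoir.fread_loops import (FillConfig, Fragment, anchor_fit,
                                build_fragment_db, complete_model, fill_gap,
                                propensity_score)
from memoir.geometry import kabsch
from memoir.io_formats import Chain, Structure
from memoir.medeller_build import (build_schedule, generate_core, local_quality)
from memoir.mpt_align import align_target_template
from oracles import two_point_rmsd

B = substitution_matrices.load("BLOSUM62")
LOOP_LEN = BundleSpec().loop_length


@pytest.fixture(scope="module")
def self_core(bundle, annotated_bundle, bundle_target):
    pair, _, _ = align_target_template(bundle_target, annotated_bundle)
    structure, _ = bundle
    return generate_core(pair, structure, build_schedule(annotated_bundle, pair),
                         local_quality(pair), annotated_template=annotated_bundle,
                         target_id="target")


@pytest.fixture(scope="module")
def bundle_db(bundle):
    structure, _ = bundle
    return build_fragment_db([structure], "membrane", (2, 8))


def _loop_ranges():
    spec = BundleSpec()
    period = spec.helix_length + spec.loop_length
    return [range(spec.helix_length + k * period,
                  spec.helix_length + k * period + spec.loop_length)
            for k in range(spec.n_helices - 1)]


def _delete(core, indices):
    test = core.copy()
    for i in indices:
        test.entries[i] = None
    return test


# ---------------------------------------------------------------------------
# database construction

def test_window_arithmetic_single_chain():
    """A 20-residue contiguous chain yields 20-(5+6)+1 = 10 fragments of
    loop length 5."""
    helix = make_ideal_helix(20)
    st = Structure("h", [Chain("A", helix)])
    db = build_fragment_db([st], "membrane", (5, 5))
    assert len(db.fragments(5)) == 10


def test_chain_break_excludes_spanning_windows():
    helix = make_ideal_helix(20)
    for res in helix[10:]:               # translate second half far away
        for atom in res.atoms:
            res.atoms[atom] = res.atoms[atom] + np.array([8.0, 0.0, 0.0])
    st = Structure("h", [Chain("A", helix)])
    db = build_fragment_db([st], "membrane", (5, 5))
    # only windows fully inside either contiguous half survive: r10 has no
    # window of span 11, so nothing at all
    for frag in db.fragments(5):
        assert not (frag.start_number <= 10 <= frag.start_number + 10)
    assert len(db.fragments(5)) == 0


def test_short_structure_contributes_nothing():
    st = Structure("h", [Chain("A", make_ideal_helix(8))])
    db = build_fragment_db([st], "membrane", (5, 5))
    assert db.size == 0


def test_length_index_invariant(bundle_db):
    for length, frags in bundle_db.by_length.items():
        assert all(f.length == length for f in frags)
        assert all(f.coords.shape == (length + 6, 4, 3) for f in frags)


# ---------------------------------------------------------------------------
# propensity

def test_propensity_self_score():
    assert propensity_score("LLLLL", "LLLLL") == 5 * B["L", "L"]


def test_propensity_prefers_identity():
    assert propensity_score("AAAA", "WWWW") < propensity_score("AAAA", "AAAA")


def test_propensity_length_mismatch():
    with pytest.raises(ValueError, match="fragment length mismatch"):
        propensity_score("AAA", "AAAA")


def test_propensity_threshold_monotone(bundle_db):
    frags = bundle_db.fragments(5)
    gap_seq = "LIVFL"
    counts = []
    for thr in (-10.0, 0.0, 10.0, 20.0, 30.0):
        counts.append(sum(propensity_score(gap_seq, f.sequence) >= thr
                          for f in frags))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# anchor fitting

def test_anchor_fit_self_identity(bundle_db, self_core):
    gap_indices = list(_loop_ranges()[0])
    core = _delete(self_core, gap_indices)
    from memoir.fread_loops import _gather_anchors
    anchors, side = _gather_anchors(core, core.gaps[0])
    native = next(f for f in bundle_db.fragments(LOOP_LEN)
                  if f.start_number == gap_indices[0] + 1 - 3)
    rmsd, R, t = anchor_fit(anchors, native, side)
    assert rmsd < 1e-6
    assert np.allclose(R, np.eye(3), atol=1e-6)


def test_anchor_fit_rotation_invariant(bundle_db, self_core):
    gap_indices = list(_loop_ranges()[0])
    core = _delete(self_core, gap_indices)
    from memoir.fread_loops import _gather_anchors
    anchors, side = _gather_anchors(core, core.gaps[0])
    frag = bundle_db.fragments(LOOP_LEN)[7]
    rmsd0, _, _ = anchor_fit(anchors, frag, side)
    theta = np.radians(63.0)
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    rotated = Fragment(frag.source_id, frag.start_number, frag.db_class,
                       frag.length, frag.sequence,
                       frag.coords @ R.T + np.array([5.0, -3.0, 11.0]))
    rmsd1, _, _ = anchor_fit(anchors, rotated, side)
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


def test_two_point_superposition_closed_form():
    """Kabsch RMSD on 2-point toy sets equals the closed-form value."""
    rng = np.random.default_rng(4)
    for _ in range(10):
        p = rng.normal(size=(2, 3))
        q = rng.normal(size=(2, 3))
        _, _, rmsd = kabsch(p, q)
        assert rmsd == pytest.approx(two_point_rmsd(p, q), abs=1e-9)


# ---------------------------------------------------------------------------
# gap filling

def test_native_loop_recovery(bundle, bundle_db, self_core):
    """Deleting each loop and refilling from a database containing the
    source structure restores the native backbone to < 1e-3 A."""
    structure, _ = bundle
    for gap_indices in _loop_ranges():
        core = _delete(self_core, list(gap_indices))
        native = {i: {a: np.array(v) for a, v in
                      self_core.entries[i].atoms.items()
                      if a in ("N", "CA", "C", "O")}
                  for i in gap_indices}
        fill = fill_gap(core, core.gaps[0], [bundle_db], FillConfig.hicov())
        assert fill.status == "filled"
        assert fill.chosen.anchor_rmsd < 1e-6          # native ranked first
        assert fill.chosen.fragment.source_id.startswith(structure.id)
        deviations = [np.linalg.norm(core.entries[i].atoms[a] - native[i][a])
                      for i in gap_indices for a in ("N", "CA", "C", "O")]
        assert max(deviations) < 1e-3


def test_ranking_matches_bruteforce(bundle_db, self_core):
    """Candidate order equals an independent sort over all length-matched
    fragments by (anchor RMSD, -propensity, source)."""
    gap_indices = list(_loop_ranges()[1])
    core = _delete(self_core, gap_indices)
    gap = core.gaps[0]
    config = FillConfig("test", anchor_rmsd_max=1e9, propensity_min=-1e9,
                        use_soluble=True, allow_terminal=True,
                        alternatives_k=10_000)
    from memoir.fread_loops import _gather_anchors
    anchors, side = _gather_anchors(core, gap)
    gap_seq = core.target_sequence[gap.start:gap.end + 1]
    expected = []
    for frag in bundle_db.fragments(gap.length):
        prop = propensity_score(gap_seq, frag.sequence)
        rmsd, _, _ = anchor_fit(anchors, frag, side)
        expected.append((rmsd, -prop, frag.source_id, frag.start_number))
    expected.sort()
    fill = fill_gap(core, gap, [bundle_db], config)
    got = [(c.anchor_rmsd, -c.propensity, c.fragment.source_id,
            c.fragment.start_number) for c in fill.alternatives]
    assert got == expected


def test_no_fragment_of_right_length_leaves_gap(self_core, bundle_db):
    gap_indices = list(_loop_ranges()[0])
    core = _delete(self_core, gap_indices)
    from memoir.fread_loops import FragmentDB
    empty = FragmentDB("membrane")
    fill = fill_gap(core, core.gaps[0], [empty], FillConfig.hicov())
    assert fill.status == "no_candidates"
    assert all(core.entries[i] is None for i in gap_indices)


def test_unknown_gap_rejected(self_core, bundle_db):
    from memoir.medeller_build import GapInterval
    with pytest.raises(KeyError, match="unknown gap"):
        fill_gap(self_core.copy(), GapInterval(3, 7, 2, 8), [bundle_db],
                 FillConfig.hicov())


# ---------------------------------------------------------------------------
# two-tier completion

def test_hiacc_hicov_threshold_split(self_core, bundle):
    """A loop whose best candidate passes only the relaxed anchor threshold
    is filled in hicov but not hiacc, so hicov coverage is strictly higher."""
    other, _ = make_helical_bundle(BundleSpec(seed=9, radius=10.5))
    foreign_db = build_fragment_db([other], "membrane", (2, 8))
    core = _delete(self_core, list(_loop_ranges()[0]))
    hiacc, hiacc_fills = complete_model(core, foreign_db, None, mode="hiacc")
    hicov, hicov_fills = complete_model(core, foreign_db, None, mode="hicov")
    assert hicov.coverage > hiacc.coverage
    assert any(f.status == "filled" for f in hicov_fills)
    assert all(f.status != "filled" for f in hiacc_fills)


def test_identical_models_when_all_pass_strict(self_core, bundle_db):
    core = _delete(self_core, list(_loop_ranges()[2]))
    hiacc, _ = complete_model(core, bundle_db, None, mode="hiacc")
    hicov, _ = complete_model(core, bundle_db, None, mode="hicov")
    for ea, ec in zip(hiacc.entries, hicov.entries):
        if ea is None:
            assert ec is None
            continue
        for atom in ea.atoms:
            assert np.array_equal(ea.atoms[atom], ec.atoms[atom])


def test_core_immutable_under_filling(self_core, bundle_db):
    core = _delete(self_core, list(_loop_ranges()[1]))
    before = {i: {a: v.copy() for a, v in e.atoms.items()}
              for i, e in enumerate(core.entries) if e is not None}
    model, _ = complete_model(core, bundle_db, None, mode="hicov")
    for i, atoms in before.items():
        for a, v in atoms.items():
            assert np.array_equal(model.entries[i].atoms[a], v)
            assert np.array_equal(core.entries[i].atoms[a], v)


def test_threshold_relaxation_never_unfills(self_core, bundle_db):
    core = _delete(self_core, list(_loop_ranges()[0]))
    strict = FillConfig("s", 0.5, 20.0, True, True)
    relaxed = FillConfig("r", 2.0, 0.0, True, True)
    m1, f1 = complete_model(core, bundle_db, None, config=strict)
    m2, f2 = complete_model(core, bundle_db, None, config=relaxed)
    filled1 = {(f.gap.start, f.gap.end) for f in f1 if f.status == "filled"}
    filled2 = {(f.gap.start, f.gap.end) for f in f2 if f.status == "filled"}
    assert filled1 <= filled2


def test_hicov_config_never_stricter():
    hiacc, hicov = FillConfig.hiacc(), FillConfig.hicov()
    assert hicov.anchor_rmsd_max >= hiacc.anchor_rmsd_max
    assert hicov.propensity_min <= hiacc.propensity_min
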