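import itertools
import random

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from memoir.io_formats import SequenceRecord
from memoir.mpt_align import (EnvironmentClass, MultipleAlignment,
                              PairwiseAlignment, UNKNOWN_ENV, align_pair,
                              build_guide_tree, build_library,
                              default_scoring_model, extract_pair,
                              neutral_scoring_model, progressive_align,
                              score_column, select_clade, transfer_annotation)
from oracles import all_gapped_rows, brute_force_global_score

B = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"
TAIL_H = EnvironmentClass("tail", "H", "buried")


# ---------------------------------------------------------------------------
# column scoring

def test_score_column_reduces_to_base_when_unknown():
    model = default_scoring_model()
    for a, b in itertools.product("LWDK", repeat=2):
        assert score_column(model, a, UNKNOWN_ENV, b, UNKNOWN_ENV) == B[a, b]


def test_score_column_tail_bonuses():
    model = default_scoring_model()
    assert score_column(model, "A", TAIL_H, "L", UNKNOWN_ENV) == B["A", "L"] + 2
    assert score_column(model, "A", TAIL_H, "D", UNKNOWN_ENV) == B["A", "D"] - 2
    # both sides contribute
    assert score_column(model, "L", TAIL_H, "L", TAIL_H) == B["L", "L"] + 4


def test_tail_gap_open_invariant():
    model = default_scoring_model()
    assert model.open_cost(TAIL_H) >= model.open_cost(
        EnvironmentClass("non-membrane", "C", "accessible"))


# ---------------------------------------------------------------------------
# pairwise DP

def test_identical_sequences_align_gap_free():
    seq = "MKTAYIAKQR"
    aln = align_pair(SequenceRecord("a", seq), SequenceRecord("b", seq),
                     neutral_scoring_model())
    assert aln.row_a == aln.row_b == seq
    assert aln.score == sum(B[c, c] for c in seq)


def test_dp_matches_bruteforce_enumeration():
    rng = random.Random(7)
    neutral = neutral_scoring_model()
    for _ in range(30):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 6)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 6)))
        aln = align_pair(SequenceRecord("a", a), SequenceRecord("b", b), neutral)
        assert aln.score == pytest.approx(brute_force_global_score(a, b))


def test_neutral_model_matches_independent_gotoh():
    """With all-unknown environments the DP reduces to standard global
    affine alignment (independent implementation: Biopython)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = B
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    rng = random.Random(3)
    neutral = neutral_scoring_model()
    for _ in range(50):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
        mine = align_pair(SequenceRecord("a", a), SequenceRecord("b", b), neutral)
        assert mine.score == pytest.approx(aligner.align(a, b).score)


def test_gap_avoids_tail_segment():
    """A deletion that could sit inside or outside the tail segment is
    placed outside: the tail multiplier makes opening there dearer."""
    model = default_scoring_model()
    # template: 6 tail residues flanked by non-membrane coil
    nm = EnvironmentClass("non-membrane", "C", "accessible")
    env_b = [nm] * 3 + [TAIL_H] * 6 + [nm] * 3
    b = SequenceRecord("b", "GSA" + "LILILI" + "ASG")
    a = SequenceRecord("a", "GSA" + "LILIL" + "ASG")  # one residue shorter
    aln = align_pair(a, b, model, env_a=[UNKNOWN_ENV] * len(a.sequence), env_b=env_b)
    gap_cols = [i for i, c in enumerate(aln.row_a) if c == "-"]
    assert len(gap_cols) == 1
    assert aln.env_b[gap_cols[0]].layer != "tail"


def test_alignment_rows_recover_inputs():
    rng = random.Random(5)
    model = default_scoring_model()
    for _ in range(10):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 25)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 25)))
        aln = align_pair(SequenceRecord("a", a), SequenceRecord("b", b), model)
        assert aln.ungapped("a") == a and aln.ungapped("b") == b


# ---------------------------------------------------------------------------
# annotation transfer

def _toy_annotated(seq, layers):
    """Annotated-template stand-in with given layers, H ss, accessible."""
    from memoir.membrane_annotate import ResidueAnnotation

    class Toy:
        sequence = seq
        annotations = [ResidueAnnotation(l, "H", "accessible", 0.5)
                       for l in layers]
    return Toy()


def test_transfer_identity_copies_index_for_index():
    seq = "MKTAYIAKQR"
    layers = ["tail"] * 5 + ["non-membrane"] * 5
    toy = _toy_annotated(seq, layers)
    envs = transfer_annotation(toy, SequenceRecord("h", seq))
    assert [e.layer for e in envs] == layers


def test_transfer_insertion_gets_unknown():
    seq = "MKTAYIAKQR"
    toy = _toy_annotated(seq, ["tail"] * 10)
    hom = SequenceRecord("h", seq[:5] + "GGG" + seq[5:])
    envs = transfer_annotation(toy, hom)
    assert len(envs) == len(hom.sequence)
    unknown = [i for i, e in enumerate(envs) if e.layer == "unknown"]
    assert len(unknown) == 3
    inherited = [e for e in envs if e.layer == "tail"]
    assert len(inherited) == 10


# ---------------------------------------------------------------------------
# guide tree

def _pair_dist():
    return {frozenset(("a", "b")): 0.1, frozenset(("c", "d")): 0.2,
            frozenset(("a", "c")): 0.8, frozenset(("a", "d")): 0.8,
            frozenset(("b", "c")): 0.8, frozenset(("b", "d")): 0.8}


def test_two_leaves_single_cherry():
    tree = build_guide_tree(["a", "b"], {frozenset(("a", "b")): 0.4})
    assert set(tree.root.leaf_names) == {"a", "b"}
    assert tree.root.height == pytest.approx(0.2)


def test_upgma_recovers_clean_pairs():
    tree = build_guide_tree(list("abcd"), _pair_dist())
    kids = {frozenset(c.leaf_names) for c in tree.root.children}
    assert kids == {frozenset("ab"), frozenset("cd")}
    # hand-computed UPGMA heights: cherry heights are half the pair distance
    heights = {frozenset(c.leaf_names): c.height for c in tree.root.children}
    assert heights[frozenset("ab")] == pytest.approx(0.05)
    assert heights[frozenset("cd")] == pytest.approx(0.10)


def test_upgma_input_order_invariant():
    t1 = build_guide_tree(list("abcd"), _pair_dist())
    t2 = build_guide_tree(list("dcba"), _pair_dist())

    def shape(node):
        if node.is_leaf:
            return node.name
        return tuple(shape(c) for c in node.children)

    assert shape(t1.root) == shape(t2.root)


def test_tree_needs_two_leaves():
    with pytest.raises(ValueError, match="two leaves"):
        build_guide_tree(["a"], {})


def test_select_clade():
    tree = build_guide_tree(list("abcd"), _pair_dist())
    assert select_clade(tree, "a", "b") == {"a", "b"}       # sisters
    assert select_clade(tree, "a", "c") == {"a", "b", "c", "d"}
    with pytest.raises(KeyError, match="unknown leaf"):
        tree.mrca("a", "z")


def test_select_clade_eight_leaves_bruteforce():
    """MRCA subtree on a constructed 8-leaf tree checked against a
    brute-force LCA walk."""
    ids = list("abcdefgh")
    rng = random.Random(2)
    dist = {}
    # two clusters: abcde tight, fgh tight, far apart
    for i, j in itertools.combinations(ids, 2):
        both_first = i in "abcde" and j in "abcde"
        both_second = i in "fgh" and j in "fgh"
        base = 0.1 if (both_first or both_second) else 0.9
        dist[frozenset((i, j))] = base + 0.01 * rng.random()
    tree = build_guide_tree(ids, dist)
    clade = select_clade(tree, "a", "e")
    assert clade <= set("abcde") and {"a", "e"} <= clade

    def brute_lca(node, x, y):
        if x in node.leaf_names and y in node.leaf_names:
            for c in node.children:
                r = brute_lca(c, x, y)
                if r is not None:
                    return r
            return set(node.leaf_names)
        return None

    assert clade == brute_lca(tree.root, "a", "e")


# ---------------------------------------------------------------------------
# consistency library

def _neutral_alignments(seqs):
    neutral = neutral_scoring_model()
    return [align_pair(SequenceRecord(i, seqs[i]), SequenceRecord(j, seqs[j]),
                       neutral)
            for i, j in itertools.combinations(sorted(seqs), 2)]


def test_library_two_sequences_primary_only():
    seqs = {"a": "MKTAY", "b": "MKTAW"}
    lib = build_library(_neutral_alignments(seqs))
    pid = 4 / 5 * 100
    assert lib.weight("a", 0, "b", 0) == pytest.approx(pid)


def test_library_three_identical_extension():
    seqs = {i: "MKTAY" for i in "abc"}
    lib = build_library(_neutral_alignments(seqs))
    for pos in range(5):
        assert lib.weight("a", pos, "b", pos) == pytest.approx(200.0)


def test_library_symmetry():
    seqs = {"a": "MKTAYIAK", "b": "MKTAYHAK", "c": "MKTAY"}
    lib = build_library(_neutral_alignments(seqs))
    for ((i, a), (j, b)), w in lib.items():
        assert lib.weight(j, b, i, a) == w
        assert w >= 0


# ---------------------------------------------------------------------------
# progressive alignment

def test_identical_sequences_gap_free_msa():
    seqs = {i: "MKTAYIAK" for i in "abc"}
    lib = build_library(_neutral_alignments(seqs))
    tree = build_guide_tree(list("abc"),
                            {frozenset(p): 0.0
                             for p in itertools.combinations("abc", 2)})
    msa = progressive_align(seqs, tree, lib)
    assert all(row == "MKTAYIAK" for row in msa.rows.values())


def test_progressive_near_exhaustive_optimum():
    """On random toy triples the progressive MSA reaches >= 95% of the
    exhaustive library-score optimum over MSAs of width <= 8."""
    rng = random.Random(11)
    hits = 0
    trials = 12
    for _ in range(trials):
        seqs = {i: "".join(rng.choice(AA) for _ in range(rng.randint(3, 4)))
                for i in "abc"}
        alns = _neutral_alignments(seqs)
        lib = build_library(alns)
        dist = {frozenset((a.id_a, a.id_b)): 1 - a.percent_identity()
                for a in alns}
        msa = progressive_align(seqs, build_guide_tree(list("abc"), dist), lib)
        score = msa.library_score(lib)
        best = -1.0
        maxlen = max(map(len, seqs.values()))
        for width in range(maxlen, min(maxlen + 3, 9)):
            for ra in all_gapped_rows(seqs["a"], width):
                for rb in all_gapped_rows(seqs["b"], width):
                    for rc in all_gapped_rows(seqs["c"], width):
                        m = MultipleAlignment({"a": ra, "b": rb, "c": rc})
                        best = max(best, m.library_score(lib))
        if score >= 0.95 * best - 1e-9:
            hits += 1
    assert hits == trials


def test_msa_rows_recover_sequences():
    seqs = {"a": "MKTAYIAK", "b": "MKTAIAK", "c": "MKTAYIHAK"}
    alns = _neutral_alignments(seqs)
    lib = build_library(alns)
    dist = {frozenset((a.id_a, a.id_b)): 1 - a.percent_identity() for a in alns}
    msa = progressive_align(seqs, build_guide_tree(list("abc"), dist), lib)
    for rid, seq in seqs.items():
        assert msa.ungapped(rid) == seq


# ---------------------------------------------------------------------------
# pair extraction

def test_extract_pair_from_two_row_msa():
    msa = MultipleAlignment({"t": "MK-TAY", "x": "MKQTAY"})
    pair = extract_pair(msa, "t", "x")
    assert pair.row_a == "MK-TAY" and pair.row_b == "MKQTAY"


def test_extract_pair_drops_dual_gaps():
    msa = MultipleAlignment({"t": "MK--AY", "x": "MKQ-AY", "h": "MKQWAY"})
    pair = extract_pair(msa, "t", "x")
    assert pair.row_a == "MK-AY" and pair.row_b == "MKQAY"
    assert pair.ungapped("a") == "MKAY" and pair.ungapped("b") == "MKQAY"


def test_extract_pair_missing_row():
    msa = MultipleAlignment({"t": "MKT"})
    with pytest.raises(KeyError, match="id not in alignment"):
        extract_pair(msa, "t", "zzz")


def test_pairwise_alignment_invariants():
    with pytest.raises(ValueError):
        PairwiseAlignment("a", "b", "M-K", "MK")  # ragged
    with pytest.raises(ValueError):
        PairwiseAlignment("a", "b", "M-K", "M-K")  # gap-gap column
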