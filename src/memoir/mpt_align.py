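"""Environment-guided target-template alignment.

The alignment stage exploits the membrane's constraints on sequence:
residues in transmembrane helices are rarely aligned to gaps (indels are
rare in membrane-embedded elements) and are preferentially aligned to
residue types favoured there.  Concretely:

* the template's per-residue environment (membrane layer x secondary
  structure x accessibility) is transferred onto each homologue through an
  environment-agnostic first-pass alignment;
* every pair of sequences is aligned by a three-state affine-gap dynamic
  programme whose column score is a base substitution matrix (BLOSUM62)
  plus signed environment bonuses, and whose gap-open cost is multiplied
  when the gap is placed against a lipid-tail position;
* a UPGMA guide tree over 1 - identity selects the clade descending from
  the most recent common ancestor of target and template;
* a consistency library in the T-Coffee style (primary weights = percent
  identity x 100, triplet extension with min weights) scores a progressive
  profile-profile multiple alignment, from which the final target-template
  pairwise alignment is extracted.

The environment-specific scoring parameters here are declared, transparent
defaults (see :func:`default_scoring_model`), all config-overridable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._tables import CHARGED, TM_HYDROPHOBIC
from .io_formats import SequenceRecord

__all__ = [
    "EnvironmentClass", "UNKNOWN_ENV", "ScoringModel",
    "default_scoring_model", "neutral_scoring_model",
    "score_column", "align_pair", "PairwiseAlignment",
    "transfer_annotation", "build_guide_tree", "GuideTree", "TreeNode",
    "select_clade", "build_library", "ConsistencyLibrary",
    "progressive_align", "MultipleAlignment", "extract_pair",
    "align_target_template",
]


@dataclass(frozen=True)
class EnvironmentClass:
    layer: str = "unknown"          # tail | head | non-membrane | unknown
    ss: str = "unknown"             # H | E | C | unknown
    accessibility: str = "unknown"  # accessible | buried | unknown


UNKNOWN_ENV = EnvironmentClass()


def _blosum62():
    return substitution_matrices.load("BLOSUM62")


@dataclass
class ScoringModel:
    """Base matrix + environment bonuses + per-environment gap model."""
    base: object = field(default_factory=_blosum62)
    # (layer, ss) -> {residue letter: half-bit offset}
    bonus_table: dict = field(default_factory=dict)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # layer -> multiplier applied to gap_open when gapping against it
    open_multiplier: dict = field(default_factory=dict)

    def __post_init__(self):
        tail_mult = self.open_multiplier.get("tail", 1.0)
        nonmem_mult = self.open_multiplier.get("non-membrane", 1.0)
        if tail_mult < nonmem_mult:
            raise ValueError("tail gap-open must be >= non-membrane gap-open")

    def base_score(self, a: str, b: str) -> float:
        alphabet = self.base.alphabet
        a = a if a in alphabet else "X"
        b = b if b in alphabet else "X"
        return float(self.base[a, b])

    def bonus(self, env: EnvironmentClass, aa: str) -> float:
        table = self.bonus_table.get((env.layer, env.ss))
        if table is None:
            return 0.0
        return float(table.get(aa, 0.0))

    def open_cost(self, env: EnvironmentClass | None) -> float:
        if env is None:
            return self.gap_open
        return self.gap_open * self.open_multiplier.get(env.layer, 1.0)

    def extend_cost(self, env: EnvironmentClass | None) -> float:
        return self.gap_extend


def default_scoring_model() -> ScoringModel:
    """Declared defaults: +2 half-bits for TM-favoured hydrophobics aligned
    into (tail, H) environments, -2 for charged residues there; tail
    gap-open multiplier 2.0."""
    bonus = {aa: 2.0 for aa in TM_HYDROPHOBIC}
    bonus.update({aa: -2.0 for aa in CHARGED})
    return ScoringModel(bonus_table={("tail", "H"): bonus},
                        open_multiplier={"tail": 2.0})


def neutral_scoring_model() -> ScoringModel:
    """No environment bonuses, unit gap multipliers: standard Gotoh."""
    return ScoringModel()


def score_column(model: ScoringModel, aa_i: str, env_i: EnvironmentClass,
                 aa_j: str, env_j: EnvironmentClass) -> float:
    """base(aa_i, aa_j) + bonus(env_i, aa_j) + bonus(env_j, aa_i)."""
    return (model.base_score(aa_i, aa_j)
            + model.bonus(env_i, aa_j) + model.bonus(env_j, aa_i))


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float | None = None
    env_a: list | None = None  # per-column EnvironmentClass of row_a (None on gaps)
    env_b: list | None = None

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == "-" and cb == "-":
                raise ValueError("gap-gap column in pairwise alignment")

    @property
    def width(self) -> int:
        return len(self.row_a)

    def ungapped(self, which: str) -> str:
        row = self.row_a if which == "a" else self.row_b
        return row.replace("-", "")

    def percent_identity(self) -> float:
        matches = sum(1 for a, b in zip(self.row_a, self.row_b)
                      if a == b and a != "-")
        return matches / min(len(self.ungapped("a")), len(self.ungapped("b")))

    def column_positions(self):
        """Yield (pos_a | None, pos_b | None) per column (sequence indices)."""
        ia = ib = 0
        for ca, cb in zip(self.row_a, self.row_b):
            pa = ia if ca != "-" else None
            pb = ib if cb != "-" else None
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            yield pa, pb


def align_pair(a: SequenceRecord, b: SequenceRecord, model: ScoringModel | None = None,
               env_a=None, env_b=None) -> PairwiseAlignment:
    """Global three-state affine alignment with environment-aware scoring.

    Traceback tiebreak: match > gap-in-b (consume a) > gap-in-a, so the
    result is deterministic among co-optimal alignments.
    """
    model = model or default_scoring_model()
    sa, sb = a.sequence, b.sequence
    env_a = list(env_a) if env_a is not None else [UNKNOWN_ENV] * len(sa)
    env_b = list(env_b) if env_b is not None else [UNKNOWN_ENV] * len(sb)
    if len(env_a) != len(sa) or len(env_b) != len(sb):
        raise ValueError("environment lists must match sequence lengths")
    n, m = len(sa), len(sb)
    NEG = -1e18
    # state matrices: M match, X gap in b (consumes a), Y gap in a (consumes b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        opening = model.open_cost(env_a[0]) if i == 1 else model.extend_cost(env_a[i - 1])
        X[i, 0] = (0.0 if i == 1 else X[i - 1, 0]) - opening
    for j in range(1, m + 1):
        opening = model.open_cost(env_b[0]) if j == 1 else model.extend_cost(env_b[j - 1])
        Y[0, j] = (0.0 if j == 1 else Y[0, j - 1]) - opening

    for i in range(1, n + 1):
        ea = env_a[i - 1]
        ca = sa[i - 1]
        open_a = model.open_cost(ea)
        ext_a = model.extend_cost(ea)
        for j in range(1, m + 1):
            eb = env_b[j - 1]
            s = score_column(model, ca, ea, sb[j - 1], eb)
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - open_a, Y[i - 1, j] - open_a,
                          X[i - 1, j] - ext_a)
            open_b = model.open_cost(eb)
            Y[i, j] = max(M[i, j - 1] - open_b, X[i, j - 1] - open_b,
                          Y[i, j - 1] - model.extend_cost(eb))

    # traceback, preference M > X > Y at every choice
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: ({"M": M, "X": X, "Y": Y}[st][i, j],
                                                 {"M": 2, "X": 1, "Y": 0}[st]))
    best_score = {"M": M, "X": X, "Y": Y}[state][n, m]
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ra.append(sa[i - 1])
            rb.append(sb[j - 1])
            s = score_column(model, sa[i - 1], env_a[i - 1], sb[j - 1], env_b[j - 1])
            prev_val = M[i, j] - s
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], prev_val)
        elif state == "X":
            ra.append(sa[i - 1])
            rb.append("-")
            ea = env_a[i - 1]
            open_a, ext_a = model.open_cost(ea), model.extend_cost(ea)
            val = X[i, j]
            i -= 1
            if abs(M[i, j] - open_a - val) < 1e-9:
                state = "M"
            elif abs(X[i, j] - ext_a - val) < 1e-9:
                state = "X"
            else:
                state = "Y"
        else:
            ra.append("-")
            rb.append(sb[j - 1])
            eb = env_b[j - 1]
            open_b, ext_b = model.open_cost(eb), model.extend_cost(eb)
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] - open_b - val) < 1e-9:
                state = "M"
            elif abs(X[i, j] - open_b - val) < 1e-9:
                state = "X"
            else:
                state = "Y"
        if i == 0 and j == 0:
            break
        if i == 0 and state != "Y":
            state = "Y"
        if j == 0 and state != "X":
            state = "X"
    ra.reverse()
    rb.reverse()
    row_a, row_b = "".join(ra), "".join(rb)
    cols_a: list = []
    cols_b: list = []
    ia = ib = 0
    for c_a, c_b in zip(row_a, row_b):
        cols_a.append(env_a[ia] if c_a != "-" else None)
        cols_b.append(env_b[ib] if c_b != "-" else None)
        if c_a != "-":
            ia += 1
        if c_b != "-":
            ib += 1
    return PairwiseAlignment(a.id, b.id, row_a, row_b, float(best_score),
                             cols_a, cols_b)


def _pick_state(m, x, y, target) -> str:
    if abs(m - target) < 1e-9:
        return "M"
    if abs(x - target) < 1e-9:
        return "X"
    return "Y"


# ---------------------------------------------------------------------------
# Annotation transfer

def annotations_to_envs(annotated_template) -> list[EnvironmentClass]:
    """Convert an AnnotatedTemplate's per-residue labels to environments."""
    return [EnvironmentClass(a.layer, a.ss, a.accessibility)
            for a in annotated_template.annotations]


def transfer_annotation(annotated_template, homologue: SequenceRecord
                        ) -> list[EnvironmentClass]:
    """Copy the template's environment onto a homologue position-wise.

    The homologue is first aligned to the template sequence with the
    annotation-free scoring model (avoiding the circularity of annotations
    guiding the alignment that defines them); positions aligned to a
    template residue inherit its environment, gap-aligned positions stay
    all-unknown.
    """
    template_seq = SequenceRecord("__template__", annotated_template.sequence)
    template_envs = annotations_to_envs(annotated_template)
    aln = align_pair(homologue, template_seq, neutral_scoring_model())
    envs = [UNKNOWN_ENV] * len(homologue.sequence)
    for pa, pb in aln.column_positions():
        if pa is not None and pb is not None:
            envs[pa] = template_envs[pb]
    return envs


# ---------------------------------------------------------------------------
# Guide tree (UPGMA with lexicographic tiebreaks)

@dataclass
class TreeNode:
    leaf_names: tuple[str, ...]
    height: float = 0.0
    children: tuple = ()
    name: str | None = None  # leaf label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def rep(self) -> str:
        return min(self.leaf_names)


@dataclass
class GuideTree:
    root: TreeNode

    @property
    def leaf_names(self) -> set[str]:
        return set(self.root.leaf_names)

    def mrca(self, a: str, b: str) -> TreeNode:
        for name in (a, b):
            if name not in self.root.leaf_names:
                raise KeyError(f"unknown leaf {name!r}")
        node = self.root
        while True:
            nxt = None
            for child in node.children:
                if a in child.leaf_names and b in child.leaf_names:
                    nxt = child
                    break
            if nxt is None:
                return node
            node = nxt


def build_guide_tree(ids, distances) -> GuideTree:
    """UPGMA agglomeration over a symmetric distance matrix.

    ``distances`` is either a dict keyed by frozenset({i, j}) or a full
    square array in the order of ``ids``.  Ties are broken by the
    lexicographically smallest (representative_i, representative_j) pair.
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("tree needs two leaves")
    if isinstance(distances, dict):
        dist = {frozenset(k): float(v) for k, v in distances.items()}
    else:
        arr = np.asarray(distances, dtype=float)
        dist = {frozenset((ids[i], ids[j])): float(arr[i, j])
                for i in range(len(ids)) for j in range(i + 1, len(ids))}

    clusters: dict[str, TreeNode] = {
        i: TreeNode(leaf_names=(i,), name=i) for i in ids}
    sizes = {i: 1 for i in ids}
    d = {frozenset((a, b)): dist[frozenset((a, b))]
         for a in ids for b in ids if a < b}

    while len(clusters) > 1:
        best = None
        for key, value in d.items():
            a, b = sorted(key)
            cand = (value, a, b)
            if best is None or cand < best:
                best = cand
        value, a, b = best
        na, nb = clusters.pop(a), clusters.pop(b)
        merged = TreeNode(leaf_names=tuple(sorted(na.leaf_names + nb.leaf_names)),
                          height=value / 2.0,
                          children=tuple(sorted((na, nb), key=lambda n: n.rep)))
        rep = merged.rep
        sa, sb = sizes.pop(a), sizes.pop(b)
        new_d = {}
        for key, val in d.items():
            if a in key or b in key:
                continue
            new_d[key] = val
        for c in clusters:
            da = d[frozenset((a, c))]
            db = d[frozenset((b, c))]
            new_d[frozenset((rep, c))] = (sa * da + sb * db) / (sa + sb)
        clusters[rep] = merged
        sizes[rep] = sa + sb
        d = new_d
    return GuideTree(next(iter(clusters.values())))


def select_clade(tree: GuideTree, target_id: str, template_id: str) -> set[str]:
    """Leaf ids descending from the MRCA of target and template."""
    return set(tree.mrca(target_id, template_id).leaf_names)


# ---------------------------------------------------------------------------
# Consistency library

class ConsistencyLibrary:
    """Symmetric residue-pair weights supporting the T-Coffee objective."""

    def __init__(self):
        self._w: dict[tuple, float] = {}

    @staticmethod
    def _key(i: str, a: int, j: str, b: int):
        return ((i, a), (j, b)) if (i, a) <= (j, b) else ((j, b), (i, a))

    def add(self, i: str, a: int, j: str, b: int, w: float) -> None:
        if w < 0:
            raise ValueError("library weights are non-negative")
        key = self._key(i, a, j, b)
        self._w[key] = self._w.get(key, 0.0) + w

    def weight(self, i: str, a: int, j: str, b: int) -> float:
        return self._w.get(self._key(i, a, j, b), 0.0)

    def __len__(self) -> int:
        return len(self._w)

    def items(self):
        return self._w.items()


def build_library(alignments) -> ConsistencyLibrary:
    """Primary weights (pid x 100 per aligned pair) plus triplet extension."""
    lib = ConsistencyLibrary()
    pair_maps: dict[tuple[str, str], dict[int, int]] = {}
    pair_w: dict[tuple[str, str], float] = {}
    for aln in alignments:
        pid = aln.percent_identity() * 100.0
        fwd: dict[int, int] = {}
        for pa, pb in aln.column_positions():
            if pa is not None and pb is not None:
                fwd[pa] = pb
                lib.add(aln.id_a, pa, aln.id_b, pb, pid)
        pair_maps[(aln.id_a, aln.id_b)] = fwd
        pair_maps[(aln.id_b, aln.id_a)] = {v: k for k, v in fwd.items()}
        pair_w[(aln.id_a, aln.id_b)] = pid
        pair_w[(aln.id_b, aln.id_a)] = pid
    seq_ids = sorted({sid for pair in pair_maps for sid in pair})
    for i in seq_ids:
        for j in seq_ids:
            if i >= j:
                continue
            for k in seq_ids:
                if k == i or k == j:
                    continue
                m_ik = pair_maps.get((i, k))
                m_kj = pair_maps.get((k, j))
                if m_ik is None or m_kj is None:
                    continue
                w = min(pair_w[(i, k)], pair_w[(k, j)])
                for a, c in m_ik.items():
                    b = m_kj.get(c)
                    if b is not None:
                        lib.add(i, a, j, b, w)
    return lib


# ---------------------------------------------------------------------------
# Progressive profile alignment

@dataclass
class MultipleAlignment:
    rows: dict[str, str]

    def __post_init__(self):
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("ragged multiple alignment")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace("-", "")

    def library_score(self, library: ConsistencyLibrary) -> float:
        ids = list(self.rows)
        pos = {rid: [] for rid in ids}
        for rid in ids:
            p = 0
            for ch in self.rows[rid]:
                pos[rid].append(p if ch != "-" else None)
                if ch != "-":
                    p += 1
        total = 0.0
        for c in range(self.width):
            present = [(rid, pos[rid][c]) for rid in ids if pos[rid][c] is not None]
            for x in range(len(present)):
                for y in range(x + 1, len(present)):
                    (i, a), (j, b) = present[x], present[y]
                    total += library.weight(i, a, j, b)
        return total


def _merge_profiles(A: dict[str, str], B: dict[str, str],
                    library: ConsistencyLibrary) -> dict[str, str]:
    ids_a, ids_b = list(A), list(B)
    wa = len(next(iter(A.values())))
    wb = len(next(iter(B.values())))

    def columns(P, ids):
        pos = {rid: 0 for rid in ids}
        cols = []
        for c in range(len(next(iter(P.values())))):
            col = []
            for rid in ids:
                ch = P[rid][c]
                if ch != "-":
                    col.append((rid, pos[rid]))
                    pos[rid] += 1
            cols.append(col)
        return cols

    cols_a = columns(A, ids_a)
    cols_b = columns(B, ids_b)

    def colscore(ca, cb) -> float:
        if not ca or not cb:
            return 0.0
        total = 0.0
        count = 0
        for (i, a) in ca:
            for (j, b) in cb:
                total += library.weight(i, a, j, b)
                count += 1
        return total / count if count else 0.0

    S = np.zeros((wa + 1, wb + 1))
    for i in range(1, wa + 1):
        for j in range(1, wb + 1):
            S[i, j] = max(S[i - 1, j - 1] + colscore(cols_a[i - 1], cols_b[j - 1]),
                          S[i - 1, j], S[i, j - 1])
    # traceback: prefer diagonal > consume-A > consume-B
    i, j = wa, wb
    ops: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(S[i, j] - (S[i - 1, j - 1]
                                   + colscore(cols_a[i - 1], cols_b[j - 1]))) < 1e-9:
            ops.append("D")
            i, j = i - 1, j - 1
        elif i > 0 and abs(S[i, j] - S[i - 1, j]) < 1e-9:
            ops.append("A")
            i -= 1
        else:
            ops.append("B")
            j -= 1
    ops.reverse()
    merged: dict[str, list[str]] = {rid: [] for rid in ids_a + ids_b}
    pa = pb = 0
    for op in ops:
        if op == "D":
            for rid in ids_a:
                merged[rid].append(A[rid][pa])
            for rid in ids_b:
                merged[rid].append(B[rid][pb])
            pa += 1
            pb += 1
        elif op == "A":
            for rid in ids_a:
                merged[rid].append(A[rid][pa])
            for rid in ids_b:
                merged[rid].append("-")
            pa += 1
        else:
            for rid in ids_a:
                merged[rid].append("-")
            for rid in ids_b:
                merged[rid].append(B[rid][pb])
            pb += 1
    return {rid: "".join(chars) for rid, chars in merged.items()}


def progressive_align(seqs: dict[str, str], tree: GuideTree,
                      library: ConsistencyLibrary) -> MultipleAlignment:
    """Profile-profile progressive alignment in guide-tree post-order.

    Column score is the mean library weight over constituent residue pairs;
    gaps inside profiles are frozen (once a gap, always a gap).
    """
    def rec(node: TreeNode) -> dict[str, str]:
        if node.is_leaf:
            return {node.name: seqs[node.name]}
        profiles = [rec(ch) for ch in node.children]
        out = profiles[0]
        for prof in profiles[1:]:
            out = _merge_profiles(out, prof, library)
        return out

    return MultipleAlignment(rec(tree.root))


def extract_pair(msa: MultipleAlignment, target_id: str, template_id: str,
                 template_envs=None) -> PairwiseAlignment:
    """Target-template rows of the MSA with dual-gap columns dropped."""
    for rid in (target_id, template_id):
        if rid not in msa.rows:
            raise KeyError(f"id not in alignment: {rid!r}")
    ra_chars = []
    rb_chars = []
    for ca, cb in zip(msa.rows[target_id], msa.rows[template_id]):
        if ca == "-" and cb == "-":
            continue
        ra_chars.append(ca)
        rb_chars.append(cb)
    row_a, row_b = "".join(ra_chars), "".join(rb_chars)
    env_b = None
    if template_envs is not None:
        env_b = []
        p = 0
        for cb in row_b:
            env_b.append(template_envs[p] if cb != "-" else None)
            if cb != "-":
                p += 1
    return PairwiseAlignment(target_id, template_id, row_a, row_b,
                             None, None, env_b)


# ---------------------------------------------------------------------------
# Orchestration

def align_target_template(target: SequenceRecord, annotated_template,
                          homologues=(), model: ScoringModel | None = None,
                          template_id: str | None = None):
    """Full alignment stage: annotation transfer, pairwise alignments, guide
    tree, MRCA clade, consistency library, progressive MSA, pair extraction.

    Returns ``(pair_alignment, msa, clade_ids)``.
    """
    model = model or default_scoring_model()
    template_id = template_id or annotated_template.structure.id
    template = SequenceRecord(template_id, annotated_template.sequence)
    template_envs = annotations_to_envs(annotated_template)

    records = {target.id: target, template.id: template}
    envs = {target.id: [UNKNOWN_ENV] * len(target.sequence),
            template.id: template_envs}
    for hom in homologues:
        if hom.id in records:
            continue
        records[hom.id] = hom
        envs[hom.id] = transfer_annotation(annotated_template, hom)

    ids = sorted(records)
    alignments = {}
    dist = {}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            i, j = ids[x], ids[y]
            aln = align_pair(records[i], records[j], model, envs[i], envs[j])
            alignments[(i, j)] = aln
            dist[frozenset((i, j))] = 1.0 - aln.percent_identity()

    if len(ids) == 2:
        pair = alignments[tuple(sorted((target.id, template.id)))]
        pair = _orient_pair(pair, target.id)
        pair.env_b = _column_envs(pair.row_b, template_envs)
        msa = MultipleAlignment({target.id: pair.row_a, template.id: pair.row_b})
        return pair, msa, {target.id, template.id}

    tree = build_guide_tree(ids, dist)
    clade = select_clade(tree, target.id, template.id)
    clade_alignments = [a for (i, j), a in alignments.items()
                        if i in clade and j in clade]
    library = build_library(clade_alignments)
    subtree = build_guide_tree(sorted(clade),
                               {k: v for k, v in dist.items() if k <= clade})
    msa = progressive_align({i: records[i].sequence for i in clade},
                            subtree, library)
    pair = extract_pair(msa, target.id, template.id, template_envs)
    return pair, msa, clade


def _orient_pair(aln: PairwiseAlignment, first_id: str) -> PairwiseAlignment:
    if aln.id_a == first_id:
        return aln
    return PairwiseAlignment(aln.id_b, aln.id_a, aln.row_b, aln.row_a,
                             aln.score, aln.env_b, aln.env_a)


def _column_envs(row: str, envs):
    out = []
    p = 0
    for ch in row:
        out.append(envs[p] if ch != "-" else None)
        if ch != "-":
            p += 1
    return out
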