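"""Fragment-based loop modelling: database, filtering, ranking, grafting.

Gaps left by the core builder are filled from a length-indexed database of
backbone fragments cut from known structures.  For each gap, candidate
fragments of the right length are first filtered by sequence propensity
(the summed substitution score between the unmodelled target residues and
the fragment's residues), then ranked by how closely the fragment's
flanking residues superpose onto the modelled anchors of the gap (anchor
RMSD after a Kabsch fit).  The best fragment is grafted — its loop backbone
is rigidly transformed and spliced into the gap, the core left untouched —
and the top alternatives are retained.

Two stringencies produce the two output models: the high-accuracy mode uses
the membrane fragment database with strict thresholds, the high-coverage
mode adds the soluble database and relaxed thresholds (and is the only mode
allowed to model chain-terminal gaps, with single-sided anchoring).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._tables import ONE_TO_THREE
from .geometry import apply_transform, kabsch
from .medeller_build import CoreModel, GapInterval, ModelledResidue

__all__ = [
    "Fragment", "FragmentDB", "FillConfig", "LoopCandidate", "LoopFill",
    "build_fragment_db", "propensity_score", "anchor_fit", "fill_gap",
    "complete_model",
]

log = logging.getLogger(__name__)

BACKBONE = ("N", "CA", "C", "O")
N_ANCHOR = 3           # flanking residues per side
MAX_CA_CA = 4.2        # chain-continuity threshold (A)


@dataclass(frozen=True)
class Fragment:
    source_id: str
    start_number: int          # author number of the first flank residue
    db_class: str              # membrane | soluble
    length: int                # loop residues
    sequence: str              # loop letters only
    coords: np.ndarray         # (length + 6, 4, 3): N, CA, C, O per residue

    def __post_init__(self):
        if self.coords.shape != (self.length + 2 * N_ANCHOR, 4, 3):
            raise ValueError("fragment coordinate array has wrong shape")

    @property
    def left_anchor_coords(self) -> np.ndarray:
        return self.coords[:N_ANCHOR]

    @property
    def right_anchor_coords(self) -> np.ndarray:
        return self.coords[-N_ANCHOR:]

    @property
    def loop_coords(self) -> np.ndarray:
        return self.coords[N_ANCHOR:N_ANCHOR + self.length]


@dataclass
class FragmentDB:
    db_class: str
    by_length: dict[int, list[Fragment]] = field(default_factory=dict)

    def fragments(self, length: int) -> list[Fragment]:
        return self.by_length.get(length, [])

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.by_length.values())


@dataclass(frozen=True)
class FillConfig:
    mode: str                    # hiacc | hicov
    anchor_rmsd_max: float
    propensity_min: float
    use_soluble: bool
    allow_terminal: bool
    alternatives_k: int = 10

    @classmethod
    def hiacc(cls) -> "FillConfig":
        return cls("hiacc", anchor_rmsd_max=1.0, propensity_min=25.0,
                   use_soluble=False, allow_terminal=False)

    @classmethod
    def hicov(cls) -> "FillConfig":
        return cls("hicov", anchor_rmsd_max=2.0, propensity_min=0.0,
                   use_soluble=True, allow_terminal=True)


@dataclass
class LoopCandidate:
    fragment: Fragment
    propensity: float
    anchor_rmsd: float
    rotation: np.ndarray
    translation: np.ndarray


@dataclass
class LoopFill:
    gap: GapInterval
    mode: str
    status: str                   # filled | no_candidates | no_anchors | terminal_skipped
    chosen: LoopCandidate | None = None
    alternatives: list = field(default_factory=list)
    candidate_count: int = 0


# ---------------------------------------------------------------------------
# Database construction

def build_fragment_db(structures, db_class: str = "membrane",
                      length_range: tuple[int, int] = (2, 14)) -> FragmentDB:
    """Cut every contiguous window (loop + 3-residue flanks) from the chains.

    Windows crossing a chain break (consecutive CA-CA >= 4.2 A) or touching
    a residue with incomplete backbone are excluded.
    """
    lo, hi = length_range
    db = FragmentDB(db_class)
    for structure in structures:
        for chain in structure.chains:
            res = chain.residues
            usable = [r.has_complete_backbone for r in res]
            contiguous = []
            for i in range(len(res) - 1):
                ok = (usable[i] and usable[i + 1]
                      and np.linalg.norm(res[i + 1].atoms["CA"] - res[i].atoms["CA"])
                      < MAX_CA_CA)
                contiguous.append(ok)
            for length in range(lo, hi + 1):
                span = length + 2 * N_ANCHOR
                if len(res) < span:
                    log.debug("%s/%s too short for length %d",
                              structure.id, chain.id, length)
                    continue
                for start in range(len(res) - span + 1):
                    if not all(usable[start:start + span]):
                        continue
                    if not all(contiguous[start:start + span - 1]):
                        continue
                    window = res[start:start + span]
                    coords = np.array([[r.atoms[a] for a in BACKBONE]
                                       for r in window])
                    seq = "".join(r.one_letter
                                  for r in window[N_ANCHOR:N_ANCHOR + length])
                    db.by_length.setdefault(length, []).append(Fragment(
                        source_id=f"{structure.id}/{chain.id}",
                        start_number=window[0].number, db_class=db_class,
                        length=length, sequence=seq, coords=coords))
    return db


# ---------------------------------------------------------------------------
# Scoring

_BLOSUM = substitution_matrices.load("BLOSUM62")


def propensity_score(gap_sequence: str, fragment_sequence: str) -> float:
    """Summed BLOSUM62 score between gap and fragment residues (half-bits)."""
    if len(gap_sequence) != len(fragment_sequence):
        raise ValueError("fragment length mismatch")
    total = 0.0
    for a, b in zip(gap_sequence, fragment_sequence):
        ka = a if a in _BLOSUM.alphabet else "X"
        kb = b if b in _BLOSUM.alphabet else "X"
        total += float(_BLOSUM[ka, kb])
    return total


def anchor_fit(anchor_coords: np.ndarray, fragment: Fragment,
               side: str = "both"):
    """Kabsch superposition of the fragment's anchor residues onto the model's.

    ``anchor_coords`` is (6, 4, 3) for double-sided gaps (left then right
    flank) or (3, 4, 3) for single-sided terminal gaps with ``side`` set to
    ``"left"`` (anchors N-terminal of the gap) or ``"right"``.

    Returns ``(anchor_rmsd, R, t)`` with the transform mapping fragment
    coordinates into the model frame.
    """
    anchor_coords = np.asarray(anchor_coords, float)
    if side == "both":
        frag_pts = np.concatenate([fragment.left_anchor_coords,
                                   fragment.right_anchor_coords])
    elif side == "left":
        frag_pts = fragment.left_anchor_coords
    elif side == "right":
        frag_pts = fragment.right_anchor_coords
    else:
        raise ValueError(f"unknown side {side!r}")
    model_pts = anchor_coords.reshape(-1, 3)
    frag_pts = frag_pts.reshape(-1, 3)
    if model_pts.shape != frag_pts.shape:
        raise ValueError("insufficient anchors")
    R, t, rmsd = kabsch(frag_pts, model_pts)
    return rmsd, R, t


# ---------------------------------------------------------------------------
# Filling

def _gather_anchors(core: CoreModel, gap: GapInterval):
    """Model anchor coordinates for a gap; returns (coords, side) or None."""
    def side_coords(indices):
        pts = []
        for i in indices:
            if i < 0 or i >= len(core.entries):
                return None
            e = core.entries[i]
            if e is None or any(a not in e.atoms for a in BACKBONE):
                return None
            pts.append([e.atoms[a] for a in BACKBONE])
        return np.array(pts)

    left = side_coords(range(gap.start - N_ANCHOR, gap.start))
    right = side_coords(range(gap.end + 1, gap.end + 1 + N_ANCHOR))
    if gap.left_anchor is None:
        return (right, "right") if right is not None else None
    if gap.right_anchor is None:
        return (left, "left") if left is not None else None
    if left is None or right is None:
        return None
    return np.concatenate([left, right]), "both"


def fill_gap(core: CoreModel, gap: GapInterval, dbs, config: FillConfig) -> LoopFill:
    """Fill one gap in place: filter, rank, graft the best candidate.

    Ranking is by anchor RMSD ascending, ties by propensity descending, then
    source id — deterministic.  On an empty candidate list the gap is left
    unfilled and the status recorded.
    """
    if not any(g.start == gap.start and g.end == gap.end for g in core.gaps):
        raise KeyError(f"unknown gap {gap.start}-{gap.end}")
    if gap.is_terminal and not config.allow_terminal:
        return LoopFill(gap, config.mode, "terminal_skipped")
    anchors = _gather_anchors(core, gap)
    if anchors is None:
        return LoopFill(gap, config.mode, "no_anchors")
    anchor_coords, side = anchors
    gap_seq = core.target_sequence[gap.start:gap.end + 1]

    scored: list[tuple] = []
    for db in dbs:
        if db.db_class == "soluble" and not config.use_soluble:
            continue
        for frag in db.fragments(gap.length):
            prop = propensity_score(gap_seq, frag.sequence)
            if prop < config.propensity_min:
                continue
            rmsd, R, t = anchor_fit(anchor_coords, frag, side)
            if rmsd > config.anchor_rmsd_max:
                continue
            scored.append((rmsd, -prop, frag.source_id, frag.start_number,
                           LoopCandidate(frag, prop, rmsd, R, t)))
    scored.sort(key=lambda item: item[:4])
    candidates = [item[4] for item in scored]
    if not candidates:
        return LoopFill(gap, config.mode, "no_candidates",
                        candidate_count=0)
    best = candidates[0]
    loop = apply_transform(best.fragment.loop_coords.reshape(-1, 3),
                           best.rotation, best.translation).reshape(-1, 4, 3)
    for offset, idx in enumerate(range(gap.start, gap.end + 1)):
        aa = core.target_sequence[idx]
        atoms = {name: loop[offset, k].copy() for k, name in enumerate(BACKBONE)}
        core.entries[idx] = ModelledResidue(
            index=idx, name=ONE_TO_THREE.get(aa, "UNK"), status="loop",
            atoms=atoms, source=("fragment", best.fragment.source_id,
                                 best.fragment.start_number))
    return LoopFill(gap, config.mode, "filled", chosen=best,
                    alternatives=candidates[:config.alternatives_k],
                    candidate_count=len(candidates))


def complete_model(core: CoreModel, membrane_db: FragmentDB,
                   soluble_db: FragmentDB | None = None,
                   mode: str = "hiacc",
                   config: FillConfig | None = None):
    """Fill every gap of the core under the mode's configuration.

    Returns ``(model, fills)`` where ``model`` is a new CoreModel with loops
    grafted in (the core coordinates are untouched) and ``fills`` the
    per-gap reports.
    """
    if config is None:
        config = FillConfig.hiacc() if mode == "hiacc" else FillConfig.hicov()
    model = core.copy()
    dbs = [membrane_db]
    if soluble_db is not None:
        dbs.append(soluble_db)
    fills = [fill_gap(model, gap, dbs, config) for gap in core.gaps]
    return model, fills
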