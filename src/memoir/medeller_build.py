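"""Core-model generation by membrane-outward coordinate copying.

Homology modelling is most reliable in the middle of transmembrane
segments, where the bilayer constrains structure most strongly.  The core
builder therefore seeds on the aligned runs whose template residues sit in
the lipid-tail layer and copies template coordinates outward from each seed
in both sequence directions — through head-layer and then non-membrane
positions — until a local assessment of alignment quality says structural
similarity can no longer be assumed.

Copied atoms are the backbone (N, CA, C, O) plus C-beta; the full side
chain is copied only where target and template residue types are identical
("conserved").  Target insertions (template-gap columns) terminate
extension, since they have no template coordinates; template-only columns
(target deletions) are walked through.  What remains is the core model plus
a manifest of unmodelled gaps for the loop-modelling stage.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from ._tables import ONE_TO_THREE
from .io_formats import Chain, Residue, Structure
from .mpt_align import PairwiseAlignment

__all__ = [
    "QualityProfile", "ModelledResidue", "GapInterval", "CoreModel",
    "local_quality", "build_schedule", "generate_core",
    "write_gap_manifest", "read_gap_manifest",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 11
DEFAULT_THRESHOLD = 0.3


@dataclass
class QualityProfile:
    scores: np.ndarray          # one value in [0, 1] per alignment column
    window: int = DEFAULT_WINDOW
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


@dataclass
class ModelledResidue:
    index: int                  # 0-based target sequence position
    name: str                   # 3-letter code of the TARGET residue
    status: str                 # "core" | "loop"
    atoms: dict[str, np.ndarray]
    source: tuple | None = None  # (template author number, icode) or fragment id
    layer: str | None = None
    conserved: bool = False


@dataclass(frozen=True)
class GapInterval:
    start: int                  # 0-based target indices, inclusive
    end: int
    left_anchor: int | None     # adjacent modelled index or None at a terminus
    right_anchor: int | None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_terminal(self) -> bool:
        return self.left_anchor is None or self.right_anchor is None


@dataclass
class CoreModel:
    target_id: str
    target_sequence: str
    entries: list  # ModelledResidue | None, one slot per target residue
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.entries) != len(self.target_sequence):
            raise ValueError("entries must align with the target sequence")

    @property
    def modelled_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e is not None]

    @property
    def coverage(self) -> float:
        return 100.0 * len(self.modelled_indices) / len(self.target_sequence)

    @property
    def gaps(self) -> list[GapInterval]:
        gaps = []
        n = len(self.entries)
        i = 0
        while i < n:
            if self.entries[i] is None:
                j = i
                while j < n and self.entries[j] is None:
                    j += 1
                left = i - 1 if i > 0 else None
                right = j if j < n else None
                gaps.append(GapInterval(i, j - 1, left, right))
                i = j
            else:
                i += 1
        return gaps

    def to_structure(self, chain_id: str = "A") -> Structure:
        residues = [Residue(e.name, e.index + 1, "",
                            {k: np.array(v, float) for k, v in e.atoms.items()})
                    for e in self.entries if e is not None]
        return Structure(self.target_id, [Chain(chain_id, residues)])

    def copy(self) -> "CoreModel":
        entries = []
        for e in self.entries:
            if e is None:
                entries.append(None)
            else:
                entries.append(ModelledResidue(
                    e.index, e.name, e.status,
                    {k: np.array(v, float) for k, v in e.atoms.items()},
                    e.source, e.layer, e.conserved))
        return CoreModel(self.target_id, self.target_sequence, entries,
                         list(self.notes))


# ---------------------------------------------------------------------------

def local_quality(aln: PairwiseAlignment, window: int = DEFAULT_WINDOW,
                  threshold: float = DEFAULT_THRESHOLD) -> QualityProfile:
    """Windowed identity-plus-similarity score per alignment column.

    Column contribution: 1 for an identical pair, 0.5 for a non-identical
    positive-scoring (BLOSUM62) pair, 0 otherwise and on gap columns.  The
    profile value at a column is the mean contribution over the centred
    window; truncated windows at the ends are renormalised by their actual
    width.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    B = substitution_matrices.load("BLOSUM62")
    v = np.zeros(aln.width)
    for c, (a, b) in enumerate(zip(aln.row_a, aln.row_b)):
        if a == "-" or b == "-":
            continue
        if a == b:
            v[c] = 1.0
        else:
            ka = a if a in B.alphabet else "X"
            kb = b if b in B.alphabet else "X"
            if B[ka, kb] > 0:
                v[c] = 0.5
    kernel = np.ones(window)
    sums = np.convolve(v, kernel, mode="same")
    counts = np.convolve(np.ones_like(v), kernel, mode="same")
    return QualityProfile(sums / counts, window, threshold)


def build_schedule(annotated_template, aln: PairwiseAlignment) -> list[tuple[int, int]]:
    """Seed runs (inclusive column intervals) for outward extension.

    Seeds are the maximal aligned runs whose template residues lie in the
    lipid-tail layer, processed N to C.  With no tail-layer run at all the
    longest aligned run is the single fallback seed.
    """
    layers = [a.layer for a in annotated_template.annotations]
    cols = list(aln.column_positions())
    tail_runs: list[tuple[int, int]] = []
    aligned_runs: list[tuple[int, int]] = []

    def collect(predicate, out):
        start = None
        for c, (pa, pb) in enumerate(cols):
            good = pa is not None and pb is not None and predicate(pb)
            if good and start is None:
                start = c
            elif not good and start is not None:
                out.append((start, c - 1))
                start = None
        if start is not None:
            out.append((start, len(cols) - 1))

    collect(lambda pb: layers[pb] == "tail", tail_runs)
    collect(lambda pb: True, aligned_runs)
    if tail_runs:
        return tail_runs
    if not aligned_runs:
        return []
    log.warning("no membrane core found; falling back to longest aligned run")
    return [max(aligned_runs, key=lambda r: (r[1] - r[0], -r[0]))]


def generate_core(aln: PairwiseAlignment, template_structure: Structure,
                  schedule, quality: QualityProfile,
                  annotated_template=None, chain_id: str | None = None,
                  target_id: str | None = None, max_bridge: int = 0) -> CoreModel:
    """Copy template coordinates outward from each seed run.

    ``aln`` must have the target as row_a and the template as row_b.
    Extension in a direction stops at the first column with quality below
    threshold, at a target-insertion (template-gap) run longer than
    ``max_bridge`` (default 0: any insertion stops), at a template residue
    with incomplete backbone, or on reaching an already modelled residue.
    """
    template_res = template_structure.chain(chain_id).residues
    target_seq = aln.ungapped("a")
    layers = None
    if annotated_template is not None:
        layers = [a.layer for a in annotated_template.annotations]
    cols = list(aln.column_positions())
    entries: list = [None] * len(target_seq)
    notes: list[str] = []

    def copy_column(c) -> str:
        """Returns 'copied', 'skip' (no target residue) or 'stop'."""
        pa, pb = cols[c]
        if pa is None:
            return "skip"          # deletion: no target residue to model
        if pb is None:
            return "insertion"     # target residue with no coordinates
        if quality.scores[c] < quality.threshold:
            return "stop"
        tres = template_res[pb]
        if not tres.has_complete_backbone:
            notes.append(f"template residue {tres.number}{tres.icode} "
                         "lacks backbone; extension stopped")
            return "stop"
        if entries[pa] is not None:
            return "stop"          # met another seed's territory
        target_aa = target_seq[pa]
        conserved = (target_aa == tres.one_letter)
        if conserved:
            atoms = {k: np.array(v, float) for k, v in tres.atoms.items()}
        else:
            atoms = {k: np.array(tres.atoms[k], float)
                     for k in ("N", "CA", "C", "O") if k in tres.atoms}
            if "CB" in tres.atoms and target_aa != "G":
                atoms["CB"] = np.array(tres.atoms["CB"], float)
        if target_aa == "G":
            atoms.pop("CB", None)
        entries[pa] = ModelledResidue(
            index=pa, name=ONE_TO_THREE.get(target_aa, "UNK"), status="core",
            atoms=atoms, source=(tres.number, tres.icode),
            layer=layers[pb] if layers else None, conserved=conserved)
        return "copied"

    def walk(columns):
        run_insertions = 0
        for c in columns:
            r = copy_column(c)
            if r == "stop":
                break
            if r == "insertion":
                run_insertions += 1
                if run_insertions > max_bridge:
                    break
            else:
                run_insertions = 0

    for (cs, ce) in schedule:
        for c in range(cs, ce + 1):        # seed interior: copy what is copyable
            copy_column(c)
        walk(range(cs - 1, -1, -1))        # extend N-ward
        walk(range(ce + 1, len(cols)))     # extend C-ward
    return CoreModel(target_id or aln.id_a, target_seq, entries, notes)


# ---------------------------------------------------------------------------

def write_gap_manifest(core: CoreModel, path) -> None:
    payload = {
        "target_id": core.target_id,
        "target_sequence": core.target_sequence,
        "modelled": [
            {"index": e.index, "status": e.status, "conserved": e.conserved,
             "layer": e.layer}
            for e in core.entries if e is not None
        ],
        "gaps": [
            {"start": g.start, "end": g.end,
             "left_anchor": g.left_anchor, "right_anchor": g.right_anchor}
            for g in core.gaps
        ],
        "notes": core.notes,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_gap_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
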