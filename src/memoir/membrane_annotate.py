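"""Per-residue environment annotation of a template structure.

Each residue of the (single selected chain of the) template is labelled with:

* membrane layer — ``tail`` (hydrophobic lipid-tail slab), ``head`` (polar
  lipid-head shell) or ``non-membrane``;
* secondary structure — H/E/C from backbone dihedral regions;
* accessibility — accessible/buried from relative solvent-accessible area.

The membrane position itself is found geometrically: an exhaustive grid
search for the slab (normal, centre offset, tail half-width) maximising the
contrast Q = mean Kyte-Doolittle hydrophobicity of exposed residues inside
the tail layer minus the mean outside it.  This is a purely structural
stand-in for annotation pipelines that derive membrane contact from
molecular-dynamics simulation databases; the label set (lipid tails, lipid
heads, outside) is the same, so downstream environment-aware scoring is
unaffected by the choice.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._tables import KYTE_DOOLITTLE, MAX_ASA, MAX_ASA_DEFAULT
from .geometry import dihedral
from .io_formats import Structure

__all__ = [
    "MembraneSlab", "ResidueAnnotation", "AnnotatedTemplate",
    "assign_secondary_structure", "compute_relative_asa",
    "fit_membrane_slab", "slab_quality", "annotate_template",
    "write_annotation_tsv", "read_annotation_tsv",
]

log = logging.getLogger(__name__)

BURIED_THRESHOLD = 0.07
HEAD_WIDTH = 6.0

LAYERS = ("tail", "head", "non-membrane")


@dataclass(frozen=True)
class MembraneSlab:
    normal: np.ndarray
    center_offset: float
    tail_half_width: float
    head_width: float = HEAD_WIDTH

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("slab normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        if not (10.0 <= self.tail_half_width <= 20.0):
            raise ValueError("tail_half_width must be in [10, 20] A")
        if self.head_width < 0:
            raise ValueError("head_width must be non-negative")

    def layer_of(self, point: np.ndarray) -> str:
        d = abs(float(np.dot(np.asarray(point, float), self.normal)) - self.center_offset)
        if d <= self.tail_half_width:
            return "tail"
        if d <= self.tail_half_width + self.head_width:
            return "head"
        return "non-membrane"


@dataclass(frozen=True)
class ResidueAnnotation:
    layer: str
    ss: str
    accessibility: str
    rel_asa: float


@dataclass
class AnnotatedTemplate:
    structure: Structure
    chain_id: str | None
    annotations: list[ResidueAnnotation]
    slab: MembraneSlab

    def __post_init__(self):
        n = len(self.structure.chain(self.chain_id).residues)
        if len(self.annotations) != n:
            raise ValueError("annotations must align index-for-index with residues")

    @property
    def residues(self):
        return self.structure.chain(self.chain_id).residues

    @property
    def sequence(self) -> str:
        return self.structure.sequence(self.chain_id)

    def layer_track(self) -> str:
        code = {"tail": "T", "head": "P", "non-membrane": "."}
        return "".join(code[a.layer] for a in self.annotations)


# ---------------------------------------------------------------------------
# Secondary structure from backbone dihedrals

_H_PHI = (-100.0, -30.0)
_H_PSI = (-80.0, -5.0)
_E_PHI = (-180.0, -90.0)
_CHAIN_BREAK_CN = 2.5  # A


def _in(value, lohi):
    return lohi[0] <= value <= lohi[1]


def assign_secondary_structure(structure: Structure, chain_id: str | None = None) -> list[str]:
    """H/E/C labels from phi/psi regions, with minimum run lengths.

    Helix runs shorter than 4 and strand runs shorter than 3 are demoted to
    coil; residues with undefined dihedrals (termini, chain breaks, missing
    backbone atoms) are coil.
    """
    residues = structure.chain(chain_id).residues
    n = len(residues)
    raw = ["C"] * n
    for i, res in enumerate(residues):
        if not res.has_complete_backbone:
            log.warning("residue %s%s lacks backbone atoms; labelled C",
                        res.number, res.icode)
            continue
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < n else None
        phi = psi = None
        if prev_res is not None and prev_res.has_complete_backbone:
            if np.linalg.norm(prev_res.atoms["C"] - res.atoms["N"]) <= _CHAIN_BREAK_CN:
                phi = dihedral(prev_res.atoms["C"], res.atoms["N"],
                               res.atoms["CA"], res.atoms["C"])
        if next_res is not None and "N" in next_res.atoms:
            if np.linalg.norm(res.atoms["C"] - next_res.atoms["N"]) <= _CHAIN_BREAK_CN:
                psi = dihedral(res.atoms["N"], res.atoms["CA"],
                               res.atoms["C"], next_res.atoms["N"])
        if phi is None or psi is None:
            continue
        if _in(phi, _H_PHI) and _in(psi, _H_PSI):
            raw[i] = "H"
        elif _in(phi, _E_PHI) and (90.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0):
            raw[i] = "E"
    return _demote_short_runs(raw, {"H": 4, "E": 3})


def _demote_short_runs(labels: list[str], min_run: dict[str, int]) -> list[str]:
    out = list(labels)
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if out[i] in min_run and (j - i) < min_run[out[i]]:
            for k in range(i, j):
                out[k] = "C"
        i = j
    return out


# ---------------------------------------------------------------------------
# Relative accessible surface area

def compute_relative_asa(structure: Structure, chain_id: str | None = None,
                         point_number: int = 384, probe_radius: float = 1.4) -> list[float]:
    """Shrake-Rupley relative ASA per residue of the selected chain.

    Occlusion is computed over all atoms of the structure; per-residue ASA is
    normalised by the residue type's theoretical maximum and clamped to
    [0, 1].
    """
    import biotite.structure as struc

    atoms = []
    for ch in structure.chains:
        for res in ch.residues:
            for name, xyz in res.atoms.items():
                atoms.append((ch.id, res, name, xyz))
    if not atoms:
        raise ValueError("structure has no atoms")
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a[3] for a in atoms], dtype=np.float32)
    arr.chain_id = np.array([a[0] or "A" for a in atoms])
    arr.res_id = np.array([a[1].number for a in atoms])
    arr.ins_code = np.array([a[1].icode for a in atoms])
    arr.res_name = np.array([a[1].name for a in atoms])
    arr.atom_name = np.array([a[2] for a in atoms])
    arr.element = np.array([_element(a[2]) for a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    per_atom = struc.sasa(arr, probe_radius=probe_radius, point_number=point_number,
                          vdw_radii="Single")
    per_atom = np.nan_to_num(per_atom, nan=0.0)

    target = structure.chain(chain_id)
    sums: dict[int, float] = {}
    for value, (cid, res, _, _) in zip(per_atom, atoms):
        if cid == target.id:
            sums[id(res)] = sums.get(id(res), 0.0) + float(value)
    out = []
    for res in target.residues:
        ref = MAX_ASA.get(res.name, MAX_ASA_DEFAULT)
        out.append(min(1.0, sums.get(id(res), 0.0) / ref))
    return out


def _element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return stripped[0] if stripped else "C"


# ---------------------------------------------------------------------------
# Hydrophobic-slab fit

def _normal_grid(step_deg: float) -> np.ndarray:
    normals = [np.array([0.0, 0.0, 1.0])]
    for theta in np.arange(step_deg, 90.0 + 1e-9, step_deg):
        th = np.radians(theta)
        for phi in np.arange(0.0, 360.0, step_deg):
            ph = np.radians(phi)
            normals.append(np.array([np.sin(th) * np.cos(ph),
                                     np.sin(th) * np.sin(ph),
                                     np.cos(th)]))
    return np.array(normals)


def slab_quality(structure: Structure, rel_asa, slab: MembraneSlab,
                 chain_id: str | None = None,
                 buried_threshold: float = BURIED_THRESHOLD) -> float:
    """Hydrophobicity contrast Q of a candidate slab (exposed residues only)."""
    residues = structure.chain(chain_id).residues
    ca = np.array([r.atoms["CA"] for r in residues])
    hyd = np.array([KYTE_DOOLITTLE.get(r.one_letter, 0.0) for r in residues])
    exposed = np.asarray(rel_asa, float) >= buried_threshold
    proj = ca[exposed] @ slab.normal
    inside = np.abs(proj - slab.center_offset) <= slab.tail_half_width
    if inside.all() or not inside.any():
        return -np.inf
    he = hyd[exposed]
    return float(he[inside].mean() - he[~inside].mean())


def fit_membrane_slab(structure: Structure, rel_asa, chain_id: str | None = None, *,
                      buried_threshold: float = BURIED_THRESHOLD,
                      angle_step_deg: float = 5.0, offset_step: float = 1.0,
                      width_min: float = 10.0, width_max: float = 20.0,
                      width_step: float = 1.0,
                      head_width: float = HEAD_WIDTH) -> MembraneSlab:
    """Exhaustive grid search for the membrane slab maximising Q.

    The search is deterministic: on exact Q ties the smallest
    (normal-grid index, offset index, width index) wins.
    """
    residues = structure.chain(chain_id).residues
    ca = np.array([r.atoms["CA"] for r in residues if "CA" in r.atoms])
    hyd = np.array([KYTE_DOOLITTLE.get(r.one_letter, 0.0)
                    for r in residues if "CA" in r.atoms])
    exposed = np.array([ra >= buried_threshold
                        for r, ra in zip(residues, rel_asa) if "CA" in r.atoms])
    if not exposed.any():
        raise ValueError("no exposed residues; cannot position membrane")

    normals = _normal_grid(angle_step_deg)
    proj_all = ca @ normals.T          # (n, K)
    proj_exp = proj_all[exposed]       # (ne, K)
    he = hyd[exposed]
    ne = len(he)
    total = he.sum()
    offsets = np.arange(np.floor(proj_all.min()), np.ceil(proj_all.max()) + 1e-9,
                        offset_step)
    widths = np.arange(width_min, width_max + 1e-9, width_step)

    K = len(normals)
    Q = np.full((K, len(offsets), len(widths)), -np.inf)
    for oi, off in enumerate(offsets):
        d = np.abs(proj_exp - off)             # (ne, K)
        for wi, w in enumerate(widths):
            inside = d <= w
            n_in = inside.sum(axis=0)
            s_in = he @ inside
            valid = (n_in > 0) & (n_in < ne)
            with np.errstate(invalid="ignore", divide="ignore"):
                q = s_in / np.maximum(n_in, 1) - (total - s_in) / np.maximum(ne - n_in, 1)
            Q[:, oi, wi] = np.where(valid, q, -np.inf)

    flat = int(np.argmax(Q))  # first occurrence => smallest (k, o, w) on ties
    k, oi, wi = np.unravel_index(flat, Q.shape)
    return MembraneSlab(normal=normals[k], center_offset=float(offsets[oi]),
                        tail_half_width=float(widths[wi]), head_width=head_width)


# ---------------------------------------------------------------------------
# Composition

def annotate_template(structure: Structure, chain_id: str | None = None, *,
                      buried_threshold: float = BURIED_THRESHOLD,
                      head_width: float = HEAD_WIDTH,
                      angle_step_deg: float = 5.0,
                      point_number: int = 384,
                      slab: MembraneSlab | None = None) -> AnnotatedTemplate:
    """Full annotation: secondary structure, relative ASA, slab fit, layers.

    A precomputed ``slab`` (e.g. a fixture's construction slab) can be passed
    to skip the grid search.
    """
    ss = assign_secondary_structure(structure, chain_id)
    rel_asa = compute_relative_asa(structure, chain_id, point_number=point_number)
    if slab is None:
        slab = fit_membrane_slab(structure, rel_asa, chain_id,
                                 buried_threshold=buried_threshold,
                                 angle_step_deg=angle_step_deg,
                                 head_width=head_width)
    annotations = []
    for res, s, ra in zip(structure.chain(chain_id).residues, ss, rel_asa):
        if "CA" in res.atoms:
            layer = slab.layer_of(res.atoms["CA"])
        else:
            layer = "non-membrane"
        acc = "buried" if ra < buried_threshold else "accessible"
        annotations.append(ResidueAnnotation(layer, s, acc, ra))
    return AnnotatedTemplate(structure, chain_id, annotations, slab)


def write_annotation_tsv(annotated: AnnotatedTemplate, path) -> None:
    lines = ["author_number\tlayer\tss\taccessibility\trel_asa"]
    for res, ann in zip(annotated.residues, annotated.annotations):
        num = f"{res.number}{res.icode}"
        lines.append(f"{num}\t{ann.layer}\t{ann.ss}\t{ann.accessibility}\t{ann.rel_asa:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_tsv(path) -> list[ResidueAnnotation]:
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        _, layer, ss, acc, rel = line.split("\t")
        out.append(ResidueAnnotation(layer, ss, acc, float(rel)))
    return out
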