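"""Synthetic membrane-like test structures and homologous sequence families.

Real transmembrane structures cannot be bundled with the package, so every
downstream stage is exercised on ideal antiparallel helical bundles built
here from internal coordinates.  The generator returns the membrane slab it
used for construction, giving annotation and model-building tests an exact
ground truth.  Sequences follow the classic two-letter-world rule of membrane
biophysics: hydrophobic residue types inside the hydrophobic slab, polar ones
outside, which is precisely the signal the slab-fitting optimiser looks for.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._tables import AMINO_ACIDS, ONE_TO_THREE
from .geometry import nerf_place, unit
from .io_formats import Chain, Residue, SequenceRecord, Structure, write_fasta, write_pdb

__all__ = ["BundleSpec", "make_ideal_helix", "make_helical_bundle",
           "mutate_sequence", "write_fixture_set"]

# Ideal backbone internal coordinates
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_PHI_HELIX, _PSI_HELIX = -57.0, -47.0

# Residue alphabets for the z-dependent sequence pattern
_HYDROPHOBIC_CYCLE = "LIVF"
_POLAR_CYCLE = "SNDK"

TAIL_HALF_WIDTH = 15.0  # hydrophobic half-width used by all fixtures (A)
HEAD_WIDTH = 6.0


@dataclass(frozen=True)
class BundleSpec:
    n_helices: int = 4
    helix_length: int = 20
    loop_length: int = 5
    tilt_deg: float = 0.0
    radius: float = 9.0
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 1:
            raise ValueError("need at least one helix")
        if self.helix_length < 8:
            raise ValueError("helix_length must be >= 8")
        if self.loop_length < 2:
            raise ValueError("loop_length must be >= 2")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def n_residues(self) -> int:
        return self.n_helices * self.helix_length + (self.n_helices - 1) * self.loop_length


def make_ideal_helix(n_res: int, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
                     phi: float = _PHI_HELIX, psi: float = _PSI_HELIX) -> list[Residue]:
    """Poly-alanine alpha-helix built from ideal internal coordinates.

    The backbone is generated residue-by-residue with standard bond
    lengths/angles and the given (phi, psi); the finished helix is rotated so
    its axis lies along ``axis`` and centred at ``origin``.
    """
    if n_res < 4:
        raise ValueError("helix too short: need at least 4 residues")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(nerf_place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(nerf_place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(nerf_place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    O = [nerf_place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
         for i in range(n_res)]
    CB = [nerf_place(N[i], C[i], CA[i], _B_CA_CB, 110.6, 122.6)
          for i in range(n_res)]

    ca_arr = np.array(CA)
    # second differences of CA positions lie exactly in the plane
    # perpendicular to a regular helix's axis: take the null direction
    second = np.diff(ca_arr, n=2, axis=0)
    _, _, vt = np.linalg.svd(second - second.mean(axis=0) * 0.0)
    helix_axis = vt[-1]
    if np.dot(ca_arr[-1] - ca_arr[0], helix_axis) < 0:
        helix_axis = -helix_axis
    target = unit(np.asarray(axis, float))
    R = _rotation_between(helix_axis, target)
    centroid = ca_arr.mean(axis=0)
    origin = np.asarray(origin, float)

    residues = []
    for i in range(n_res):
        atoms = {}
        for name, pos in (("N", N[i]), ("CA", CA[i]), ("C", C[i]),
                          ("O", O[i]), ("CB", CB[i])):
            atoms[name] = R @ (pos - centroid) + origin
        residues.append(Residue("ALA", i + 1, "", atoms))
    return residues


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    a, b = unit(a), unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = unit(np.cross(a, perp))
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _bezier_loop_cas(a: np.ndarray, b: np.ndarray, apex_sign: float, n_points: int,
                     rng: np.random.Generator, spacing: float = 3.8) -> list[np.ndarray]:
    """CA positions of a loop of ``n_points`` residues joining anchors a and b.

    Points are arc-length-uniform along a quadratic Bezier whose control point
    is lifted along z until the path length matches (n_points + 1) * spacing.
    """
    chord = float(np.linalg.norm(b - a))
    target_len = (n_points + 1) * spacing
    if chord > (n_points + 1) * 4.15:
        raise ValueError("loop too short to span helices; increase loop_length")
    jitter = np.append(rng.uniform(-0.8, 0.8, size=2), 0.0)

    def curve_points(h: float, m: int = 400) -> np.ndarray:
        ctrl = (a + b) / 2.0 + np.array([0.0, 0.0, apex_sign * h]) + jitter
        t = np.linspace(0.0, 1.0, m)[:, None]
        return ((1 - t) ** 2) * a + 2 * (1 - t) * t * ctrl + (t ** 2) * b

    def path_len(h: float) -> float:
        pts = curve_points(h)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    lo, hi = 0.0, 5.0
    while path_len(hi) < target_len and hi < 200.0:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if path_len(mid) < target_len:
            lo = mid
        else:
            hi = mid
    pts = curve_points(0.5 * (lo + hi))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    out = []
    for i in range(1, n_points + 1):
        s = total * i / (n_points + 1)
        j = int(np.searchsorted(cum, s))
        j = min(max(j, 1), len(pts) - 1)
        frac = (s - cum[j - 1]) / max(cum[j] - cum[j - 1], 1e-12)
        out.append(pts[j - 1] + frac * (pts[j] - pts[j - 1]))
    return out


def _coil_residues(cas: list[np.ndarray], prev_ca: np.ndarray, next_ca: np.ndarray) -> list[Residue]:
    """Approximate backbone (N, CA, C, O, CB) around given loop CA positions."""
    residues = []
    ext = [prev_ca] + list(cas) + [next_ca]
    for i, ca in enumerate(cas, start=1):
        d_prev = unit(ca - ext[i - 1])
        d_next = unit(ext[i + 1] - ca)
        perp = np.cross(d_prev, d_next)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d_next, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-6:
                perp = np.array([1.0, 0.0, 0.0])
        perp = unit(perp)
        atoms = {
            "N": ca - 1.46 * d_prev,
            "CA": np.array(ca),
            "C": ca + 1.52 * d_next,
            "O": ca + 1.52 * d_next + 1.23 * perp,
            "CB": ca + 1.53 * unit(perp + 0.5 * (d_prev - d_next)),
        }
        residues.append(Residue("ALA", i, "", atoms))
    return residues


def make_helical_bundle(spec: BundleSpec):
    """Antiparallel helical bundle with membrane-patterned sequence.

    Returns ``(structure, true_slab)`` where ``true_slab`` is the
    construction membrane (normal +z, centre 0, tail half-width 15 A,
    head width 6 A).  Deterministic under ``spec.seed``.
    """
    from .membrane_annotate import MembraneSlab  # local import: avoid cycle

    rng = np.random.default_rng(spec.seed)
    helices: list[list[Residue]] = []
    for k in range(spec.n_helices):
        theta = 2.0 * np.pi * k / spec.n_helices
        center = np.array([spec.radius * np.cos(theta),
                           spec.radius * np.sin(theta), 0.0])
        base_axis = np.array([0.0, 0.0, 1.0 if k % 2 == 0 else -1.0])
        if spec.tilt_deg:
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])
            base_axis = _rotvec(radial, np.radians(spec.tilt_deg)) @ base_axis
        helices.append(make_ideal_helix(spec.helix_length, origin=center, axis=base_axis))

    # clash check between helices (CA-CA < 2 A)
    for i in range(spec.n_helices):
        for j in range(i + 1, spec.n_helices):
            ci = np.array([r.atoms["CA"] for r in helices[i]])
            cj = np.array([r.atoms["CA"] for r in helices[j]])
            d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=-1)
            if d.min() < 2.0:
                raise ValueError("bundle clash: enlarge radius")

    residues: list[Residue] = []
    for k, helix in enumerate(helices):
        residues.extend(r.copy() for r in helix)
        if k + 1 < spec.n_helices:
            a = helix[-1].atoms["CA"]
            b = helices[k + 1][0].atoms["CA"]
            apex_sign = 1.0 if a[2] > 0 else -1.0
            cas = _bezier_loop_cas(a, b, apex_sign, spec.loop_length, rng)
            residues.extend(_coil_residues(cas, a, b))

    seq_chars = []
    for i, res in enumerate(residues):
        res.number = i + 1
        z = abs(res.atoms["CA"][2])
        if z <= TAIL_HALF_WIDTH:
            letter = _HYDROPHOBIC_CYCLE[i % len(_HYDROPHOBIC_CYCLE)]
        else:
            letter = _POLAR_CYCLE[i % len(_POLAR_CYCLE)]
        res.name = ONE_TO_THREE[letter]
        seq_chars.append(letter)

    structure = Structure(f"bundle{spec.seed}", [Chain("A", residues)])
    slab = MembraneSlab(normal=np.array([0.0, 0.0, 1.0]), center_offset=0.0,
                        tail_half_width=TAIL_HALF_WIDTH, head_width=HEAD_WIDTH)
    return structure, slab


def _rotvec(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = unit(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def mutate_sequence(seq, sub_rate: float, indel_rate: float, seed: int,
                    record_id: str | None = None) -> SequenceRecord:
    """Point-mutate and indel a sequence; deterministic under ``seed``.

    Substitutions always change the letter; indels have length uniform on
    {1, 2, 3}, insertions drawing uniform letters.
    """
    if isinstance(seq, SequenceRecord):
        parent_id, seq = seq.id, seq.sequence
    else:
        parent_id = "seq"
    if not seq:
        raise ValueError("empty sequence")
    if not (0.0 <= sub_rate <= 1.0 and 0.0 <= indel_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = list(seq)
    for i, ch in enumerate(letters):
        if rng.random() < sub_rate:
            choices = [a for a in AMINO_ACIDS if a != ch]
            letters[i] = choices[int(rng.integers(len(choices)))]
    out: list[str] = []
    i = 0
    while i < len(letters):
        if rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.extend(AMINO_ACIDS[int(rng.integers(20))] for _ in range(length))
        out.append(letters[i])
        i += 1
    if not out:
        out = [letters[0]]
    return SequenceRecord(record_id or f"{parent_id}|m{seed}", "".join(out))


def write_fixture_set(outdir, seeds=(0, 1, 2), n_homologues: int = 12,
                      spec: BundleSpec | None = None) -> dict[str, Path]:
    """Write a self-contained fixture directory: bundle PDBs, their sequences
    and a mutated homologue family for each seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for seed in seeds:
        s = spec or BundleSpec()
        s = BundleSpec(s.n_helices, s.helix_length, s.loop_length, s.tilt_deg,
                       s.radius, seed)
        structure, _ = make_helical_bundle(s)
        pdb = outdir / f"bundle{seed}.pdb"
        write_pdb(structure, pdb)
        seq = SequenceRecord(structure.id, structure.sequence())
        fasta = outdir / f"bundle{seed}.fasta"
        write_fasta([seq], fasta)
        homs = [mutate_sequence(seq, 0.15, 0.01, seed * 1000 + i)
                for i in range(n_homologues)]
        hfasta = outdir / f"bundle{seed}_homologues.fasta"
        write_fasta(homs, hfasta)
        paths[f"bundle{seed}"] = pdb
        paths[f"bundle{seed}_fasta"] = fasta
        paths[f"bundle{seed}_homologues"] = hfasta
    return paths
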