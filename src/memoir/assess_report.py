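"""Model and alignment quality metrics, traffic-light guidance, summaries.

Metrics: backbone RMSD over a residue selection (with optional Kabsch
superposition), GDT_TS from a seeded superposition search, coverage, and a
traffic-light quality guide whose identity red/amber boundary is anchored
to the 15% homology floor used in homologue selection.

The package also ships a published 15-target benchmark of transmembrane
domain models (percent identity, coverage, and backbone RMSD for three
modelling services); :func:`benchmark_summary` reproduces its column means.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np

from .geometry import kabsch
from .io_formats import Structure
from .medeller_build import CoreModel

__all__ = [
    "QualityReport", "backbone_rmsd", "gdt_ts", "coverage",
    "quality_guide", "summarize_columns", "load_tm_benchmark",
    "benchmark_summary",
]

BACKBONE = ("N", "CA", "C", "O")
GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)

IDENTITY_GREEN = 30.0
IDENTITY_AMBER = 15.0   # the homology floor: below this, models are unreliable
COVERAGE_GREEN = 80.0
COVERAGE_AMBER = 60.0


@dataclass(frozen=True)
class QualityReport:
    sequence_identity: float      # percent
    coverage: float               # percent
    identity_level: str           # green | amber | red
    coverage_level: str
    notes: tuple = ()


def _common_keys(a: Structure, b: Structure, chain_a=None, chain_b=None):
    ra = {r.key: r for r in a.chain(chain_a).residues}
    rb = {r.key: r for r in b.chain(chain_b).residues}
    return [k for k in ra if k in rb], ra, rb


def _collect(a: Structure, b: Structure, selection, atoms, chain_a=None, chain_b=None):
    keys, ra, rb = _common_keys(a, b, chain_a, chain_b)
    if selection is not None:
        wanted = [(k, "") if isinstance(k, int) else tuple(k) for k in selection]
        keys = [k for k in wanted if k in ra and k in rb]
    pa, pb = [], []
    for k in keys:
        res_a, res_b = ra[k], rb[k]
        if any(at not in res_a.atoms or at not in res_b.atoms for at in atoms):
            continue
        pa.extend(res_a.atoms[at] for at in atoms)
        pb.extend(res_b.atoms[at] for at in atoms)
    if not pa:
        raise ValueError("no common residues")
    return np.array(pa), np.array(pb)


def backbone_rmsd(model_a: Structure, model_b: Structure, selection=None,
                  superpose: bool = True, atoms=BACKBONE,
                  chain_a: str | None = None, chain_b: str | None = None) -> float:
    """Backbone RMSD (A) over the residues common to both models.

    ``selection`` optionally restricts to given author numbers (ints or
    (number, icode) pairs).  With ``superpose`` an optimal least-squares fit
    is applied first.
    """
    pa, pb = _collect(model_a, model_b, selection, atoms, chain_a, chain_b)
    if superpose:
        _, _, rmsd = kabsch(pa, pb)
        return rmsd
    return float(np.sqrt(((pa - pb) ** 2).sum() / len(pa)))


def gdt_ts(model: Structure, reference: Structure, selection=None,
           chain_a: str | None = None, chain_b: str | None = None,
           per_cutoff: bool = False):
    """Global distance test total score (percent).

    For each cutoff in 1/2/4/8 A, the maximal fraction of common CA atoms
    within the cutoff is sought by seeding a superposition from every
    3-residue window and iteratively refitting on the residues currently
    within the cutoff; the score is the mean fraction over cutoffs x 100.
    """
    pa, pb = _collect(model, reference, selection, ("CA",), chain_a, chain_b)
    n = len(pa)
    best = {c: 0.0 for c in GDT_CUTOFFS}

    def evaluate(R, t):
        moved = pa @ R.T + t
        d = np.linalg.norm(moved - pb, axis=1)
        for cutoff in GDT_CUTOFFS:
            frac = float((d <= cutoff).mean())
            if frac > best[cutoff]:
                best[cutoff] = frac

    def refine(seed_idx):
        R, t, _ = kabsch(pa[seed_idx], pb[seed_idx])
        evaluate(R, t)
        for cutoff in GDT_CUTOFFS:
            Rc, tc = R, t
            for _ in range(3):
                moved = pa @ Rc.T + tc
                d = np.linalg.norm(moved - pb, axis=1)
                within = np.where(d <= cutoff)[0]
                if len(within) < 3:
                    break
                Rc, tc, _ = kabsch(pa[within], pb[within])
                evaluate(Rc, tc)

    refine(np.arange(n))
    for start in range(0, max(n - 2, 1)):
        idx = np.arange(start, min(start + 3, n))
        if len(idx) < 3:
            break
        refine(idx)
    if per_cutoff:
        return {c: 100.0 * f for c, f in best.items()}
    return 100.0 * sum(best.values()) / len(GDT_CUTOFFS)


def coverage(model, target) -> float:
    """Percent of target residues present in the model."""
    if isinstance(target, str):
        target_len = len(target)
    else:
        target_len = int(target)
    if isinstance(model, CoreModel):
        n_modelled = len(model.modelled_indices)
    elif isinstance(model, Structure):
        n_modelled = len(model.chain().residues)
    else:
        n_modelled = int(model)
    return 100.0 * n_modelled / target_len


def _level(value: float, green: float, amber: float) -> str:
    if value >= green:
        return "green"
    if value >= amber:
        return "amber"
    return "red"


def quality_guide(sequence_identity: float, cov: float, *,
                  identity_green: float = IDENTITY_GREEN,
                  identity_amber: float = IDENTITY_AMBER,
                  coverage_green: float = COVERAGE_GREEN,
                  coverage_amber: float = COVERAGE_AMBER) -> QualityReport:
    """Traffic-light report: green for values likely to give a good model.

    Identity bands (percent): green >= 30, amber 15-30, red < 15 — the red
    boundary is the same identity floor below which candidate homologues are
    rejected.  Coverage: green >= 80, amber 60-80, red < 60.  Boundaries are
    inclusive upward.
    """
    return QualityReport(
        sequence_identity=sequence_identity,
        coverage=cov,
        identity_level=_level(sequence_identity, identity_green, identity_amber),
        coverage_level=_level(cov, coverage_green, coverage_amber),
    )


def summarize_columns(rows, percent_columns=()) -> list[float | int]:
    """Arithmetic mean per column, rounded half-up to 2 decimals.

    Columns listed in ``percent_columns`` (by index) are rounded half-up to
    integers, matching the presentation convention of percent columns.
    """
    rows = [list(r) for r in rows]
    if not rows:
        raise ValueError("nothing to summarize")
    arity = {len(r) for r in rows}
    if len(arity) > 1:
        raise ValueError("rows must have equal arity")
    out: list[float | int] = []
    for c in range(len(rows[0])):
        mean = sum(Decimal(str(r[c])) for r in rows) / Decimal(len(rows))
        if c in percent_columns:
            out.append(int(mean.quantize(Decimal("1"), rounding=ROUND_HALF_UP)))
        else:
            out.append(float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)))
    return out


def load_tm_benchmark() -> list[dict]:
    """The bundled 15-target transmembrane-domain model benchmark."""
    path = resources.files("memoir.data") / "tm_benchmark_15.tsv"
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for row in reader:
            rows.append({
                "target": row["target"], "template": row["template"],
                "pct_id": float(row["pct_id"]), "pct_cov": float(row["pct_cov"]),
                "rmsd_memoir": float(row["rmsd_memoir"]),
                "rmsd_hhpred": float(row["rmsd_hhpred"]),
                "rmsd_swissmodel": float(row["rmsd_swissmodel"]),
            })
    return rows


def benchmark_summary() -> dict[str, float | int]:
    """Column means of the bundled benchmark (coverage as integer percent)."""
    rows = load_tm_benchmark()
    numeric = [[r["pct_cov"], r["rmsd_memoir"], r["rmsd_hhpred"],
                r["rmsd_swissmodel"]] for r in rows]
    cov_mean, memoir, hhpred, swiss = summarize_columns(numeric, percent_columns=(0,))
    return {
        "n_targets": len(rows),
        "coverage_mean_pct": cov_mean,
        "rmsd_mean_memoir": memoir,
        "rmsd_mean_hhpred": hhpred,
        "rmsd_mean_swissmodel": swiss,
    }
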