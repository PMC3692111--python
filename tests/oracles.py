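"""Independent reference implementations used only to check the package."""
import numpy as np
from Bio.Align import substitution_matrices

_B = substitution_matrices.load("BLOSUM62")


def brute_force_global_score(a: str, b: str, gap_open: float = 11.0,
                             gap_extend: float = 1.0) -> float:
    """Best global affine-gap score by exhaustive enumeration of alignments.

    The first residue of a gap run costs ``gap_open``; each further residue
    ``gap_extend``.  Only feasible for short sequences.
    """
    best = -np.inf

    def rec(i, j, score, state):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _B[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_open if state != "X" else gap_extend
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = gap_open if state != "Y" else gap_extend
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "start")
    return float(best)


def all_gapped_rows(seq: str, width: int):
    """Every placement of ``width - len(seq)`` gaps into a row of ``width``."""
    from itertools import combinations
    for gaps in combinations(range(width), width - len(seq)):
        g = set(gaps)
        it = iter(seq)
        yield "".join("-" if k in g else next(it) for k in range(width))


def two_point_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Closed-form optimal-superposition RMSD between two 2-point sets."""
    d1 = np.linalg.norm(p[1] - p[0])
    d2 = np.linalg.norm(q[1] - q[0])
    return abs(d1 - d2) / 2.0
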