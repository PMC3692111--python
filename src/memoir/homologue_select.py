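"""Homologue filtering, redundancy reduction, balancing and capping.

Candidate homologues of the target and of the template (gathered by any
external search) are reduced to the set that actually guides the
target-template alignment:

1. reject candidates with < 15% identity to their query, or whose length is
   > 3/2 or < 2/3 of the query's (strict inequalities: boundary values kept);
2. make each side non-redundant at 80% identity (greedy, ordered by identity
   to the query, ties by id);
3. combine the two sides in equal numbers (seeded random sample of the
   larger side), re-deduplicate;
4. cap at 125 sequences by seeded random selection.

Percent identity is computed from a global affine-gap alignment (BLOSUM62,
gap open 11 / extend 1) as identical aligned pairs divided by the length of
the shorter sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

__all__ = [
    "SelectionConfig", "HomologueSet", "AuditEntry",
    "percent_identity", "global_alignment", "filter_candidates",
    "reduce_redundancy", "combine_balanced", "cap_random",
    "select_homologues", "write_audit_tsv",
]


@dataclass(frozen=True)
class SelectionConfig:
    min_identity: float = 0.15
    len_ratio_hi: float = 3.0 / 2.0
    len_ratio_lo: float = 2.0 / 3.0
    redundancy_identity: float = 0.80
    cap: int = 125
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.min_identity < self.redundancy_identity < 1.0):
            raise ValueError("need 0 < min_identity < redundancy_identity < 1")
        if not (self.len_ratio_lo < 1.0 < self.len_ratio_hi):
            raise ValueError("length ratio bounds must straddle 1")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")


@dataclass(frozen=True)
class AuditEntry:
    id: str
    decision: str        # kept | rejected
    reason: str          # "" | identity | length | redundant | unsampled
    identity: float
    length_ratio: float


@dataclass
class HomologueSet:
    query_id: str
    members: list[SequenceRecord]
    provenance: dict[str, str] = field(default_factory=dict)  # id -> side tag
    audit: list[AuditEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ids in homologue set")


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_alignment(a: str, b: str):
    """First optimal global affine-gap alignment (BLOSUM62, 11/1)."""
    return _aligner().align(a, b)[0]


def percent_identity(a, b) -> float:
    """Identity fraction over a global alignment, denominator = shorter length."""
    sa = a.sequence if isinstance(a, SequenceRecord) else a
    sb = b.sequence if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aln = global_alignment(sa, sb)
    identities = aln.counts().identities
    return identities / min(len(sa), len(sb))


def filter_candidates(query: SequenceRecord, candidates, config: SelectionConfig
                      ) -> tuple[list[SequenceRecord], list[AuditEntry]]:
    """Identity and length-ratio filters; strict rejection, boundaries kept."""
    survivors: list[SequenceRecord] = []
    audit: list[AuditEntry] = []
    for cand in candidates:
        ratio = len(cand) / len(query)
        pid = percent_identity(query, cand)
        if ratio > config.len_ratio_hi or ratio < config.len_ratio_lo:
            audit.append(AuditEntry(cand.id, "rejected", "length", pid, ratio))
        elif pid < config.min_identity:
            audit.append(AuditEntry(cand.id, "rejected", "identity", pid, ratio))
        else:
            survivors.append(cand)
            audit.append(AuditEntry(cand.id, "kept", "", pid, ratio))
    return survivors, audit


def reduce_redundancy(seqs, threshold: float, reference: SequenceRecord
                      ) -> list[SequenceRecord]:
    """Greedy Hobohm-style representative selection.

    Sequences are visited in order of decreasing identity to the reference
    query (ties by id); a sequence is accepted iff its identity to every
    already-accepted one is below ``threshold``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    ranked = sorted(seqs, key=lambda s: (-percent_identity(reference, s), s.id))
    accepted: list[SequenceRecord] = []
    for seq in ranked:
        if all(percent_identity(seq, acc) < threshold for acc in accepted):
            accepted.append(seq)
    return accepted


def combine_balanced(target_side, template_side, config: SelectionConfig,
                     reference: SequenceRecord) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Equal-number combination of the two sides, then re-deduplication."""
    import warnings

    target_side = list(target_side)
    template_side = list(template_side)
    if not target_side or not template_side:
        warnings.warn("unbalanced: one side empty")
        combined = target_side + template_side
    else:
        n = min(len(target_side), len(template_side))
        rng = np.random.default_rng(config.seed)

        def sample(side):
            if len(side) == n:
                return side
            idx = sorted(rng.choice(len(side), size=n, replace=False))
            return [side[i] for i in idx]

        combined = sample(target_side) + sample(template_side)
    provenance = {}
    for s in combined:
        side = "target-side" if s in target_side else "template-side"
        provenance[s.id] = side
    combined = reduce_redundancy(combined, config.redundancy_identity, reference)
    return combined, {s.id: provenance[s.id] for s in combined}


def cap_random(seqs, config: SelectionConfig) -> list[SequenceRecord]:
    """Seeded uniform sample of at most ``config.cap`` sequences."""
    seqs = list(seqs)
    if len(seqs) <= config.cap:
        return seqs
    rng = np.random.default_rng(config.seed)
    idx = sorted(rng.choice(len(seqs), size=config.cap, replace=False))
    return [seqs[i] for i in idx]


def select_homologues(target: SequenceRecord, target_candidates,
                      template: SequenceRecord, template_candidates,
                      config: SelectionConfig | None = None) -> HomologueSet:
    """The full selection chain for both sides; audit log attached."""
    config = config or SelectionConfig()
    t_surv, t_audit = filter_candidates(target, target_candidates, config)
    x_surv, x_audit = filter_candidates(template, template_candidates, config)
    t_nr = reduce_redundancy(t_surv, config.redundancy_identity, target)
    x_nr = reduce_redundancy(x_surv, config.redundancy_identity, template)
    combined, provenance = combine_balanced(t_nr, x_nr, config, target)
    capped = cap_random(combined, config)
    audit = t_audit + x_audit
    kept_ids = {s.id for s in capped}
    return HomologueSet(
        query_id=target.id,
        members=capped,
        provenance={i: provenance.get(i, "target-side") for i in kept_ids},
        audit=audit,
    )


def write_audit_tsv(audit, path) -> None:
    lines = ["id\tdecision\treason\tidentity\tlength_ratio"]
    for e in audit:
        lines.append(f"{e.id}\t{e.decision}\t{e.reason}\t{e.identity:.4f}\t{e.length_ratio:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
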