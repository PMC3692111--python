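"""End-to-end orchestration: annotate, select, align, build, fill, assess.

The pipeline takes a target sequence and a template structure (plus
optionally pre-gathered homologue sets and fragment databases) and produces
the output bundle: the core model, the high-accuracy and high-coverage
models, the target-template alignment with its environment annotation
track, the full multiple sequence alignment, per-loop alternatives, a
quality report and the resolved configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import assess_report, fread_loops, homologue_select, medeller_build, mpt_align
from .io_formats import (SequenceRecord, Structure, write_alignment, write_pdb)
from .membrane_annotate import AnnotatedTemplate, annotate_template, write_annotation_tsv

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "StageError"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    chain_id: str | None = None
    seed: int = 0
    buried_threshold: float = 0.07
    head_width: float = 6.0
    angle_step_deg: float = 5.0
    quality_window: int = 11
    quality_threshold: float = 0.3
    min_identity: float = 0.15
    redundancy_identity: float = 0.80
    cap: int = 125
    hiacc_anchor_rmsd_max: float = 1.0
    hiacc_propensity_min: float = 25.0
    hicov_anchor_rmsd_max: float = 2.0
    hicov_propensity_min: float = 0.0
    alternatives_k: int = 10

    def selection_config(self) -> homologue_select.SelectionConfig:
        return homologue_select.SelectionConfig(
            min_identity=self.min_identity,
            redundancy_identity=self.redundancy_identity,
            cap=self.cap, seed=self.seed)

    def fill_config(self, mode: str) -> fread_loops.FillConfig:
        if mode == "hiacc":
            return fread_loops.FillConfig(
                "hiacc", self.hiacc_anchor_rmsd_max, self.hiacc_propensity_min,
                use_soluble=False, allow_terminal=False,
                alternatives_k=self.alternatives_k)
        return fread_loops.FillConfig(
            "hicov", self.hicov_anchor_rmsd_max, self.hicov_propensity_min,
            use_soluble=True, allow_terminal=True,
            alternatives_k=self.alternatives_k)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: PipelineConfig
    annotated: AnnotatedTemplate
    homologues: homologue_select.HomologueSet | None
    msa: mpt_align.MultipleAlignment
    pair: mpt_align.PairwiseAlignment
    core: medeller_build.CoreModel
    hiacc: medeller_build.CoreModel
    hiacc_fills: list
    hicov: medeller_build.CoreModel
    hicov_fills: list
    report: dict


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(target: SequenceRecord, template: Structure, *,
                 target_homologues=None, template_homologues=None,
                 membrane_db: fread_loops.FragmentDB | None = None,
                 soluble_db: fread_loops.FragmentDB | None = None,
                 config: PipelineConfig | None = None,
                 outdir=None) -> PipelineResult:
    """Run the full pipeline; optionally write the output bundle to outdir."""
    config = config or PipelineConfig()

    annotated = _stage("annotate")(annotate_template)(
        template, config.chain_id,
        buried_threshold=config.buried_threshold,
        head_width=config.head_width,
        angle_step_deg=config.angle_step_deg)

    template_seq = SequenceRecord(template.id, template.sequence(config.chain_id))
    homset = None
    selected: list[SequenceRecord] = []
    if target_homologues or template_homologues:
        homset = _stage("select")(homologue_select.select_homologues)(
            target, target_homologues or [], template_seq,
            template_homologues or [], config.selection_config())
        selected = homset.members
    else:
        log.warning("no homologue sets supplied; aligning target and template alone")

    pair, msa, clade = _stage("align")(mpt_align.align_target_template)(
        target, annotated, selected, template_id=template.id)

    quality = _stage("core")(medeller_build.local_quality)(
        pair, config.quality_window, config.quality_threshold)
    schedule = _stage("core")(medeller_build.build_schedule)(annotated, pair)
    core = _stage("core")(medeller_build.generate_core)(
        pair, template, schedule, quality,
        annotated_template=annotated, chain_id=config.chain_id,
        target_id=target.id)

    if membrane_db is None:
        membrane_db = fread_loops.FragmentDB("membrane")
    hiacc, hiacc_fills = _stage("loops")(fread_loops.complete_model)(
        core, membrane_db, None, config=config.fill_config("hiacc"))
    hicov, hicov_fills = _stage("loops")(fread_loops.complete_model)(
        core, membrane_db, soluble_db, config=config.fill_config("hicov"))

    identity_pct = 100.0 * pair.percent_identity()
    guide = assess_report.quality_guide(identity_pct, hiacc.coverage)
    report = {
        "target_id": target.id,
        "template_id": template.id,
        "sequence_identity_pct": round(identity_pct, 2),
        "identity_level": guide.identity_level,
        "core_coverage_pct": round(core.coverage, 2),
        "hiacc_coverage_pct": round(hiacc.coverage, 2),
        "hicov_coverage_pct": round(hicov.coverage, 2),
        "coverage_level": assess_report.quality_guide(
            identity_pct, hicov.coverage).coverage_level,
        "n_homologues_selected": len(selected),
        "clade_size": len(clade),
        "gaps": [
            {"start": g.start, "end": g.end,
             "hiacc": _fill_status(hiacc_fills, g),
             "hicov": _fill_status(hicov_fills, g)}
            for g in core.gaps
        ],
    }

    result = PipelineResult(config, annotated, homset, msa, pair, core,
                            hiacc, hiacc_fills, hicov, hicov_fills, report)
    if outdir is not None:
        _write_bundle(result, target, Path(outdir))
    return result


def _fill_status(fills, gap) -> str:
    for f in fills:
        if f.gap.start == gap.start and f.gap.end == gap.end:
            return f.status
    return "missing"


def _write_bundle(result: PipelineResult, target: SequenceRecord, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_pdb(result.core.to_structure(), outdir / "core.pdb")
    write_pdb(result.hiacc.to_structure(), outdir / "hiacc.pdb")
    write_pdb(result.hicov.to_structure(), outdir / "hicov.pdb")
    # target-template alignment with the template's environment track
    track = []
    code = {"tail": "T", "head": "P", "non-membrane": "."}
    for env in (result.pair.env_b or []):
        track.append("-" if env is None else code.get(env.layer, "?"))
    rows = {target.id: result.pair.row_a,
            result.report["template_id"]: result.pair.row_b}
    tracks = {result.report["template_id"]: "".join(track)} if track else None
    write_alignment(rows, outdir / "alignment.afa", tracks)
    write_alignment(result.msa.rows, outdir / "msa.afa")
    write_annotation_tsv(result.annotated, outdir / "template_annotation.tsv")
    medeller_build.write_gap_manifest(result.core, outdir / "gaps.json")
    if result.homologues is not None:
        homologue_select.write_audit_tsv(result.homologues.audit,
                                         outdir / "homologue_audit.tsv")
    loops_dir = outdir / "loops"
    loops_dir.mkdir(exist_ok=True)
    for fills, mode in ((result.hiacc_fills, "hiacc"), (result.hicov_fills, "hicov")):
        for f in fills:
            if f.status != "filled":
                continue
            _write_alternatives(f, loops_dir /
                                f"{mode}_gap{f.gap.start + 1}-{f.gap.end + 1}.pdb")
    (outdir / "report.json").write_text(json.dumps(result.report, indent=1) + "\n")
    result.config.to_json(outdir / "config.json")


def _write_alternatives(fill, path) -> None:
    """Multi-model PDB of the candidate loop backbones (transformed)."""
    from .geometry import apply_transform
    lines = []
    for m, cand in enumerate(fill.alternatives, start=1):
        lines.append(f"MODEL     {m:4d}")
        coords = apply_transform(cand.fragment.loop_coords.reshape(-1, 3),
                                 cand.rotation, cand.translation).reshape(-1, 4, 3)
        serial = 0
        for r_off in range(cand.fragment.length):
            resnum = fill.gap.start + 1 + r_off
            for k, name in enumerate(("N", "CA", "C", "O")):
                serial += 1
                x, y, z = coords[r_off, k]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3} GLY A{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {name[0]:>2}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
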