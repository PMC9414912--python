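"""End-to-end orchestration and report rendering.

Runs the full analysis from a single configuration: read proteins and array
layout, quantify each serum group's scan, Z-score normalise, call reactive
peptides, compute group-vs-control Z-ratios, flag nonspecific (control-
reactive) peptides, merge epitope regions, and write the report bundle — a
machine-readable reactivity table (one row per peptide carrying at least one
mark, sequences decorated as ``^start^SEQUENCE^end^``), a region report, the
Z-score heatmap matrix, and optional annotation-overlap tables.

All outputs are UTF-8, tab-separated, LF-terminated and deterministic:
re-running on identical inputs produces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import PipelineError, ValidationError
from .library import DEFAULT_K, DEFAULT_LINKER, PeptideLibrary, read_fasta, read_gal, build_library
from .regions import (
    AlignmentProjection,
    AnnotationTrack,
    EpitopeRegion,
    annotate_overlap,
    calls_by_protein,
    export_heatmap_matrix,
    merge_regions,
    read_aligned_fasta,
    read_annotations,
)
from .signal import average_duplicates, read_gpr
from .stats import (
    DEFAULT_Z_THRESHOLD,
    DEFAULT_ZRATIO_THRESHOLD,
    GroupComparison,
    ReactivityCall,
    ZProfile,
    call_reactive,
    call_significant,
    flag_control_reactive,
    zratio,
    zscore,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str
    gpr: dict[str, str]              # group label -> GPR path
    outdir: str
    gal: str | None = None           # optional cross-check of spot IDs
    alignment: str | None = None
    annotations: str | None = None
    control_label: str = "control"
    linker: str = DEFAULT_LINKER
    k: int = DEFAULT_K
    z_threshold: float = DEFAULT_Z_THRESHOLD
    zratio_threshold: float = DEFAULT_ZRATIO_THRESHOLD
    sided: str = "greater"
    max_gap: int = 0
    exclude_control_reactive: bool = True
    # candidate protective regions: require group-vs-control significance in
    # addition to reactivity (the analysis focuses on Z-ratio > threshold),
    # and support by at least this many overlapping peptides.  With step-1
    # tiling a genuine linear epitope is always covered by several adjacent
    # peptides, so isolated single-peptide hits are treated as noise here
    # (they remain visible in the reactivity table).
    require_significant: bool = True
    min_region_peptides: int = 2
    heatmap_png: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        n_control = sum(1 for g in self.gpr if g == self.control_label)
        if n_control != 1:
            raise ValidationError(
                f"control label {self.control_label!r} must name exactly one "
                f"provided group, found {n_control}"
            )
        for thr in (self.z_threshold, self.zratio_threshold):
            if thr <= 0:
                raise ValidationError("thresholds must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"{path}: bad config: {exc}") from exc


@dataclass
class PipelineResult:
    library: PeptideLibrary
    profiles: dict[str, ZProfile]
    calls: dict[str, list[ReactivityCall]]
    comparisons: dict[str, GroupComparison]
    regions: list[EpitopeRegion]
    table: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("tile")
        proteins = read_fasta(config.fasta)
        library = build_library(proteins, linker=config.linker, k=config.k)
        if config.gal is not None:
            gal_ids = read_gal(config.gal)
            if gal_ids != library.spot_ids:
                raise ValidationError(
                    "GAL layout does not match the library built from the FASTA"
                )
        stage("quantify")
        profiles: dict[str, ZProfile] = {}
        for group, path in config.gpr.items():
            scan = read_gpr(path, library, sample_id=group, group_label=group)
            logger.info("%s: %d spots read, %d flagged dropped",
                        group, len(scan.spots), scan.n_flagged_dropped)
            iv = average_duplicates(scan, library)
            profiles[group] = zscore(iv)
        stage("call")
        calls = {
            g: call_reactive(p, z_threshold=config.z_threshold, group_label=g)
            for g, p in profiles.items()
        }
        control_calls = calls[config.control_label]
        comparisons: dict[str, GroupComparison] = {}
        for g in profiles:
            if g == config.control_label:
                continue
            comp = zratio(profiles[g], profiles[config.control_label])
            call_significant(
                comp, zr_threshold=config.zratio_threshold, sided=config.sided
            )
            comparisons[g] = comp
            flag_control_reactive(calls[g], control_calls)
        for g in profiles:
            n_reactive = sum(c.is_reactive for c in calls[g])
            n_sig = len(comparisons[g].significant) if g in comparisons else 0
            logger.info("%s: %d reactive peptides, %d significant vs control",
                        g, n_reactive, n_sig)
        stage("regions")
        regions: list[EpitopeRegion] = []
        for g in profiles:
            if g == config.control_label:
                continue
            group_calls = calls[g]
            if config.require_significant:
                sig = comparisons[g].significant
                group_calls = [
                    replace(c, is_reactive=c.is_reactive and c.peptide_id in sig)
                    for c in group_calls
                ]
            by_prot = calls_by_protein(group_calls, library)
            for pid in sorted(by_prot):
                regions.extend(
                    r
                    for r in merge_regions(
                        by_prot[pid],
                        library.proteins[pid],
                        group_label=g,
                        max_gap=config.max_gap,
                        exclude_control_reactive=config.exclude_control_reactive,
                        k=config.k,
                        linker_len=len(config.linker),
                    )
                    if r.n_peptides >= config.min_region_peptides
                )
        logger.info("%d epitope regions called", len(regions))
        stage("report")
        group_order = list(config.gpr)
        table = render_reactivity_table(
            calls, comparisons, library,
            control_label=config.control_label, group_order=group_order,
        )
        outputs: dict[str, Path] = {}
        table_path = outdir / "reactivity_table.tsv"
        table.to_csv(table_path, sep="\t", index=False, lineterminator="\n")
        outputs["reactivity_table"] = table_path
        region_path = outdir / "regions.tsv"
        write_region_report(regions, region_path)
        outputs["regions"] = region_path
        heatmap_path = outdir / "heatmap.tsv"
        png_path = outdir / "heatmap.png" if config.heatmap_png else None
        export_heatmap_matrix(
            [profiles[g] for g in group_order], library,
            tsv_path=heatmap_path, png_path=png_path,
            z_threshold=config.z_threshold,
        )
        outputs["heatmap"] = heatmap_path
        if config.annotations is not None:
            alignment = (
                read_aligned_fasta(config.alignment)
                if config.alignment is not None else None
            )
            tracks = read_annotations(config.annotations)
            overlap_path = outdir / "annotation_overlap.tsv"
            write_overlap_report(regions, tracks, alignment, overlap_path)
            outputs["annotation_overlap"] = overlap_path
        return PipelineResult(
            library=library, profiles=profiles, calls=calls,
            comparisons=comparisons, regions=regions, table=table,
            outputs=outputs,
        )
    except (ValidationError, PipelineError):
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline failed: {exc}") from exc


REGION_COLUMNS = (
    "protein_id", "group", "index_first", "index_last", "start", "end",
    "n_peptides", "peak_z", "mean_z", "control_contaminated",
)


def write_region_report(regions: Sequence[EpitopeRegion], path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "group": r.group_label,
            "index_first": r.index_range[0],
            "index_last": r.index_range[1],
            "start": r.span[0],
            "end": r.span[1],
            "n_peptides": r.n_peptides,
            "peak_z": round(r.peak_z, 6),
            "mean_z": round(r.mean_z, 6),
            "control_contaminated": r.control_contaminated,
        }
        for r in sorted(
            regions, key=lambda r: (r.protein_id, r.group_label, r.index_range)
        )
    ]
    pd.DataFrame(rows, columns=list(REGION_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_overlap_report(
    regions: Sequence[EpitopeRegion],
    tracks: Sequence[AnnotationTrack],
    alignment: AlignmentProjection | None,
    path,
) -> None:
    rows = []
    for r in sorted(regions, key=lambda r: (r.protein_id, r.group_label, r.index_range)):
        for track in tracks:
            for rep in annotate_overlap(r, track, alignment):
                rows.append(
                    {
                        "protein_id": r.protein_id,
                        "group": r.group_label,
                        "region_start": r.span[0],
                        "region_end": r.span[1],
                        **{k: (round(v, 6) if isinstance(v, float) else v)
                           for k, v in rep.items()},
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def render_reactivity_table(
    calls: Mapping[str, list[ReactivityCall]],
    comparisons: Mapping[str, GroupComparison],
    library: PeptideLibrary,
    control_label: str = "control",
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per peptide carrying at least one mark in any group.

    Marks: ``x`` when the group Z-score exceeds the reactive threshold,
    ``†`` when the group-vs-control Z-ratio is significant.  The decorated
    sequence column shows the linker-clipped protein residues with their
    1-based positions, ``^start^SEQUENCE^end^``.
    """
    groups = list(group_order) if group_order is not None else list(calls)
    call_maps = {g: {c.peptide_id: c for c in calls[g]} for g in groups}
    rows = []
    for pep in library.peptides:
        spot_id = library.spot_id_of(pep.sequence)
        marks = {}
        any_mark = False
        for g in groups:
            call = call_maps[g].get(spot_id)
            mark = ""
            if call is not None and call.is_reactive:
                mark = "x"
            if g in comparisons and spot_id in comparisons[g].significant:
                mark = (mark + " †").strip()
            marks[g] = mark
            any_mark = any_mark or bool(mark)
        if not any_mark:
            continue
        prot = library.proteins[pep.protein_id]
        start, end = pep.span
        clipped = prot.sequence[start - 1 : end]
        rows.append(
            {
                "peptide_no": pep.index,
                "protein_id": pep.protein_id,
                "species": prot.species_tag,
                "sequence": f"^{start}^{clipped}^{end}^",
                **marks,
            }
        )
    columns = ["peptide_no", "protein_id", "species", "sequence", *groups]
    return pd.DataFrame(rows, columns=columns)
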