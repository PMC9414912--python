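"""Epitope regions: merging reactive runs, alignment projection, annotation.

A called epitope region is a maximal run of consecutive reactive peptide
indices on one protein for one serum group; its protein span runs from the
start of the first peptide's footprint to the end of the last (the full
15-mer footprint, matching how printed reactivity tables report spans).
Peptides flagged as control-reactive break runs by default — nonspecific
binding is excluded from candidate protective regions — but can optionally be
kept, in which case the region is marked as control-contaminated.

Regions are compared with externally annotated intervals (protective chimera
peptides, protein-protein interaction domains) directly when the annotation
lives on the same protein, or after projection through a user-supplied
multiple sequence alignment when it lives on a homolog.  All coordinates are
1-based inclusive; annotation tables here deliberately are NOT BED (0-based
half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import ValidationError
from .library import PeptideLibrary, ProteinRecord, index_to_protein_span
from .stats import DEFAULT_Z_THRESHOLD, ReactivityCall, ZProfile

logger = logging.getLogger(__name__)


@dataclass
class EpitopeRegion:
    """A maximal run of reactive overlapping peptides, in protein coordinates."""

    protein_id: str
    group_label: str
    index_range: tuple[int, int]
    span: tuple[int, int]
    peak_z: float
    mean_z: float
    n_peptides: int
    control_contaminated: bool = False


@dataclass(frozen=True)
class AnnotationEntry:
    reference_id: str
    start: int
    end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"annotation on {self.reference_id!r}: start {self.start} > end {self.end}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotationTrack:
    """A named set of annotated intervals (e.g. protective chimera peptides)."""

    name: str
    entries: list[AnnotationEntry]


class AlignmentProjection:
    """Residue ↔ alignment-column maps over a gapped multiple alignment.

    All aligned strings must have equal length; the ungapped content of each
    row is the corresponding protein sequence.
    """

    GAP_CHARS = "-."

    def __init__(self, aligned: dict[str, str]):
        lengths = {len(s) for s in aligned.values()}
        if len(lengths) > 1:
            raise ValidationError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        if not aligned:
            raise ValidationError("empty alignment")
        self.aligned = dict(aligned)
        self.n_columns = lengths.pop()
        # residue position (1-based) -> column (1-based), per sequence
        self._res2col: dict[str, list[int]] = {}
        self._col2res: dict[str, np.ndarray] = {}
        for sid, row in self.aligned.items():
            res2col = []
            col2res = np.zeros(self.n_columns + 1, dtype=int)  # 0 = gap
            r = 0
            for c, ch in enumerate(row, start=1):
                if ch not in self.GAP_CHARS:
                    r += 1
                    res2col.append(c)
                    col2res[c] = r
            self._res2col[sid] = res2col
            self._col2res[sid] = col2res

    def ids(self) -> list[str]:
        return list(self.aligned)

    def ungapped(self, seq_id: str) -> str:
        row = self.aligned[seq_id]
        return "".join(ch for ch in row if ch not in self.GAP_CHARS)

    def residue_to_column(self, seq_id: str, pos: int) -> int:
        cols = self._res2col[seq_id]
        if not 1 <= pos <= len(cols):
            raise ValidationError(
                f"residue {pos} out of range for {seq_id!r} (length {len(cols)})"
            )
        return cols[pos - 1]


def project_span(
    alignment: AlignmentProjection,
    from_id: str,
    span: tuple[int, int],
    to_id: str,
) -> tuple[int, int] | None:
    """Project a residue span through the alignment onto another sequence.

    The span's residues are mapped to their alignment columns on ``from_id``;
    the residues of ``to_id`` falling within that column window form the
    projected span (gap-only edges shrink inward).  Returns ``None`` if the
    window contains no residue of ``to_id`` (the span falls in a deletion).
    """
    for sid in (from_id, to_id):
        if sid not in alignment.aligned:
            raise ValidationError(f"sequence {sid!r} not present in alignment")
    start, end = span
    if start > end:
        raise ValidationError(f"invalid span {span}")
    c1 = alignment.residue_to_column(from_id, start)
    c2 = alignment.residue_to_column(from_id, end)
    col2res = alignment._col2res[to_id]
    residues = col2res[c1 : c2 + 1]
    residues = residues[residues > 0]
    if residues.size == 0:
        return None
    return int(residues.min()), int(residues.max())


def merge_regions(
    indexed_calls: Sequence[tuple[int, ReactivityCall]],
    protein: ProteinRecord,
    group_label: str,
    max_gap: int = 0,
    exclude_control_reactive: bool = True,
    k: int = 15,
    linker_len: int = 7,
) -> list[EpitopeRegion]:
    """Merge reactive peptide indices of one protein/group into regions.

    ``indexed_calls`` pairs each per-protein peptide index with its call,
    sorted by index.  Maximal runs of reactive indices with inter-run gaps
    ``<= max_gap`` are merged.  Control-reactive peptides are excluded from
    runs by default; a region adjacent to (or, when they are kept, containing)
    such a peptide is marked control-contaminated.
    """
    calls = sorted(indexed_calls, key=lambda t: t[0])
    control_idx = {
        i for i, c in calls if c.is_reactive and c.control_reactive
    }
    eligible = [
        (i, c)
        for i, c in calls
        if c.is_reactive and not (exclude_control_reactive and c.control_reactive)
    ]
    regions: list[EpitopeRegion] = []
    run: list[tuple[int, ReactivityCall]] = []

    def _close(run: list[tuple[int, ReactivityCall]]) -> None:
        i_first, i_last = run[0][0], run[-1][0]
        zs = [c.zscore for _, c in run]
        contaminated = any(
            idx in control_idx for idx in range(i_first - 1, i_last + 2)
        )
        regions.append(
            EpitopeRegion(
                protein_id=protein.id,
                group_label=group_label,
                index_range=(i_first, i_last),
                span=(
                    index_to_protein_span(i_first, protein.length, linker_len, k)[0],
                    index_to_protein_span(i_last, protein.length, linker_len, k)[1],
                ),
                peak_z=max(zs),
                mean_z=float(np.mean(zs)),
                n_peptides=len(run),
                control_contaminated=contaminated,
            )
        )

    for i, c in eligible:
        if run and i - run[-1][0] > max_gap + 1:
            _close(run)
            run = []
        run.append((i, c))
    if run:
        _close(run)
    return regions


def calls_by_protein(
    calls: Iterable[ReactivityCall], library: PeptideLibrary
) -> dict[str, list[tuple[int, ReactivityCall]]]:
    """Expand spot-level calls to per-protein (index, call) lists.

    A deduplicated spot shared by several proteins contributes its call to
    every origin.  Lists are sorted by index.
    """
    out: dict[str, list[tuple[int, ReactivityCall]]] = {
        pid: [] for pid in library.proteins
    }
    for call in calls:
        for protein_id, index in library.origins_of_spot(call.peptide_id):
            out[protein_id].append((index, call))
    for pid in out:
        out[pid].sort(key=lambda t: t[0])
    return out


def locate_annotation(
    entry: AnnotationEntry, protein: ProteinRecord
) -> tuple[int, int]:
    """Interval of an annotation given as a literal sequence on a reference.

    Exact substring match only; for homologs without an exact match, project
    a located interval through the alignment instead.
    """
    if not entry.sequence:
        raise ValidationError("annotation entry carries no sequence to locate")
    pos = protein.sequence.find(entry.sequence)
    if pos < 0:
        raise ValidationError(
            f"annotation sequence not found in {protein.id!r}; "
            "locate it on its own reference and use the alignment projection"
        )
    return pos + 1, pos + len(entry.sequence)


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two closed 1-based intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def annotate_overlap(
    region: EpitopeRegion,
    track: AnnotationTrack,
    alignment: AlignmentProjection | None = None,
) -> list[dict]:
    """Overlap of a called region with every entry of an annotation track.

    Entries on a different reference than the region's protein are projected
    through the alignment (and skipped, with a log message, if no alignment is
    available or the projection is empty).  Fractions are of the region's and
    of the annotation's length, both in [0, 1].
    """
    reports: list[dict] = []
    for entry in track.entries:
        interval: tuple[int, int] | None = entry.interval
        if entry.reference_id != region.protein_id:
            if alignment is None:
                logger.warning(
                    "no alignment: cannot compare %s annotation on %r with region on %r",
                    track.name, entry.reference_id, region.protein_id,
                )
                continue
            interval = project_span(
                alignment, entry.reference_id, entry.interval, region.protein_id
            )
            if interval is None:
                logger.info(
                    "%s %s:%d-%d projects to a gap on %s",
                    track.name, entry.reference_id, entry.start, entry.end,
                    region.protein_id,
                )
                continue
        ov = overlap_length(region.span, interval)
        region_len = region.span[1] - region.span[0] + 1
        ann_len = interval[1] - interval[0] + 1
        reports.append(
            {
                "track": track.name,
                "reference_id": entry.reference_id,
                "annotation_start": entry.start,
                "annotation_end": entry.end,
                "projected_start": interval[0],
                "projected_end": interval[1],
                "overlap_length": ov,
                "region_fraction": ov / region_len,
                "annotation_fraction": ov / ann_len,
            }
        )
    return reports


# ---------------------------------------------------------------------------
# Heatmap matrix export
# ---------------------------------------------------------------------------

def export_heatmap_matrix(
    profiles: Sequence[ZProfile],
    library: PeptideLibrary,
    tsv_path=None,
    png_path=None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Peptides × samples matrix of Z-scores, in protein-then-index order.

    Shared (deduplicated) spots appear once per origin.  The ``reactive_in``
    column lists samples whose Z exceeds the threshold for that row.  Output
    is deterministic: fixed row order, fixed float format.
    """
    if not profiles:
        raise ValidationError("need at least one Z-profile")
    seq_to_spot = library._seq_to_spot
    rows = []
    for pep in library.peptides:
        spot_id = seq_to_spot[pep.sequence]
        row: dict = {
            "protein_id": pep.protein_id,
            "index": pep.index,
            "peptide_id": spot_id,
        }
        marks = []
        for prof in profiles:
            zval = prof.z.get(spot_id, float("nan"))
            row[prof.sample_id] = zval
            if zval > z_threshold:
                marks.append(prof.sample_id)
        row["reactive_in"] = ",".join(marks)
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["protein_id", "index"], kind="stable").reset_index(drop=True)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6f",
                  lineterminator="\n")
    if png_path is not None:
        _plot_heatmap(df, [p.sample_id for p in profiles], png_path)
    return df


def _plot_heatmap(df: pd.DataFrame, sample_ids: list[str], png_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = df[sample_ids].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4 + 0.6 * len(sample_ids), 8))
    im = ax.imshow(mat, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(sample_ids)), sample_ids, rotation=45, ha="right")
    ax.set_ylabel("peptides (protein order)")
    fig.colorbar(im, ax=ax, label="Z-score")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_aligned_fasta(path) -> AlignmentProjection:
    """Read an equal-length gapped FASTA alignment (e.g. Clustal Omega output).

    The alignment is consumed, never computed here.
    """
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValidationError(f"{path}: not a valid alignment: {exc}") from exc
    return AlignmentProjection({rec.id: str(rec.seq).upper() for rec in aln})


ANNOTATION_COLUMNS = ("id", "start", "end", "name")


def read_annotations(path) -> list[AnnotationTrack]:
    """Read BED-like annotation TSV into tracks grouped by name.

    Columns: ``id`` (reference sequence), ``start``, ``end`` (1-based,
    inclusive — unlike BED), ``name`` (track), optional ``sequence``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: annotation table missing columns {sorted(missing)}"
        )
    has_seq = "sequence" in df.columns
    tracks: dict[str, list[AnnotationEntry]] = {}
    for _, row in df.iterrows():
        seq = None
        if has_seq and isinstance(row["sequence"], str) and row["sequence"]:
            seq = row["sequence"]
        entry = AnnotationEntry(
            reference_id=str(row["id"]),
            start=int(row["start"]),
            end=int(row["end"]),
            sequence=seq,
        )
        tracks.setdefault(str(row["name"]), []).append(entry)
    return [AnnotationTrack(name=n, entries=e) for n, e in sorted(tracks.items())]
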