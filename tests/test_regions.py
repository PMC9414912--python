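"""Region merging, alignment projection, annotation overlap, heatmap export."""

import numpy as np
import pytest

from epitile import (
    AlignmentProjection,
    AnnotationEntry,
    AnnotationTrack,
    EpitopeRegion,
    ProteinRecord,
    ReactivityCall,
    ValidationError,
    ZProfile,
    annotate_overlap,
    build_library,
    export_heatmap_matrix,
    locate_annotation,
    merge_regions,
    overlap_length,
    project_span,
    read_aligned_fasta,
    read_annotations,
)
from .conftest import Q38_PEPTIDE, protein_with_marker


def make_calls(protein, reactive, control_reactive=()):
    """(index, call) pairs for every peptide index of a protein."""
    out = []
    for i in range(1, protein.length + 1):
        call = ReactivityCall(
            peptide_id=f"pep{i}",
            group_label="g",
            zscore=3.0 if i in reactive else 0.0,
            is_reactive=i in reactive,
            control_reactive=i in control_reactive,
        )
        out.append((i, call))
    return out


@pytest.fixture(scope="module")
def protein157():
    return protein_with_marker("TSGLLSPVRRDQPLF", at=103, length=157)


class TestMergeRegions:
    def test_unbroken_run_is_one_region(self, protein157):
        regions = merge_regions(
            make_calls(protein157, set(range(128, 137))), protein157, "g"
        )
        assert len(regions) == 1
        assert regions[0].index_range == (128, 136)
        assert regions[0].n_peptides == 9

    def test_gap_splits_runs(self, protein157):
        regions = merge_regions(
            make_calls(protein157, {128, 129, 130, 136}), protein157, "g", max_gap=0
        )
        assert [r.index_range for r in regions] == [(128, 130), (136, 136)]

    def test_max_gap_bridges_single_dropout(self, protein157):
        regions = merge_regions(
            make_calls(protein157, {128, 129, 131, 132}), protein157, "g", max_gap=1
        )
        assert [r.index_range for r in regions] == [(128, 132)]
        assert regions[0].n_peptides == 4

    def test_span_is_full_15mer_footprint(self, protein157):
        regions = merge_regions(
            make_calls(protein157, {128, 129, 130}), protein157, "g"
        )
        assert regions[0].span == (121, 137)

    def test_control_flagged_break_runs_and_mark_contamination(self, protein157):
        calls = make_calls(
            protein157, set(range(120, 131)), control_reactive={125}
        )
        regions = merge_regions(calls, protein157, "g")
        assert [r.index_range for r in regions] == [(120, 124), (126, 130)]
        assert all(r.control_contaminated for r in regions)

    def test_control_flagged_kept_on_request(self, protein157):
        calls = make_calls(
            protein157, set(range(120, 131)), control_reactive={125}
        )
        regions = merge_regions(
            calls, protein157, "g", exclude_control_reactive=False
        )
        assert [r.index_range for r in regions] == [(120, 130)]
        assert regions[0].control_contaminated

    @pytest.mark.parametrize("seed", range(20))
    def test_merge_decompose_round_trip(self, protein157, seed):
        """Union of region index ranges = non-flagged reactive indices;
        regions are disjoint and sorted."""
        rng = np.random.default_rng(seed)
        reactive = {int(i) for i in rng.integers(1, 158, size=40)}
        flagged = {int(i) for i in rng.integers(1, 158, size=8)}
        regions = merge_regions(
            make_calls(protein157, reactive, flagged), protein157, "g"
        )
        covered = set()
        prev_end = 0
        for r in regions:
            lo, hi = r.index_range
            assert lo > prev_end  # sorted and disjoint
            prev_end = hi
            covered |= set(range(lo, hi + 1))
        assert covered == reactive - flagged


class TestProjectSpan:
    ALN = {
        "a": "MACDEF-GHIKL",
        "b": "MACDEFWGHIKL",
        "c": "MAC---W--IKL",
    }

    def test_identity_projection(self):
        aln = AlignmentProjection(self.ALN)
        assert project_span(aln, "b", (3, 8), "b") == (3, 8)

    def test_identical_ungapped_rows_project_identically(self):
        aln = AlignmentProjection({"x": "MACDEFGH", "y": "MACDEFGH"})
        assert project_span(aln, "x", (2, 5), "y") == (2, 5)

    def test_span_in_deletion_projects_to_none(self):
        aln = AlignmentProjection(self.ALN)
        # b residues 4-6 (DEF) sit in a gap of c
        assert project_span(aln, "b", (4, 6), "c") is None

    def test_gap_edges_shrink_inward(self):
        aln = AlignmentProjection(self.ALN)
        # b 4-10 = DEFWGHI -> c has only W (col 7) and I (col 10)
        assert project_span(aln, "b", (4, 10), "c") == (4, 5)

    def test_unknown_id_and_bad_span(self):
        aln = AlignmentProjection(self.ALN)
        with pytest.raises(ValidationError):
            project_span(aln, "z", (1, 2), "a")
        with pytest.raises(ValidationError):
            project_span(aln, "a", (5, 200), "b")

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_and_subspan_nesting(self, seed):
        """Projected start <= end; projecting a sub-span yields a sub-span."""
        rng = np.random.default_rng(seed)
        cols = 40
        rows = {}
        for sid in "ab":
            mask = rng.random(cols) < 0.75
            if mask.sum() < 5:
                mask[:5] = True
            rows[sid] = "".join(
                "ACDEFGHIKL"[rng.integers(10)] if m else "-" for m in mask
            )
        aln = AlignmentProjection(rows)
        la = len(aln.ungapped("a"))
        lo, hi = sorted(rng.integers(1, la + 1, size=2).tolist())
        outer = project_span(aln, "a", (lo, hi), "b")
        if outer is None:
            return
        assert outer[0] <= outer[1]
        sub = project_span(aln, "a", (lo, hi - (hi - lo) // 2), "b")
        if sub is not None:
            assert outer[0] <= sub[0] and sub[1] <= outer[1]


class TestLocateAnnotation:
    def test_chimera_peptide_located_at_its_printed_interval(self):
        ref = protein_with_marker(Q38_PEPTIDE, at=104, length=200, seed=11)
        entry = AnnotationEntry("Q38", 1, 1, sequence=Q38_PEPTIDE)
        assert locate_annotation(entry, ref) == (104, 184)

    def test_sequence_at_position_one(self):
        prot = ProteinRecord(id="p", sequence="MACDEFGHIKLMNPQ")
        entry = AnnotationEntry("p", 1, 1, sequence="MACDEFGHIK")
        assert locate_annotation(entry, prot) == (1, 10)

    def test_absent_sequence_errors_toward_alignment_route(self):
        prot = ProteinRecord(id="p", sequence="MACDEFGHIKLMNPQ")
        entry = AnnotationEntry("p", 1, 1, sequence="WWWWW")
        with pytest.raises(ValidationError, match="alignment"):
            locate_annotation(entry, prot)


class TestAnnotateOverlap:
    def region(self, span, protein_id="p"):
        return EpitopeRegion(
            protein_id=protein_id, group_label="g", index_range=(1, 1),
            span=span, peak_z=3.0, mean_z=3.0, n_peptides=1,
        )

    def test_region_inside_annotation(self):
        track = AnnotationTrack("Q38", [AnnotationEntry("p", 104, 184)])
        (rep,) = annotate_overlap(self.region((121, 137)), track)
        assert rep["overlap_length"] == 17
        assert rep["region_fraction"] == pytest.approx(1.0)

    def test_disjoint_intervals(self):
        track = AnnotationTrack("t", [AnnotationEntry("p", 1, 20)])
        (rep,) = annotate_overlap(self.region((50, 64)), track)
        assert rep["overlap_length"] == 0

    def test_annotation_nested_in_region(self):
        track = AnnotationTrack("t", [AnnotationEntry("p", 55, 60)])
        (rep,) = annotate_overlap(self.region((50, 64)), track)
        assert rep["annotation_fraction"] == pytest.approx(1.0)

    def test_overlap_length_is_symmetric(self):
        a, b = (10, 30), (25, 40)
        assert overlap_length(a, b) == overlap_length(b, a) == 6

    def test_projection_through_alignment(self):
        aln = AlignmentProjection({"q": "MACDEFGHIK", "p": "MACDEF--IK"})
        track = AnnotationTrack("t", [AnnotationEntry("q", 5, 10)])
        (rep,) = annotate_overlap(self.region((1, 8), protein_id="p"), track, aln)
        assert (rep["projected_start"], rep["projected_end"]) == (5, 8)


class TestHeatmapExport:
    def _profiles(self, library, n_samples=2, seed=0):
        rng = np.random.default_rng(seed)
        profs = []
        for s in range(n_samples):
            z = rng.normal(size=library.n_distinct)
            z = (z - z.mean()) / z.std(ddof=1)
            profs.append(
                ZProfile(f"s{s}", dict(zip(library.spot_ids, z.tolist())), 0.0, 1.0)
            )
        return profs

    def test_matrix_shape_and_row_order(self, protein157):
        lib = build_library([protein157])
        df = export_heatmap_matrix(self._profiles(lib), lib)
        assert df.shape[0] == len(lib.peptides)
        assert list(df["index"]) == sorted(df["index"])
        assert {"s0", "s1"} <= set(df.columns)

    def test_no_marks_when_all_null(self, protein157):
        lib = build_library([protein157])
        profs = self._profiles(lib)
        for p in profs:
            p.z = {k: 0.0 for k in p.z}
        df = export_heatmap_matrix(profs, lib)
        assert (df["reactive_in"] == "").all()

    def test_tsv_is_byte_deterministic(self, tmp_path, protein157):
        lib = build_library([protein157])
        profs = self._profiles(lib)
        p1, p2 = tmp_path / "h1.tsv", tmp_path / "h2.tsv"
        export_heatmap_matrix(profs, lib, tsv_path=p1)
        export_heatmap_matrix(profs, lib, tsv_path=p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestReaders:
    def test_aligned_fasta_round_trip(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nMACDEF-GHIKL\n>b\nMACDEFWGHIKL\n")
        aln = read_aligned_fasta(path)
        assert aln.ids() == ["a", "b"]
        assert aln.ungapped("a") == "MACDEFGHIKL"

    def test_ragged_alignment_errors(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\nMACDEF\n>b\nMACDEFGHI\n")
        with pytest.raises(ValidationError):
            read_aligned_fasta(path)

    def test_annotation_table(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "id\tstart\tend\tname\nQ38\t104\t184\tQ38_epitope\n"
            "Q38\t123\t184\tSUB_interaction_domain\n"
        )
        tracks = read_annotations(path)
        assert [t.name for t in tracks] == ["Q38_epitope", "SUB_interaction_domain"]
        assert tracks[0].entries[0].interval == (104, 184)

    def test_inverted_interval_errors(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("id\tstart\tend\tname\nQ38\t184\t104\tt\n")
        with pytest.raises(ValidationError):
            read_annotations(path)
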