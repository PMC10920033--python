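import numpy as np
import pytest

import conacc as cc
from conacc.curation import CurationConfig
from conacc.formats_io import AlignmentBlock, AlignmentRow


def pair(ref_text, tgt_text, ref_start=0, tgt_start=0, species="A_sagrei"):
    def row(sp, src, start, text, src_size=10000):
        return AlignmentRow(
            species=sp, src=src, src_start=start,
            size=len(text) - text.count("-"), src_size=src_size,
            strand="+", text=text,
        )

    return AlignmentBlock([
        row("A_carolinensis", "A_carolinensis.chr1", ref_start, ref_text),
        row(species, f"{species}.scaf1", tgt_start, tgt_text),
    ])


class TestTrimAndSplitN:
    def test_edge_ns_are_trimmed(self):
        (out,) = cc.trim_and_split_n(pair("NNACGT", "NNACGT"))
        assert out.ncols == 4
        assert out.rows[0].text == "ACGT"
        assert out.rows[0].src_start == 2

    def test_long_internal_run_splits_the_block(self):
        # 6-N run over a 10-base row: 6/10 > 0.5, run excised, block split
        (left, right) = cc.trim_and_split_n(pair("ACNNNNNNGT", "ACGTACGTAC"))
        assert (left.ncols, right.ncols) == (2, 2)
        assert left.rows[0].text == "AC" and right.rows[0].text == "GT"
        assert right.rows[0].src_start == 8
        assert right.rows[1].src_start == 8

    def test_short_internal_run_is_kept(self):
        # 3-N run over 10 bases: 3/10 <= 0.5
        (out,) = cc.trim_and_split_n(pair("ACGNNNACGT", "ACGTACGTAC"))
        assert out.ncols == 10 and "NNN" in out.rows[0].text

    def test_all_n_block_is_dropped(self):
        assert cc.trim_and_split_n(pair("NNNN", "ACGT")) == []

    def test_non_pairwise_block_rejected(self):
        block = pair("ACGT", "ACGT")
        block.rows.append(
            AlignmentRow("A_allogus", "A_allogus.s1", 0, 4, 100, "+", "ACGT")
        )
        with pytest.raises(ValueError, match="pairwise"):
            cc.trim_and_split_n(block)

    def test_never_gains_columns_and_never_edits_non_n_bases(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            ref = "".join(rng.choice(list("ACGTN"), n, p=[0.2] * 4 + [0.2]))
            tgt = "".join(rng.choice(list("ACGTN"), n, p=[0.2] * 4 + [0.2]))
            block = pair(ref, tgt)
            pieces = cc.trim_and_split_n(block)
            assert sum(p.ncols for p in pieces) <= block.ncols
            for piece in pieces:
                # each piece is a contiguous column slice of the original:
                # its text must appear verbatim at its source offset
                for orig_row, new_row in zip(block.rows, piece.rows):
                    off = new_row.src_start - orig_row.src_start
                    ungapped_orig = orig_row.text.replace("-", "")
                    ungapped_new = new_row.text.replace("-", "")
                    assert (
                        ungapped_orig[off : off + len(ungapped_new)]
                        == ungapped_new
                    )


class TestResolveReferenceOverlaps:
    def test_full_containment_keeps_only_the_longer(self):
        long = pair("A" * 80, "C" * 80, ref_start=0)
        short = pair("A" * 50, "G" * 50, ref_start=0)
        out = cc.resolve_reference_overlaps([short, long])
        assert len(out) == 1 and out[0].ncols == 80

    def test_partial_overlap_trims_the_shorter(self):
        b1 = pair("A" * 100, "C" * 100, ref_start=0)
        b2 = pair("G" * 60, "T" * 60, ref_start=60)
        out = cc.resolve_reference_overlaps([b2, b1])
        ivs = sorted((b.ref_interval().start, b.ref_interval().end) for b in out)
        assert ivs == [(0, 100), (100, 120)]
        trimmed = [b for b in out if b.ref_interval().start == 100][0]
        assert trimmed.ncols == 20

    def test_disjoint_blocks_pass_unchanged(self):
        b1 = pair("A" * 30, "C" * 30, ref_start=0)
        b2 = pair("G" * 30, "T" * 30, ref_start=50)
        out = cc.resolve_reference_overlaps([b1, b2])
        assert len(out) == 2
        assert {b.ncols for b in out} == {30}

    def test_coverage_is_single_after_resolution(self):
        rng = np.random.default_rng(1)
        blocks = [
            pair("A" * n, "C" * n, ref_start=int(rng.integers(0, 200)))
            for n in rng.integers(10, 80, size=12)
        ]
        out = cc.resolve_reference_overlaps(blocks)
        covered = np.zeros(400, dtype=int)
        for b in out:
            iv = b.ref_interval()
            covered[iv.start : iv.end] += 1
        assert covered.max() <= 1


class TestMergeReferenceAnchored:
    def test_single_species_identity(self):
        b = pair("ACGTAC", "ACGTAC")
        (out,) = cc.merge_reference_anchored(
            {"A_sagrei": [b]}, "A_carolinensis"
        )
        assert out.ncols == 6 and len(out.rows) == 2
        assert out.rows[0].species == "A_carolinensis"

    def test_two_species_partition_by_coverage(self):
        b1 = pair("A" * 50, "C" * 50, ref_start=0, species="A_sagrei")
        b2 = pair("A" * 50, "G" * 50, ref_start=25, species="A_porcatus")
        out = cc.merge_reference_anchored(
            {"A_sagrei": [b1], "A_porcatus": [b2]}, "A_carolinensis"
        )
        spans = [(b.ref_interval().start, b.ref_interval().end, len(b.rows) - 1)
                 for b in out]
        assert spans == [(0, 25, 1), (25, 50, 2), (50, 75, 1)]

    def test_insertions_against_reference_are_dropped(self):
        b = pair("AC--GT", "ACTTGT")
        (out,) = cc.merge_reference_anchored({"A_sagrei": [b]}, "A_carolinensis")
        assert out.ncols == 4
        assert out.rows[1].text == "ACGT"

    def test_conflicting_reference_bases_raise(self):
        b1 = pair("ACGT", "ACGT", species="A_sagrei")
        b2 = pair("TCGT", "ACGT", species="A_porcatus")
        with pytest.raises(ValueError, match="conflicting"):
            cc.merge_reference_anchored(
                {"A_sagrei": [b1], "A_porcatus": [b2]}, "A_carolinensis"
            )


class TestFilterSpeciesCount:
    def _block(self, n_species):
        rows = [
            AlignmentRow(f"sp{i}", f"sp{i}.c", 0, 4, 100, "+", "ACGT")
            for i in range(n_species)
        ]
        return AlignmentBlock(rows)

    def test_threshold_boundary(self):
        cfg = CurationConfig(min_species=7)
        assert cc.filter_species_count([self._block(8)], cfg)
        assert cc.filter_species_count([self._block(7)], cfg)
        assert not cc.filter_species_count([self._block(6)], cfg)

    def test_mixed_fixture_matches_hand_count(self):
        counts = [8, 6, 7, 5, 8, 7, 4, 8, 6, 7]
        blocks = [self._block(n) for n in counts]
        kept = cc.filter_species_count(blocks, CurationConfig(min_species=7))
        assert len(kept) == sum(1 for n in counts if n >= 7)
        assert [len(b.rows) for b in kept] == [n for n in counts if n >= 7]


class TestCurationPipeline:
    def test_artifact_injection_round_trip(self):
        plan = cc.plan_windows(12, 0, 0, seed=5)
        ds = cc.generate_dataset(plan, seed=5)
        per_species = cc.to_pairwise(ds.blocks, "A_carolinensis")
        cfg = cc.ArtifactConfig(
            edge_n_fraction=0.5, internal_n_fraction=0.0,
            missing_species_fraction=0.0, duplicate_fraction=0.3,
        )
        noisy = cc.inject_artifacts(per_species, cfg, seed=6)
        curated = cc.curate_pairwise(noisy, "A_carolinensis")
        # every curated block passes the species filter and disjoint coverage
        assert all(len(b.rows) >= 7 for b in curated)
        seen = np.zeros(plan.length, dtype=int)
        for b in curated:
            iv = b.ref_interval()
            seen[iv.start : iv.end] += 1
        assert seen.max() <= 1
        # retained reference bases agree with the artefact-free dataset
        ref_truth = {}
        for b in ds.blocks:
            iv = b.ref_interval()
            for i, ch in enumerate(b.reference.text):
                ref_truth[iv.start + i] = ch
        for b in curated:
            iv = b.ref_interval()
            for i, ch in enumerate(b.reference.text):
                assert ch == ref_truth[iv.start + i]
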