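"""Windowing, conservation scoring, rank normalization, window contrast."""

import numpy as np
import pytest

from grapesdr.formats import GeneModel, GenomeAnnotation
from grapesdr.stats import kruskal_groups, rank_normalize
from grapesdr.synteny import AnchorPair, CollinearBlock
from grapesdr.windows import (
    GeneWindow,
    assign_homologous,
    assign_orthologous,
    compare_windows,
    conservation_score,
    make_windows,
    rank_normalize_scores,
)


def annotation(n, contig="chr1"):
    return GenomeAnnotation.from_genes(
        "ref",
        [
            GeneModel(f"g{i}", contig, i * 100, i * 100 + 50, "+", i)
            for i in range(n)
        ],
    )


def block(block_id, pairs, orientation="plus"):
    anchors = [
        AnchorPair(f"g{r}", f"t{t}", r, t, b) for r, t, b in pairs
    ]
    return CollinearBlock(block_id, "chr1", "c1", anchors, orientation)


class TestMakeWindows:
    def test_exact_division(self):
        assert len(make_windows(annotation(24), 12)) == 2

    def test_trailing_genes_dropped(self):
        wins = make_windows(annotation(25), 12)
        assert len(wins) == 2
        covered = {g for w in wins for g in w.gene_ids}
        assert "g24" not in covered and len(covered) == 24

    def test_reference_scale_window_count(self):
        # 2307 full 12-gene windows <=> 27,684 genes
        assert len(make_windows(annotation(2307 * 12), 12)) == 2307

    def test_windows_restart_per_contig(self):
        genes = [
            GeneModel(f"a{i}", "chr1", i * 10, i * 10 + 5, "+", i)
            for i in range(13)
        ] + [
            GeneModel(f"b{i}", "chr2", i * 10, i * 10 + 5, "+", i)
            for i in range(12)
        ]
        ann = GenomeAnnotation.from_genes("ref", genes)
        wins = make_windows(ann, 12)
        assert [w.contig for w in wins] == ["chr1", "chr2"]


class TestConservationScore:
    @pytest.mark.parametrize(
        "pair,self_,expected",
        [(250.0, 500.0, 0.5), (500.0, 500.0, 1.0), (520.0, 500.0, 1.0)],
    )
    def test_ratio_and_clamp(self, pair, self_, expected):
        assert conservation_score(pair, self_) == expected

    def test_nonpositive_self_score_rejected(self):
        with pytest.raises(ValueError):
            conservation_score(100.0, 0.0)


SELF = {f"g{i}": 500.0 for i in range(24)}
WINDOW = GeneWindow(0, "chr1", tuple(f"g{i}" for i in range(12)))


class TestAssignOrthologous:
    def test_block_covering_most_window_genes_wins(self):
        b_big = block("b1", [(i, i, 100.0) for i in range(7)])
        b_small = block("b2", [(i, i + 12, 400.0) for i in range(4)])
        (a,) = assign_orthologous([WINDOW], [b_big, b_small], SELF, "h")
        assert a.selected_blocks == ["b1"]
        assert a.collinear_gene_count == 7

    def test_tie_broken_by_score_then_id(self):
        b1 = block("b1", [(i, i, 100.0) for i in range(5)])
        b2 = block("b2", [(i, i + 20, 300.0) for i in range(5)])
        (a,) = assign_orthologous([WINDOW], [b1, b2], SELF, "h")
        assert a.selected_blocks == ["b2"]  # same coverage, higher score
        b3 = block("b0", [(i, i + 40, 300.0) for i in range(5)])
        (a,) = assign_orthologous([WINDOW], [b2, b3], SELF, "h")
        assert a.selected_blocks == ["b0"]  # full tie -> smaller id

    def test_no_overlapping_block(self):
        far = block("b1", [(i + 12, i, 100.0) for i in range(6)])
        (a,) = assign_orthologous([WINDOW], [far], SELF, "h")
        assert a.collinear_gene_count == 0 and a.gene_scores == {}

    def test_scores_use_best_anchor_within_selected_block(self):
        b = block("b1", [(i, i, 100.0) for i in range(6)])
        b.anchors.append(AnchorPair("g0", "t9", 0, 9, 450.0))
        (a,) = assign_orthologous([WINDOW], [b], SELF, "h")
        assert a.gene_scores["g0"] == pytest.approx(450.0 / 500.0)


class TestAssignHomologous:
    def test_wgd_doubles_region_count(self):
        r1 = block("b1", [(i, i, 100.0) for i in range(6)])
        r2 = block("b2", [(i, i + 50, 90.0) for i in range(6)])
        (a,) = assign_homologous([WINDOW], [r1, r2], SELF, "h")
        assert a.region_count == 2

    def test_gene_scored_from_greatest_bitscore_across_regions(self):
        rA = block("b1", [(0, 0, 300.0), (1, 1, 300.0)])
        rB = block("b2", [(0, 30, 450.0), (1, 31, 100.0)])
        (a,) = assign_homologous([WINDOW], [rA, rB], SELF, "h")
        assert a.gene_scores["g0"] == pytest.approx(0.9)
        assert a.gene_scores["g1"] == pytest.approx(0.6)

    def test_single_anchor_region_not_counted(self):
        stray = block("b1", [(0, 0, 300.0)])
        (a,) = assign_homologous([WINDOW], [stray], SELF, "h")
        assert a.region_count == 0 and a.gene_scores == {}

    def test_homologous_count_at_least_orthologous(self, genome_set):
        gs = genome_set
        from grapesdr.synteny import detect_collinear_blocks
        from grapesdr.windows import make_windows

        wins = make_windows(gs.ref, 12)[:40]
        hap = sorted(gs.annotations)[0]
        blocks = detect_collinear_blocks(
            gs.ref, gs.annotations[hap], gs.hit_tables[hap]
        )
        self_scores = gs.hit_tables[hap].self_scores
        orth = assign_orthologous(wins, blocks, self_scores, hap)
        homo = assign_homologous(wins, blocks, self_scores, hap)
        for o, h in zip(orth, homo):
            assert h.collinear_gene_count >= o.collinear_gene_count
            assert o.collinear_gene_count <= 12


class TestRankNormalize:
    def test_plain_ranks(self):
        assert rank_normalize(np.array([0.2, 0.5, 0.9])).tolist() == [0.0, 0.5, 1.0]

    def test_ties_take_mean_rank(self):
        assert rank_normalize(np.array([0.3, 0.3, 0.8])).tolist() == [
            0.25, 0.25, 1.0,
        ]

    def test_full_tie_and_singleton_map_to_half(self):
        assert rank_normalize(np.array([0.7] * 5)).tolist() == [0.5] * 5
        assert rank_normalize(np.array([0.3])).tolist() == [0.5]

    def test_groupwise_normalization_is_independent_per_group(self):
        scores = {("a", 1): 0.1, ("a", 2): 0.9, ("b", 1): 0.5}
        groups = {("a", 1): "eu", ("a", 2): "eu", ("b", 1): "other"}
        normed = rank_normalize_scores(scores, groups)
        assert normed[("a", 1)] == 0.0
        assert normed[("a", 2)] == 1.0
        assert normed[("b", 1)] == 0.5


class TestCompareWindows:
    def test_fully_separated_focus_rejects(self):
        import pandas as pd

        rows = [(0, f"h{i}", "eudicot", "orthologous", 12, 1, 1.0, 0.95)
                for i in range(10)]
        rows += [
            (w, f"h{i}", "eudicot", "orthologous", 5, 1, 0.4, 0.3)
            for w in range(1, 11)
            for i in range(10)
        ]
        df = pd.DataFrame(
            rows,
            columns=[
                "window_index", "haplotype", "clade", "mode",
                "collinear_gene_count", "region_count", "mean_score",
                "mean_normalized_score",
            ],
        )
        res = compare_windows(df, 0)
        assert res["counts"]["p"] < 0.001
        assert res["scores"]["p"] < 0.001

    def test_type_one_error_calibrated(self):
        # focus drawn from the background distribution: ~5% rejections
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            focus = rng.normal(size=12)
            background = rng.normal(size=120)
            res = kruskal_groups({"f": focus, "b": background})
            rejections += res.p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_identical_groups_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            res = kruskal_groups({"a": np.ones(5), "b": np.ones(5)})
        assert res.H == 0.0 and res.p == 1.0
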