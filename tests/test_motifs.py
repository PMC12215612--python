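"""Promoter extraction, PWM scanning, group-specific site calls."""

import numpy as np
import pytest

from grapesdr.formats import GeneModel, GenomeAnnotation
from grapesdr.motifs import (
    PWM,
    MotifHit,
    Promoter,
    differential_site_counts,
    extract_promoters,
    group_specific_sites,
    read_jaspar_pfm,
    reverse_complement,
    scan_pwm,
)
from grapesdr.simulate import simulate_promoter_groups

CONSENSUS = "TGGTAGGT"


def consensus_pwm(consensus=CONSENSUS, strength=97):
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        mat[base_index[b], j] = strength
    return PWM("M0001", mat)


def annotation_with_genome(tss=10_000, strand="+", contig_len=30_000):
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(4, size=contig_len))
    if strand == "+":
        gene = GeneModel("g1", "chr1", tss, tss + 500, "+", 0)
    else:
        gene = GeneModel("g1", "chr1", tss - 500, tss, "-", 0)
    ann = GenomeAnnotation.from_genes("h1", [gene])
    return ann, {"chr1": seq}


class TestExtractPromoters:
    def test_plus_strand_takes_upstream_3kb(self):
        ann, genome = annotation_with_genome(tss=10_000, strand="+")
        (p,) = extract_promoters(ann, genome)
        assert len(p) == 3000
        assert p.sequence == genome["chr1"][7000:10_000]

    def test_truncation_at_contig_start(self):
        ann, genome = annotation_with_genome(tss=1199, strand="+")
        (p,) = extract_promoters(ann, genome)
        assert len(p) == 1199

    def test_minus_strand_reverse_complemented(self):
        ann, genome = annotation_with_genome(tss=10_000, strand="-")
        (p,) = extract_promoters(ann, genome)
        assert p.sequence == reverse_complement(genome["chr1"][10_000:13_000])

    def test_gene_at_edge_skipped_with_warning(self):
        gene = GeneModel("g1", "chr1", 0, 100, "+", 0)
        ann = GenomeAnnotation.from_genes("h1", [gene])
        with pytest.warns(UserWarning, match="no upstream"):
            assert extract_promoters(ann, {"chr1": "ACGT" * 100}) == []


class TestScanPWM:
    def test_planted_consensus_found_at_2104(self):
        rng = np.random.default_rng(5)
        seq = list("ACGT"[i] for i in rng.integers(4, size=3000))
        start = 3000 - 2104
        seq[start : start + len(CONSENSUS)] = CONSENSUS
        prom = Promoter("g1", "h1", "M", "".join(seq))
        hits = scan_pwm(prom, consensus_pwm())
        exact = [h for h in hits if h.upstream_offset == 2104]
        assert exact and exact[0].relative_score == pytest.approx(1.0)
        assert exact[0].strand == "+"

    def test_complement_consensus_hits_minus_strand_only(self):
        rng = np.random.default_rng(6)
        seq = list("ACGT"[i] for i in rng.integers(4, size=500))
        rc = reverse_complement(CONSENSUS)
        seq[200 : 200 + len(rc)] = rc
        prom = Promoter("g1", "h1", "M", "".join(seq))
        hits = [h for h in scan_pwm(prom, consensus_pwm()) if
                h.relative_score > 0.99]
        assert hits and all(h.strand == "-" for h in hits)
        assert any(h.upstream_offset == 500 - 200 for h in hits)

    def test_two_mismatches_score_below_threshold(self):
        pwm = consensus_pwm()
        mutated = "CGGTAGGA"  # 2 mismatches of TGGTAGGT
        prom = Promoter("g1", "h1", "M", "A" * 100 + mutated + "A" * 100)
        hits = scan_pwm(prom, pwm, min_rel_score=0.80)
        assert all(h.relative_score < 0.80 for h in hits) or hits == []

    def test_scan_matches_exhaustive_enumeration(self):
        # independent per-window rescoring of every reported hit
        pwm = consensus_pwm(strength=30)
        rng = np.random.default_rng(7)
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=400))
        prom = Promoter("g1", "h1", "M", seq)
        hits = scan_pwm(prom, pwm, min_rel_score=0.6, both_strands=False)
        lods = pwm.log_odds()
        smin = lods.min(axis=0).sum()
        smax = lods.max(axis=0).sum()
        base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
        expected = {}
        for i in range(len(seq) - pwm.length + 1):
            s = sum(
                lods[base_index[seq[i + j]], j] for j in range(pwm.length)
            )
            rel = (s - smin) / (smax - smin)
            if rel >= 0.6:
                expected[len(seq) - i] = rel
        got = {h.upstream_offset: h.relative_score for h in hits}
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    def test_motif_longer_than_promoter_yields_nothing(self):
        prom = Promoter("g1", "h1", "M", "ACG")
        assert scan_pwm(prom, consensus_pwm()) == []

    def test_strand_symmetry_under_reverse_complement(self):
        pwm = consensus_pwm()
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=300))
        p_fwd = Promoter("g1", "h1", "M", seq)
        p_rc = Promoter("g1", "h1", "M", reverse_complement(seq))
        h_fwd = scan_pwm(p_fwd, pwm, min_rel_score=0.5)
        h_rc = scan_pwm(p_rc, pwm, min_rel_score=0.5)
        scores = lambda hs: sorted(round(h.relative_score, 9) for h in hs)
        assert scores(h_fwd) == scores(h_rc)


class TestGroupSpecificSites:
    def _hits(self, spec):
        """spec: list of (group, hap, offset)."""
        return [
            MotifHit("M0001", "YABBY3", h, g, o, "+", 0.95) for g, h, o in spec
        ]

    def _promoters(self, groups):
        return [
            Promoter("YABBY3", f"{g}{i}", g, "ACGTACGT")
            for g, n in groups.items()
            for i in range(n)
        ]

    def test_site_in_all_m_absent_elsewhere_is_reported(self):
        proms = self._promoters({"M": 4, "F": 3, "H": 3})
        hits = self._hits(
            [("M", f"M{i}", 2100 + (i * 5 - 8)) for i in range(4)]
        )
        df = group_specific_sites(hits, proms)
        assert len(df) == 1
        assert df.iloc[0]["group"] == "M"
        assert abs(df.iloc[0]["consensus_offset"] - 2100) < 30

    def test_missing_one_group_member_not_reported(self):
        proms = self._promoters({"M": 4, "F": 3})
        hits = self._hits([("M", f"M{i}", 2100) for i in range(3)])
        assert group_specific_sites(hits, proms).empty

    def test_hit_in_other_group_blocks_call(self):
        proms = self._promoters({"M": 4, "F": 3, "H": 3})
        hits = self._hits(
            [("M", f"M{i}", 2100) for i in range(4)] + [("H", "H0", 2110)]
        )
        assert group_specific_sites(hits, proms).empty


class TestDifferentialCounts:
    def test_direction_and_margin(self):
        proms = [
            Promoter("g", f"M{i}", "M", "ACGT") for i in range(2)
        ] + [Promoter("g", f"F{i}", "F", "ACGT") for i in range(2)]
        from grapesdr.motifs import MotifHit

        hits = [
            MotifHit("M0001", "g", f"M{i}", "M", o, "+", 0.9)
            for i in range(2)
            for o in (100, 200, 300)
        ] + [MotifHit("M0001", "g", f"F{i}", "F", 100, "+", 0.9) for i in range(2)]
        df = differential_site_counts(hits, proms)
        assert df.iloc[0]["direction"] == "M"
        assert df.iloc[0]["margin"] == pytest.approx(2.0)

    def test_equal_counts_omitted(self):
        proms = [Promoter("g", "M0", "M", "ACGT"), Promoter("g", "F0", "F", "ACGT")]
        from grapesdr.motifs import MotifHit

        hits = [
            MotifHit("M0001", "g", "M0", "M", 100, "+", 0.9),
            MotifHit("M0001", "g", "F0", "F", 100, "+", 0.9),
        ]
        assert differential_site_counts(hits, proms).empty


class TestPlantedMotifRecovery:
    def test_planted_m_only_motif_recovered(self):
        proms = simulate_promoter_groups(
            CONSENSUS, {"M": 4, "F": 3, "H": 3}, {"M": 2104}, seed=1
        )
        pwm = consensus_pwm()
        hits = [h for p in proms for h in scan_pwm(p, pwm, min_rel_score=0.9)]
        df = group_specific_sites(hits, proms)
        m_rows = df[df["group"] == "M"]
        assert len(m_rows) == 1
        assert m_rows.iloc[0]["consensus_offset"] == pytest.approx(2104)

    def test_label_permutation_abolishes_call(self):
        proms = simulate_promoter_groups(
            CONSENSUS, {"M": 4, "F": 3, "H": 3}, {"M": 2104}, seed=1
        )
        pwm = consensus_pwm()
        hits = [h for p in proms for h in scan_pwm(p, pwm, min_rel_score=0.9)]
        rng = np.random.default_rng(99)
        labels = [p.group for p in proms]
        abolished = 0
        from dataclasses import replace

        for _ in range(100):
            perm = rng.permutation(len(labels))
            relabel = {
                proms[i].haplotype_id: labels[perm[i]] for i in range(len(proms))
            }
            proms2 = [replace(p, group=relabel[p.haplotype_id]) for p in proms]
            hits2 = [replace(h, group=relabel[h.haplotype_id]) for h in hits]
            df = group_specific_sites(hits2, proms2)
            if df[df["group"] == "M"].empty:
                abolished += 1
        assert abolished >= 95


def test_jaspar_pfm_round_trip(tmp_path):
    text = (
        ">MA0001.1 TEST\n"
        "A  [ 10  0 30 ]\n"
        "C  [  0 40  0 ]\n"
        "G  [ 30  0 10 ]\n"
        "T  [  0  0  0 ]\n"
    )
    path = tmp_path / "m.pfm"
    path.write_text(text)
    (pwm,) = read_jaspar_pfm(path)
    assert pwm.length == 3
    assert pwm.matrix[1, 1] == 40
    assert pwm.consensus() in {"ACA", "ACG", "GCA", "GCG"}
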