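"""Cluster delineation, promoter methylation, transcript matching, evidence integration."""

import itertools

import numpy as np
import pytest

from npomics.evidence import (
    EvidenceRecord,
    TranscriptHit,
    classify_backbone,
    delineate_cluster,
    integrate_evidence,
    is_transcript_matched,
    promoter_methylated,
    region_overlap_agreement,
)
from npomics.genome import CoverageTrack, Gene, MacSet

from conftest import make_gene


def layout(spec):
    """Build genes + a track from (id, start, length, covered) tuples."""
    genes, length = [], 0
    for gid, start, glen, covered in spec:
        genes.append(Gene(id=gid, scaffold="s1", start=start, end=start + glen - 1))
        length = max(length, start + glen + 1_000)
    depth = np.zeros(length, dtype=np.int64)
    for gid, start, glen, covered in spec:
        if covered:
            depth[start - 1 : start - 1 + glen] = 10
    return genes, CoverageTrack("s1", depth)


class TestDelineateCluster:
    def test_lone_core(self):
        genes, track = layout([("core", 1_000, 1_000, True)])
        cluster = delineate_cluster(genes[0], genes, track)
        assert cluster.members == ["core"]
        assert classify_backbone(cluster) == "isolated"

    def test_large_gap_stops_extension(self):
        # transcribed neighbor 5 kbp away joins; next gene 12 kbp beyond stops
        genes, track = layout(
            [("core", 1_000, 1_000, True),
             ("n1", 7_000, 1_000, True),       # gap 5,000
             ("n2", 20_001, 1_000, True)]      # gap 12,000
        )
        cluster = delineate_cluster(genes[0], genes, track)
        assert cluster.members == ["core", "n1"]
        assert classify_backbone(cluster) == "clustered"

    def test_greedy_stop_at_first_failure(self):
        # untranscribed neighbor blocks a transcribed gene just beyond it
        genes, track = layout(
            [("core", 1_000, 1_000, True),
             ("blocker", 4_000, 1_000, False),  # gap 2,000, silent
             ("beyond", 6_000, 1_000, True)]    # would pass, never reached
        )
        cluster = delineate_cluster(genes[0], genes, track)
        assert cluster.members == ["core"]

    def test_gap_boundary_inclusive(self):
        # intergenic distance next.start - prev.end - 1: exactly 10,000 joins
        genes, track = layout(
            [("core", 1_000, 1_000, True), ("n1", 12_000, 1_000, True)]
        )
        assert delineate_cluster(genes[0], genes, track).members == ["core", "n1"]
        genes, track = layout(
            [("core", 1_000, 1_000, True), ("n1", 12_001, 1_000, True)]
        )
        assert delineate_cluster(genes[0], genes, track).members == ["core"]

    def test_extension_runs_both_directions(self):
        genes, track = layout(
            [("left", 1_000, 1_000, True),
             ("core", 4_000, 1_000, True),
             ("right", 7_000, 1_000, True)]
        )
        cluster = delineate_cluster(genes[1], genes, track)
        assert cluster.members == ["left", "core", "right"]
        assert cluster.span == (1_000, 7_999)

    def test_silent_core_still_seeds(self):
        genes, track = layout(
            [("core", 1_000, 1_000, False), ("n1", 4_000, 1_000, True)]
        )
        assert delineate_cluster(genes[0], genes, track).members == ["core", "n1"]

    def test_core_missing_from_scaffold(self):
        genes, track = layout([("g1", 1_000, 1_000, True)])
        with pytest.raises(KeyError):
            delineate_cluster(make_gene("absent"), genes, track)

    def test_raising_depth_never_shrinks_cluster(self):
        spec = [("core", 1_000, 1_000, True), ("n1", 4_000, 1_000, False),
                ("n2", 7_000, 1_000, True)]
        genes, track = layout(spec)
        before = delineate_cluster(genes[0], genes, track).members
        track.depth += 10  # now everything is covered
        after = delineate_cluster(genes[0], genes, track).members
        assert set(before) <= set(after)


class TestPromoterMethylation:
    def test_mac_near_tss(self):
        gene = make_gene(start=10_000, end=12_000)
        assert promoter_methylated(gene, MacSet("s1", [9_900]))

    def test_window_boundary_inclusive(self):
        gene = make_gene(start=10_000, end=12_000)  # TSS 10,000 on '+'
        assert promoter_methylated(gene, MacSet("s1", [9_500]))       # exactly 500
        assert not promoter_methylated(gene, MacSet("s1", [9_499]))   # 501 away

    def test_minus_strand_uses_gene_end(self):
        gene = make_gene(start=10_000, end=12_000, strand="-")
        assert promoter_methylated(gene, MacSet("s1", [12_400]))
        assert not promoter_methylated(gene, MacSet("s1", [10_000]))

    def test_empty_mac_set(self):
        assert not promoter_methylated(make_gene(), MacSet("s1", []))

    def test_scaffold_mismatch_rejected(self):
        with pytest.raises(ValueError):
            promoter_methylated(make_gene(), MacSet("s2", [1_000]))


class TestTranscriptMatch:
    eligible = dict(n_domains=3, length_aa=150)

    def test_all_thresholds_pass(self):
        gene = make_gene(**self.eligible)
        hits = [TranscriptHit("g1", 1e-10, 99.0, 0.99)]
        assert is_transcript_matched(hits, gene) is True

    @pytest.mark.parametrize(
        "hit",
        [
            TranscriptHit("g1", 1e-10, 94.0, 0.99),   # similarity fails
            TranscriptHit("g1", 0.01, 99.0, 0.99),    # evalue fails
            TranscriptHit("g1", 1e-10, 99.0, 0.90),   # hsp/query fails
            TranscriptHit("g1", 1e-10, 95.0, 0.99),   # similarity not > 95
        ],
    )
    def test_single_failing_threshold(self, hit):
        gene = make_gene(**self.eligible)
        assert is_transcript_matched([hit], gene) is False

    def test_empty_hits_silent(self):
        assert is_transcript_matched([], make_gene(**self.eligible)) is False

    def test_ineligible_gene_excluded_not_silent(self):
        few_domains = make_gene(n_domains=2, length_aa=150)
        short = make_gene(n_domains=4, length_aa=90)
        hits = [TranscriptHit("g1", 1e-10, 99.0, 0.99)]
        assert is_transcript_matched(hits, few_domains) is None
        assert is_transcript_matched(hits, short) is None


class TestIntegrateEvidence:
    def test_active_any_is_disjunction_over_all_combinations(self):
        for t, m, d in itertools.product([False, True], repeat=3):
            rec = EvidenceRecord("g", t, m, d)
            assert rec.active_any == (t or m or d)

    def test_summary_fractions(self):
        genes = [make_gene(f"g{i}") for i in range(4)]
        t = {"g0": True, "g1": False, "g2": False, "g3": False}
        m = {"g0": False, "g1": True, "g2": False, "g3": False}
        d = {g.id: False for g in genes}
        records, summary = integrate_evidence(genes, t, m, d)
        overall = summary[summary.strain == "overall"].iloc[0]
        assert overall.frac_active_any == 0.5
        assert overall.frac_transcribed == 0.25

    def test_methylation_alone_makes_active(self):
        genes = [make_gene("g0")]
        records, _ = integrate_evidence(
            genes, {"g0": False}, {"g0": True}, {"g0": False}
        )
        assert records[0].active_any

    def test_missing_flag_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            integrate_evidence([make_gene("g0")], {}, {"g0": True}, {"g0": True})

    def test_per_strain_split(self):
        genes = [make_gene(f"g{i}") for i in range(2)]
        flags = {g.id: True for g in genes}
        off = {g.id: False for g in genes}
        _, summary = integrate_evidence(
            genes, flags, off, off, strain_of={"g0": "A", "g1": "B"}
        )
        assert set(summary.strain) == {"A", "B", "overall"}


class TestRegionOverlap:
    def test_identical_sets(self):
        genes = [make_gene("g", start=100, end=200)]
        assert region_overlap_agreement([("s1", 100, 200)], genes) == 1.0

    def test_single_shared_base_counts(self):
        genes = [make_gene("g", start=100, end=200)]
        assert region_overlap_agreement([("s1", 200, 300)], genes) == 1.0
        assert region_overlap_agreement([("s1", 201, 300)], genes) == 0.0

    def test_absent_scaffold(self):
        genes = [make_gene("g", scaffold="s9", start=100, end=200)]
        assert region_overlap_agreement([("s1", 1, 10_000)], genes) == 0.0
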