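"""Conservation averaging, SNP density, host-transcript assignment, context."""

import numpy as np
import pytest

from oracles import per_base_mean_score
from snofam import genomics
from snofam.core_io import (ConservationTrack, Family, Gene, HostModel,
                            SNPSet, SnoRNARecord, Transcript)


def make_sno(start, end, strand="+", host="G1", biotype="coding", sid="s1"):
    return SnoRNARecord(sid, sid, "CD", "F1", "A" * (end - start), "chr1",
                        start, end, strand, host_gene_id=host,
                        host_biotype=biotype)


class TestConservation:
    def test_uniform_track(self):
        track = ConservationTrack([("chr1", 0, 100, 0.8)])
        sno = make_sno(10, 20)
        assert genomics.conservation_score(sno, track) == pytest.approx(0.8)

    def test_partial_coverage_counts_uncovered_as_zero(self):
        track = ConservationTrack([("chr1", 0, 100, 0.8)])
        sno = make_sno(90, 110)  # 10 nt at 0.8, 10 nt uncovered
        assert genomics.conservation_score(sno, track) == pytest.approx(0.4)
        # dropping uncovered bases instead gives the covered-only mean
        assert genomics.conservation_score(
            sno, track, uncovered_zero=False) == pytest.approx(0.8)

    def test_empty_track_scores_zero(self):
        assert genomics.conservation_score(
            make_sno(0, 50), ConservationTrack([])) == 0.0

    def test_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            edges = np.sort(rng.choice(np.arange(0, 200), 8, replace=False))
            intervals = [("chr1", int(edges[i]), int(edges[i + 1]),
                          round(float(rng.uniform(0, 1)), 3))
                         for i in range(0, 6, 2)]
            track = ConservationTrack(intervals)
            s = int(rng.integers(0, 150))
            e = s + int(rng.integers(1, 50))
            sno = make_sno(s, e)
            expected = per_base_mean_score(
                [(a, b, v) for _, a, b, v in intervals], s, e)
            assert genomics.conservation_score(sno, track) == pytest.approx(expected)

    def test_invariant_under_interval_splitting(self):
        whole = ConservationTrack([("chr1", 0, 100, 0.6)])
        split = ConservationTrack([("chr1", 0, 33, 0.6), ("chr1", 33, 71, 0.6),
                                   ("chr1", 71, 100, 0.6)])
        sno = make_sno(5, 95)
        assert genomics.conservation_score(sno, whole) == pytest.approx(
            genomics.conservation_score(sno, split))


class TestSnpDensity:
    @pytest.mark.parametrize("n_snps, length, expected", [
        (0, 100, 0.0), (2, 100, 20.0), (1, 80, 12.5),
    ])
    def test_formula(self, n_snps, length, expected):
        sno = make_sno(1000, 1000 + length)
        snps = SNPSet([("chr1", 1000 + 3 * i) for i in range(n_snps)])
        assert genomics.snp_density(sno, snps) == pytest.approx(expected)

    def test_linear_scaling(self):
        rng = np.random.default_rng(4)
        length = 120
        sno = make_sno(0, length)
        positions = rng.choice(length, size=30, replace=False)
        for k in (5, 10, 30):
            snps = SNPSet([("chr1", int(p)) for p in positions[:k]])
            assert genomics.snp_density(sno, snps) == pytest.approx(
                1000.0 * k / length)


def _plus_host():
    # exons 800-900 and 1170-1250; intron hosts the snoRNA at 1000-1100
    t = Transcript("T1", "T1", "+", ((800, 900), (1170, 1250)))
    return HostModel({"G1": Gene("G1", "chr1", "+", "coding", (t,))})


class TestHostAssignment:
    def test_plus_strand_distance(self):
        sno = make_sno(1000, 1100, strand="+")
        pl = genomics.assign_host_transcript(sno, _plus_host())
        assert pl.intronic
        assert pl.distance_to_downstream_exon == 70

    def test_minus_strand_mirror(self):
        # reflect the plus-strand geometry around position 2000
        t = Transcript("T1", "T1", "-", ((750, 830), (1100, 1200)))
        host = HostModel({"G1": Gene("G1", "chr1", "-", "coding", (t,))})
        sno = make_sno(900, 1000, strand="-")
        pl = genomics.assign_host_transcript(sno, host)
        assert pl.intronic
        # 3' end of a minus-strand snoRNA is its genomic start (900); the
        # downstream exon in transcript orientation ends at 830
        assert pl.distance_to_downstream_exon == 70

    def test_exonic_in_every_transcript_is_not_intronic(self):
        t = Transcript("T1", "T1", "+", ((900, 1200),))
        host = HostModel({"G1": Gene("G1", "chr1", "+", "coding", (t,))})
        pl = genomics.assign_host_transcript(make_sno(1000, 1100), host)
        assert not pl.intronic
        assert pl.distance_to_downstream_exon is None

    def test_exon_count_then_name_sort(self):
        # T_b has more exons than T_a? no: equal counts, name breaks the tie
        exons = ((800, 900), (1170, 1250))
        tb = Transcript("t2", "T_b", "+", exons)
        ta = Transcript("t1", "T_a", "+", exons)
        host = HostModel({"G1": Gene("G1", "chr1", "+", "coding", (tb, ta))})
        pl = genomics.assign_host_transcript(make_sno(1000, 1100), host)
        assert pl.transcript_id == "t1"

    def test_overlapping_transcript_skipped_for_more_exons(self):
        # the 3-exon transcript covers the snoRNA with an exon, so the 2-exon
        # transcript is chosen despite sorting later
        t3 = Transcript("t3", "T_big", "+",
                        ((800, 900), (1000, 1100), (1170, 1250)))
        t2 = Transcript("t2", "T_small", "+", ((800, 900), (1170, 1250)))
        host = HostModel({"G1": Gene("G1", "chr1", "+", "coding", (t3, t2))})
        pl = genomics.assign_host_transcript(make_sno(1000, 1100), host)
        assert pl.transcript_id == "t2"
        assert pl.distance_to_downstream_exon == 70

    def test_generator_distances_recovered(self, default_bundle, default_result):
        """Planted intron distances recovered exactly across the cohort."""
        truth = default_bundle.truth_snorna.set_index("snorna_id")
        sno = default_result.sno_summary.set_index("snorna_id")
        got = sno["distance_to_downstream_exon"].astype(str)
        want = truth["intron_distance"].astype(str)
        hosted = want != "."
        assert hosted.sum() > 100
        assert (got.loc[hosted.index[hosted]] == want[hosted]).all()


class TestContext:
    def _family(self, biotypes, statuses=None, hosts=None):
        ids = tuple(f"m{i}" for i in range(len(biotypes)))
        fam = Family("F", "CD", ids)
        records = {}
        for i, (mid, bt) in enumerate(zip(ids, biotypes)):
            host = None if bt == "intergenic" else (
                hosts[i] if hosts else f"G{i}")
            records[mid] = SnoRNARecord(
                mid, mid, "CD", "F", "ACGT", "chr1", 100 * i, 100 * i + 4, "+",
                host_gene_id=host, host_biotype=bt)
        st = statuses or {m: True for m in ids}
        return fam, records, st

    @pytest.mark.parametrize("biotypes, category", [
        (["coding", "coding"], "coding_only"),
        (["coding", "noncoding"], "mixed"),
        (["intergenic", "intergenic"], "intergenic_only"),
        (["coding", "intergenic"], "mixed"),
    ])
    def test_categories(self, biotypes, category):
        fam, records, st = self._family(biotypes)
        call = genomics.classify_family_context(fam, records, st)
        assert call.category == category

    def test_same_host_requires_shared_gene(self):
        fam, records, st = self._family(["coding", "coding"],
                                        hosts=["G1", "G1"])
        assert genomics.classify_family_context(fam, records, st).same_host
        fam, records, st = self._family(["coding", "coding"],
                                        hosts=["G1", "G2"])
        assert genomics.classify_family_context(fam, records, st).same_host is False

    def test_same_host_undefined_below_two_expressed(self):
        fam, records, _ = self._family(["coding", "coding"], hosts=["G1", "G1"])
        st = {"m0": True, "m1": False}
        assert genomics.classify_family_context(fam, records, st).same_host is None

    def test_expressed_only_with_no_expressed_is_undefined(self):
        fam, records, _ = self._family(["coding", "coding"])
        st = {"m0": False, "m1": False}
        call = genomics.classify_family_context(fam, records, st,
                                                expressed_only=True)
        assert call.category == genomics.UNDEFINED_CATEGORY

    def test_categories_partition_families(self, default_result):
        """Category counts sum to the family count for both settings."""
        fam = default_result.family_summary
        for col in ("context_category", "context_category_expressed"):
            assert fam[col].value_counts().sum() == len(fam)
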