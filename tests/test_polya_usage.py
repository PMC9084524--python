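"""PolyA-site pipeline: cleavage inference, clustering, priming filter,
usage testing and representative-pair selection."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from placentakit import polya_usage as pa
from placentakit import synthetic_data as sd
from placentakit.polya_usage import PolyASite, ThreePrimeRead


class TestInferCleavage:
    @pytest.mark.parametrize(
        "aln_strand,pos,expected",
        [("+", 1000, ("chr1", "-", 1000)), ("-", 2000, ("chr1", "+", 2000))],
    )
    def test_strand_inversion(self, aln_strand, pos, expected):
        read = ThreePrimeRead("chr1", aln_strand, pos, "s1")
        assert pa.infer_cleavage_site(read) == expected

    def test_bed_fixture_matches_hand_table(self, tmp_path):
        bed = tmp_path / "reads.bed"
        bed.write_text(
            "chr1\t99\t150\ts1\t0\t+\n"
            "chr1\t200\t250\ts1\t0\t-\n"
            "chr2\t9\t60\ts2\t0\t+\n"
            "chr2\t400\t460\ts2\t0\t-\n"
        )
        reads = pa.read_three_prime_bed(bed)
        sites = [pa.infer_cleavage_site(r) for r in reads]
        assert sites == [
            ("chr1", "-", 100),  # + alignment: 5' end = start+1
            ("chr1", "+", 250),  # - alignment: 5' end = end
            ("chr2", "-", 10),
            ("chr2", "+", 460),
        ]


class TestCallSites:
    def test_all_reads_one_position(self):
        reads = [ThreePrimeRead("c", "-", 500, "s1") for _ in range(7)]
        sites = pa.call_sites(reads)
        assert len(sites) == 1
        assert (sites[0].position, sites[0].support) == (500, 7)

    def test_two_clusters_200nt_apart(self):
        reads = [ThreePrimeRead("c", "-", 500 + d, "s1") for d in (-3, 0, 0, 2)]
        reads += [ThreePrimeRead("c", "-", 700 + d, "s1") for d in (0, 0, 1)]
        sites = sorted(pa.call_sites(reads, tolerance=50), key=lambda s: s.position)
        assert [s.position for s in sites] == [500, 700]
        assert [s.support for s in sites] == [4, 3]

    def test_spread_within_tolerance_single_site_at_mode(self):
        positions = [480, 490, 500, 500, 500, 510, 520]
        reads = [ThreePrimeRead("c", "-", p, "s1") for p in positions]
        sites = pa.call_sites(reads, tolerance=50)
        assert len(sites) == 1
        assert sites[0].position == 500
        assert sites[0].support == len(positions)

    def test_assignment_partitions_reads(self):
        rng = np.random.default_rng(0)
        reads = [
            ThreePrimeRead("c", "-", int(p), "s1")
            for p in np.concatenate(
                [rng.normal(1000, 8, 50), rng.normal(1500, 8, 30)]
            ).round()
        ]
        sites = pa.call_sites(reads, tolerance=50)
        assert sum(s.support for s in sites) == len(reads)
        positions = sorted(s.position for s in sites)
        assert all(b - a > 50 for a, b in zip(positions, positions[1:]))

    def test_min_support_stops_clustering(self):
        reads = [ThreePrimeRead("c", "-", 100, "s1")] * 5 + [
            ThreePrimeRead("c", "-", 900, "s1")
        ]
        sites = pa.call_sites(reads, min_support=3)
        assert [s.position for s in sites] == [100]


class TestInternalPrimingFilter:
    def make_genome(self, mid: str) -> dict:
        # site at position 101 on '+' mRNA strand; `mid` controls context
        return {"c": mid}

    def test_signal_site_kept(self):
        # AATAAA 25 nt upstream of position 101, non-A downstream
        seq = "C" * 70 + "AATAAA" + "C" * 25 + "G" * 40
        site = PolyASite("c", "+", 101, 10)
        kept = pa.filter_internal_priming([site], {"c": seq})
        assert kept == [site]
        assert site.signal_ok is True

    def test_a_tract_without_signal_removed(self):
        seq = "C" * 100 + "G" + "A" * 18 + "C" * 40
        site = PolyASite("c", "+", 101, 10)
        kept, removed = pa.filter_internal_priming(
            [site], {"c": seq}, return_removed=True
        )
        assert kept == []
        assert "A-rich" in removed[0][1]

    def test_a_tract_with_signal_kept(self):
        seq = "C" * 70 + "AATAAA" + "C" * 25 + "A" * 18 + "C" * 40
        site = PolyASite("c", "+", 101, 10)
        assert pa.filter_internal_priming([site], {"c": seq}) == [site]

    def test_minus_strand_site(self):
        # mRNA '-' strand: signal upstream means higher genomic coords,
        # AATAAA in mRNA sense = TTTATT genomic; downstream = lower coords.
        seq = "G" * 60 + "C" * 40 + "TTTATT" + "G" * 40
        # place site so the genomic window [pos+10, pos+40] contains TTTATT
        site = PolyASite("c", "-", 101 - 25, 10)
        kept = pa.filter_internal_priming([site], {"c": seq})
        assert kept and kept[0].signal_ok

    def test_empty_site_list(self):
        assert pa.filter_internal_priming([], {"c": "ACGT"}) == []

    def test_synthetic_decoys_removed(self):
        reads, genome, models = sd.gen_three_prime_reads(
            depth=500, ip_rate=0.2, seed=8
        )
        sites = pa.call_sites(reads)
        kept, removed = pa.filter_internal_priming(
            sites, genome, return_removed=True
        )
        decoy = models[0].decoy_pos
        decoy_sites = [s for s in sites if abs(s.position - decoy) <= 50]
        removed_positions = {s.position for s, _ in removed}
        assert decoy_sites
        assert all(s.position in removed_positions for s in decoy_sites)
        true_positions = sorted(s.position for s in kept)
        assert len(true_positions) == 2


def make_pair_with_counts(prox_counts: dict, dist_counts: dict) -> pa.PolyAPair:
    prox = PolyASite("c", "+", 100, sum(prox_counts.values()), dict(prox_counts))
    dist = PolyASite("c", "+", 600, sum(dist_counts.values()), dict(dist_counts))
    return pa.PolyAPair("g", prox, dist)


class TestProximalUsage:
    def test_zero_proximal(self):
        pair = make_pair_with_counts({"s1": 0}, {"s1": 50})
        assert pa.proximal_usage(pair, "s1") == 0.0

    def test_equal_counts(self):
        pair = make_pair_with_counts({"s1": 25}, {"s1": 25})
        assert pa.proximal_usage(pair, "s1") == 50.0

    def test_zero_denominator_missing(self):
        pair = make_pair_with_counts({"s1": 1}, {"s1": 1})
        assert pa.proximal_usage(pair, "s2") is None

    def test_scale_invariance(self):
        p1 = make_pair_with_counts({"s1": 10}, {"s1": 30})
        p2 = make_pair_with_counts({"s1": 50}, {"s1": 150})
        assert pa.proximal_usage(p1, "s1") == pa.proximal_usage(p2, "s1")

    def test_mbd2_like_shift_recovered(self):
        """Proximal usage ~0% in WT and ~50% in DKO, as planted."""
        reads, genome, models = sd.gen_three_prime_reads(
            usage={"WT": 0.02, "DKO": 0.5}, depth=1000, ip_rate=0.0, seed=12
        )
        sites = pa.call_sites(reads)
        top2 = sorted(sites, key=lambda s: -s.support)[:2]
        pair = pa.make_pair("Mbd2like", *top2)
        wt = np.mean([pa.proximal_usage(pair, f"WT_{i}") for i in (1, 2)])
        dko = np.mean([pa.proximal_usage(pair, f"DKO_{i}") for i in (1, 2)])
        assert wt < 7.0
        assert dko == pytest.approx(50.0, abs=5.0)


class TestPairTest:
    def test_identical_fractions_ns(self):
        pair = make_pair_with_counts(
            {"KO_1": 20, "WT_1": 40}, {"KO_1": 20, "WT_1": 40}
        )
        (res,) = pa.test_pairs(
            [pair], {"KO_1": "KO", "WT_1": "WT"}, [("KO", "WT")]
        )
        assert res.status == "ns"
        assert res.log2fc == 0.0

    def test_strong_shift_called_enhanced(self):
        pair = make_pair_with_counts(
            {"KO_1": 900, "WT_1": 100}, {"KO_1": 100, "WT_1": 900}
        )
        (res,) = pa.test_pairs(
            [pair], {"KO_1": "KO", "WT_1": "WT"}, [("KO", "WT")]
        )
        assert res.status == "enhanced"
        assert res.fdr < 0.1
        # cross-check the p-value against a direct Fisher test
        _, p = sps.fisher_exact([[900, 100], [100, 900]])
        assert res.pvalue == pytest.approx(p)

    def test_doubling_both_sites_stays_ns(self):
        pair = make_pair_with_counts(
            {"KO_1": 400, "WT_1": 200}, {"KO_1": 1200, "WT_1": 600}
        )
        (res,) = pa.test_pairs(
            [pair], {"KO_1": "KO", "WT_1": "WT"}, [("KO", "WT")]
        )
        assert res.status == "ns"
        assert res.log2fc == pytest.approx(0.0)

    def test_zero_margin_flagged(self):
        pair = make_pair_with_counts({"KO_1": 0, "WT_1": 0}, {"KO_1": 50, "WT_1": 50})
        (res,) = pa.test_pairs(
            [pair], {"KO_1": "KO", "WT_1": "WT"}, [("KO", "WT")]
        )
        assert res.continuity_corrected


class TestSelectRepresentativePair:
    def run(self, pairs, sig_counts, fcs, **kw):
        results = []
        for pair, n_sig, fc in zip(pairs, sig_counts, fcs):
            for i in range(3):
                status = "enhanced" if i < n_sig else "ns"
                results.append(
                    pa.PairTestResult(pair.pair_id, pair.gene_id, f"cmp{i}",
                                      fc, 0.001, 0.001 if i < n_sig else 0.9, status)
                )
        return pa.select_representative_pair(pairs, results, **kw)

    def pair_with_reads(self, gene, prox_pos, reads):
        prox = PolyASite("c", "+", prox_pos, reads // 2, {"s": reads // 2})
        dist = PolyASite("c", "+", prox_pos + 500, reads - reads // 2,
                         {"s": reads - reads // 2})
        return pa.PolyAPair(gene, prox, dist)

    def test_single_pair_selected_via_rule_i(self):
        pair = self.pair_with_reads("g", 100, 200)
        sel, trace = self.run([pair], [1], [2.0])
        assert sel is pair
        assert any("(i)" in t for t in trace)

    def test_largest_fc_candidate_with_sufficient_reads(self):
        a = self.pair_with_reads("g", 100, 200)   # 2 significant, |FC|=2
        b = self.pair_with_reads("g", 2000, 1000)  # 1 significant, max reads
        sel, _ = self.run([a, b], [2, 1], [2.0, 0.5])
        assert sel is a  # 200 >= 0.15 * 1000

    def test_low_read_candidate_falls_through_to_max_read_pair(self):
        a = self.pair_with_reads("g", 100, 100)    # candidate, 0.10 * max reads
        b = self.pair_with_reads("g", 2000, 1000)
        sel, trace = self.run([a, b], [2, 1], [2.0, 0.5])
        assert sel is b
        assert any("(ii)" in t for t in trace)

    def test_rule_iii_and_discard_without_fallback(self):
        a = self.pair_with_reads("g", 100, 100)  # 0.10 of max: below both cuts
        b = self.pair_with_reads("g", 2000, 1000)
        sel, trace = self.run([a, b], [2, 1], [2.0, 0.5], max_read_fallback=False)
        assert sel is None
        assert any("(iv)" in t for t in trace)
        # with a raised rule-(i) cutoff, a 0.35-of-max candidate fails (i)
        # but clears the 30% rescue threshold of rule (iii)
        a2 = self.pair_with_reads("g", 100, 350)
        sel2, trace2 = self.run([a2, b], [2, 1], [2.0, 0.5],
                                read_frac_1=0.5, max_read_fallback=False)
        assert sel2 is a2
        assert any("(iii)" in t for t in trace2)

    def test_selection_is_deterministic(self):
        a = self.pair_with_reads("g", 100, 500)
        b = self.pair_with_reads("g", 2000, 500)
        sel1, _ = self.run([a, b], [1, 1], [1.0, 1.0])
        sel2, _ = self.run([b, a], [1, 1], [1.0, 1.0])
        assert sel1.pair_id == sel2.pair_id


def test_bed_roundtrip(tmp_path):
    reads, _, _ = sd.gen_three_prime_reads(depth=50, seed=2)
    path = tmp_path / "reads.bed"
    sd.write_reads_bed(reads, path)
    back = pa.read_three_prime_bed(path)
    assert [(r.chrom, r.alignment_strand, r.five_prime_pos, r.sample_id)
            for r in back] == [
        (r.chrom, r.alignment_strand, r.five_prime_pos, r.sample_id) for r in reads
    ]


def test_genome_fasta_roundtrip(tmp_path):
    _, genome, _ = sd.gen_three_prime_reads(depth=10, seed=2)
    path = tmp_path / "genome.fa"
    sd.write_genome_fasta(genome, path)
    assert pa.read_genome_fasta(path) == genome
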