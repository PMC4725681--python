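"""Demultiplexing, primer trimming, exact clustering, and conclusions."""

import numpy as np
import pytest

from nucbarcode.core_io import SeqRecord, reverse_complement
from nucbarcode.insilico_pcr import ReferenceRecord, ReferenceSet
from nucbarcode.primer_design import PrimerPair
from nucbarcode.quantification import CValueTable
from nucbarcode.read_assignment import (Cluster, ConfigurationError,
                                        MidScheme, TrimmedRead, assign_reads,
                                        cluster_exact, conclude_clusters,
                                        demultiplex, lineage_summary,
                                        orient_and_trim, taxonomy_summary)
from nucbarcode.synthetic_data import (MID1, MID2, LocusModel,
                                       default_mid_scheme, simulate_genomes,
                                       simulate_reads)
from nucbarcode.insilico_pcr import build_reference_set, GENOME_PRESET
from conftest import mutate, random_dna

F = "TCCTTCTGGATGTTGTAGTC"
R = "AAGATGCAGATCTTCGTGAA"
PAIR = PrimerPair("23579-aaa", F, R)


def refset_of(inners_by_species):
    refset = ReferenceSet()
    for taxid, inners in inners_by_species.items():
        for i, inner in enumerate(inners):
            refset.add(ReferenceRecord(inner, taxid, "genome", f"g{taxid}:{i}"))
    return refset


class TestMidScheme:
    def test_published_mids_are_valid(self):
        scheme = MidScheme({"s1": (MID1, MID1), "s2": (MID2, MID2)})
        assert scheme.mid_length == 10

    def test_duplicate_mid_across_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            MidScheme({"s1": (MID1, MID1), "s2": (MID1, MID2)})

    def test_near_identical_mids_rejected(self):
        near = MID1[:-1] + ("A" if MID1[-1] != "A" else "C")
        with pytest.raises(ConfigurationError, match="fewer than 2"):
            MidScheme({"s1": (MID1, MID1), "s2": (near, near)})


class TestDemultiplex:
    def test_mid1_prefix_routes_and_strips(self):
        scheme = MidScheme({"s1": (MID1, MID1), "s2": (MID2, MID2)})
        payload = "TCCTTCTGGA"
        bins, unassigned = demultiplex([SeqRecord("r", MID1 + payload)], scheme)
        assert [r.sequence for r in bins["s1"]] == [payload]
        assert bins["s2"] == [] and unassigned == []

    def test_unmatched_prefix_unassigned(self):
        scheme = default_mid_scheme()
        bins, unassigned = demultiplex([SeqRecord("r", "T" * 40)], scheme)
        assert unassigned and not bins["sample1"]

    def test_simulated_routing_matches_ledger(self, tax):
        genomes, ledger = simulate_genomes([4577, 3847], LocusModel(copies=2),
                                           seed=61)
        scheme = MidScheme({"s1": (MID1, MID1), "s2": (MID2, MID2)})
        cvalues = CValueTable({4577: 2.73, 3847: 1.13})
        reads1, led1 = simulate_reads({4577: 1.0}, cvalues, ledger, PAIR,
                                      scheme, 500, error_rate=0.0, seed=61,
                                      sample="s1")
        reads2, led2 = simulate_reads({3847: 1.0}, cvalues, ledger, PAIR,
                                      scheme, 500, error_rate=0.0, seed=62,
                                      sample="s2")
        pooled = []
        for i, r in enumerate(reads1 + reads2):
            pooled.append(SeqRecord(f"p{i}", r.sequence))
        bins, unassigned = demultiplex(pooled, scheme)
        assert len(bins["s1"]) + len(bins["s2"]) + len(unassigned) == 1000
        assert len(bins["s1"]) == 500 and len(bins["s2"]) == 500


class TestOrientAndTrim:
    def test_forward_read_trimmed(self, rng):
        inner = random_dna(rng, 154)
        (t,), rejected = orient_and_trim(
            [SeqRecord("r", F + inner + reverse_complement(R))], PAIR)
        assert t.inner == inner and t.orientation == "+"
        assert rejected == []

    def test_reverse_read_reoriented(self, rng):
        inner = random_dna(rng, 154)
        read = R + reverse_complement(inner) + reverse_complement(F)
        (t,), _ = orient_and_trim([SeqRecord("r", read)], PAIR)
        assert t.inner == inner and t.orientation == "-"

    def test_missing_3prime_primer_is_tolerated(self, rng):
        inner = random_dna(rng, 154)
        (t,), rejected = orient_and_trim([SeqRecord("r", F + inner)], PAIR)
        assert t.inner == inner
        assert rejected == []

    def test_no_5prime_primer_rejected(self, rng):
        trimmed, rejected = orient_and_trim(
            [SeqRecord("r", random_dna(rng, 100))], PAIR)
        assert trimmed == [] and len(rejected) == 1

    def test_primer_errors_within_budget_recovered(self):
        rng = np.random.default_rng(67)
        for n_err in (1, 2):
            inner = random_dna(rng, 154)
            read = (mutate(rng, F, n_err) + inner
                    + reverse_complement(mutate(rng, R, n_err)))
            (t,), _ = orient_and_trim([SeqRecord("r", read)], PAIR,
                                      max_trim_errors=2)
            assert t.inner == inner

    def test_three_primer_errors_rejected_at_budget_two(self):
        rng = np.random.default_rng(68)
        inner = random_dna(rng, 154)
        # corrupt both primers so neither end anchors
        read = (mutate(rng, F, 3) + inner
                + reverse_complement(mutate(rng, R, 3)))
        trimmed, rejected = orient_and_trim([SeqRecord("r", read)], PAIR,
                                            max_trim_errors=2)
        assert len(rejected) == 1


class TestClusterExact:
    def test_reads_and_reference_cluster_together(self):
        refset = refset_of({4577: ["AAAA"]})
        reads = [TrimmedRead("r1", "AAAA", "+"), TrimmedRead("r2", "AAAA", "-")]
        (cluster,) = cluster_exact(reads, refset)
        assert cluster.category == "mixed"
        assert cluster.n_reads == 2 and cluster.n_refs == 1

    def test_single_difference_splits_clusters(self):
        refset = refset_of({4577: ["AAAA"]})
        clusters = cluster_exact([TrimmedRead("r1", "AAAT", "+")], refset)
        categories = sorted(c.category for c in clusters)
        assert categories == ["reads_only", "refs_only"]

    def test_length_difference_splits_clusters(self):
        refset = refset_of({4577: ["AAAA"]})
        clusters = cluster_exact([TrimmedRead("r1", "AAAAA", "+")], refset)
        assert sorted(c.category for c in clusters) == \
               ["reads_only", "refs_only"]

    def test_partition_equals_group_by_oracle(self):
        rng = np.random.default_rng(71)
        pool = [random_dna(rng, 40) for _ in range(600)]
        reads = [TrimmedRead(f"r{i}", pool[int(rng.integers(600))], "+")
                 for i in range(10_000)]
        refset = refset_of({int(rng.integers(1, 5)): [pool[i]]
                            for i in rng.choice(600, 50, replace=False)})
        clusters = cluster_exact(reads, refset)
        oracle: dict[str, list[str]] = {}
        for read in reads:
            oracle.setdefault(read.inner, []).append(read.id)
        for ref in refset.records:
            oracle.setdefault(ref.inner_sequence, [])
        assert len(clusters) == len(oracle)
        for c in clusters:
            assert sorted(c.read_ids) == sorted(oracle[c.representative])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(72)
        reads = [TrimmedRead(f"r{i}", random_dna(rng, 10), "+")
                 for i in range(50)]
        refset = refset_of({1: [reads[0].inner]})
        a = cluster_exact(reads, refset)
        b = cluster_exact(reads[::-1], refset)
        assert {c.representative: sorted(c.read_ids) for c in a} == \
               {c.representative: sorted(c.read_ids) for c in b}


class TestConclusions:
    def test_multi_species_cluster_concludes_at_lca(self, tax):
        cluster = Cluster("AAAA", read_ids=["r1"])
        cluster.reference_records = [
            ReferenceRecord("AAAA", tax.taxid_of("Triticum aestivum"), "db", "x"),
            ReferenceRecord("AAAA", tax.taxid_of("Zea mays"), "db", "y"),
        ]
        report = conclude_clusters([cluster], tax)
        assert tax.name_of(report.table[0].conclusion) == "Poaceae"

    def test_single_species_cluster_concludes_at_species(self, tax):
        zea = tax.taxid_of("Zea mays")
        cluster = Cluster("AAAA", read_ids=["r1", "r2"])
        cluster.reference_records = [
            ReferenceRecord("AAAA", zea, "db", "x"),
            ReferenceRecord("AAAA", zea, "db", "y")]
        report = conclude_clusters([cluster], tax)
        assert report.table[0].conclusion == zea

    def test_report_ordering_and_totals(self, tax):
        zea = tax.taxid_of("Zea mays")
        clusters = []
        for i, (seq, n) in enumerate([("CCCC", 3), ("AAAA", 7), ("GGGG", 3)]):
            c = Cluster(seq, read_ids=[f"{seq}{j}" for j in range(n)])
            c.reference_records = [ReferenceRecord(seq, zea, "db", f"s{i}")]
            clusters.append(c)
        clusters.append(Cluster("TTTT", read_ids=["u1", "u2"]))  # reads-only
        clusters.append(Cluster("TTAA",
                                reference_records=[
                                    ReferenceRecord("TTAA", zea, "db", "z")]))
        report = conclude_clusters(clusters, tax)
        assert [c.representative for c in report.table] == \
               ["AAAA", "CCCC", "GGGG"]  # desc reads, ties lexicographic
        assert report.totals["assigned"] == 13
        assert report.totals["unassigned"] == 2
        assert report.totals["assigned"] + report.totals["unassigned"] == \
               report.totals["trimmed"]
        assert len(report.refs_only) == 1

    def test_taxonomy_summary_conserves_reads(self, tax):
        zea = tax.taxid_of("Zea mays")
        triticum = tax.taxid_of("Triticum aestivum")
        c1 = Cluster("AAAA", read_ids=["a"] * 10,
                     reference_records=[ReferenceRecord("AAAA", zea, "db", "x")])
        c2 = Cluster("CCCC", read_ids=["b"] * 4,
                     reference_records=[
                         ReferenceRecord("CCCC", zea, "db", "y"),
                         ReferenceRecord("CCCC", triticum, "db", "z")])
        report = conclude_clusters([c1, c2], tax)
        summary = taxonomy_summary(report, tax)
        assert summary[zea] == (1, 10)
        assert summary[tax.taxid_of("Poaceae")] == (1, 4)
        assert sum(n for _, n in summary.values()) == \
               report.totals["assigned"]
        cumulative = lineage_summary(report, tax)
        assert cumulative[tax.root] == (2, 14)
        assert cumulative[tax.taxid_of("Poaceae")] == (2, 14)
        assert cumulative[zea] == (1, 10)


def test_count_conservation_through_full_chain(tax):
    genomes, ledger = simulate_genomes([4577, 3847], LocusModel(copies=2),
                                       seed=80)
    scheme = default_mid_scheme()
    cvalues = CValueTable({4577: 2.73, 3847: 1.13})
    reads, _ = simulate_reads({4577: 0.5, 3847: 0.5}, cvalues, ledger, PAIR,
                              scheme, 600, error_rate=0.02, seed=81)
    refset = build_reference_set(PAIR, genomes, GENOME_PRESET)
    report = assign_reads(reads, PAIR, refset, tax, scheme=scheme)
    t = report.totals
    assert t["reads_in"] == 600
    assert t["demux_assigned"] + (600 - t["demux_assigned"]) == 600
    assert t["trimmed"] + t["rejected_at_trim"] == t["demux_assigned"]
    assert t["assigned"] + t["unassigned"] == t["trimmed"]


def test_conclusions_never_leave_source_lineage(tax):
    """Pure-species reads at 1% error never conclude off-lineage."""
    cvalues = CValueTable({4577: 2.73, 3847: 1.13})
    for seed in range(100, 120):
        genomes, ledger = simulate_genomes([4577, 3847],
                                           LocusModel(copies=2,
                                                      inner_divergence=0.05),
                                           seed=seed)
        refset = build_reference_set(PAIR, genomes, GENOME_PRESET)
        scheme = default_mid_scheme()
        reads, _ = simulate_reads({4577: 1.0}, cvalues, ledger, PAIR, scheme,
                                  200, error_rate=0.01, seed=seed)
        report = assign_reads(reads, PAIR, refset, tax, scheme=scheme)
        lineage = set(tax.lineage(4577))
        for cluster in report.table:
            assert cluster.conclusion in lineage
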