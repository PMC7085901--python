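"""Two-step junction workflow: aligner vs exhaustive oracle, calling, quantification."""

import numpy as np
import pytest

from spliceoform.gene_models import enumerate_junctions
from spliceoform.junction_analysis import (
    JunctionCounts,
    MappingParams,
    apply_min_abundance_filter,
    call_isoforms,
    count_junction_reads,
    filter_reads_to_gene_regions,
    quantify_transcripts,
)
from spliceoform.synthetic_data import ReadSimParams, simulate_reads

from oracle import BruteRefs, brute_junction_counts, brute_matches_any


def _mixed_reads(fixture, n_pairs, seed, error_rate=0.005, include_normalizer=True):
    txs = fixture.transcripts_by_role()
    abundances = {
        txs["canonical"].transcript_id: 10.0,
        txs["isoform"].transcript_id: 1.0,
    }
    if include_normalizer:
        abundances[txs["normalizer"].transcript_id] = 5.0
    return simulate_reads(
        {t.transcript_id: t for t in txs.values()},
        abundances,
        ReadSimParams(library_size=n_pairs, error_rate=error_rate, seed=seed),
    )


class TestFilterStep:
    def test_normalizer_reads_not_retained(self, fixture, gene_regions, junction_library):
        txs = fixture.transcripts_by_role()
        reads = simulate_reads(
            {txs["normalizer"].transcript_id: txs["normalizer"]},
            {txs["normalizer"].transcript_id: 1.0},
            ReadSimParams(library_size=150, error_rate=0.0, seed=1),
        )
        kept = filter_reads_to_gene_regions(reads, gene_regions, MappingParams(), junction_library)
        assert len(kept) == 0

    def test_error_free_canonical_reads_all_retained(self, fixture, gene_regions, junction_library):
        txs = fixture.transcripts_by_role()
        reads = simulate_reads(
            {txs["canonical"].transcript_id: txs["canonical"]},
            {txs["canonical"].transcript_id: 1.0},
            ReadSimParams(library_size=150, error_rate=0.0, seed=2),
        )
        kept = filter_reads_to_gene_regions(reads, gene_regions, MappingParams(), junction_library)
        assert len(kept) == len(reads)

    def test_matches_brute_force_read_by_read(self, fixture, gene_regions, junction_library):
        reads = _mixed_reads(fixture, 100, seed=3, error_rate=0.02)
        params = MappingParams()
        kept = filter_reads_to_gene_regions(reads, gene_regions, params, junction_library)
        kept_ids = set(kept.ids)
        refs = dict(gene_regions)
        for j in junction_library:
            refs[f"junction:{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}"] = j.sequence
        brute = BruteRefs(refs, reads.read_length)
        for rid, seq in zip(reads.ids, reads.sequences):
            assert (rid in kept_ids) == brute_matches_any(seq, brute, params.max_mismatches)


class TestCountingOracle:
    @pytest.mark.parametrize("error_rate,seed", [(0.0, 7), (0.02, 8)])
    def test_counts_equal_exhaustive_scan(self, fixture, junction_library, error_rate, seed):
        """Seed-and-extend junction counting equals the all-offsets Hamming scan."""
        reads = _mixed_reads(fixture, 300, seed=seed, error_rate=error_rate,
                             include_normalizer=False)
        params = MappingParams()
        got = count_junction_reads(reads, junction_library, params)
        expected, expected_amb = brute_junction_counts(reads, junction_library, params)
        assert got.counts == expected
        assert got.ambiguous_discarded == expected_amb

    def test_specificity_paralog_reads_never_count_for_dmrt1(self, fixture, junction_library):
        para = fixture.transcript_sequence("Dmrt2_canonical")
        reads = simulate_reads(
            {para.transcript_id: para}, {para.transcript_id: 1.0},
            ReadSimParams(library_size=400, error_rate=0.0, seed=9),
        )
        counts = count_junction_reads(reads, junction_library, MappingParams())
        assert all(c == 0 for (g, _, _), c in counts.counts.items() if g == "Dmrt1")
        # the same reads do support Dmrt2's own consecutive junctions
        assert sum(c for (g, u, d), c in counts.counts.items() if g == "Dmrt2") > 0

    def test_completeness_exactly_five_supported_junctions(self, fixture, junction_library):
        """Canonical + skip transcript at >=20x junction coverage: exactly
        {(1,2),(2,3),(3,4),(4,5),(1,4)} supported, every other pair zero."""
        reads = _mixed_reads(fixture, 3000, seed=10, error_rate=0.0,
                             include_normalizer=False)
        counts = count_junction_reads(reads, junction_library, MappingParams())
        dmrt1 = counts.for_gene("Dmrt1")
        supported = {pair for pair, c in dmrt1.items() if c > 0}
        assert supported == {(1, 2), (2, 3), (3, 4), (4, 5), (1, 4)}
        assert min(dmrt1[p] for p in supported) >= 20

    def test_exon_interior_read_counts_nowhere(self, fixture, junction_library, dmrt1):
        exon4 = dmrt1.exon_sequence(4, fixture.genome)  # 159 bp
        from spliceoform.synthetic_data import SimulatedReadSet
        import pandas as pd

        reads = SimulatedReadSet(
            ["r1/1"], [exon4[:150]],
            pd.DataFrame([{"fragment_id": "r1", "transcript_id": "x", "start": 0, "end": 150}]),
            150,
        )
        counts = count_junction_reads(reads, junction_library, MappingParams())
        assert sum(counts.counts.values()) == 0

    def test_read_centered_on_skip_junction_counts_once(self, fixture, junction_library):
        j = next(x for x in junction_library if x.key == ("Dmrt1", 1, 4))
        b = j.breakpoint_offset
        read = j.sequence[b - 75 : b + 75]
        from spliceoform.synthetic_data import SimulatedReadSet
        import pandas as pd

        reads = SimulatedReadSet(
            ["r1/1"], [read],
            pd.DataFrame([{"fragment_id": "r1", "transcript_id": "x", "start": 0, "end": 150}]),
            150,
        )
        counts = count_junction_reads(reads, junction_library, MappingParams())
        assert counts.get("Dmrt1", 1, 4) == 1
        assert sum(counts.counts.values()) == 1

    def test_ambiguous_reads_follow_policy(self, fixture):
        """Two genes with identical exon sequences force equal-mismatch hits."""
        from spliceoform.gene_models import GeneModel, GenomicInterval

        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        genome = {"sA": seq, "sB": seq}  # bit-identical scaffolds
        genes = [
            GeneModel("gA", [GenomicInterval("sA", 0, 300), GenomicInterval("sA", 500, 800)]),
            GeneModel("gB", [GenomicInterval("sB", 0, 300), GenomicInterval("sB", 500, 800)]),
        ]
        lib = enumerate_junctions(genes, 142, genome)
        junc = lib.junctions[0]
        b = junc.breakpoint_offset
        read = junc.sequence[b - 75 : b + 75]
        from spliceoform.synthetic_data import SimulatedReadSet
        import pandas as pd

        reads = SimulatedReadSet(
            ["r1/1"], [read],
            pd.DataFrame([{"fragment_id": "r1", "transcript_id": "x", "start": 0, "end": 150}]),
            150,
        )
        discard = count_junction_reads(reads, lib, MappingParams(ambiguous_policy="discard"))
        assert sum(discard.counts.values()) == 0
        assert discard.ambiguous_discarded == 1
        count_all = count_junction_reads(reads, lib, MappingParams(ambiguous_policy="count_all"))
        assert count_all.get("gA", 1, 2) == 1 and count_all.get("gB", 1, 2) == 1

    def test_fragment_contributes_at_most_once_per_junction(self, fixture, junction_library):
        """Both mates spanning the same junction yield a single count."""
        j = next(x for x in junction_library if x.key == ("Dmrt1", 2, 3))
        b = j.breakpoint_offset
        read = j.sequence[b - 75 : b + 75]
        from spliceoform.gene_models import reverse_complement
        from spliceoform.synthetic_data import SimulatedReadSet
        import pandas as pd

        reads = SimulatedReadSet(
            ["f/1", "f/2"], [read, reverse_complement(read)],
            pd.DataFrame([{"fragment_id": "f", "transcript_id": "x", "start": 0, "end": 150}]),
            150,
        )
        counts = count_junction_reads(reads, junction_library, MappingParams())
        assert counts.get("Dmrt1", 2, 3) == 1


def _counts(dmrt1, mapping, total=1000):
    base = {("Dmrt1", u, d): 0 for u in range(1, 6) for d in range(u + 1, 6)}
    base.update({("Dmrt1", u, d): c for (u, d), c in mapping.items()})
    return JunctionCounts(base, total_reads=total)


class TestIsoformCalling:
    def test_canonical_only(self, dmrt1):
        counts = _counts(dmrt1, {(1, 2): 50, (2, 3): 40, (3, 4): 45, (4, 5): 60})
        call = call_isoforms(counts, dmrt1, min_support=3)
        assert [t.transcript_id for t, _ in call.transcripts] == ["Dmrt1_canonical"]

    def test_skip_junction_adds_delta_ex2_ex3(self, dmrt1):
        counts = _counts(
            dmrt1, {(1, 2): 50, (2, 3): 40, (3, 4): 45, (4, 5): 60, (1, 4): 12}
        )
        call = call_isoforms(counts, dmrt1, min_support=3)
        names = {t.transcript_id: t for t, _ in call.transcripts}
        assert set(names) == {"Dmrt1_canonical", "Dmrt1_DeltaEx2Ex3"}
        assert names["Dmrt1_DeltaEx2Ex3"].exon_indices == (1, 4, 5)
        assert names["Dmrt1_DeltaEx2Ex3"].skipped_exons == (2, 3)

    def test_all_zero_counts_calls_nothing(self, dmrt1):
        call = call_isoforms(_counts(dmrt1, {}), dmrt1, min_support=3)
        assert call.transcripts == []

    def test_below_min_support_ignored(self, dmrt1):
        counts = _counts(
            dmrt1, {(1, 2): 50, (2, 3): 40, (3, 4): 45, (4, 5): 60, (1, 4): 2}
        )
        call = call_isoforms(counts, dmrt1, min_support=3)
        assert [t.transcript_id for t, _ in call.transcripts] == ["Dmrt1_canonical"]

    def test_skip_without_flanking_support_not_called(self, dmrt1):
        # (4,5) unsupported: the ΔEx2Ex3 chain 1-(1,4)-4-(4,5)-5 is incomplete
        counts = _counts(dmrt1, {(1, 2): 50, (2, 3): 40, (3, 4): 45, (1, 4): 12})
        call = call_isoforms(counts, dmrt1, min_support=3)
        assert all(t.transcript_id != "Dmrt1_DeltaEx2Ex3" for t, _ in call.transcripts)

    def test_multiple_skips_flagged_ambiguous(self, dmrt1):
        counts = _counts(
            dmrt1,
            {(1, 2): 50, (2, 3): 40, (3, 4): 45, (4, 5): 60, (1, 4): 12, (2, 4): 9},
        )
        call = call_isoforms(counts, dmrt1, min_support=3)
        assert set(call.ambiguous_junctions) == {(1, 4), (2, 4)}

    def test_absent_gene_warns_and_returns_empty(self, dmrt1):
        counts = JunctionCounts({("Other", 1, 2): 5}, total_reads=10)
        with pytest.warns(UserWarning, match="Dmrt1"):
            call = call_isoforms(counts, dmrt1, min_support=1)
        assert call.transcripts == []


class TestQuantification:
    def test_canonical_only_counts(self, dmrt1):
        counts = _counts(dmrt1, {(1, 2): 10, (2, 3): 10, (3, 4): 10, (4, 5): 10}, total=1000)
        call = call_isoforms(counts, dmrt1, min_support=3)
        quant = quantify_transcripts(counts, call, dmrt1).set_index("transcript_id")
        assert quant.loc["Dmrt1_canonical", "cpm"] == pytest.approx(10 / 1000 * 1e6)

    def test_shared_junction_excluded(self, dmrt1):
        counts = _counts(
            dmrt1, {(1, 2): 30, (2, 3): 30, (3, 4): 30, (4, 5): 999, (1, 4): 6},
            total=10_000,
        )
        call = call_isoforms(counts, dmrt1, min_support=3)
        quant = quantify_transcripts(counts, call, dmrt1).set_index("transcript_id")
        # canonical mean over its unique junctions (1,2),(2,3),(3,4) only
        assert quant.loc["Dmrt1_canonical", "cpm"] == pytest.approx(30 / 10_000 * 1e6)
        assert quant.loc["Dmrt1_DeltaEx2Ex3", "cpm"] == pytest.approx(6 / 10_000 * 1e6)
        assert quant.loc["Dmrt1_canonical", "unique_junctions"] == "1-2;2-3;3-4"

    def test_ten_to_one_recovered_within_30_percent(self, fixture, junction_library, dmrt1):
        """Junction-count quantification recovers an order-of-magnitude
        canonical:isoform ratio to within +-30% across seeds."""
        ratios = []
        for seed in range(10):
            reads = _mixed_reads(fixture, 20_000, seed=100 + seed, error_rate=0.001,
                                 include_normalizer=False)
            counts = count_junction_reads(reads, junction_library, MappingParams())
            call = call_isoforms(counts, dmrt1, min_support=3)
            quant = quantify_transcripts(counts, call, dmrt1).set_index("transcript_id")
            ratios.append(
                quant.loc["Dmrt1_canonical", "cpm"] / quant.loc["Dmrt1_DeltaEx2Ex3", "cpm"]
            )
        assert all(7.0 <= r <= 13.0 for r in ratios)


class TestMinAbundanceFilter:
    def test_low_isoform_dropped_canonical_kept(self):
        kept = apply_min_abundance_filter({"canonical": 100.0, "isoform": 5.0}, 10.0)
        assert kept == {"canonical": 100.0}

    def test_zero_threshold_identity(self):
        ab = {"a": 0.0, "b": 1.0}
        assert apply_min_abundance_filter(ab, 0.0) == ab

    def test_retained_set_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        ab = {f"t{i}": float(v) for i, v in enumerate(rng.exponential(10, size=30))}
        sizes = [
            len(apply_min_abundance_filter(ab, thr))
            for thr in np.linspace(0, 50, 40)
        ]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_disparity_threshold_exists_in_ten_to_one_scenario(self):
        """There is a cutoff separating the rare isoform from the canonical —
        the depth-dependent assembly-disparity phenomenon."""
        abundances = {"canonical": 100.0, "isoform": 10.0}
        thresholds = [
            thr for thr in np.linspace(0, 200, 401)
            if set(apply_min_abundance_filter(abundances, thr)) == {"canonical"}
        ]
        assert thresholds  # non-empty window
        assert min(thresholds) > 10.0 - 1e-9 and max(thresholds) <= 100.0
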