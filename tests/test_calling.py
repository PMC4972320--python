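"""The core caller: windows, two-candidate gene TSS, antisense calls, filters."""

import numpy as np
import pytest

from datsscan import (
    PipelineConfig,
    SearchWindow,
    StrandedCounts,
    TranscriptModel,
    TssAnchor,
    best_bin_candidate,
    build_search_windows,
    call_antisense_tss,
    call_gene_tss,
    filter_datss,
    run_pipeline,
)
from datsscan.calling import TssCall

from conftest import make_counts
from oracles import gene_tss_oracle


def anchor(pos, gene="G1", strand="+", chrom="chrT", ids=("NM_1",)):
    return TssAnchor(chrom, strand, pos, gene, tuple(ids))


def window(start, end, member, gene="G1", strand="+", chrom="chrT"):
    return SearchWindow(chrom, strand, start, end, gene, list(member))


class TestBuildSearchWindows:
    def test_same_gene_overlap_unions(self, toy_config):
        wins = build_search_windows([anchor(1000), anchor(1500)], toy_config)
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end) == (0, 2500)
        assert wins[0].member_tss == [1000, 1500]

    def test_different_genes_cut_at_midpoint(self, toy_config):
        wins = build_search_windows(
            [anchor(1000, "A"), anchor(1800, "B", ids=("NM_2",))], toy_config
        )
        assert [(w.start, w.end) for w in wins] == [(0, 1400), (1400, 2800)]

    def test_isolated_anchor_clipped_at_chrom_start(self, toy_config):
        wins = build_search_windows([anchor(1000)], toy_config)
        assert (wins[0].start, wins[0].end) == (0, 2000)

    def test_clipped_at_chrom_end(self, toy_config):
        wins = build_search_windows([anchor(950)], toy_config, {"chrT": 1500})
        assert (wins[0].start, wins[0].end) == (0, 1500)

    def test_resolved_windows_never_overlap(self, toy_config):
        rng = np.random.default_rng(11)
        pos = np.cumsum(rng.integers(200, 3000, size=40)) + 2000
        anchors = [anchor(int(p), f"G{i}", ids=(f"NM_{i}",)) for i, p in enumerate(pos)]
        wins = build_search_windows(anchors, toy_config)
        wins.sort(key=lambda w: w.start)
        for a, b in zip(wins, wins[1:]):
            assert a.end <= b.start


class TestBestBinCandidate:
    def test_densest_bin_beats_single_tall_position(self, toy_config):
        counts = make_counts({("chrT", "+", 100): 6, ("chrT", "+", 105): 5, ("chrT", "+", 900): 7})
        # bins covering both 100 and 105 sum to 11 > 7; argmax inside is 100
        assert best_bin_candidate(window(0, 1000, [500]), counts, toy_config) == 100

    def test_single_nonzero_position(self, toy_config):
        counts = make_counts({("chrT", "+", 333): 2})
        assert best_bin_candidate(window(0, 1000, [500]), counts, toy_config) == 333

    def test_all_zero_window_is_none(self, toy_config):
        counts = make_counts({})
        assert best_bin_candidate(window(0, 1000, [500]), counts, toy_config) is None

    def test_short_window_single_truncated_bin(self, toy_config):
        counts = make_counts({("chrT", "+", 50): 3, ("chrT", "+", 80): 9})
        assert best_bin_candidate(window(0, 120, [60]), counts, toy_config) == 80


class TestCallGeneTss:
    def test_annotation_pulls_call_to_nearby_candidate(self, toy_config):
        counts = make_counts({("chrT", "+", 100): 6, ("chrT", "+", 105): 5, ("chrT", "+", 900): 7})
        call = call_gene_tss(window(0, 1000, [890]), counts, toy_config)
        assert (call.pos, call.count) == (900, 7)

    def test_annotation_near_bin_candidate(self, toy_config):
        counts = make_counts({("chrT", "+", 100): 6, ("chrT", "+", 105): 5, ("chrT", "+", 900): 7})
        call = call_gene_tss(window(0, 1000, [120]), counts, toy_config)
        assert (call.pos, call.count) == (100, 6)

    def test_subthreshold_window_yields_none(self, toy_config):
        counts = make_counts({("chrT", "+", 100): 4})
        assert call_gene_tss(window(0, 1000, [100]), counts, toy_config) is None

    def test_count_is_at_called_base(self, toy_config):
        counts = make_counts({("chrT", "+", 400): 9, ("chrT", "+", 410): 3})
        call = call_gene_tss(window(0, 1000, [400]), counts, toy_config)
        assert (call.pos, call.count, call.klass, call.strand) == (400, 9, "gene", "+")

    def test_matches_exhaustive_oracle_on_random_windows(self, toy_config):
        """Spot equivalence with the enumeration oracle (full sweep in acceptance)."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            w_len = int(rng.integers(200, 3001))
            start = int(rng.integers(0, 5000))
            n_pos = int(rng.integers(0, 31))
            sparse = {}
            for _ in range(n_pos):
                sparse[int(rng.integers(start, start + w_len))] = int(rng.integers(1, 20))
            member = sorted(int(rng.integers(start, start + w_len)) for _ in range(int(rng.integers(1, 4))))
            counts = make_counts({("chrT", "+", p): c for p, c in sparse.items()})
            win = window(start, start + w_len, member)
            got = call_gene_tss(win, counts, toy_config)
            expect = gene_tss_oracle(start, start + w_len, member, sparse, 5)
            if expect is None:
                assert got is None
            else:
                assert (got.pos, got.count) == expect


class TestCallAntisense:
    def gene_call(self, pos=5000, strand="+"):
        return TssCall("gene", "chrT", strand, pos, 20, "G1")

    def test_uatss_in_upstream_antisense_region(self, toy_config):
        counts = make_counts({("chrT", "-", 4600): 7})
        call = call_antisense_tss(self.gene_call(), counts, "upstream", toy_config)
        assert (call.klass, call.pos, call.strand, call.distance) == ("uaTSS", 4600, "-", 400)

    def test_datss_ignores_subthreshold_positions(self, toy_config):
        counts = make_counts({("chrT", "-", 5507): 6, ("chrT", "-", 5020): 4})
        call = call_antisense_tss(self.gene_call(), counts, "downstream", toy_config)
        assert (call.klass, call.pos, call.distance) == ("daTSS", 5507, 507)

    def test_minus_gene_upstream_region_mirrors(self, toy_config):
        counts = make_counts({("chrT", "+", 5400): 8})
        call = call_antisense_tss(self.gene_call(strand="-"), counts, "upstream", toy_config)
        assert (call.klass, call.pos, call.strand, call.distance) == ("uaTSS", 5400, "+", 400)

    def test_region_boundaries_are_exclusive_of_gene_tss(self, toy_config):
        # counts at the gene TSS itself or beyond the span never qualify
        counts = make_counts({("chrT", "-", 5000): 50, ("chrT", "-", 7001): 50})
        assert call_antisense_tss(self.gene_call(), counts, "downstream", toy_config) is None
        counts2 = make_counts({("chrT", "-", 7000): 6})
        call = call_antisense_tss(self.gene_call(), counts2, "downstream", toy_config)
        assert call.pos == 7000 and call.distance == 2000

    def test_empty_region_is_none(self, toy_config):
        counts = make_counts({})
        assert call_antisense_tss(self.gene_call(), counts, "upstream", toy_config) is None


class TestFilterDatss:
    def gene(self):
        return TssCall("gene", "chrT", "+", 5000, 20, "G1")

    def da(self):
        return TssCall("daTSS", "chrT", "-", 5507, 6, "G1", linked_gene_pos=5000)

    def test_hidden_gene_signal_drops_call(self, toy_config):
        # upstream of a minus-strand daTSS runs toward increasing coordinates
        counts = make_counts({("chrT", "+", 5900): 2})
        keep, reason = filter_datss(self.da(), self.gene(), counts, [], toy_config)
        assert (keep, reason) == (False, "hidden-gene-uaTSS")

    def test_hidden_gene_threshold_is_fraction_of_gene_count(self, toy_config):
        counts = make_counts({("chrT", "+", 5900): 1})  # 1 < 0.10 * 20
        keep, reason = filter_datss(self.da(), self.gene(), counts, [], toy_config)
        assert keep

    def test_annotated_tss_on_datss_strand_drops_call(self, toy_config):
        anchors = [TssAnchor("chrT", "-", 5800, "HIDDEN", ("NM_9",))]
        keep, reason = filter_datss(self.da(), self.gene(), make_counts({}), anchors, toy_config)
        assert (keep, reason) == (False, "potential-gene-TSS")

    def test_annotated_tss_on_other_strand_ignored(self, toy_config):
        anchors = [TssAnchor("chrT", "+", 5800, "OTHER", ("NM_9",))]
        keep, _ = filter_datss(self.da(), self.gene(), make_counts({}), anchors, toy_config)
        assert keep

    def test_clean_call_kept(self, toy_config):
        keep, reason = filter_datss(self.da(), self.gene(), make_counts({}), [], toy_config)
        assert (keep, reason) == (True, None)

    def test_plus_strand_datss_upstream_runs_left(self, toy_config):
        da = TssCall("daTSS", "chrT", "+", 4500, 6, "G1", linked_gene_pos=5000)
        gene = TssCall("gene", "chrT", "-", 5000, 20, "G1")
        counts = make_counts({("chrT", "-", 4100): 2})
        keep, reason = filter_datss(da, gene, counts, [], toy_config)
        assert (keep, reason) == (False, "hidden-gene-uaTSS")


class TestRunPipeline:
    def toy_models(self):
        return [TranscriptModel("NM_1", "G1", "chrT", "+", 5000, 10000, ((5000, 10000),))]

    def test_composed_toy_scenario(self, toy_config):
        counts = make_counts(
            {
                ("chrT", "+", 5000): 20,
                ("chrT", "-", 4600): 7,
                ("chrT", "-", 5507): 6,
            }
        )
        cs = run_pipeline(self.toy_models(), counts, toy_config)
        assert [c.pos for c in cs.gene_calls] == [5000]
        assert [c.pos for c in cs.ua_calls] == [4600]
        assert [c.pos for c in cs.da_calls] == [5507]
        assert cs.summary()["median_da_distance"] == 507

    def test_decoy_configuration_filters_datss(self, toy_config):
        counts = make_counts(
            {
                ("chrT", "+", 5000): 20,
                ("chrT", "-", 5507): 6,
                ("chrT", "+", 5900): 2,  # hidden-gene signal
            }
        )
        cs = run_pipeline(self.toy_models(), counts, toy_config)
        assert cs.da_calls == []
        assert [(c.pos, r) for c, r in cs.dropped_da] == [(5507, "hidden-gene-uaTSS")]

    def test_zero_counts_empty_callset(self, toy_config):
        cs = run_pipeline(self.toy_models(), make_counts({}), toy_config)
        assert cs.summary()["n_gene_tss"] == 0

    def test_empty_annotation_empty_callset(self, toy_config):
        cs = run_pipeline([], make_counts({("chrT", "+", 5): 50}), toy_config)
        assert cs.all_calls() == []

    def test_every_call_meets_threshold(self, default_callset):
        _, cs = default_callset
        assert all(c.count >= cs.read_threshold for c in cs.all_calls())

    def test_antisense_calls_link_and_oppose_strand(self, default_callset):
        _, cs = default_callset
        gene_by_name = {c.gene_name: c for c in cs.gene_calls}
        for c in cs.ua_calls + cs.da_calls:
            g = gene_by_name[c.gene_name]
            assert c.strand != g.strand
            assert c.linked_gene_pos == g.pos
            limit = 1000 if c.klass == "uaTSS" else 2000
            assert 1 <= c.distance <= limit

    def test_surviving_datss_pass_filters_post_hoc(self, default_sim, default_callset):
        """Independent re-check: no kept daTSS satisfies either drop condition."""
        _, models, _, counts = default_sim
        _, cs = default_callset
        from datsscan import nonredundant_tss

        anchors = nonredundant_tss(models)
        anchor_pos = {(a.strand, a.pos) for a in anchors}
        gene_by_name = {c.gene_name: c for c in cs.gene_calls}
        for c in cs.da_calls:
            g = gene_by_name[c.gene_name]
            lo, hi = (c.pos - 1000, c.pos) if c.strand == "+" else (c.pos + 1, c.pos + 1001)
            region = counts.window_array(c.chrom, max(lo, 0), hi, g.strand)
            assert region.max(initial=0) < 0.10 * g.count
            assert not any(
                (c.strand, p) in anchor_pos for p in range(c.pos - 1000, c.pos + 1001)
            )


class TestStrandMirror:
    def test_mirrored_genome_yields_mirrored_calls(self):
        """Reversing coordinates and strands re-calls every TSS at its mirror."""
        from datsscan import SyntheticConfig, simulate_counts, simulate_genome

        config = SyntheticConfig(seed=8, n_genes=40, chrom_length=1_000_000, min_gene_spacing=20_000)
        models, truth = simulate_genome(config)
        counts = simulate_counts(truth, config)
        L = config.chrom_length
        flip = {"+": "-", "-": "+"}

        mirrored_models = [
            TranscriptModel(
                m.transcript_id,
                m.gene_name,
                m.chrom,
                flip[m.strand],
                L - m.tx_end,
                L - m.tx_start,
                tuple(sorted((L - e, L - s) for s, e in m.exons)),
            )
            for m in models
        ]
        mirrored_counts = StrandedCounts({m.chrom: L for m in models})
        for (chrom, strand) in list(counts.keys()):
            pos, vals = counts.positions(chrom, strand)
            for p, v in zip(pos, vals):
                mirrored_counts.add(chrom, flip[strand], L - 1 - int(p), int(v))

        cfg = PipelineConfig(read_threshold=5)
        cs = run_pipeline(models, counts, cfg)
        cs_m = run_pipeline(mirrored_models, mirrored_counts, cfg)
        for attr in ("gene_calls", "ua_calls", "da_calls"):
            orig = {(c.strand, c.pos, c.count) for c in getattr(cs, attr)}
            mirr = {(flip[c.strand], L - 1 - c.pos, c.count) for c in getattr(cs_m, attr)}
            assert mirr == orig
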