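"""Synthetic screen: effect assignment, sorting/sequencing, read emission."""

import numpy as np
import pandas as pd
import pytest

from chipperscan.chipper_sim import LibraryEntry, LibraryPool, Provenance
from chipperscan.screen_sim import (
    BINS,
    SCAFFOLD_PREFIX,
    ScreenConfig,
    TruthElement,
    assign_effects,
    default_truth_elements,
    emit_reads,
    make_barcode_table,
    simulate_screen_counts,
)


def make_entry(domain, count, region="r", strand="+", start=100, pam="AGG",
               pam_class="NGG", junction=False, context4=""):
    k = len(domain) - 1
    if strand == "+":
        last, third = start + k - 1, start + k - 3
    else:
        last, third = start, start + 2
    prov = Provenance(
        region_id=None if junction else region,
        strand=None if junction else strand,
        spacer_start=None if junction else start,
        spacer_len=k,
        pam_seq="" if junction else pam,
        pam_class="OTHER" if junction else pam_class,
        pam_context4=context4,
        last_base_pos=None if junction else last,
        third_last_pos=None if junction else third,
        junction=junction,
    )
    return LibraryEntry(domain, count, (prov,))


def make_pool(entries):
    return LibraryPool(entries=entries, clone_count=sum(e.count for e in entries),
                       n_fragments=0, short_fragment_skips=0)


def element_at(start, end, profile, region="r", cls="five_prime_hit"):
    return TruthElement(region, start, end, cls, profile, name="el")


class TestAssignEffects:
    def test_zero_cut_probability_is_point_mass_on_neg(self):
        pool = make_pool([make_entry("G" + "A" * 19, 5, pam_class="OTHER")])
        truth = [element_at(0, 1000, (0, 0, 0, 1.0))]
        dist = assign_effects(pool, truth, ScreenConfig())
        np.testing.assert_allclose(dist[0], [1, 0, 0, 0])

    def test_ngg_inside_element_mixture_arithmetic(self):
        # WT x NGG activity 0.8 on a (0,0,0,1) element -> (0.2, 0, 0, 0.8)
        pool = make_pool([make_entry("G" + "A" * 19, 5, start=100)])
        truth = [element_at(0, 1000, (0, 0, 0, 1.0))]
        dist = assign_effects(pool, truth, ScreenConfig())
        np.testing.assert_allclose(dist[0], [0.2, 0, 0, 0.8])

    def test_outside_all_elements_stays_neg_regardless_of_pam(self):
        pool = make_pool([make_entry("G" + "A" * 19, 5, start=100)])
        truth = [element_at(500, 600, (0, 0, 0, 1.0))]
        dist = assign_effects(pool, truth, ScreenConfig())
        np.testing.assert_allclose(dist[0], [1, 0, 0, 0])

    def test_junction_guides_always_neg(self):
        pool = make_pool([make_entry("G" + "A" * 19, 5, junction=True)])
        truth = [element_at(0, 1000, (0, 0, 0, 1.0))]
        dist = assign_effects(pool, truth, ScreenConfig())
        np.testing.assert_allclose(dist[0], [1, 0, 0, 0])

    def test_cut_site_is_third_last_base(self):
        # plus-strand guide at start=100, len 19: cut site (third-last) = 116
        pool = make_pool([make_entry("G" + "A" * 19, 5, start=100)])
        inside = [element_at(116, 117, (0, 0, 0, 1.0))]
        outside = [element_at(117, 118, (0, 0, 0, 1.0))]
        assert assign_effects(pool, inside, ScreenConfig())[0][3] == pytest.approx(0.8)
        assert assign_effects(pool, outside, ScreenConfig())[0][0] == pytest.approx(1.0)

    def test_overlapping_elements_rejected(self):
        pool = make_pool([make_entry("G" + "A" * 19, 5, start=100)])
        truth = [element_at(0, 1000, (0, 0, 0, 1.0)),
                 element_at(50, 500, (0, 0, 1.0, 0))]
        with pytest.raises(ValueError, match="overlapping"):
            assign_effects(pool, truth, ScreenConfig())

    def test_gtgg_context_exception(self):
        entry = make_entry("G" + "A" * 19, 5, pam="GTG", pam_class="OTHER",
                           context4="GTGG")
        pool = make_pool([entry])
        truth = [element_at(0, 1000, (0, 0, 0, 1.0))]
        off = assign_effects(pool, truth, ScreenConfig())
        on = assign_effects(pool, truth, ScreenConfig(gtgg_activity=0.1))
        assert off[0][0] == pytest.approx(1.0)
        assert on[0][3] == pytest.approx(0.1)


class TestSimulateScreenCounts:
    def test_single_guide_point_mass_high(self):
        pool = make_pool([make_entry("G" + "A" * 19, 10, start=100)])
        truth = [element_at(0, 1000, (0, 0, 0, 1.0))]
        cfg = ScreenConfig(n_cells=10_000, replicates=2, read_depth=1000, seed=1,
                           pam_activity={("WT", "NGG"): 1.0})
        res = simulate_screen_counts(pool, truth, cfg)
        for rep in (1, 2):
            assert res.counts.loc["A" * 19, f"rep{rep}_high"] == 1000
            assert res.counts[f"rep{rep}_neg"].sum() == 0

    def test_fixed_seed_reproducible(self):
        entries = [make_entry("G" + b * 19, 5 + i, start=100 + 30 * i)
                   for i, b in enumerate("ACGT")]
        pool = make_pool(entries)
        cfg = ScreenConfig(n_cells=5000, replicates=2, read_depth=500, seed=3)
        a = simulate_screen_counts(pool, [], cfg)
        b = simulate_screen_counts(pool, [], cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_neutral_screen_neg_frequencies_track_library(self):
        rng = np.random.default_rng(0)
        entries = [
            make_entry("G" + "".join(rng.choice(list("ACGT"), 19)), int(c), start=100)
            for c in rng.integers(50, 500, size=40)
        ]
        pool = make_pool(entries)
        cfg = ScreenConfig(n_cells=1_000_000, replicates=1, read_depth=1_000_000, seed=4)
        res = simulate_screen_counts(pool, [], cfg)
        obs = res.counts["rep1_neg"] / res.counts["rep1_neg"].sum()
        lib = pd.Series(pool.frequencies, index=[e.spacer for e in pool.entries])
        # two-stage sampling (cells then reads): allow 4 combined SEs
        n_cells = int(1_000_000 * cfg.infection_rate)
        for sp in lib.index:
            f = lib[sp]
            se = np.sqrt(f * (1 - f) * (1 / n_cells + 1 / 1_000_000))
            assert abs(obs[sp] - f) < 4 * se + 1e-6

    def test_empty_positive_bins_flagged_without_elements(self):
        pool = make_pool([make_entry("G" + "A" * 19, 10, start=100)])
        cfg = ScreenConfig(n_cells=1000, replicates=1, read_depth=100, seed=5)
        res = simulate_screen_counts(pool, [], cfg)
        empties = res.samples.set_index("sample_id")["empty"]
        assert not empties["rep1_neg"]
        assert empties[["rep1_low", "rep1_med", "rep1_high"]].all()


class TestEmitReads:
    def test_read_structure_with_printed_barcode(self, tmp_path):
        pool = make_pool([make_entry("G" + "A" * 19, 10, start=100)])
        cfg = ScreenConfig(n_cells=1000, replicates=1, read_depth=5, seed=6,
                           pam_activity={("WT", "NGG"): 0.0})
        res = simulate_screen_counts(pool, [], cfg)
        # first sample (rep1_neg) carries the printed barcode cgtgat
        assert res.samples.iloc[0]["barcode"] == "CGTGAT"
        out = tmp_path / "reads.fastq"
        n = emit_reads(res, out, cfg, np.random.default_rng(0))
        lines = out.read_text().splitlines()
        assert n == 5 and len(lines) == 20
        read = lines[1]
        assert read.startswith("A" * 19 + SCAFFOLD_PREFIX + "CGTGAT")

    def test_empty_count_table_empty_fastq(self, tmp_path):
        pool = make_pool([make_entry("G" + "A" * 19, 10, start=100)])
        cfg = ScreenConfig(n_cells=1000, replicates=1, read_depth=5, seed=6)
        res = simulate_screen_counts(pool, [], cfg)
        res.counts.loc[:, :] = 0
        out = tmp_path / "reads.fastq"
        assert emit_reads(res, out, cfg) == 0
        assert out.read_text() == ""

    def test_missing_barcode_rejected(self, tmp_path):
        pool = make_pool([make_entry("G" + "A" * 19, 10, start=100)])
        cfg = ScreenConfig(n_cells=1000, replicates=1, read_depth=5, seed=6)
        res = simulate_screen_counts(pool, [], cfg)
        res.samples.loc[0, "barcode"] = np.nan
        with pytest.raises(ValueError, match="barcode"):
            emit_reads(res, tmp_path / "r.fastq", cfg)


def test_truth_element_validation():
    with pytest.raises(ValueError, match="sum"):
        TruthElement("r", 0, 10, "five_prime_hit", (0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="element_class"):
        TruthElement("r", 0, 10, "bogus", (1.0, 0, 0, 0))


def test_default_truth_layout_disjoint_and_inside(screen_region):
    truth = default_truth_elements(screen_region)
    assert len(truth) == 3
    ivs = sorted((t.start, t.end) for t in truth)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 <= s2
    assert all(0 <= t.start < t.end <= len(screen_region) for t in truth)


def test_barcode_table_unique_and_six_nt():
    bt = make_barcode_table(replicates=3)
    assert bt["barcode"].is_unique
    assert (bt["barcode"].str.len() == 6).all()
    assert len(bt) == 3 * len(BINS)
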