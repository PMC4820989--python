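"""In-silico digest: ligation, fragmentation, end release, clone pool."""

import numpy as np
import pytest
from scipy import stats as sps

from chipperscan import refmodel
from chipperscan.chipper_sim import (
    ChipperParams,
    build_library,
    fragment_dna,
    release_end_sgRNAs,
    simulate_concatemer,
)
from chipperscan.refmodel import ReferenceRegion, enumerate_sites, random_region

from conftest import random_dna, revcomp_oracle


def no_jitter_params(**kw):
    kw.setdefault("length_jitter", {19: 1.0})
    return ChipperParams(**kw)


class TestChipperParams:
    def test_released_lengths_derive_from_cut_and_spacer(self):
        p = ChipperParams()
        assert p.released_long == 27 - 8 == 19
        assert p.released_short == 25 - 8 == 17

    def test_jitter_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            ChipperParams(length_jitter={19: 0.5}).validate()

    def test_fragment_bounds_validated(self):
        with pytest.raises(ValueError):
            ChipperParams(fragment_min=500, fragment_max=450).validate()


class TestConcatemer:
    def test_single_region_at_its_own_length(self, rng):
        region = ReferenceRegion("r", random_dna(rng, 100))
        cat = simulate_concatemer([region], 100, rng)
        assert len(cat.segments) == 1
        seg = cat.segments[0]
        expected = region.sequence if seg.orientation == "+" else revcomp_oracle(region.sequence)
        assert cat.sequence == expected

    def test_deterministic_under_fixed_seed(self, rng):
        regions = [ReferenceRegion(f"r{i}", random_dna(rng, 80)) for i in range(3)]
        a = simulate_concatemer(regions, 2000, np.random.default_rng(7))
        b = simulate_concatemer(regions, 2000, np.random.default_rng(7))
        assert a.sequence == b.sequence
        assert a.segments == b.segments

    def test_empty_region_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            simulate_concatemer([], 100, rng)

    def test_segments_map_back_to_region_substrings(self, rng):
        regions = [ReferenceRegion(f"r{i}", random_dna(rng, 60)) for i in range(4)]
        by_id = {r.region_id: r for r in regions}
        cat = simulate_concatemer(regions, 1000, rng)
        for seg in cat.segments:
            piece = cat.sequence[seg.concat_start : seg.concat_end]
            original = by_id[seg.region_id].sequence
            assert piece == (original if seg.orientation == "+" else revcomp_oracle(original))

    def test_interval_spanning_junction_flagged(self, rng):
        regions = [ReferenceRegion("a", "A" * 50), ReferenceRegion("c", "C" * 50)]
        cat = simulate_concatemer(regions, 200, rng)
        j = cat.junctions[0]
        assert cat.map_interval(j - 5, j + 5, "+") is None
        assert cat.map_interval(j - 10, j, "+") is not None


class TestFragmentDna:
    def test_zero_fragments(self, rng):
        region = random_region(2000, seed=1)
        cat = simulate_concatemer([region], 2000, rng)
        frags = fragment_dna(cat, ChipperParams(n_fragments=0), rng)
        assert frags == []

    def test_lengths_within_bounds(self, rng):
        region = random_region(5000, seed=2)
        cat = simulate_concatemer([region], 5000, rng)
        frags = fragment_dna(cat, ChipperParams(n_fragments=10_000), rng)
        lengths = np.array([f.length for f in frags])
        assert lengths.min() >= 400 and lengths.max() <= 450
        starts = np.array([f.concat_start for f in frags])
        assert starts.min() >= 0
        assert (starts + lengths).max() <= len(cat)

    def test_start_positions_uniform_by_chisquare(self):
        rng = np.random.default_rng(99)
        region = random_region(20_000, seed=3)
        cat = simulate_concatemer([region], 20_000, rng)
        frags = fragment_dna(cat, ChipperParams(n_fragments=100_000), rng)
        starts = np.array([f.concat_start for f in frags])
        # valid start range depends on each fragment's length; bin well inside it
        hist, _ = np.histogram(starts[starts < 19_000], bins=50, range=(0, 19_000))
        _, p = sps.chisquare(hist)
        assert p > 0.01

    def test_short_concatemer_rejected(self, rng):
        region = random_region(300, seed=4)
        cat = simulate_concatemer([region], 300, rng)
        with pytest.raises(ValueError):
            fragment_dna(cat, ChipperParams(), rng)


class TestReleaseEnds:
    def _one_fragment_setup(self, seq):
        region = ReferenceRegion("r", seq)
        cat = simulate_concatemer([region], len(seq), np.random.default_rng(0))
        return region, cat

    def test_manual_string_construction_40bp(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 40)
        region = ReferenceRegion("r", seq)
        # force plus orientation by trying seeds until the single segment is '+'
        s = 0
        while True:
            cat = simulate_concatemer([region], 40, np.random.default_rng(s))
            if cat.segments[0].orientation == "+":
                break
            s += 1
        params = no_jitter_params()
        from chipperscan.chipper_sim import FragmentRecord

        frag = FragmentRecord(0, 40)
        rel = release_end_sgRNAs(frag, cat, {"r": region}, params, np.random.default_rng(1))
        by_end = {r.end: r for r in rel}
        assert by_end["left"].targeting_domain == "G" + seq[:19]
        assert by_end["right"].targeting_domain == "G" + revcomp_oracle(seq[40 - 19 :])

    def test_jitter_disabled_gives_20_base_domains(self):
        region = random_region(3000, seed=5)
        params = no_jitter_params(
            n_fragments=500, clone_count=2000, concatemer_length=3500
        )
        pool = build_library([region], params, seed=6)
        assert {len(e.targeting_domain) for e in pool.entries} == {20}

    def test_palindromic_fragment_symmetric_inserts(self):
        rng = np.random.default_rng(0)
        half = random_dna(rng, 20)
        seq = half + revcomp_oracle(half)  # 40-bp palindrome
        region = ReferenceRegion("r", seq)
        s = 0
        while True:
            cat = simulate_concatemer([region], 40, np.random.default_rng(s))
            if cat.segments[0].orientation == "+":
                break
            s += 1
        from chipperscan.chipper_sim import FragmentRecord

        rel = release_end_sgRNAs(
            FragmentRecord(0, 40), cat, {"r": region}, no_jitter_params(),
            np.random.default_rng(1),
        )
        left, right = rel
        assert left.insert_seq == right.insert_seq


class TestBuildLibrary:
    def test_single_clone(self):
        region = random_region(2000, seed=7)
        params = ChipperParams(n_fragments=100, clone_count=1, concatemer_length=2500)
        pool = build_library([region], params, seed=8)
        assert sum(e.count for e in pool.entries) == 1

    def test_deterministic_pool(self, tmp_path):
        region = random_region(2000, seed=9)
        params = ChipperParams(n_fragments=500, clone_count=5000, concatemer_length=2500)
        a = build_library([region], params, seed=10)
        b = build_library([region], params, seed=10)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_tsv(pa)
        b.to_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_inventory_subset_of_theoretical_enumeration(self):
        region = random_region(3000, seed=11)
        params = no_jitter_params(
            n_fragments=2000, clone_count=20_000, concatemer_length=4000
        )
        pool = build_library([region], params, seed=12)
        theoretical = {
            "G" + s.spacer_seq for s in enumerate_sites(region, 19, pam_filter=None)
        }
        # guides at the region edge have no room for a 3-nt PAM and are not
        # enumerable sites; containment applies to full-PAM releases
        released = {
            e.targeting_domain
            for e in pool.entries
            if any(not p.junction and len(p.pam_seq) == 3 for p in e.provenances)
        }
        assert released <= theoretical

    def test_provenance_roundtrip_exact(self):
        regions = [random_region(1500, seed=s, region_id=f"r{s}") for s in (13, 14)]
        by_id = {r.region_id: r for r in regions}
        params = no_jitter_params(
            n_fragments=1000, clone_count=5000, concatemer_length=8000
        )
        pool = build_library(regions, params, seed=15)
        checked = 0
        for e in pool.entries:
            for p in e.provenances:
                if p.junction:
                    continue
                seq = by_id[p.region_id].sequence
                sub = seq[p.spacer_start : p.spacer_start + p.spacer_len]
                if p.strand == "-":
                    sub = revcomp_oracle(sub)
                assert e.targeting_domain == "G" + sub
                checked += 1
        assert checked > 100

    def test_high_breakpoint_density_saturates_enumeration(self):
        # with ~50x breakpoint coverage nearly every NGG position is released
        region = random_region(2000, seed=16)
        params = no_jitter_params(
            n_fragments=25_000, clone_count=300_000, concatemer_length=20_000
        )
        pool = build_library([region], params, seed=17)
        theoretical = {
            "G" + s.spacer_seq for s in enumerate_sites(region, 19, pam_filter={"NGG"})
        }
        released = pool.unique_inventory(junction_free=True)
        covered = len(theoretical & released) / len(theoretical)
        assert covered >= 0.99

    def test_domain_length_mode_is_20_under_default_jitter(self):
        region = random_region(5000, seed=18)
        params = ChipperParams(n_fragments=5000, clone_count=50_000, concatemer_length=6000)
        pool = build_library([region], params, seed=19)
        hist = {}
        for e in pool.entries:
            hist[len(e.targeting_domain)] = hist.get(len(e.targeting_domain), 0) + e.count
        assert max(hist, key=hist.get) == 20
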