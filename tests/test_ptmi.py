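"""Window scanning, peak/spot calling, within-protein permutation and motif rules."""

import math
from collections import Counter
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmnet.ptmi import (
    ScanConfig,
    call_spots,
    find_hyperphospho_degrons,
    find_py_nls,
    local_peaks,
    min_sites_exceeding,
    modification_states,
    multi_ptm_high_density_counts,
    permute_types_within_protein,
    scan_windows,
)

from conftest import make_dataset, make_protein


class TestScanWindows:
    def test_start_arithmetic(self):
        p = make_protein("P", "A" * 40)
        assert [w.start for w in scan_windows(p)] == [1, 11, 21]
        assert [w.start for w in scan_windows(make_protein("P", "A" * 49))] == [1, 11, 21]
        assert [w.start for w in scan_windows(make_protein("P", "A" * 50))] == [1, 11, 21, 31]

    def test_short_protein_yields_nothing(self):
        assert scan_windows(make_protein("P", "A" * 19)) == []

    def test_dual_modified_lysine_counts_twice(self):
        seq = "K" + "S" * 39
        p = make_protein("P", seq, [(1, "Ac"), (1, "Ub"), (5, "pST")])
        w = scan_windows(p)[0]
        assert w.n_mods == 3
        assert w.ptm_density == pytest.approx(0.15)
        assert w.n_types == 3
        assert w.styk_density == 1.0

    def test_unmodified_protein_all_zero(self):
        assert all(w.n_mods == 0 for w in scan_windows(make_protein("P", "A" * 60)))

    def test_density_matches_bruteforce_recount(self, bundle):
        for p in list(bundle.dataset)[:40]:
            for w in scan_windows(p):
                direct = sum(1 for s in p.sites if w.start <= s.position <= w.end)
                assert w.n_mods == direct
                styk = sum(1 for aa in p.sequence[w.start - 1 : w.end] if aa in "STYK")
                assert w.styk_density == pytest.approx(styk / w.width)


class TestLocalPeaks:
    def test_single_cluster_yields_single_peak(self):
        # cluster in the first phase: profile (3, 0, 0)
        p = make_protein("P", "S" * 40, [(5, "pST"), (7, "pST"), (9, "pST")])
        windows = scan_windows(p)
        assert [w.n_mods for w in windows] == [3, 0, 0]
        peaks = local_peaks(windows)
        assert len(peaks) == 1 and peaks[0].start == 1
        # cluster shared by two overlapping windows: leftmost of the tied pair wins
        p2 = make_protein("P", "S" * 40, [(25, "pST"), (26, "pST"), (27, "pST")])
        assert [w.n_mods for w in scan_windows(p2)] == [0, 3, 3]
        peaks2 = local_peaks(scan_windows(p2))
        assert len(peaks2) == 1 and peaks2[0].start == 11

    def test_flat_positive_profile_takes_every_other_window(self):
        seq = "S" * 80
        sites = [(pos, "pST") for pos in range(5, 81, 10)]  # one record per 10-residue phase
        p = make_protein("P", seq, sites)
        windows = scan_windows(p)
        assert len({w.n_mods for w in windows}) == 1
        peaks = local_peaks(windows)
        assert [w.start for w in peaks] == [1, 21, 41, 61]

    def test_all_zero_profile_has_no_peaks(self):
        assert local_peaks(scan_windows(make_protein("P", "S" * 80))) == []

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_greedy_set_is_valid_and_maximal(self, counts):
        length = 20 + 10 * (len(counts) - 1)
        seq = ["S"] * length
        sites = []
        for i, k in enumerate(counts):
            for j in range(k):
                sites.append((1 + i * 10 + j, "pST"))
        p = make_protein("P", "".join(seq), sites)
        windows = scan_windows(p)
        peaks = local_peaks(windows)
        # pairwise non-overlapping
        for a in peaks:
            assert sum(1 for b in peaks if a.overlaps(b)) == 1
        # each peak is a local maximum among span-overlapping scan windows
        for w in peaks:
            for other in windows:
                if other is not w and other.overlaps(w) and abs(other.start - w.start) <= 10:
                    assert other.ptm_density <= w.ptm_density
        # maximality: every modified local-max window overlaps some chosen peak
        for i, w in enumerate(windows):
            if w.n_mods < 1:
                continue
            left_ok = i == 0 or windows[i - 1].ptm_density <= w.ptm_density
            right_ok = i == len(windows) - 1 or windows[i + 1].ptm_density <= w.ptm_density
            if left_ok and right_ok:
                assert any(w.overlaps(pk) for pk in peaks)


class TestCountingRules:
    @pytest.mark.parametrize("width,theta,expected", [(20, 0.3, 7), (20, 0.05, 2), (10, 0.3, 4)])
    def test_min_sites_exceeding(self, width, theta, expected):
        assert min_sites_exceeding(width, theta) == expected

    @given(width=st.integers(1, 40), theta=st.floats(0.01, 1.5))
    @settings(max_examples=100, deadline=None)
    def test_min_sites_enumeration_oracle(self, width, theta):
        k = min_sites_exceeding(width, theta)
        assert k / width > theta
        assert (k - 1) / width <= theta

    @pytest.mark.parametrize("k,expected", [(7, 128), (0, 1), (10, 1024)])
    def test_modification_states(self, k, expected):
        assert modification_states(k) == expected


class TestCallSpots:
    def test_isolated_dense_window_gives_width_long_spot(self):
        seq = "A" * 20 + "S" * 20 + "A" * 20
        sites = [(pos, "pST") for pos in (21, 24, 27, 30, 33, 36, 39)]
        p = make_protein("P", seq, sites)
        spots = call_spots(p)
        assert len(spots) == 1
        assert (spots[0].start, spots[0].end, spots[0].length) == (21, 40, 20)
        assert spots[0].classification == "single"

    def test_adjacent_dense_windows_merge(self):
        seq = "S" * 60
        sites = [(pos, "pST") for pos in range(1, 29, 2)]  # 14 records over 1..27
        p = make_protein("P", seq, sites)
        spots = call_spots(p)
        assert len(spots) == 1
        assert spots[0].start == 1 and spots[0].end >= 30
        assert spots[0].density > 0.3

    def test_multi_classification_and_disjointness(self, bundle):
        for p in bundle.dataset:
            spots = call_spots(p)
            for s in spots:
                types = {x.ptm_type for x in p.sites if s.start <= x.position <= s.end}
                assert set(s.types) == types
                assert s.classification == ("single" if len(types) == 1 else "multi")
            for a, b in zip(spots, spots[1:]):
                assert a.end < b.start

    def test_minimal_single_spot_holds_seven_pst(self):
        seq = "S" * 20 + "A" * 40
        p = make_protein("P", seq, [(i, "pST") for i in (1, 4, 7, 10, 13, 16, 19)])
        spots = call_spots(p)
        assert len(spots) == 1 and spots[0].classification == "single"
        assert spots[0].n_mods == 7 == min_sites_exceeding(20, 0.3)


class TestTypePermutation:
    def test_positions_fixed_labels_conserved(self):
        p = make_protein("P", "K" * 4 + "S" * 26 + "Y" * 10, [(5, "pST"), (2, "Ac")])
        q = permute_types_within_protein(p, 0)
        assert [s.position for s in q.sites] == [2, 5]
        assert sorted(s.ptm_type for s in q.sites) == ["Ac", "pST"]

    def test_single_record_is_identity(self):
        p = make_protein("P", "S" * 30, [(5, "pST")])
        assert permute_types_within_protein(p, 1) is p

    def test_same_type_everywhere_is_identity_in_effect(self):
        p = make_protein("P", "S" * 30, [(5, "pST"), (9, "pST"), (22, "pST")])
        q = permute_types_within_protein(p, 2)
        assert q.sites == p.sites

    def test_type_blind_density_profile_invariant(self, bundle, rng):
        for p in list(bundle.dataset)[:30]:
            q = permute_types_within_protein(p, rng)
            assert [s.position for s in q.sites] == [s.position for s in p.sites]
            assert Counter(s.ptm_type for s in q.sites) == Counter(s.ptm_type for s in p.sites)
            obs = [w.n_mods for w in scan_windows(p)]
            perm = [w.n_mods for w in scan_windows(q)]
            assert obs == perm

    def test_all_orderings_uniform_over_seeds(self):
        p = make_protein("P", "KSY" + "A" * 27, [(1, "Ac"), (2, "pST"), (3, "pY")])
        freq = Counter()
        for seed in range(1000):
            q = permute_types_within_protein(p, seed)
            freq[tuple(s.ptm_type for s in q.sites)] += 1
        assert len(freq) == 6
        for combo in freq:
            assert abs(freq[combo] / 1000 - 1 / 6) < 0.05

    def test_compatible_mode_respects_residue_classes(self, rng):
        p = make_protein("P", "KKSSYY" + "A" * 24, [(1, "Ac"), (2, "Ub"), (3, "pST"), (5, "pY")])
        for _ in range(20):
            q = permute_types_within_protein(p, rng, mode="compatible")
            for s in q.sites:
                assert s.residue in {"Ac": "K", "Ub": "K", "pST": "ST", "pY": "Y"}[s.ptm_type]


class TestMultiPTMHighDensity:
    def test_single_type_proteome_never_multi(self):
        ds = make_dataset(make_protein("P", "S" * 40, [(i, "pST") for i in range(1, 9)]))
        r = multi_ptm_high_density_counts(ds, ScanConfig(theta=0.1), R=10, seed=0)
        assert r["observed_multi"] == 0
        assert np.all(r["null_multi"] == 0)

    def test_reproducible_with_fixed_seed(self, bundle):
        small = make_dataset(*list(bundle.dataset)[:10])
        a = multi_ptm_high_density_counts(small, R=2, seed=9)
        b = multi_ptm_high_density_counts(small, R=2, seed=9)
        assert np.array_equal(a["null_multi"], b["null_multi"])
        assert np.array_equal(a["null_single"], b["null_single"])

    def test_null_multi_matches_exhaustive_label_enumeration(self):
        # 4 records: a pure-pST dense cluster plus one distant Ac
        p = make_protein("P", "S" * 55 + "K" + "S" * 4, [(5, "pST"), (10, "pST"), (15, "pST"), (56, "Ac")])
        ds = make_dataset(p)
        config = ScanConfig(theta=0.1)
        obs = multi_ptm_high_density_counts(ds, config, R=1, seed=0)
        assert obs["observed_multi"] == 0

        def count_multi(labels):
            q = make_protein("P", p.sequence, [(s.position, lab) for s, lab in zip(p.sites, labels)])
            windows = [w for w in scan_windows(q, config) if w.ptm_density > config.theta]
            return sum(1 for w in windows if w.n_types >= 2)

        exact = np.mean([count_multi(perm) for perm in set(permutations(["pST", "pST", "pST", "Ac"]))])
        assert exact > 0
        r = multi_ptm_high_density_counts(ds, config, R=600, seed=1)
        se = r["null_multi"].std() / math.sqrt(600)
        assert r["null_multi"].mean() == pytest.approx(exact, abs=4 * se + 1e-9)


class TestMotifs:
    def test_py_nls_minimal_match_and_gap_rule(self):
        assert len(find_py_nls(make_protein("P", "AAARAAPYAAAAAAAAAAAA"))) == 1
        assert find_py_nls(make_protein("P", "AAARAPYAAAAAAAAAAAAA")) == []
        m = find_py_nls(make_protein("P", "AAAKAAAAAPYAAAAAAAAA"))[0]
        assert (m.start, m.end) == (4, 11)

    def test_py_nls_phospho_flag_and_span_sites(self):
        seq = "AAARAAPYAAAAAAAAAAAA"
        p = make_protein("P", seq, [(8, "pY")])
        m = find_py_nls(p)[0]
        assert m.py_phosphorylated
        assert len(m.sites_in_span) == 1
        assert find_py_nls(make_protein("P", seq))[0].py_phosphorylated is False

    def test_py_nls_overlapping_matches_reported(self):
        matches = find_py_nls(make_protein("P", "RAKAAPYAAAAAAAAAAAAA"))
        assert {m.start for m in matches} == {1, 3}

    def degron_spot(self, seq, sites):
        p = make_protein("P", seq, sites)
        ds = make_dataset(p)
        spots = call_spots(p, ScanConfig(theta=0.1))
        return find_hyperphospho_degrons(spots, ds), spots

    def test_degron_rule_satisfied(self):
        seq = "SPSSSAAAAAAAAAAAAAKA" + "A" * 20
        sites = [(1, "pST"), (3, "pST"), (4, "pST"), (5, "pST"), (19, "Ub")]
        hits, spots = self.degron_spot(seq, sites)
        assert len(spots) == 1 and hits == spots

    def test_degron_requires_proline_directed_site(self):
        seq = "SASSSAAAAAAAAAAAAAKA" + "A" * 20
        sites = [(1, "pST"), (3, "pST"), (4, "pST"), (5, "pST"), (19, "Ub")]
        hits, spots = self.degron_spot(seq, sites)
        assert len(spots) == 1 and hits == []

    def test_degron_requires_four_pst(self):
        seq = "SPSSAAAAAAAAAAAAKKAA" + "A" * 20
        sites = [(1, "pST"), (3, "pST"), (4, "pST"), (17, "Ub"), (18, "Ub")]
        hits, spots = self.degron_spot(seq, sites)
        assert len(spots) == 1 and hits == []
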