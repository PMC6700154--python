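"""Binning, pair counting, smoothing and group pooling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mempot.aa import AA_INDEX, AA_ORDER
from mempot.contact_counts import (
    DEFAULT_SCHEME,
    BinningScheme,
    GroupDef,
    GROUPS,
    PairCounts,
    accumulate_pair_counts,
    distance_to_bin,
    pool_group_counts,
    smooth_counts,
    smoothing_kernel,
)
from mempot.structure_io import RadiusTable

from conftest import make_structure, random_structure


class TestDistanceToBin:
    @pytest.mark.parametrize(
        "d,expected",
        [(3.0, 0), (9.95, 23), (4.05, 3), (9.9, 23), (3.3, 1), (3.29999, 0),
         (15.0, 23), (0.0, 0), (2.5, 0)],
    )
    def test_clamp_policy(self, d, expected):
        assert distance_to_bin(d) == expected

    def test_discard_policy(self):
        scheme = BinningScheme(sub3_policy="discard")
        assert distance_to_bin(2.5, scheme) is None
        assert distance_to_bin(3.1, scheme) == 0

    @pytest.mark.parametrize("d", [-1.0, float("nan"), float("inf")])
    def test_invalid_distance(self, d):
        with pytest.raises(ValueError):
            distance_to_bin(d)

    @given(st.floats(min_value=3.0, max_value=9.89))
    def test_bin_brackets_distance(self, d):
        b = distance_to_bin(d)
        assert 0 <= b <= 22
        assert DEFAULT_SCHEME.lower_edge(b) - 1e-6 <= d
        assert d < DEFAULT_SCHEME.lower_edge(b + 1) + 1e-6


class TestAccumulate:
    def test_adjacent_pairs_excluded(self):
        st_ = make_structure([
            ("A", "A", (0, 0, 0)), ("A", "G", (4, 0, 0)), ("A", "L", (8, 0, 0)),
        ])
        counts = accumulate_pair_counts([st_], "TM")
        assert counts.n_events == 1  # only (1, 3)
        assert counts.pair[AA_INDEX["A"], AA_INDEX["L"], distance_to_bin(8.0)] == 1

    def test_cross_region_pairs_dropped(self):
        st_ = make_structure([
            ("A", "A", (0, 0, 0), "TM"), ("A", "G", (4, 0, 0), "TM"),
            ("A", "L", (8, 0, 0), "EM"),
        ])
        counts = accumulate_pair_counts([st_], "TM")
        assert counts.n_events == 0

    def test_gl_region_counts_everything(self):
        st_ = make_structure([
            ("A", "A", (0, 0, 0), "TM"), ("A", "G", (4, 0, 0), "TM"),
            ("A", "L", (8, 0, 0), "EM"),
        ])
        assert accumulate_pair_counts([st_], "GL").n_events == 1

    def test_inter_chain_policy(self):
        st_ = make_structure([
            ("A", "A", (0, 0, 0)), ("A", "G", (4, 0, 0)),
            ("B", "L", (2, 5, 0)), ("B", "V", (6, 5, 0)),
        ])
        assert accumulate_pair_counts([st_], "TM").n_events == 0
        assert accumulate_pair_counts([st_], "TM", inter_chain=True).n_events == 4

    def test_unassigned_regions_error(self):
        st_ = make_structure([
            ("A", "A", (0, 0, 0), "UNASSIGNED"), ("A", "G", (4, 0, 0), "TM"),
            ("A", "L", (8, 0, 0), "TM"),
        ])
        with pytest.raises(ValueError):
            accumulate_pair_counts([st_], "TM")

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            accumulate_pair_counts([], "TM")

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        st_ = random_structure(rng, n=50, box=15.0)
        counts = accumulate_pair_counts([st_], "TM")
        pair = np.zeros_like(counts.pair)
        single = np.zeros_like(counts.single)
        res = st_.residues
        for i in range(len(res)):
            for j in range(i + 1, len(res)):
                if abs(res[i].seq_index - res[j].seq_index) <= 1:
                    continue
                if res[i].region != "TM" or res[j].region != "TM":
                    continue
                b = distance_to_bin(float(np.linalg.norm(res[i].center - res[j].center)))
                s1, s2 = AA_INDEX[res[i].aa], AA_INDEX[res[j].aa]
                pair[s1, s2, b] += 1
                pair[s2, s1, b] += 1
                single[s1, b] += 1
                single[s2, b] += 1
        np.testing.assert_array_equal(counts.pair, pair)
        np.testing.assert_array_equal(counts.single, single)
        # double-storage conservation and shared distance marginal
        assert counts.total == 2 * counts.n_events
        np.testing.assert_array_equal(counts.dist, counts.dist_single)

    def test_per_protein_additivity_and_loo_subtraction(self, small_dataset):
        structures = small_dataset.structures
        pooled = accumulate_pair_counts(structures, "TM")
        total = sum(
            (c for c in pooled.per_protein.values()),
            PairCounts.zeros("TM", pooled.scheme),
        )
        np.testing.assert_array_equal(pooled.pair, total.pair)
        held = structures[3].structure_id
        reduced = pooled.subtract(pooled.per_protein[held])
        recount = accumulate_pair_counts(
            [s for s in structures if s.structure_id != held], "TM"
        )
        np.testing.assert_array_equal(reduced.pair, recount.pair)
        np.testing.assert_array_equal(reduced.single, recount.single)

    def test_counts_tsv_round_trip(self, small_dataset):
        counts = accumulate_pair_counts(small_dataset.structures[:2], "EM")
        again = PairCounts.from_tsv(counts.to_tsv())
        assert again.region == "EM"
        np.testing.assert_array_equal(again.pair, counts.pair)
        np.testing.assert_array_equal(again.single, counts.single)


class TestSmoothing:
    def _impulse(self, b):
        c = PairCounts.zeros("TM")
        c.pair[0, 1, b] = 1.0
        c.pair[1, 0, b] = 1.0
        c.single[0, b] = 1.0
        return c

    def test_unit_impulse_response(self):
        sm = smooth_counts(self._impulse(10))
        for off in range(5):
            assert sm.single[0, 10 + off] == pytest.approx(0.75 ** off)
            assert sm.single[0, 10 - off] == pytest.approx(0.75 ** off)
        assert sm.single[0, 10 + 5] == 0.0
        # spec's printed weights for alpha = 4/3
        np.testing.assert_allclose(
            sm.single[0, 11:15], [0.75, 0.5625, 0.421875, 0.31640625]
        )

    def test_boundary_truncation_and_overflow_isolation(self):
        sm = smooth_counts(self._impulse(1))
        assert sm.single[0, 0] == pytest.approx(0.75)
        near_overflow = smooth_counts(self._impulse(22))
        assert near_overflow.single[0, 23] == 0.0  # overflow never receives
        ovf = smooth_counts(self._impulse(23))
        assert ovf.single[0, 23] == 1.0  # ...and never spreads
        assert ovf.single[0, 22] == 0.0

    def test_zero_table_stays_zero(self):
        sm = smooth_counts(PairCounts.zeros("EM"))
        assert sm.pair.sum() == 0 and sm.single.sum() == 0

    def test_random_table_matches_literal_nine_term_sum(self):
        rng = np.random.default_rng(3)
        c = PairCounts.zeros("TM")
        c.pair = rng.integers(0, 50, size=c.pair.shape).astype(float)
        c.pair = c.pair + c.pair.swapaxes(0, 1)
        c.single = rng.integers(0, 50, size=c.single.shape).astype(float)
        sm = smooth_counts(c)
        expected = np.zeros(24)
        row = c.single[5]
        for d in range(23):
            total = row[d]
            for i in range(1, 5):
                if d - i >= 0:
                    total += (3 / 4) ** i * row[d - i]
                if d + i <= 22:
                    total += (3 / 4) ** i * row[d + i]
            expected[d] = total
        expected[23] = row[23]
        np.testing.assert_allclose(sm.single[5], expected, rtol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        x = PairCounts.zeros("TM")
        y = PairCounts.zeros("TM")
        x.single = rng.random(x.single.shape)
        y.single = rng.random(y.single.shape)
        combo = PairCounts.zeros("TM")
        combo.single = 2.0 * x.single + 3.0 * y.single
        np.testing.assert_allclose(
            smooth_counts(combo).single,
            2.0 * smooth_counts(x).single + 3.0 * smooth_counts(y).single,
            rtol=1e-12,
        )

    def test_double_smoothing_rejected(self):
        sm = smooth_counts(PairCounts.zeros("TM"))
        with pytest.raises(ValueError):
            smooth_counts(sm)

    def test_kernel_is_symmetric(self):
        k = smoothing_kernel()
        np.testing.assert_array_equal(k, k.T)


def _uniform_radii(**overrides):
    radii = {a: 0.0 for a in AA_ORDER}
    radii.update(overrides)
    return RadiusTable(radii)


class TestGroupPooling:
    def test_zero_shifts_equal_member_sum(self):
        st_ = make_structure([
            ("A", "K", (0, 0, 0)), ("A", "G", (2, 0, 0)), ("A", "D", (4.6, 0, 0)),
            ("A", "R", (0, 5, 0)), ("A", "G", (2, 5, 0)), ("A", "E", (4.6, 5, 0)),
        ])
        gc = pool_group_counts(
            [st_], "TM", (GROUPS["positive"], GROUPS["negative"]), _uniform_radii()
        )
        raw = accumulate_pair_counts([st_], "TM")
        member_sum = sum(
            raw.pair[AA_INDEX[a], AA_INDEX[b]] for a in "KR" for b in "DE"
        )
        np.testing.assert_array_equal(gc.counts, member_sum)

    def test_radius_shift_moves_bin(self):
        st_ = make_structure([
            ("A", "K", (0, 0, 0)), ("A", "G", (2, 0, 0)), ("A", "D", (4.6, 0, 0)),
        ])
        radii = _uniform_radii(K=0.3)  # delta(K)=0.3, delta(D)=0
        gc = pool_group_counts(
            [st_], "TM", (GROUPS["positive"], GROUPS["negative"]), radii
        )
        assert gc.counts[distance_to_bin(4.3)] == 1
        assert gc.counts.sum() == 1

    def test_self_group_single_event(self):
        st_ = make_structure([
            ("A", "R", (0, 0, 0)), ("A", "G", (2, 0, 0)), ("A", "R", (5, 0, 0)),
        ])
        gc = pool_group_counts(
            [st_], "TM", (GROUPS["positive"], GROUPS["positive"]), _uniform_radii()
        )
        assert gc.counts.sum() == 1
        assert gc.counts[distance_to_bin(5.0)] == 1

    def test_reference_marginal_matches_full_counts(self, small_dataset):
        structures = small_dataset.structures[:3]
        gc = pool_group_counts(
            structures, "TM", (GROUPS["positive"], GROUPS["negative"]),
            _uniform_radii(),
        )
        raw = accumulate_pair_counts(structures, "TM")
        np.testing.assert_array_equal(gc.ref_dist, raw.dist)

    def test_overlapping_groups_rejected(self):
        g1 = GroupDef("x", ("K", "R"))
        g2 = GroupDef("y", ("R", "E"))
        st_ = make_structure([("A", "K", (0, 0, 0)), ("A", "G", (2, 0, 0)),
                              ("A", "E", (5, 0, 0))])
        with pytest.raises(ValueError):
            pool_group_counts([st_], "TM", (g1, g2), _uniform_radii())

    def test_group_shift_invariants(self):
        radii = _uniform_radii(K=0.5, R=1.0)
        shifts = GROUPS["positive"].shifts(radii)
        assert shifts["K"] == 0.0 and shifts["R"] == 0.5
        assert min(shifts.values()) == 0.0
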