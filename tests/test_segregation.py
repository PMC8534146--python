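import numpy as np
import pandas as pd
import pytest

from fpseg import (
    ContactMatrix,
    aggregate_domain_contacts,
    calibrate_threshold,
    call_seg_mix,
    classify_bins_cpg_sine,
    compute_drs,
    compute_ors,
    compute_ror,
    compute_rs_distance,
    compute_tc10,
    drs_series,
    lad_overlap_analysis,
    segregation_extent,
)
from fpseg.domains import DomainSet
from fpseg.segregation import SegMixResult
from conftest import random_symmetric_matrix
import oracles


def table_from_pairs(labels, pairs):
    """Build a DomainContactTable frame from {(i,j): D} with i<=j."""
    rows = []
    for (i, j), d in pairs.items():
        rows.append({"chrom": "chr1", "dom_i": i, "dom_j": j,
                     "key_i": f"chr1:{i}", "key_j": f"chr1:{j}",
                     "label_i": labels[i], "label_j": labels[j],
                     "n_bins_i": 1, "n_bins_j": 1, "contact_sum": d,
                     "D": d, "intra": i == j})
    return pd.DataFrame(rows)


class TestOrs:
    def test_hand_example(self):
        """D(F1,F2)=1, D(F1,P1)=D(F2,P1)=0.25 -> ORs(F) = 2/0.5 = 4."""
        dct = table_from_pairs("FFP", {(0, 1): 1.0, (0, 2): 0.25, (1, 2): 0.25})
        assert compute_ors(dct, "F") == pytest.approx(4.0)

    def test_uniform_pair_counting(self):
        """2 F + 2 P domains, all D equal: 2 ordered FF pairs / 4 FP pairs = 0.5."""
        labels = "FFPP"
        pairs = {(i, j): 1.0 for i in range(4) for j in range(i + 1, 4)}
        dct = table_from_pairs(labels, pairs)
        assert compute_ors(dct, "F") == pytest.approx(0.5)
        assert compute_ors(dct, "P") == pytest.approx(0.5)

    def test_zero_cross_type_errors(self):
        dct = table_from_pairs("FFP", {(0, 1): 1.0, (0, 2): 0.0, (1, 2): 0.0})
        with pytest.raises(ValueError, match="cross-type"):
            compute_ors(dct, "F")

    def test_intra_excluded(self):
        dct = table_from_pairs("FFP", {(0, 0): 9.0, (0, 1): 1.0,
                                       (0, 2): 0.5, (1, 2): 0.5})
        assert compute_ors(dct, "F") == pytest.approx(2.0)


class TestDrs:
    def test_direct_division(self):
        dct = table_from_pairs("FFP", {(0, 1): 1.0, (0, 2): 0.25, (1, 2): 0.25})
        drs = drs_series(compute_drs(dct))
        assert drs["chr1:0"] == pytest.approx(4.0)

    def test_sole_prairie_zero_numerator(self):
        dct = table_from_pairs("FFP", {(0, 1): 1.0, (0, 2): 0.25, (1, 2): 0.25})
        drs = drs_series(compute_drs(dct))
        assert drs["chr1:2"] == 0.0

    def test_no_cross_contact_undefined(self):
        dct = table_from_pairs("FFP", {(0, 1): 1.0, (0, 2): 0.0, (1, 2): 0.5})
        drs = drs_series(compute_drs(dct))
        assert np.isnan(drs["chr1:0"])  # F1 has no cross-type contact

    def test_matches_naive_oracle(self, rng):
        labels = "".join(rng.choice(["F", "P"], size=12))
        pairs = {(i, j): float(rng.uniform(0, 3))
                 for i in range(12) for j in range(i, 12)}
        dct = table_from_pairs(labels, pairs)
        drs = drs_series(compute_drs(dct))
        D = {(i, j): d for (i, j), d in pairs.items() if i != j}
        for i in range(12):
            expect = oracles.drs_naive(labels, D, i)
            got = drs[f"chr1:{i}"]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-12)


class TestRsDistance:
    def test_hand_enumeration(self):
        """Labels FFPP with C(0,1)=2, C(1,2)=1, C(2,3)=2 at d=1."""
        v = np.zeros((4, 4))
        v[0, 1] = 2.0
        v[1, 2] = 1.0
        v[2, 3] = 2.0
        v = v + v.T
        m = ContactMatrix("chr1", 40_000, v)
        rs_f = compute_rs_distance(m, list("FFPP"), "F")
        rs_p = compute_rs_distance(m, list("FFPP"), "P")
        assert rs_f[1] == pytest.approx(4.0)
        assert rs_p[1] == pytest.approx(4.0)

    def test_all_one_type_undefined(self, rng):
        m = random_symmetric_matrix(rng, 5)
        rs = compute_rs_distance(m, list("FFFFF"), "F")
        assert rs.isna().all()

    def test_scale_invariance(self, rng):
        m = random_symmetric_matrix(rng, 20)
        labels = list(rng.choice(["F", "P"], size=20))
        a = compute_rs_distance(m, labels, "F")
        b = compute_rs_distance(m.scaled(7.0), labels, "F")
        pd.testing.assert_series_equal(a, b)


class TestTc10:
    def test_single_top_pair(self, rng):
        """11-bin single diagonal: top 10% of 10 entries is the largest pair."""
        n = 11
        v = np.zeros((n, n))
        i = np.arange(n - 1)
        v[i, i + 1] = np.arange(1, n)  # values 1..10, max at (9,10)
        v = v + v.T
        labels = ["F"] * 9 + ["F", "P"]  # pair (9,10) is F-P
        m = ContactMatrix("chr1", 40_000, v + 1e-9 * random_symmetric_matrix(rng, n).values)
        tc = compute_tc10(m, labels)
        assert tuple(tc.proportions.loc[1]) == (0.0, 1.0, 0.0)

    def test_zero_in_top_tier_zeroes_triple(self):
        n = 11
        v = np.zeros((n, n))
        m = ContactMatrix("chr1", 40_000, v)
        tc = compute_tc10(m, ["F", "P"] * 5 + ["F"])
        assert (tc.proportions.loc[1] == 0).all()

    def test_positive_matrix_full_critical_distance(self, rng):
        m = random_symmetric_matrix(rng, 30)
        labels = list(rng.choice(["F", "P"], size=30))
        tc = compute_tc10(m, labels)
        assert tc.critical_distance_bp == 29 * 40_000
        assert not tc.interleaved

    def test_triples_sum_to_one_or_zero(self, rng):
        m = random_symmetric_matrix(rng, 40)
        labels = list(rng.choice(["F", "P"], size=40))
        tc = compute_tc10(m, labels)
        sums = tc.proportions.sum(axis=1)
        assert ((np.isclose(sums, 1.0)) | (sums == 0)).all()

    def test_matches_naive_oracle(self, rng):
        m = random_symmetric_matrix(rng, 25)
        labels = list(rng.choice(["F", "P"], size=25))
        tc = compute_tc10(m, labels)
        for d in (1, 5, 12, 24):
            expect = oracles.tc10_naive(m.values, labels, d)
            assert tuple(tc.proportions.loc[d]) == pytest.approx(expect, abs=1e-12)


def drs_frame(values, labels=None):
    n = len(values)
    labels = labels or ["F"] * n
    return pd.DataFrame({"domain": [f"chr1:{i}" for i in range(n)],
                         "label": labels, "drs": values})


class TestCalibration:
    def test_identical_replicates_zero_threshold(self):
        d = drs_frame([1.0, 2.0, 3.0] * 20)
        t = calibrate_threshold(drs_series(d), drs_series(d))
        assert t == 0.0

    def test_gaussian_noise_recovers_two_sigma(self):
        """ln-ratio noise N(0, 0.075) calibrates near 1.96 sigma = 0.147."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            r = rng.normal(0, 0.075, size=2000)
            d1 = drs_frame(np.exp(r))
            d2 = drs_frame(np.ones(2000))
            t = calibrate_threshold(drs_series(d1), drs_series(d2))
            hits += 0.132 <= t <= 0.162
        assert hits >= 48

    def test_insufficient_domains_rejected(self):
        d = drs_frame([1.0] * 30)
        with pytest.raises(ValueError, match="insufficient"):
            calibrate_threshold(drs_series(d), drs_series(d))


class TestSegMixCalls:
    def test_halving_is_mix(self):
        e = drs_frame([2.0])
        l = drs_frame([1.0])
        res = call_seg_mix(e, l, 0.1469)
        assert res.calls["call"].iloc[0] == "mix"
        assert res.calls["log_ratio"].iloc[0] == pytest.approx(np.log(0.5))

    def test_unchanged_is_neutral(self):
        e = drs_frame([2.0])
        res = call_seg_mix(e, e, 0.1469)
        assert res.calls["call"].iloc[0] == "neutral"

    def test_zero_drs_undefined(self):
        e = drs_frame([0.0])
        l = drs_frame([1.0])
        res = call_seg_mix(e, l, 0.1469)
        assert res.calls["call"].iloc[0] == "undefined"

    def test_calls_partition_domains(self, rng):
        n = 200
        e = drs_frame(rng.uniform(0, 2, n), list(rng.choice(["F", "P"], n)))
        l = drs_frame(rng.uniform(0, 2, n), list(e["label"]))
        res = call_seg_mix(e, l, 0.2)
        assert res.calls["call"].isin(["seg", "mix", "neutral", "undefined"]).all()
        assert len(res.calls) == n


class TestRor:
    def test_log_two(self):
        d1 = pd.Series(np.r_[np.full(20, 2.0), np.full(10, 0.5)])
        d2 = pd.Series(np.ones(30))
        res = compute_ror(d1, d2)
        assert (res.n_ij, res.n_ji) == (20, 10)
        assert res.ror == pytest.approx(np.log(2))

    def test_balanced_is_zero(self):
        d1 = pd.Series([2.0, 0.5])
        d2 = pd.Series([1.0, 1.0])
        assert compute_ror(d1, d2).ror == 0.0

    def test_antisymmetry(self, rng):
        d1 = pd.Series(rng.uniform(0.5, 2, 50))
        d2 = pd.Series(rng.uniform(0.5, 2, 50))
        assert compute_ror(d1, d2).ror == -compute_ror(d2, d1).ror

    def test_one_sided_warns_infinite(self):
        d1 = pd.Series([2.0, 3.0])
        d2 = pd.Series([1.0, 1.0])
        with pytest.warns(UserWarning, match="one-sided"):
            assert compute_ror(d1, d2).ror == np.inf


class TestSegregationExtent:
    def test_uniform_matrix_unity(self):
        m = ContactMatrix("chr1", 40_000, np.ones((8, 8)))
        cls = classify_bins_cpg_sine([1, 2, 3, 4, 1, 2, 3, 4],
                                     [4, 4, 4, 4, 1, 1, 1, 1])
        ex = segregation_extent(m, cls, "hChS", "hClS")
        assert ex == (1.0, 1.0)

    def test_block_matrix(self):
        """Within-class mean 2, cross-class mean 1 -> extents (2, 2)."""
        v = np.ones((8, 8))
        hi = np.arange(4)
        lo = np.arange(4, 8)
        v[np.ix_(hi, hi)] = 2.0
        v[np.ix_(lo, lo)] = 2.0
        m = ContactMatrix("chr1", 40_000, v)
        cls = classify_bins_cpg_sine([3, 3, 3, 3, 1, 1, 1, 1.5],
                                     [4, 4, 4, 4, 1, 1, 1, 1.5])
        # bins 0-3 are hChS, bins 4-7 lClS
        ex = segregation_extent(m, cls, "hChS", "lClS")
        assert ex == (2.0, 2.0)

    def test_empty_group_errors(self, rng):
        m = random_symmetric_matrix(rng, 6)
        cls = classify_bins_cpg_sine([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        with pytest.raises(ValueError, match="empty"):
            segregation_extent(m, cls, "hChS", "lClS")  # no bin is high-C high-S here?
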