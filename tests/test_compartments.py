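import numpy as np
import pandas as pd
import pytest

from fpseg import (
    CompartmentTrack,
    ContactMatrix,
    aggregate_signal,
    call_compartments,
    classify_prairie_dynamics,
    compute_cindex,
    distance_normalize,
    fp_compartment_composition,
    strict_compartments,
    transition_composition,
)
from fpseg.domains import DomainSet
import oracles


def two_block_matrix(n=40, within=2.0, cross=0.5, resolution=200_000):
    """Alternating 10-bin blocks of two types with flat distance profile."""
    types = (np.arange(n) // 10) % 2
    v = np.where(np.equal.outer(types, types), within, cross).astype(float)
    m = ContactMatrix("chr1", resolution, v, norm_state="distance")
    return m, types


def make_track(delta, cindex=None, resolution=200_000):
    delta = np.asarray(delta, dtype=float)
    return CompartmentTrack("chr1", resolution, pc1=np.where(delta == 1, 1.0, -1.0),
                            delta=delta, cindex=cindex)


class TestCallCompartments:
    def test_checkerboard_separated_exactly(self):
        m, types = two_block_matrix()
        cpg = np.where(types == 0, 1.0, 0.1)  # type 0 is CpG rich -> A
        track = call_compartments(m, cpg)
        assert np.array_equal(track.delta, np.where(types == 0, 1.0, 0.0))

    def test_cpg_orientation_pins_a_to_high_cpg(self):
        m, types = two_block_matrix()
        cpg = np.where(types == 1, 1.0, 0.1)  # now the other block is CpG rich
        track = call_compartments(m, cpg)
        assert np.array_equal(track.delta, np.where(types == 1, 1.0, 0.0))

    def test_uniform_matrix_degenerate(self):
        m = ContactMatrix("chr1", 200_000, np.ones((30, 30)), norm_state="distance")
        with pytest.raises(ValueError):
            call_compartments(m, np.arange(30.0))

    def test_requires_distance_normalized(self):
        m, types = two_block_matrix()
        m = ContactMatrix(m.chrom, m.resolution_bp, m.values, norm_state="raw")
        with pytest.raises(ValueError, match="distance"):
            call_compartments(m, np.arange(40.0))


class TestCindex:
    def test_equal_contact_gives_zero(self):
        m, types = two_block_matrix(within=1.0, cross=1.0)
        track = make_track((types == 0).astype(float))
        out = compute_cindex(m, track)
        assert np.allclose(out.cindex, 0.0)

    def test_direct_arithmetic(self):
        """Mean contact 2 to A vs 1 to B -> I = ln 2."""
        m, types = two_block_matrix(within=2.0, cross=1.0)
        track = make_track((types == 0).astype(float))
        out = compute_cindex(m, track)
        a_bin = np.flatnonzero(types == 0)[0]
        # bin in A: to-A entries are `within` (2), to-B are `cross` (1)
        assert out.cindex[a_bin] == pytest.approx(np.log(2))

    def test_scale_invariance(self):
        m, types = two_block_matrix()
        track = make_track((types == 0).astype(float))
        a = compute_cindex(m, track).cindex
        b = compute_cindex(m.scaled(2.0), track).cindex
        assert np.allclose(a, b)

    def test_matches_naive_oracle(self, rng):
        n = 30
        a = rng.uniform(0.1, 3, size=(n, n))
        v = (a + a.T) / 2
        m = ContactMatrix("chr1", 200_000, v, norm_state="distance")
        delta = rng.choice([0.0, 1.0], size=n)
        delta[:2] = [0.0, 1.0]
        track = make_track(delta)
        out = compute_cindex(m, track)
        for i in range(n):
            assert out.cindex[i] == pytest.approx(
                oracles.cindex_naive(v, delta, i), abs=1e-12)

    def test_single_compartment_errors(self):
        m, types = two_block_matrix()
        track = make_track(np.ones(40))
        with pytest.raises(ValueError, match="both compartments"):
            compute_cindex(m, track)


class TestStrictAndComposition:
    def test_strict_labels_and_lengths(self):
        """10 bins at 200 kb: 6 sA (4F+2P), 4 sB (1F+3P)."""
        delta = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        cindex = np.array([1, 1, 1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
        track = make_track(delta, cindex)
        fp = ["F", "F", "F", "F", "P", "P", "F", "P", "P", "P"]
        out, lengths = strict_compartments(track, fp)
        assert lengths == {"sAf": 800_000, "sAp": 400_000,
                           "sBf": 200_000, "sBp": 600_000}
        assert list(out.strict[:2]) == ["sA", "sA"]

    def test_discordant_bin_dropped_from_strict(self):
        delta = np.array([1.0, 0.0] * 10)
        cindex = np.array([-0.5, -0.5] * 10)  # A bins have negative C-index
        track = make_track(delta, cindex)
        out, lengths = strict_compartments(track, ["F", "P"] * 10)
        assert (np.asarray(out.strict)[delta == 1] == "none").all()
        assert lengths["sAf"] == 0

    def test_composition_sums_to_one(self, rng):
        delta = rng.choice([0.0, 1.0], size=50)
        track = make_track(delta)
        fp = list(rng.choice(["F", "P"], size=50))
        comp = fp_compartment_composition(track, fp)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_aligned_composition(self):
        delta = np.array([1.0] * 5 + [0.0] * 5)
        track = make_track(delta)
        fp = ["F"] * 5 + ["P"] * 5
        comp = fp_compartment_composition(track, fp)
        assert comp == {"Af": 0.5, "Bf": 0.0, "Ap": 0.0, "Bp": 0.5}


def prairie_domains(n=6, bins_per=5, resolution=200_000):
    """Alternating F/P domains of fixed size."""
    size = bins_per * resolution
    iv = [(i * size, (i + 1) * size) for i in range(n)]
    labels = ["F" if i % 2 == 0 else "P" for i in range(n)]
    return DomainSet.from_intervals("chr1", iv, labels)


class TestPrairieDynamics:
    def test_planted_trajectories_recovered(self):
        doms = prairie_domains()
        n_bins = 30

        def stage(delta_by_domain):
            delta = np.repeat(delta_by_domain, 5).astype(float)
            return make_track(delta)

        # prairie domains have ids 1, 3, 5; forests fixed in A
        tracks = {
            "s1": stage([1, 0, 1, 1, 1, 0]),
            "s2": stage([1, 0, 1, 0, 1, 0]),
            "s3": stage([1, 0, 1, 1, 1, 0]),
        }
        dyn = classify_prairie_dynamics(tracks, doms)
        assert dyn.classes["chr1:1"] == "stable_Bp"
        assert dyn.classes["chr1:3"] == "switchable_p"
        assert dyn.classes["chr1:5"] == "stable_Bp"

    def test_stable_a_prairie(self):
        doms = prairie_domains(n=4)
        delta = np.repeat([1, 1, 1, 0], 5).astype(float)
        tracks = {"a": make_track(delta), "b": make_track(delta)}
        dyn = classify_prairie_dynamics(tracks, doms)
        assert dyn.classes["chr1:1"] == "stable_Ap"
        assert set(dyn.classes.index) == {"chr1:1", "chr1:3"}

    def test_classes_partition_prairies(self):
        doms = prairie_domains()
        rng = np.random.default_rng(3)
        tracks = {f"s{k}": make_track(rng.choice([0.0, 1.0], 30)) for k in range(4)}
        dyn = classify_prairie_dynamics(tracks, doms)
        assert len(dyn.classes) == 3
        assert set(dyn.classes).issubset({"stable_Ap", "stable_Bp", "switchable_p"})

    def test_grid_mismatch_rejected(self):
        doms = prairie_domains()
        t1 = make_track(np.zeros(30))
        t2 = make_track(np.zeros(25))
        with pytest.raises(ValueError, match="grid"):
            classify_prairie_dynamics({"a": t1, "b": t2}, doms)


class TestTransitions:
    def test_identical_tracks_no_flips(self):
        t = make_track([1, 1, 0, 0, 1, 0])
        out = transition_composition(t, t)
        assert out["AB"] == 0.0 and out["BA"] == 0.0
        assert out["AA"] + out["BB"] == pytest.approx(1.0)

    def test_total_flip(self):
        t1 = make_track([1, 1, 1, 0, 0, 0, 0, 0])
        t2 = make_track([0, 0, 0, 0, 0, 0, 0, 0])
        out = transition_composition(t1, t2)
        assert out["AB"] == pytest.approx(3 / 8)
        assert out["AA"] == 0.0

    def test_hand_counted_eight_bins(self):
        t1 = make_track([1, 1, 0, 0, 1, 0, 1, 0])
        t2 = make_track([1, 0, 1, 0, 1, 0, 0, 1])
        out = transition_composition(t1, t2)
        assert out == {"AA": 2 / 8, "AB": 2 / 8, "BA": 2 / 8, "BB": 2 / 8}


class TestAggregateSignal:
    def test_constant_signal(self):
        sig = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [1000], "value": [2.0]})
        reg = pd.DataFrame({"chrom": "chr1", "start": [100], "end": [300]})
        out = aggregate_signal(sig, reg)
        assert out["mean"].iloc[0] == 2.0
        assert out["coverage"].iloc[0] == 1.0

    def test_weighted_mean(self):
        sig = pd.DataFrame({"chrom": "chr1", "start": [0, 50], "end": [50, 100],
                            "value": [1.0, 3.0]})
        reg = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [100]})
        assert aggregate_signal(sig, reg)["mean"].iloc[0] == 2.0

    def test_uncovered_region_zero(self):
        sig = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [10], "value": [5.0]})
        reg = pd.DataFrame({"chrom": "chr1", "start": [100], "end": [200]})
        out = aggregate_signal(sig, reg)
        assert out["mean"].iloc[0] == 0.0
        assert out["coverage"].iloc[0] == 0.0

    def test_overlapping_signal_rejected(self):
        sig = pd.DataFrame({"chrom": "chr1", "start": [0, 5], "end": [10, 15],
                            "value": [1.0, 2.0]})
        reg = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [10]})
        with pytest.raises(ValueError, match="overlap"):
            aggregate_signal(sig, reg)
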