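import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromassay.errors import PackingError, ParameterError, RangeError
from chromassay.lane import GelModel
from chromassay.synthetic_gel import (
    FragmentSample,
    NucleosomeArray,
    TwoStepParams,
    circular_distance,
    digest_mnase,
    generate_random_array,
    generate_spaced_array,
    overall_half_time,
    render_gel_profile,
    simulate_ladder_lane,
    simulate_supercoiling_lane,
    simulate_two_step,
    two_step_terminal_fraction,
)


# ---------------------------------------------------------------------------
# array generation
# ---------------------------------------------------------------------------

class TestRandomArray:
    def test_empty_case(self):
        arr = generate_random_array(3000, 0, 147, seed=1)
        assert arr.n_nucleosomes == 0
        assert arr.dyads.size == 0

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_saturated_circle_forces_unique_spacing(self, seed):
        # 2 x 147 bp on a 294 bp circle: the only packing is 147 bp apart
        arr = generate_random_array(294, 2, 147, seed=seed, circular=True)
        d = circular_distance(arr.dyads[0], arr.dyads[1], 294)
        assert d == 147

    def test_infeasible_density_raises(self):
        with pytest.raises(PackingError):
            generate_random_array(1000, 10, 147, seed=0)

    def test_deterministic_per_seed(self):
        a = generate_random_array(3000, 10, 147, seed=5)
        b = generate_random_array(3000, 10, 147, seed=5)
        assert np.array_equal(a.dyads, b.dyads)
        c = generate_random_array(3000, 10, 147, seed=6)
        assert not np.array_equal(a.dyads, c.dyads)

    def test_matches_brute_force_rejection_oracle(self):
        # oracle: naive joint rejection sampling of 10 dyads on a 3000 bp
        # circle, keeping only configurations obeying the hard-core exclusion
        L, n, f = 3000, 10, 147
        rng = np.random.default_rng(12345)
        oracle_nn = []
        accepted = 0
        while accepted < 500:
            cand = np.sort(rng.integers(0, L, size=(4000, n)), axis=1)
            gaps = np.diff(cand, axis=1)
            wrap = L - (cand[:, -1] - cand[:, 0])
            ok = (gaps.min(axis=1) >= f) & (wrap >= f)
            for row in cand[ok]:
                if accepted >= 500:
                    break
                g = np.append(np.diff(row), L - (row[-1] - row[0]))
                nn = np.minimum(g, np.roll(g, 1))
                oracle_nn.extend(nn.tolist())
                accepted += 1
        impl_nn = []
        for seed in range(500):
            arr = generate_random_array(L, n, f, seed=seed)
            g = arr.nucleosome_gaps()
            impl_nn.extend(np.minimum(g, np.roll(g, 1)).tolist())
        p = stats.ks_2samp(np.asarray(oracle_nn), np.asarray(impl_nn)).pvalue
        assert p > 0.01

    @given(
        n=st.integers(min_value=0, max_value=15),
        template=st.integers(min_value=2300, max_value=6000),
        seed=st.integers(min_value=0, max_value=10_000),
        circular=st.booleans(),
    )
    @settings(max_examples=40, deadline=None)
    def test_packing_invariant(self, n, template, seed, circular):
        arr = generate_random_array(template, n, 147, seed=seed, circular=circular)
        gaps = arr.nucleosome_gaps()
        assert np.all(gaps >= 147)
        if n:
            assert arr.dyads.min() >= 0 and arr.dyads.max() < template


class TestSpacedArray:
    def test_zero_jitter_exact_repeat(self):
        arr = generate_spaced_array(3000, 200, 0, 147, seed=3)
        assert arr.n_nucleosomes == 15
        assert set(arr.nucleosome_gaps()) == {200.0}

    def test_jitter_preserves_mean_gap(self):
        arr = generate_spaced_array(3000, 200, 10, 147, seed=3)
        succ = np.diff(arr.dyads)
        assert abs(succ.mean() - 200) <= 3

    def test_repeat_not_exceeding_footprint_raises(self):
        with pytest.raises(ParameterError):
            generate_spaced_array(3000, 147, 0, 147, seed=1)

    @pytest.mark.parametrize("jitter", [0, 5, 20, 80])
    def test_exclusion_maintained_under_any_jitter(self, jitter):
        for seed in range(10):
            arr = generate_spaced_array(3000, 200, jitter, 147, seed=seed)
            assert np.all(arr.nucleosome_gaps() >= 147)


# ---------------------------------------------------------------------------
# MNase digestion
# ---------------------------------------------------------------------------

class TestDigestion:
    @pytest.mark.parametrize(
        "array_fn",
        [
            lambda s: generate_random_array(3000, 10, 147, seed=s),
            lambda s: generate_spaced_array(3000, 200, 10, 147, seed=s),
        ],
        ids=["random", "spaced"],
    )
    def test_complete_digestion_limit(self, array_fn):
        # cut probability 1 with trimming: only footprint-length fragments
        for seed in range(5):
            arr = array_fn(seed)
            sample = digest_mnase(arr, 1.0, trimming=True, seed=seed)
            assert np.array_equal(sample.lengths, [147])
            assert sample.counts[0] == arr.n_nucleosomes

    def test_no_cuts_on_circle_gives_empty_sample(self):
        arr = generate_random_array(3000, 5, 147, seed=2)
        assert digest_mnase(arr, 0.0, seed=1).is_empty()

    def test_uncut_linear_template_is_one_fragment(self):
        arr = generate_random_array(3000, 5, 147, seed=2, circular=False)
        sample = digest_mnase(arr, 0.0, trimming=False, seed=1)
        assert sample.lengths.tolist() == [3000] and sample.counts.tolist() == [1]

    def test_bad_probability_raises(self):
        arr = generate_random_array(3000, 5, 147, seed=2)
        with pytest.raises(ParameterError):
            digest_mnase(arr, 1.5)
        with pytest.raises(ParameterError):
            digest_mnase(arr, -0.1)

    def test_enumeration_oracle_three_nucleosomes(self):
        # 3 nucleosomes at 200 bp spacing on a 600 bp circle. Under the
        # linker-cut model with trimming, fragment lengths depend only on
        # WHICH linkers are cut, so the exact expected counts per length
        # can be enumerated over the 8 cut configurations:
        #   1 cut  -> one  547 bp (tri)   P = 3 p (1-p)^2
        #   2 cuts -> one 147 + one 347   P = 3 p^2 (1-p)
        #   3 cuts -> three 147           P = p^3
        p = 0.5
        expect = {
            147: 3 * p**2 * (1 - p) * 1 + p**3 * 3,
            347: 3 * p**2 * (1 - p) * 1,
            547: 3 * p * (1 - p) ** 2 * 1,
        }
        arr = NucleosomeArray(600, True, [100, 300, 500], 147)
        n_sim = 4000
        counts = {147: 0, 347: 0, 547: 0}
        for seed in range(n_sim):
            s = digest_mnase(arr, p, trimming=True, seed=seed)
            for length, count in zip(s.lengths, s.counts):
                assert int(length) in counts, f"unexpected length {length}"
                counts[int(length)] += int(count)
        for length, mean in expect.items():
            observed = counts[length] / n_sim
            sd = math.sqrt(mean / n_sim) * 3  # generous: counts are near-Poisson
            assert abs(observed - mean) < max(3 * sd, 0.05)

    def test_partial_digest_ladder_modes(self):
        # pooled fragment lengths from many digests of spaced arrays show
        # local modes at the trimmed k-mer lengths k*repeat - mean_linker
        pooled = []
        for seed in range(200):
            arr = generate_spaced_array(3000, 200, 5, 147, seed=seed)
            s = digest_mnase(arr, 0.5, trimming=True, seed=10_000 + seed)
            pooled.append(np.repeat(s.lengths, s.counts))
        lengths = np.concatenate(pooled)
        hist, edges = np.histogram(lengths, bins=np.arange(50, 1200, 10))
        centers = 0.5 * (edges[:-1] + edges[1:])
        linker = 200 - 147
        for k in (1, 2, 3):
            expected = 200 * k - linker
            near = np.abs(centers - expected) <= 40
            mode = centers[near][np.argmax(hist[near])]
            assert abs(mode - expected) <= 15


# ---------------------------------------------------------------------------
# lane rendering
# ---------------------------------------------------------------------------

class TestRendering:
    def test_single_band_argmax_at_migration(self, quiet_gel):
        sample = FragmentSample.from_lengths([400] * 3)
        profile = render_gel_profile(sample, quiet_gel, seed=0)
        peak = profile.positions[np.argmax(profile.intensities)]
        assert abs(peak - quiet_gel.migration(400.0)) <= 1.0

    def test_mass_proportional_band_areas(self, quiet_gel):
        # equal counts of L and 2L: integrated areas 1:2
        sample = FragmentSample(np.array([200, 400]), np.array([5, 5]))
        profile = render_gel_profile(sample, quiet_gel, seed=0)
        m200, m400 = quiet_gel.migration(200.0), quiet_gel.migration(400.0)
        split = 0.5 * (m200 + m400)
        x, y = profile.positions, profile.intensities
        area_small = np.trapezoid(y[x > split], x[x > split])
        area_big = np.trapezoid(y[x <= split], x[x <= split])
        assert area_big / area_small == pytest.approx(2.0, rel=1e-3)

    def test_mass_conservation(self, quiet_gel):
        sample = FragmentSample(np.array([150, 400, 900]), np.array([4, 2, 7]))
        profile = render_gel_profile(sample, quiet_gel, seed=0, stain_constant=0.7)
        expected = 0.7 * float(np.dot(sample.counts, sample.lengths))
        assert profile.total_signal() == pytest.approx(expected, rel=1e-6)

    def test_out_of_range_length_raises(self, quiet_gel):
        sample = FragmentSample.from_lengths([10])
        with pytest.raises(RangeError):
            render_gel_profile(sample, quiet_gel)

    def test_empty_sample_raises(self, quiet_gel):
        with pytest.raises(ParameterError):
            render_gel_profile(FragmentSample.from_lengths([]), quiet_gel)

    def test_deterministic_per_seed(self, gel):
        sample = FragmentSample.from_lengths([300, 300, 500])
        a = render_gel_profile(sample, gel, seed=9)
        b = render_gel_profile(sample, gel, seed=9)
        assert np.array_equal(a.intensities, b.intensities)


class TestMobilityModel:
    def test_monotone_decreasing(self, gel):
        lengths = np.linspace(gel.min_length, gel.max_length, 200)
        m = gel.migration(lengths)
        assert np.all(np.diff(m) < 0)

    def test_round_trip_identity(self, gel):
        lengths = np.array([60.0, 147.0, 347.0, 1000.0, 5000.0])
        back = gel.length_from_migration(gel.migration(lengths))
        assert np.allclose(back, lengths, rtol=1e-12)

    def test_invalid_model_rejected(self):
        with pytest.raises(ParameterError):
            GelModel(slope=10.0)
        with pytest.raises(ParameterError):
            GelModel(band_width=0.0)
        with pytest.raises(ParameterError):
            GelModel(axis_length=50)


# ---------------------------------------------------------------------------
# supercoiling lane simulation
# ---------------------------------------------------------------------------

class TestSupercoilingLane:
    def test_truth_fractions_closed_form(self, gel):
        _, truth = simulate_supercoiling_lane(0.6, 25, 0.2, gel, seed=0)
        assert truth["sc"] == pytest.approx(0.48)
        assert truth["rel"] == pytest.approx(0.32)
        assert truth["nick"] == pytest.approx(0.2)

    def test_all_relaxed_when_unassembled(self, quiet_gel):
        profile, truth = simulate_supercoiling_lane(0.0, 25, 0.0, quiet_gel, seed=0)
        assert truth["sc"] == 0.0
        # all signal near the relaxed cluster position
        p_rel = profile.metadata["p_rel"]
        x, y = profile.positions, profile.intensities
        near = np.abs(x - p_rel) < 6 * quiet_gel.band_width
        assert np.trapezoid(y[near], x[near]) == pytest.approx(1.0, abs=0.01)

    def test_invalid_fractions_raise(self, gel):
        with pytest.raises(ParameterError):
            simulate_supercoiling_lane(1.2, 25, 0.0, gel)
        with pytest.raises(ParameterError):
            simulate_supercoiling_lane(0.5, 25, -0.1, gel)


# ---------------------------------------------------------------------------
# two-step kinetics
# ---------------------------------------------------------------------------

class TestTwoStep:
    def test_asymptote_reaches_amplitude(self):
        params = TwoStepParams(0.3, 0.1, amp_spacing=2.5)
        tc = simulate_two_step(params, [0.0, 1e6], "overall_spacing")
        assert tc.values[-1] == pytest.approx(2.5, rel=1e-9)

    def test_equal_rates_closed_form(self):
        # at kt = 1 the terminal fraction is 1 - 2/e
        params = TwoStepParams(0.5, 0.5)
        tc = simulate_two_step(params, [0.0, 2.0], "overall_spacing")
        assert tc.values[-1] == pytest.approx(1.0 - 2.0 / math.e, rel=1e-9)

    def test_individual_observables_are_first_order(self):
        params = TwoStepParams(0.4, 0.15, amp_supercoiling=65.0, amp_spacing=1.2)
        t = np.array([0.0, 1.0, 3.0, 9.0])
        sc = simulate_two_step(params, t, "supercoiling")
        assert np.allclose(sc.values, 65.0 * (1 - np.exp(-0.4 * t)))
        sp = simulate_two_step(params, t, "spacing_index")
        assert np.allclose(sp.values, 1.2 * (1 - np.exp(-0.15 * t)))

    def test_half_time_ordering_numerical(self):
        # overall half-time exceeds both individual half-times: root-finding
        for k1 in (0.05, 0.2, 0.8):
            for k2 in (0.05, 0.2, 0.8):
                t_half = overall_half_time(k1, k2)
                assert t_half > math.log(2) / k1
                assert t_half > math.log(2) / k2

    def test_degenerate_equal_rates_no_division_error(self):
        out = two_step_terminal_fraction(0.3, 0.3, np.linspace(0, 50, 20))
        assert np.all(np.isfinite(out))
        assert out[-1] == pytest.approx(1.0, abs=1e-4)

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            TwoStepParams(0.0, 0.1)
        params = TwoStepParams(0.1, 0.1)
        with pytest.raises(ParameterError):
            simulate_two_step(params, [-1.0, 0.0], "supercoiling")
        with pytest.raises(ParameterError):
            simulate_two_step(params, [0.0, 1.0], "bogus")


class TestLadderLane:
    def test_spaced_beats_random_smoke(self, gel):
        from chromassay.densitometry import (
            BandWindows,
            compute_spacing_index,
            subtract_background,
        )

        windows = BandWindows.from_calibration(gel, 200)
        wins = 0
        for seed in range(10):
            ps, _ = simulate_ladder_lane("spaced", 40, gel, seed=seed)
            pr, _ = simulate_ladder_lane("random", 40, gel, seed=seed + 500)
            idx_s = compute_spacing_index(subtract_background(ps), windows).index
            idx_r = compute_spacing_index(subtract_background(pr), windows).index
            wins += idx_s > idx_r
        assert wins >= 9

    def test_bad_kind_raises(self, gel):
        with pytest.raises(ParameterError):
            simulate_ladder_lane("striped", 10, gel, seed=0)
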