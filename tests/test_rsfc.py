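import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietconn.rsfc import (
    ConnectivityMatrix,
    bandpass,
    connectivity_matrix,
    framewise_displacement,
    internetwork_summaries,
    nuisance_regress,
    process_participant,
    rms_signal_change,
    scrub_and_replace,
)
from dietconn.synthetic import SimulationConfig, build_parcellation, generate_roi_timeseries


def make_parcellation(networks, spacing=30.0):
    """Parcellation with the given labels, all centers `spacing` mm apart."""
    n = len(networks)
    side = int(np.ceil(n ** (1 / 3))) + 1
    coords = [
        (spacing * x, spacing * y, spacing * z)
        for x in range(side) for y in range(side) for z in range(side)
    ][:n]
    return pd.DataFrame(
        {
            "roi_id": range(n),
            "x_mm": [c[0] for c in coords],
            "y_mm": [c[1] for c in coords],
            "z_mm": [c[2] for c in coords],
            "network": networks,
        }
    )


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero_trace(self):
        motion = np.tile([1.0, -2.0, 0.5, 0.01, 0.0, -0.01], (20, 1))
        assert np.all(framewise_displacement(motion) == 0.0)

    def test_single_translation_step(self):
        motion = np.zeros((10, 6))
        motion[5:, 0] = 0.3
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.3)
        assert np.all(np.delete(fd, 5) == 0.0)

    def test_rotation_arc_length_on_50mm_sphere(self):
        motion = np.zeros((10, 6))
        motion[5:, 4] = 0.01  # radians
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.5)  # 50 mm * 0.01 rad

    def test_first_frame_zero(self, rng):
        fd = framewise_displacement(rng.normal(size=(30, 6)))
        assert fd[0] == 0.0
        assert fd.shape == (30,)

    def test_wrong_column_count_rejected(self, rng):
        with pytest.raises(ValueError):
            framewise_displacement(rng.normal(size=(30, 5)))


class TestScrubAndReplace:
    def test_clean_input_untouched(self, rng):
        ts = rng.normal(size=(50, 3))
        out, pct = scrub_and_replace(ts, np.zeros(50), 0.5)
        np.testing.assert_array_equal(out, ts)
        assert pct == 0.0

    def test_scrub_percentage_arithmetic(self, rng):
        ts = rng.normal(size=(100, 2))
        fd = np.zeros(100)
        fd[42] = 1.0
        _, pct = scrub_and_replace(ts, fd, 0.5)
        assert pct == pytest.approx(1.0)

    def test_linear_interpolation_midpoint(self):
        ts = np.array([[2.0], [100.0], [4.0]])
        fd = np.array([0.0, 9.0, 0.0])
        out, _ = scrub_and_replace(ts, fd, 0.5)
        assert out[1, 0] == pytest.approx(3.0)

    def test_edge_frames_take_nearest_clean_value(self):
        ts = np.array([[99.0], [1.0], [2.0], [88.0]])
        fd = np.array([0.0, 0.0, 0.0, 9.0])
        fd[0] = 9.0
        out, pct = scrub_and_replace(ts, fd, 0.5)
        assert out[0, 0] == pytest.approx(1.0)
        assert out[3, 0] == pytest.approx(2.0)
        assert pct == pytest.approx(50.0)

    def test_frame_count_preserved(self, rng):
        ts = rng.normal(size=(40, 4))
        fd = rng.uniform(0, 1, 40)
        fd[3] = 0.0  # keep at least one clean frame
        out, _ = scrub_and_replace(ts, fd, 0.5)
        assert out.shape == ts.shape

    def test_all_contaminated_rejected(self, rng):
        with pytest.raises(ValueError):
            scrub_and_replace(rng.normal(size=(10, 2)), np.full(10, 2.0), 0.5)


class TestBandpass:
    """Transfer-function bounds checked against a plain FFT amplitude oracle."""

    @staticmethod
    def amplitude_ratio(freq_hz, tr=2.0, n=800):
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq_hz * t)[:, None]
        y = bandpass(x, tr)
        core = slice(n // 4, 3 * n // 4)  # avoid filtfilt edge transients
        spectrum_in = np.abs(np.fft.rfft(x[core, 0]))
        spectrum_out = np.abs(np.fft.rfft(y[core, 0]))
        k = spectrum_in.argmax()
        return spectrum_out[k] / spectrum_in[k]

    def test_passband_tone_preserved(self):
        assert self.amplitude_ratio(0.04) >= 0.9

    def test_stopband_tone_attenuated(self):
        assert self.amplitude_ratio(0.2) <= 0.1

    def test_dc_removed(self):
        x = np.full((200, 3), 7.5)
        y = bandpass(x, tr=2.0)
        assert np.max(np.abs(y)) < 1e-8 * 7.5

    def test_output_mean_zero(self, rng):
        y = bandpass(rng.normal(size=(300, 4)), tr=2.0)
        np.testing.assert_allclose(y.mean(axis=0), 0, atol=1e-10)

    def test_invalid_band_rejected(self, rng):
        with pytest.raises(ValueError):
            bandpass(rng.normal(size=(100, 1)), tr=2.0, f_low=0.01, f_high=0.3)


class TestNuisanceRegress:
    def test_nuisance_column_fully_removed(self, rng):
        nuis = rng.normal(size=(60, 2))
        ts = np.column_stack([nuis[:, 0], rng.normal(size=60)])
        out = nuisance_regress(ts, nuis)
        np.testing.assert_allclose(out[:, 0], 0, atol=1e-10)

    def test_orthogonal_meanzero_column_unchanged(self, rng):
        nuis = rng.normal(size=(60, 2))
        y = rng.normal(size=60)
        # project y off the intercept+nuisance span to build an orthogonal column
        X = np.column_stack([np.ones(60), nuis])
        y_perp = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        out = nuisance_regress(y_perp[:, None], nuis)
        np.testing.assert_allclose(out[:, 0], y_perp, atol=1e-10)

    def test_residuals_orthogonal_to_nuisance(self, rng):
        nuis = rng.normal(size=(30, 4))
        ts = rng.normal(size=(30, 6))
        out = nuisance_regress(ts, nuis)
        dots = nuis.T @ out
        assert np.max(np.abs(dots)) < 1e-6 * np.abs(nuis.T @ ts).max()

    def test_matches_independent_least_squares_oracle(self, rng):
        import statsmodels.api as sm
        nuis = rng.normal(size=(30, 3))
        ts = rng.normal(size=(30, 5))
        out = nuisance_regress(ts, nuis)
        X = sm.add_constant(nuis)
        for j in range(ts.shape[1]):
            oracle = sm.OLS(ts[:, j], X).fit().resid
            np.testing.assert_allclose(out[:, j], oracle, atol=1e-8)

    def test_collinear_traces_rejected(self, rng):
        base = rng.normal(size=30)
        with pytest.raises(ValueError):
            nuisance_regress(rng.normal(size=(30, 2)),
                             np.column_stack([base, 2 * base]))


class TestConnectivityMatrix:
    def test_matches_pairwise_pearson_oracle(self, rng):
        ts = rng.normal(size=(40, 5))
        parc = make_parcellation(["A"] * 3 + ["B"] * 2)
        cm = connectivity_matrix(ts, parc)
        for i in range(5):
            for j in range(i + 1, 5):
                r, _ = stats.pearsonr(ts[:, i], ts[:, j])
                assert cm.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-10)
                assert cm.z[j, i] == cm.z[i, j]

    def test_half_correlation_closed_form(self):
        # construct two columns with exact sample correlation 0.5
        n = 400
        rng = np.random.default_rng(0)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        b = b - (a @ b / n) * a  # orthogonalize
        b = (b - b.mean()) / b.std()
        y = 0.5 * a + np.sqrt(1 - 0.25) * b
        ts = np.column_stack([a, y, rng.normal(size=n)])
        cm = connectivity_matrix(ts, make_parcellation(["A", "B", "B"]))
        assert cm.z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-8)

    def test_diagonal_always_masked(self, rng):
        cm = connectivity_matrix(rng.normal(size=(30, 4)),
                                 make_parcellation(["A", "A", "B", "B"]))
        assert np.all(np.diag(cm.excluded))

    def test_close_pair_masked_regardless_of_r(self, rng):
        parc = make_parcellation(["A", "B", "B"])
        parc.loc[1, ["x_mm", "y_mm", "z_mm"]] = [15.0, 0.0, 0.0]  # 15 mm from ROI 0
        cm = connectivity_matrix(rng.normal(size=(30, 3)), parc)
        assert cm.excluded[0, 1] and cm.excluded[1, 0]

    def test_exactly_20mm_pair_retained(self, rng):
        parc = make_parcellation(["A", "B", "B"])
        parc.loc[1, ["x_mm", "y_mm", "z_mm"]] = [20.0, 0.0, 0.0]
        cm = connectivity_matrix(rng.normal(size=(30, 3)), parc)
        assert not cm.excluded[0, 1]

    def test_nonpositive_entries_flagged(self, rng):
        ts = rng.normal(size=(50, 4))
        cm = connectivity_matrix(ts, make_parcellation(["A", "A", "B", "B"]))
        assert np.array_equal(cm.nonpositive, cm.z <= 0)

    def test_zero_variance_column_rejected(self, rng):
        ts = rng.normal(size=(30, 3))
        ts[:, 1] = 4.2
        with pytest.raises(ValueError):
            connectivity_matrix(ts, make_parcellation(["A", "B", "B"]))


def toy_two_by_two():
    """2 networks x 2 ROIs with hand-set cross-network z values.

    Cross entries (A1,B1)=0.3, (A1,B2)=-0.1, (A2,B1)=0.5, (A2,B2)=0.2;
    retained positives {0.3, 0.5, 0.2} so every summary equals 1/3.
    """
    z = np.zeros((4, 4))
    z[0, 2] = 0.3
    z[0, 3] = -0.1
    z[1, 2] = 0.5
    z[1, 3] = 0.2
    z[0, 1] = 0.9  # within-network values must never enter the summaries
    z[2, 3] = 0.8
    z = z + z.T
    excluded = np.zeros((4, 4), dtype=bool)
    np.fill_diagonal(excluded, True)
    cm = ConnectivityMatrix(z=z, excluded=excluded, nonpositive=z <= 0)
    parc = make_parcellation(["A", "A", "B", "B"])
    return cm, parc


class TestInternetworkSummaries:
    def test_hand_enumerated_two_network_toy(self):
        cm, parc = toy_two_by_two()
        s = internetwork_summaries(cm, parc)
        assert s.overall_z == pytest.approx(1.0 / 3.0)
        assert s.per_network_z["A"] == pytest.approx(1.0 / 3.0)
        assert s.per_network_z["B"] == pytest.approx(1.0 / 3.0)
        assert s.pairwise_z[("A", "B")] == pytest.approx(1.0 / 3.0)

    def test_include_within_admits_intranetwork_pairs(self):
        cm, parc = toy_two_by_two()
        s = internetwork_summaries(cm, parc, include_within=True)
        assert s.overall_z == pytest.approx((0.3 + 0.5 + 0.2 + 0.9 + 0.8) / 5.0)

    def test_excluded_label_dropped_first(self, rng):
        cm, parc = toy_two_by_two()
        parc_ext = make_parcellation(["A", "A", "B", "B", "excluded"])
        z = np.full((5, 5), 0.7)
        z[:4, :4] = cm.z
        np.fill_diagonal(z, 0.0)
        excluded = np.zeros((5, 5), dtype=bool)
        np.fill_diagonal(excluded, True)
        cm5 = ConnectivityMatrix(z=z, excluded=excluded, nonpositive=z <= 0)
        s = internetwork_summaries(cm5, parc_ext)
        assert s.overall_z == pytest.approx(1.0 / 3.0)

    def test_empty_retained_set_warns_and_reports_nan(self):
        z = np.full((4, 4), -0.5)
        np.fill_diagonal(z, 0.0)
        excluded = np.zeros((4, 4), dtype=bool)
        np.fill_diagonal(excluded, True)
        cm = ConnectivityMatrix(z=z, excluded=excluded, nonpositive=z <= 0)
        with pytest.warns(UserWarning):
            s = internetwork_summaries(cm, make_parcellation(["A", "A", "B", "B"]))
        assert np.isnan(s.overall_z)

    def test_invariant_to_roi_reordering(self, rng):
        ts = rng.normal(size=(60, 8))
        labels = ["A", "A", "A", "B", "B", "C", "C", "C"]
        parc = make_parcellation(labels)
        base = internetwork_summaries(connectivity_matrix(ts, parc), parc)
        perm = rng.permutation(8)
        parc_p = parc.iloc[perm].reset_index(drop=True)
        parc_p["roi_id"] = range(8)
        permuted = internetwork_summaries(
            connectivity_matrix(ts[:, perm], parc_p), parc_p)
        assert permuted.overall_z == pytest.approx(base.overall_z, abs=1e-12)

    def test_weighted_pairwise_means_reconstruct_overall(self, rng):
        ts = rng.normal(size=(60, 9)) + 0.4 * rng.normal(size=(60, 1))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        parc = make_parcellation(labels)
        cm = connectivity_matrix(ts, parc)
        s = internetwork_summaries(cm, parc)
        # independent enumeration of retained entry counts per network pair
        lab = np.asarray(labels)
        total = 0.0
        count = 0
        for i in range(9):
            for j in range(i + 1, 9):
                if lab[i] != lab[j] and not cm.excluded[i, j] and cm.z[i, j] > 0:
                    total += cm.z[i, j]
                    count += 1
        assert s.overall_z == pytest.approx(total / count, abs=1e-12)


class TestPipelineComposition:
    def test_identity_stage_changes_nothing(self, rng):
        ts = rng.normal(size=(80, 6))
        parc = make_parcellation(["A"] * 3 + ["B"] * 3)
        filtered = bandpass(ts, tr=2.0)
        with_identity, pct = scrub_and_replace(filtered, np.zeros(80), 0.5)
        assert pct == 0.0
        a = internetwork_summaries(connectivity_matrix(filtered, parc), parc)
        b = internetwork_summaries(connectivity_matrix(with_identity, parc), parc)
        # copies may change memory layout and hence BLAS summation order
        assert a.overall_z == pytest.approx(b.overall_z, rel=1e-12)

    def test_rms_signal_change_first_frame_zero(self, rng):
        d = rms_signal_change(rng.normal(size=(20, 3)))
        assert d[0] == 0.0 and d.shape == (20,)

    def test_raising_planted_cross_correlation_raises_overall_z(self):
        spec = {"A": 8, "B": 8}
        parc = build_parcellation(spec)
        means = []
        for rho in (0.1, 0.4):
            cfg = SimulationConfig(
                n_enrolled=4, n_frames=240, parcellation_spec=spec,
                missingness_counts=(0, 0, 0, 0), fast=False,
                rsfc_mean=np.arctanh(rho), rsfc_sd=0.0, seed=21)
            vals = []
            for k in range(6):
                prng = np.random.default_rng(100 + k)
                ts, motion, nuis = generate_roi_timeseries(
                    np.arctanh(rho), parc, cfg, prng)
                s, _ = process_participant(ts, motion, nuis, parc, tr=2.0)
                vals.append(s.overall_z)
            means.append(np.mean(vals))
        assert means[1] > means[0]
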