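"""Ghost detection, GTR closed forms, and the iterative phase corrections."""

import numpy as np
import pytest

import epsighost as eg
from epsighost import oracle


def _corrupt_two(ets_single, mech, value):
    ets2 = eg.split_trains(ets_single, 2)
    apply = {
        "phase": eg.apply_phase0,
        "scale": eg.apply_magnitude_scale,
        "shift": eg.apply_time_shift,
    }[mech]
    return apply(ets2, 1, value)


class TestGhostFrequencies:
    def test_two_trains_alias_at_band_edge(self):
        assert eg.ghost_frequencies(0.0, 2, 1250.0) == [-625.0]

    def test_single_train_no_ghosts(self):
        assert eg.ghost_frequencies(0.0, 1, 1250.0) == []

    def test_four_trains(self):
        got = eg.ghost_frequencies(0.0, 4, 1250.0)
        assert got == [312.5, -625.0, -312.5]

    def test_wrapping(self):
        got = eg.ghost_frequencies(500.0, 2, 1250.0)
        assert got == [-125.0]


class TestMeasureGtr:
    def _spectrum(self, sbw, n, peaks):
        freq = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / sbw))
        mag = np.zeros(n)
        for f, m in peaks:
            mag[np.argmin(np.abs(freq - f))] = m
        return freq, mag

    def test_single_ghost_ratio(self):
        freq, mag = self._spectrum(1250.0, 50, [(0.0, 0.8), (-625.0, 0.2)])
        rep = eg.measure_gtr(freq, mag, 0.0, 2, 1250.0)
        assert rep.gtr == pytest.approx(0.25)
        assert rep.true_peak == (0.0, 0.8)

    def test_mean_over_three_ghosts(self):
        freq, mag = self._spectrum(
            1250.0, 48, [(0.0, 1.2), (312.5, 0.1), (-625.0, 0.2), (-312.5, 0.3)]
        )
        rep = eg.measure_gtr(freq, mag, 0.0, 4, 1250.0)
        assert rep.gtr == pytest.approx(0.2 / 1.2)

    def test_overlapping_windows_rejected(self):
        freq, mag = self._spectrum(1250.0, 48, [(0.0, 1.0)])
        with pytest.raises(ValueError, match="overlap"):
            eg.measure_gtr(freq, mag, 0.0, 2, 1250.0, window_hz=400.0)


class TestClosedFormEquivalence:
    @pytest.mark.parametrize("phi", [20.0, 40.0, 60.0, -40.0])
    def test_phase_gtr_matches_tan(self, ets_single, voi10, phi):
        cube = eg.reconstruct(_corrupt_two(ets_single, "phase", phi), zero_fill_to=None)
        rep = eg.measure_gtr(
            cube.freq_hz, eg.voi_spectrum(cube, voi10), 0.0, 2, cube.sbw_hz
        )
        assert rep.gtr == pytest.approx(oracle.gtr_phase(phi), rel=0.02)

    @pytest.mark.parametrize("a", [0.7, 0.8, 0.9, 1.1, 1.2, 1.3])
    def test_magnitude_gtr_matches_closed_form(self, ets_single, voi10, a):
        cube = eg.reconstruct(_corrupt_two(ets_single, "scale", a), zero_fill_to=None)
        rep = eg.measure_gtr(
            cube.freq_hz, eg.voi_spectrum(cube, voi10), 0.0, 2, cube.sbw_hz
        )
        assert rep.gtr == pytest.approx(oracle.gtr_magnitude(a), rel=0.02)

    def test_timeshift_gtr_symmetric_in_sign(self, ets_single, voi10):
        reps = []
        for s in (+1.5, -1.5):
            cube = eg.reconstruct(_corrupt_two(ets_single, "shift", s), zero_fill_to=None)
            reps.append(
                eg.measure_gtr(
                    cube.freq_hz, eg.voi_spectrum(cube, voi10), 0.0, 2, cube.sbw_hz
                ).gtr
            )
        # coarse 32-point echoes leave ~1% spline boundary asymmetry
        assert reps[0] == pytest.approx(reps[1], rel=0.02)

    def test_timeshift_gtr_follows_tan_law_along_read(self):
        """Per-voxel GTR(x) = |tan(pi g Gr tau x)|, flat along phase encode."""
        cfg = eg.SequenceConfig(
            n_read=64, n_phase=8, n_trains=1, echoes_per_train=48, delta_te_eff=0.8
        )
        x = (np.arange(64) - 32) * cfg.fov_read / 64
        slab = eg.uniform_slab_phantom(cfg, n_rows=4)
        dens = slab.species[0].density_map.copy()
        dens[:, np.abs(x) > 24] = 0.0  # object bounded well inside the FOV
        slab = eg.Phantom([eg.Species("water", dens, 0.0, np.inf)], slab.b0_map, slab.grid_spacing)
        ets = eg.apply_time_shift(eg.split_trains(eg.simulate(slab, cfg), 2), 1, 1.5)
        cube = eg.reconstruct(ets, zero_fill_to=None, chemshift=False)
        tb = np.argmin(np.abs(cube.freq_hz))
        gb = np.argmin(np.abs(cube.freq_hz + cube.sbw_hz / 2))
        gtr_vox = np.abs(cube.values[:, :, gb]) / np.abs(cube.values[:, :, tb])
        tau = cfg.points_to_time(1.5)
        pred = np.abs(np.tan(np.deg2rad(oracle.timeshift_phase_at(x, tau, cfg)) / 2))
        sel = (np.abs(x) <= 22) & (pred > 0.05) & (pred < 2.0)  # away from nulls
        row = gtr_vox[4, sel]
        assert np.all(np.abs(row - pred[sel]) <= 0.05 * pred[sel])
        # monotone growth with |x| while the phase stays under a half cycle
        right = gtr_vox[4, 33:48]
        assert np.all(np.diff(right) > 0)
        # flat along the phase-encode direction inside the object
        col = gtr_vox[3:6, 40]
        assert np.ptp(col) < 1e-6 * col.mean()


class TestTwoTrainCorrection:
    def test_recovers_injected_phase(self, ets_single, voi10):
        ets2 = _corrupt_two(ets_single, "phase", -42.5)
        res = eg.correct_two_trains(ets2, voi10)
        assert res.phi0_per_train[0] == 0.0
        assert res.phi0_per_train[1] == pytest.approx(42.5, abs=0.5)
        assert res.gtr_after < 0.01 * res.gtr_before
        assert res.gtr_before == pytest.approx(oracle.gtr_phase(42.5), rel=0.02)

    def test_no_corruption_gives_zero_phase(self, ets_single, voi10):
        ets2 = eg.split_trains(ets_single, 2)
        res = eg.correct_two_trains(ets2, voi10, grid_step_deg=2.0)
        assert res.phi0_per_train[1] in (0.0, pytest.approx(358.0))
        assert res.gtr_after <= res.gtr_before

    def test_trace_is_unimodal_up_to_wrap(self, ets_single, voi10):
        ets2 = _corrupt_two(ets_single, "phase", -80.0)
        res = eg.correct_two_trains(ets2, voi10, grid_step_deg=5.0)
        phis, gtrs = map(np.array, zip(*res.trace["phi0"]))
        # rotate so the (single) minimum comes first; then one rise, one fall
        k = int(np.argmin(gtrs))
        rotated = np.r_[gtrs[k:], gtrs[:k]]
        peak = int(np.argmax(rotated))
        assert np.all(np.diff(rotated[:peak]) > 0)
        assert np.all(np.diff(rotated[peak:]) < 0)

    def test_correction_never_raises_gtr_and_boosts_true_peak(self, ets_single, voi10):
        ets2 = _corrupt_two(ets_single, "phase", 55.0)
        res = eg.correct_two_trains(ets2, voi10, grid_step_deg=1.0)
        assert res.gtr_after <= res.gtr_before
        before = eg.reconstruct(ets2, zero_fill_to=None)
        after = eg.reconstruct(res.corrected, zero_fill_to=None)
        tb = np.argmin(np.abs(before.freq_hz))
        assert (
            eg.voi_spectrum(after, voi10)[tb] > eg.voi_spectrum(before, voi10)[tb]
        )

    def test_fast_sweep_matches_naive_reconstruction(self, ets_single, voi10):
        """The algebraic phase sweep must equal re-running the full pipeline."""
        ets2 = _corrupt_two(ets_single, "phase", 30.0)
        res = eg.correct_two_trains(ets2, voi10, grid_step_deg=45.0)
        for phi, gtr_fast in res.trace["phi0"][:4]:
            cube = eg.reconstruct(eg.apply_phase0(ets2, 1, phi), zero_fill_to=None)
            rep = eg.measure_gtr(
                cube.freq_hz, eg.voi_spectrum(cube, voi10), 0.0, 2, cube.sbw_hz
            )
            assert gtr_fast == pytest.approx(rep.gtr, rel=1e-9)

    def test_wrong_train_count_rejected(self, ets_single, voi10):
        with pytest.raises(ValueError):
            eg.correct_two_trains(eg.split_trains(ets_single, 4), voi10)


class TestFourTrainCorrection:
    @pytest.fixture()
    def corrupted4(self, ets_single):
        ets4 = eg.split_trains(ets_single, 4)
        for k, p in ((1, 25.0), (2, 28.5), (3, 32.0)):
            ets4 = eg.apply_phase0(ets4, k, p)
        return ets4

    def test_recovers_arithmetic_progression(self, corrupted4, voi10):
        res = eg.correct_four_trains(corrupted4, voi10)
        wrapped = [(p + 180.0) % 360.0 - 180.0 for p in res.phi0_per_train]
        assert wrapped[0] == 0.0
        assert wrapped[1] == pytest.approx(-25.0, abs=0.5)
        assert wrapped[2] == pytest.approx(-28.5, abs=0.5)
        assert wrapped[3] == pytest.approx(-32.0, abs=0.5)
        assert res.delta_phi == pytest.approx(-3.5, abs=0.5)
        assert res.gtr_after < 0.01 * res.gtr_before

    def test_zero_injection_recovers_identity(self, ets_single, voi10):
        res = eg.correct_four_trains(
            eg.split_trains(ets_single, 4), voi10, grid_step_deg=2.0
        )
        wrapped = [(p + 180.0) % 360.0 - 180.0 for p in res.phi0_per_train]
        assert np.allclose(np.abs(wrapped), 0.0, atol=2.0)

    def test_correcting_only_train_two_raises_other_ghosts(self, corrupted4, voi10):
        """Cancelling one train's error redistributes, and partly amplifies,
        the remaining ghost lines — single-train correction is not enough."""
        cube0 = eg.reconstruct(corrupted4, zero_fill_to=None)
        rep0 = eg.measure_gtr(
            cube0.freq_hz, eg.voi_spectrum(cube0, voi10), 0.0, 4, cube0.sbw_hz
        )
        fixed2 = eg.apply_phase0(corrupted4, 1, -25.0)
        cube1 = eg.reconstruct(fixed2, zero_fill_to=None)
        rep1 = eg.measure_gtr(
            cube1.freq_hz, eg.voi_spectrum(cube1, voi10), 0.0, 4, cube1.sbw_hz
        )
        g0 = np.array([g[1] for g in rep0.ghosts])
        g1 = np.array([g[1] for g in rep1.ghosts])
        assert g1.min() < g0.min()  # one ghost drops
        assert np.any(g1 > g0)  # at least one other rises


class TestSweepReport:
    def test_phase_sweep_matches_oracle(self, ets_single, voi10):
        values = [-40.0, 20.0, 60.0]
        df = eg.sweep_report(ets_single, voi10, {"phase0_deg": values})
        assert list(df["value"]) == values
        for _, row in df.iterrows():
            assert row["gtr"] == pytest.approx(oracle.gtr_phase(row["value"]), rel=0.02)

    def test_mechanism_validation(self, ets_single, voi10):
        with pytest.raises(ValueError):
            eg.sweep_report(ets_single, voi10, {"bogus": [1.0]})
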