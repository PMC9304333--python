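"""Landscape construction, quartic algebra, path segmentation, Erlang fits."""

import numpy as np
import pytest
from scipy import integrate

from protonspec.free_energy import (
    DstarBranch,
    FitError,
    StatisticsError,
    barrier_profiles,
    dstar_branch,
    erlang_fit,
    erlang_pdf,
    fit_all_cuts,
    fit_quartic_cut,
    free_energy_2d,
    path_mask,
    segment_paths,
    transition_state_distribution,
)
from protonspec.tracking import ExcessProtonTrack


def _track(d, roo=None, dt=1.0):
    d = np.asarray(d, dtype=float)
    roo = np.full_like(d, 2.5) if roo is None else np.asarray(roo, dtype=float)
    return ExcessProtonTrack(
        proton_index=0, first_frame=0, dt=dt, d=d, roo=roo,
        flanking_oxygens=np.zeros((len(d), 2), dtype=int),
    )


class TestFreeEnergy2D:
    def test_flat_density_gives_flat_surface(self, rng):
        n = 200_000
        d = rng.uniform(-0.4, 0.4, n)
        roo = rng.uniform(2.4, 2.6, n)
        fe = free_energy_2d((d, roo), d_bin=0.05, roo_bin=0.05, d_max=0.4)
        vals = fe.F[np.isfinite(fe.F)]
        # flat within multi-sigma counting noise
        assert np.nanmax(vals) < 10 / np.sqrt(n / vals.size)

    def test_symmetrized_exactly(self, rng):
        d = rng.normal(0.1, 0.1, 5000)  # deliberately asymmetric input
        roo = rng.normal(2.5, 0.05, 5000)
        fe = free_energy_2d((d, roo))
        np.testing.assert_array_equal(fe.F, fe.F[::-1])
        np.testing.assert_array_equal(fe.counts, fe.counts[::-1])

    def test_gauge_minimum_is_zero(self, rng):
        d = rng.normal(0.0, 0.1, 10000)
        roo = rng.normal(2.5, 0.05, 10000)
        fe = free_energy_2d((d, roo))
        assert np.nanmin(fe.F) == 0.0

    def test_boltzmann_quartic_recovery(self, rng):
        # rejection-sample a double-well quartic density at the calibrated
        # coefficient strength and recover the coefficients
        f0, g2, g4 = 1.8, -50.0, 625.0
        n = 100_000
        d = rng.uniform(-0.4, 0.4, 8 * n)
        f = f0 * (g2 * d ** 2 + g4 * d ** 4)
        keep = rng.random(8 * n) < np.exp(-(f - f.min()))
        d = d[keep][:n]
        roo = rng.uniform(2.492, 2.528, len(d))
        fe = free_energy_2d((d, roo), d_bin=0.02, roo_bin=0.04)
        j = np.argmax(fe.counts.sum(axis=0))
        # histogram gauge puts min F = 0 at the wells; restore the absolute
        # gauge F(d*) = f0 (1 - g2^2/(4 g4)) before fitting
        shift = f0 * (1 - g2 ** 2 / (4 * g4))
        fit = fit_quartic_cut(fe.d_centers, fe.F[:, j] + shift, fe.counts[:, j],
                              d_fit_max=0.4, min_counts=20)
        assert fit.gamma2 == pytest.approx(g2, rel=0.05)
        assert fit.gamma4 == pytest.approx(g4, rel=0.05)

    def test_empty_input_is_error(self):
        with pytest.raises(StatisticsError):
            free_energy_2d((np.array([]), np.array([])))

    def test_chloride_flagged_frames_excluded(self):
        tr = _track(np.full(100, 0.2))
        tr.chloride_flag[:] = True
        tr2 = _track(np.full(50, 0.3))
        fe = free_energy_2d([tr, tr2])
        assert fe.counts.sum() == pytest.approx(50)


class TestQuarticFit:
    def _cut(self, f0, g2, g4, noise=0.0, rng=None):
        d = np.arange(-0.44, 0.45, 0.02)
        f = f0 * (1 + g2 * d ** 2 + g4 * d ** 4)
        if noise and rng is not None:
            f = f + rng.normal(0, noise, len(d))
        return d, f

    def test_well_position_formula(self):
        d, f = self._cut(1.0, -0.5, 0.5)
        fit = fit_quartic_cut(d, f)
        assert fit.dstar == pytest.approx(np.sqrt(0.5), rel=1e-8)

    def test_barrier_matches_direct_evaluation(self):
        d, f = self._cut(2.0, -0.5, 0.5)
        fit = fit_quartic_cut(d, f)
        direct = fit.evaluate(np.array([0.0]))[0] - fit.evaluate(
            np.array([fit.dstar]))[0]
        assert fit.relative_barrier == pytest.approx(direct, abs=1e-10)
        assert fit.relative_barrier == pytest.approx(2.0 * 0.125, rel=1e-8)

    def test_single_well_reports_dstar_zero(self):
        d, f = self._cut(1.0, 0.8, 0.5)
        fit = fit_quartic_cut(d, f)
        assert fit.dstar == 0.0
        assert fit.relative_barrier == 0.0

    def test_nonconfining_fit_is_error(self):
        d = np.arange(-0.44, 0.45, 0.02)
        with pytest.raises(FitError):
            fit_quartic_cut(d, 1.0 - 0.5 * d ** 4)

    def test_too_few_bins_is_error(self):
        with pytest.raises(FitError):
            fit_quartic_cut(np.array([0.1, 0.2, 0.3]), np.array([1.0, 1.1, 1.2]))

    def test_quartic_algebra_identity(self, rng):
        # F(d*) = F_{d=0} (1 - g2^2/(4 g4)) for every double-well fit
        for _ in range(20):
            f0 = rng.uniform(0.5, 3.0)
            g2 = -rng.uniform(0.1, 60.0)
            g4 = rng.uniform(10.0, 1000.0)
            d, f = self._cut(f0, g2, g4)
            try:
                fit = fit_quartic_cut(d, f)
            except FitError:
                continue
            lhs = fit.evaluate(np.array([fit.dstar]))[0]
            rhs = fit.f_d0 * (1 - fit.gamma2 ** 2 / (4 * fit.gamma4))
            assert lhs == pytest.approx(rhs, abs=1e-10)


class TestDstarBranch:
    def test_exact_parabola_recovered(self):
        slope, onset = 1 / 3.0, 2.39
        fits = []
        for roo in np.arange(2.40, 2.56, 0.02):
            ds2 = slope * (roo - onset)
            g4 = 600.0
            g2 = -2 * g4 * ds2
            d = np.arange(-0.44, 0.45, 0.02)
            f = 1.5 * (1 + g2 * d ** 2 + g4 * d ** 4)
            fits.append(fit_quartic_cut(d, f, roo=roo))
        br = dstar_branch(fits)
        assert br.slope == pytest.approx(slope, abs=1e-10)
        assert br.onset == pytest.approx(onset, abs=1e-10)

    def test_noisy_points_within_three_sigma(self, rng):
        slope, onset = 1 / 3.0, 2.39
        roos = np.arange(2.41, 2.56, 0.01)
        dstars = np.sqrt(slope * (roos - onset)) + rng.normal(0, 0.005, len(roos))

        class _F:
            def __init__(self, roo, ds):
                self.roo, self.gamma2, self.gamma4 = roo, -2 * 600 * ds ** 2, 600.0
                self.dstar = abs(ds)

        br = dstar_branch([_F(r, d) for r, d in zip(roos, dstars)])
        assert br.onset == pytest.approx(onset, abs=0.01)

    def test_all_single_well_is_error(self):
        d = np.arange(-0.44, 0.45, 0.02)
        fits = [fit_quartic_cut(d, 1 + d ** 2 + d ** 4, roo=2.5)]
        with pytest.raises(FitError):
            dstar_branch(fits)


class TestBarrierProfiles:
    def test_analytic_surface_curves(self, surface):
        # evaluate the calibrated surface on exact cuts and compare the
        # extracted profiles with closed-form evaluation
        fits = []
        d = np.arange(-0.44, 0.45, 0.02)
        for roo in np.arange(2.40, 2.60, 0.01):
            f = np.asarray(surface.energy(d, roo), dtype=float)
            fits.append(fit_quartic_cut(d, f + 1e-9, roo=roo))
        prof = barrier_profiles(fits)
        for roo, f_abs, f_rel in zip(prof.roo, prof.absolute_f_d0,
                                     prof.relative_barrier):
            assert f_abs == pytest.approx(float(surface.f_d0(roo)), abs=1e-6)
            assert f_rel == pytest.approx(surface.relative_barrier(roo), abs=1e-6)
        # 3-point parabolic refinement on an asymmetric profile: O(h^2) bias
        assert prof.transition_state_roo == pytest.approx(2.42, abs=5e-3)
        assert prof.transition_state_f == pytest.approx(0.9, abs=5e-3)


class TestSegmentPaths:
    def test_complete_path_hand_segmentation(self):
        tr = _track([0.25, 0.15, 0.05, -0.10, -0.22])
        paths = segment_paths(tr, 0.2)
        assert len(paths) == 1
        p = paths[0]
        assert p.complete
        assert (p.start, p.end) == (0, 4)
        assert p.duration == pytest.approx(4.0)

    def test_incomplete_path_hand_segmentation(self):
        tr = _track([0.25, 0.10, -0.05, 0.10, 0.25])
        paths = segment_paths(tr, 0.2)
        assert len(paths) == 1
        p = paths[0]
        assert not p.complete
        assert (p.start, p.end) == (0, 4)

    def test_turning_point_extension(self):
        tr = _track([0.10, 0.30, 0.25, 0.05, -0.10, -0.25, -0.30, -0.28])
        paths = segment_paths(tr, 0.2)
        assert len(paths) == 1
        p = paths[0]
        # start extends back only to the turning point at the local maximum
        assert p.start == 1
        # end extends forward to the velocity reversal at the local minimum
        assert p.end == 6

    def test_no_crossing_yields_empty(self):
        tr = _track([0.3, 0.25, 0.3, 0.28, 0.26])
        assert segment_paths(tr, 0.2) == []

    def test_crossing_roo_interpolated(self):
        tr = _track([0.25, 0.05, -0.05, -0.25], roo=[2.50, 2.44, 2.42, 2.50])
        p = segment_paths(tr, 0.2)[0]
        assert p.crossing_roo == pytest.approx(2.43, abs=1e-12)

    def test_surrogate_paths_satisfy_defining_properties(self, medium_run,
                                                         medium_results):
        """Exhaustive re-validation of every emitted path on a long run."""
        tr = medium_results.model.tracks[0]
        branch = medium_results.branch
        dstar = branch.dstar(tr.roo)
        d = tr.d
        paths = medium_results.paths[0]
        assert len(paths) > 100
        prev_end = -1
        checked_parity = 0
        for p in paths:
            assert p.start > prev_end  # disjoint and ordered
            prev_end = p.end
            seg = d[p.start:p.end + 1]
            ds_seg = dstar[p.start:p.end + 1]
            sgn = np.sign(seg[0])
            # the segment actually reaches the d* level on its origin side
            assert np.max(seg * sgn - ds_seg) >= 0
            if ds_seg.min() <= 0:
                # below the barrier onset d* = 0: reaching the far branch and
                # crossing the midplane coincide, so parity is unconstrained
                continue
            checked_parity += 1
            crossings = int(np.sum(np.sign(seg[:-1]) * np.sign(seg[1:]) < 0))
            if p.complete:
                assert crossings % 2 == 1  # one net sign change
                assert np.sign(seg[-1]) == -sgn
            else:
                assert crossings % 2 == 0 and crossings >= 2
                assert np.sign(seg[-1]) == sgn
        assert checked_parity > 50

    def test_path_mask_covers_only_paths(self):
        tr = _track([0.25, 0.15, 0.05, -0.10, -0.22, -0.25, -0.3])
        paths = segment_paths(tr, 0.2)
        mask = path_mask(tr, paths)
        assert mask[:5].all() or mask[paths[0].start:paths[0].end + 1].all()
        assert mask.sum() == paths[0].end - paths[0].start + 1


class TestErlangFit:
    @pytest.mark.parametrize("beta", [1, 2, 3, 4, 5, 6])
    def test_mean_equals_tau_by_quadrature(self, beta):
        tau = 17.0
        mean, _ = integrate.quad(lambda t: t * erlang_pdf(t, beta, tau), 0,
                                 60 * tau)
        assert mean == pytest.approx(tau, rel=1e-8)

    def test_parameter_recovery_from_samples(self, rng):
        samples = rng.gamma(3, 14.0 / 3, 5000)
        fit = erlang_fit(samples)
        assert fit.beta == 3
        assert fit.tau_tp == pytest.approx(14.0, rel=0.05)

    def test_exponential_limit_selects_beta_one(self, rng):
        samples = rng.exponential(20.0, 5000)
        fit = erlang_fit(samples)
        assert fit.beta == 1

    def test_scale_equivariance(self, rng):
        samples = rng.gamma(3, 14.0 / 3, 5000)
        f1 = erlang_fit(samples)
        f2 = erlang_fit(samples * 2.5)
        assert f2.beta == f1.beta
        assert f2.tau_tp == pytest.approx(2.5 * f1.tau_tp, rel=1e-6)

    def test_too_few_samples_is_error(self):
        with pytest.raises(StatisticsError):
            erlang_fit(np.arange(10.0))


class TestTransitionStateDistribution:
    def test_delta_histogram_for_forced_crossings(self):
        tr = _track([0.25, 0.05, -0.05, -0.25] * 3, roo=[2.45] * 12)
        paths = segment_paths(tr, 0.2)
        edges, counts, frac = transition_state_distribution(paths)
        assert frac == 1.0  # all crossings at 2.45 > 2.39

    def test_fraction_equals_direct_count(self, medium_results):
        paths = [p for ps in medium_results.paths for p in ps if p.complete]
        _, _, frac = transition_state_distribution(paths)
        direct = np.mean([p.crossing_roo > 2.39 for p in paths])
        assert frac == pytest.approx(direct, abs=1e-12)

    def test_no_complete_paths_is_error(self):
        with pytest.raises(StatisticsError):
            transition_state_distribution([])
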