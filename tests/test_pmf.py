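"""Umbrella sampling and WHAM: protocol arithmetic, self-consistency
against an independent oracle, recovery of analytic landscapes."""

import numpy as np
import pytest

from amphimem.build import SystemSpec, build_system
from amphimem.constants import KB, KCAL, T_BODY
from amphimem.engine import IntegratorConfig, System, maxwell_velocities, \
    minimize_energy
from amphimem.pmf import (PMFProfile, UmbrellaSpec, WindowSample,
                          extract_windows, normalize_pmf, run_pull,
                          run_umbrella_window, wham)
from amphimem.synth import gen_umbrella_samples


class TestProtocolArithmetic:
    def test_published_window_layout(self):
        spec = UmbrellaSpec()  # 7 nm span, 0.1 nm spacing
        centers = spec.window_centers()
        assert len(centers) == 70
        assert centers[0] == pytest.approx(7.0)
        assert np.all(np.diff(centers) < 0)
        assert np.all(centers > 0)

    def test_small_span_window_count(self):
        spec = UmbrellaSpec(span=1.0, window_spacing=0.5)
        assert len(spec.window_centers()) == 2

    def test_pull_target_closed_form(self):
        # z(t) = z0 - rate*t: after 1000 ps at 0.0014 nm/ps from 7 nm -> 5.6
        spec = UmbrellaSpec()
        assert spec.span - spec.pull_rate * 1000.0 == pytest.approx(5.6)

    def test_discard_must_leave_samples(self):
        with pytest.raises(ValueError):
            UmbrellaSpec(time_per_window=10.0, equilibration_discard=10.0)


class TestWham:
    def test_matches_independent_fixed_point_oracle(self):
        """2 windows, 3 bins: WHAM equals a dense fixed-point iteration
        written out directly from the self-consistency equations."""
        kT = KB * T_BODY
        w1 = WindowSample(center=1.0, samples=np.array([0.95, 1.0, 1.05, 1.1]),
                          k_restraint=100.0)
        w2 = WindowSample(center=1.1, samples=np.array([1.0, 1.05, 1.1, 1.15]),
                          k_restraint=100.0)
        profile = wham([w1, w2], bin_width=0.1, tol=1e-14)
        centers = profile.z
        # oracle: direct iteration with plain loops
        hist = np.array([np.histogram(w.samples,
                                      bins=np.concatenate([centers - 0.05,
                                                           [centers[-1] + 0.05]]))[0]
                         for w in (w1, w2)], dtype=float)
        bias = np.array([[0.5 * 100.0 * (c - w.center) ** 2 for c in centers]
                         for w in (w1, w2)])
        f = np.zeros(2)
        for _ in range(200000):
            rho = np.zeros(len(centers))
            for b in range(len(centers)):
                denom = sum(hist[i].sum() * np.exp((f[i] - bias[i, b]) / kT)
                            for i in range(2))
                rho[b] = hist[:, b].sum() / denom
            f_new = np.array([-kT * np.log(sum(rho[b] * np.exp(-bias[i, b] / kT)
                                               for b in range(len(centers))))
                              for i in range(2)])
            f_new -= f_new[0]
            if np.max(np.abs(f_new - f)) < 1e-14:
                f = f_new
                break
            f = f_new
        F_oracle = -kT * np.log(rho)
        F_oracle -= np.nanmin(F_oracle[np.isfinite(F_oracle)])
        populated = hist.sum(axis=0) > 0
        assert np.allclose(profile.F[populated] * KCAL, F_oracle[populated],
                           atol=1e-8)

    def test_single_window_flat_landscape(self):
        spec = UmbrellaSpec(k_restraint=200.0)
        wins = gen_umbrella_samples(lambda z: np.zeros_like(z), spec,
                                    n_samples=4000, seed=3,
                                    centers=np.array([2.0]))
        profile = wham(wins, bin_width=0.05)
        good = profile.meta["counts"] > 100
        spread = np.nanmax(profile.F[good]) - np.nanmin(profile.F[good])
        assert spread < 2 * KB * T_BODY / KCAL  # flat within 2 kT of noise

    def test_recovers_harmonic_landscape_within_03_kcal(self):
        """The analytic-oracle recovery used as an acceptance check."""
        spec = UmbrellaSpec(k_restraint=200.0)
        centers = np.linspace(5.0, 1.0, 20)
        landscape = lambda z: 10.0 * (np.asarray(z) - 3.0) ** 2
        wins = gen_umbrella_samples(landscape, spec, n_samples=2000, seed=7,
                                    centers=centers)
        profile = wham(wins, bin_width=0.05)
        good = profile.meta["counts"] > 200
        err = profile.F[good] - landscape(profile.z[good]) / KCAL
        err -= err.mean()  # profiles are defined up to a constant
        assert np.max(np.abs(err)) < 0.3

    def test_window_order_permutation_invariant(self):
        spec = UmbrellaSpec(k_restraint=200.0)
        wins = gen_umbrella_samples(lambda z: 5.0 * (np.asarray(z) - 2.0) ** 2,
                                    spec, n_samples=500, seed=1,
                                    centers=np.linspace(3.0, 1.0, 8))
        p1 = wham(wins, bin_width=0.05)
        p2 = wham(wins[::-1], bin_width=0.05)
        assert np.allclose(p1.F, p2.F, equal_nan=True)

    def test_bimodal_pair_minima_recovered_within_one_bin(self):
        """Charged- vs neutral-head style landscape pair: the two generator
        minima are recovered at their specified positions."""
        spec = UmbrellaSpec(k_restraint=300.0)
        centers = np.linspace(4.0, 0.2, 20)
        for z_min in (1.2, 2.1):
            landscape = lambda z: 15.0 * (np.asarray(z) - z_min) ** 2
            wins = gen_umbrella_samples(landscape, spec, n_samples=1500,
                                        seed=11, centers=centers)
            profile = wham(wins, bin_width=0.05)
            z_est, _ = profile.minimum()
            assert abs(z_est - z_min) <= 0.05 + 1e-9


class TestNormalize:
    def _profile(self):
        z = np.linspace(0.0, 6.0, 121)
        return PMFProfile(z=z, F=0.5 * (z - 2.0) ** 2, bin_width=0.05)

    def test_reference_is_zero_after_call(self):
        p = normalize_pmf(self._profile(), reference_z=5.0)
        assert p.interpolate(5.0) == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self):
        p1 = normalize_pmf(self._profile(), 5.0)
        p2 = normalize_pmf(p1, 5.0)
        assert np.allclose(p1.F, p2.F)

    def test_differences_invariant(self):
        p0 = self._profile()
        p1 = normalize_pmf(p0, 5.0)
        d0 = p0.interpolate(1.0) - p0.interpolate(3.0)
        d1 = p1.interpolate(1.0) - p1.interpolate(3.0)
        assert d0 == pytest.approx(d1, abs=1e-12)

    def test_reference_outside_range_raises(self):
        with pytest.raises(ValueError):
            normalize_pmf(self._profile(), reference_z=10.0)

    def test_kj_to_kcal_uses_exact_factor(self):
        assert KCAL == 4.184


class TestUmbrellaMD:
    @pytest.fixture(scope="class")
    def am_system(self):
        spec = SystemSpec(n_lipids=32, n_waters=150, salt_conc=0.0,
                          am_species="1cM", am_height=3.0, box_z=12.0, seed=4)
        top, frame = build_system(spec)
        system = System(top, frame)
        minimize_energy(system, max_steps=60)
        system.frame.velocities = maxwell_velocities(top, 310.0, 2)
        return top, system.frame.copy()

    def test_pull_tracks_moving_target(self, am_system):
        top, frame = am_system
        sys_ = System(top, frame.copy())
        uspec = UmbrellaSpec(k_restraint=500.0, span=3.0, pull_rate=0.05,
                             seed=2)
        traj, table = run_pull(sys_, uspec, stride=100)
        assert table["target"].iloc[0] == pytest.approx(3.0)
        assert table["target"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
        # coordinate follows the target within the restraint's thermal width
        late = table[table["time"] > 5.0]
        assert np.mean(np.abs(late["coordinate"] - late["target"])) < 0.5

    def test_zero_rate_keeps_target_constant(self, am_system):
        top, frame = am_system
        sys_ = System(top, frame.copy())
        uspec = UmbrellaSpec(k_restraint=500.0, span=2.5, pull_rate=0.0, seed=2)
        traj, table = run_pull(sys_, uspec, stride=10)
        assert (table["target"] == 2.5).all()

    def test_extract_windows_requires_coverage(self):
        import pandas as pd
        table = pd.DataFrame({"time": [0, 1, 2], "target": [2.0, 1.9, 1.8],
                              "coordinate": [2.0, 1.95, 1.9]})
        spec = UmbrellaSpec(span=2.0, window_spacing=0.5)
        with pytest.raises(ValueError, match="does not cover"):
            extract_windows(table, spec, tol=0.05)

    def test_window_sampling_statistics(self, am_system):
        """Restrained coordinate: mean near center, variance of order
        kT/k (the bilayer's own restoring force narrows it slightly)."""
        top, frame = am_system
        sys_ = System(top, frame.copy())
        uspec = UmbrellaSpec(k_restraint=500.0, span=3.0,
                             time_per_window=20.0, equilibration_discard=5.0,
                             seed=2)
        ws = run_umbrella_window(sys_, 3.0, uspec, stride=5)
        sd_bias = np.sqrt(KB * T_BODY / uspec.k_restraint)
        assert abs(ws.samples.mean() - 3.0) < 4 * sd_bias
        assert 0.2 * sd_bias < ws.samples.std() < 2.0 * sd_bias

    def test_discard_equal_to_length_errors(self, am_system):
        top, frame = am_system
        sys_ = System(top, frame.copy())
        with pytest.raises(ValueError):
            UmbrellaSpec(time_per_window=5.0, equilibration_discard=5.0)
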