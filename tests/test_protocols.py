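"""Doublet/triplet protocols, sensitivity, sweeps, and memory decay."""

import math

import numpy as np
import pytest
from scipy import optimize

from hdexc import (
    SensitivityConfig,
    SpikeTrain,
    damping_coefficient,
    delta_isi_min,
    delta_isi_min_if_analytic,
    doublet_discriminability,
    doublet_map,
    gif_model,
    if_model,
    locate_doublet_maximum,
    memory_decay_curve,
    sweep_sensitivity,
    triplet_discriminability,
    triplet_discriminability_if_closed,
)


class TestDoublets:
    def test_canonical_values(self, canonical_gif, canonical_if):
        assert doublet_discriminability(canonical_if, 1.0, 2.0) == pytest.approx(
            0.027038, abs=5e-6
        )
        assert doublet_discriminability(canonical_gif, 1.0, 2.0) == pytest.approx(
            0.045083, abs=5e-6
        )

    def test_symmetry_and_zero_diagonal(self, canonical_gif):
        assert doublet_discriminability(canonical_gif, 0.8, 0.8) == pytest.approx(0.0, abs=1e-15)
        assert doublet_discriminability(canonical_gif, 0.6, 1.9) == pytest.approx(
            doublet_discriminability(canonical_gif, 1.9, 0.6), rel=1e-12
        )

    def test_if_closed_form(self, canonical_if):
        # IF doublet: D = (2 s^2/alpha) e^{-alpha(isi1+isi2)} sinh^2(alpha(isi2-isi1)/2)
        i1, i2, s = 0.7, 2.4, 1.3
        ref = (2 * s * s) * math.exp(-(i1 + i2)) * math.sinh((i2 - i1) / 2) ** 2
        assert doublet_discriminability(canonical_if, i1, i2, s) == pytest.approx(ref, rel=1e-12)

    def test_positive_isis_required(self, canonical_gif):
        with pytest.raises(ValueError):
            doublet_discriminability(canonical_gif, -1.0, 1.0)


class TestTriplets:
    def test_canonical_values(self, canonical_gif, canonical_if):
        assert triplet_discriminability(canonical_if, 1.0, 1.0, 1.0) == pytest.approx(
            0.07350, abs=5e-6
        )
        assert triplet_discriminability(canonical_gif, 1.0, 1.0, 1.0) == pytest.approx(
            0.08362, abs=1e-5
        )

    def test_if_closed_form_agrees_with_generic(self, canonical_if):
        for m, d, s in [(1.0, 1.0, 2.0), (0.5, 0.3, 1.0), (2.0, 2.5, 1.7)]:
            generic = triplet_discriminability(canonical_if, m, d, s)
            closed = triplet_discriminability_if_closed(1.0, m, d, s)
            assert generic == pytest.approx(closed, rel=1e-10)

    def test_zero_delta_is_zero(self, canonical_gif):
        assert triplet_discriminability(canonical_gif, 1.0, 0.0) == 0.0

    def test_delta_range_enforced(self, canonical_gif):
        with pytest.raises(ValueError):
            triplet_discriminability(canonical_gif, 1.0, 2.0)  # delta = 2m collides
        with pytest.raises(ValueError):
            triplet_discriminability(canonical_gif, 1.0, -0.1)

    def test_gif_profile_non_monotone(self, canonical_gif):
        # intrinsic oscillations make D(delta) non-monotone at some mean ISIs,
        # unlike the strictly increasing IF profile
        found = False
        for m in (1.0, 1.5, 2.0):
            deltas = np.linspace(0.0, 2 * m * (1 - 1e-9), 400)[1:]
            vals = np.array(
                [triplet_discriminability(canonical_gif, m, d, 2.0) for d in deltas]
            )
            if np.any(np.diff(vals) < 0):
                found = True
        assert found
        # and the IF profile is strictly increasing everywhere
        deltas = np.linspace(0.0, 2 * (1 - 1e-9), 400)[1:]
        if_vals = np.array([triplet_discriminability_if_closed(1.0, 1.0, d, 2.0) for d in deltas])
        assert np.all(np.diff(if_vals) > 0)


class TestSensitivity:
    def test_if_canonical_value(self):
        res = delta_isi_min_if_analytic(1.0, SensitivityConfig(mean_isi=1.0, amplitude=2.0))
        assert res.defined
        assert res.delta_isi_min == pytest.approx(1.27170, abs=5e-6)

    def test_if_undefined_at_unit_amplitude(self):
        res = delta_isi_min_if_analytic(1.0, SensitivityConfig(mean_isi=1.0, amplitude=1.0))
        assert not res.defined and res.delta_isi_min is None

    def test_if_analytic_matches_numerical_inversion(self):
        # independent oracle: direct root of the triplet closed form
        for alpha, m, s in [(1.0, 1.0, 2.0), (0.7, 1.5, 2.5), (2.0, 0.8, 3.0)]:
            cfg = SensitivityConfig(mean_isi=m, amplitude=s)
            res = delta_isi_min_if_analytic(alpha, cfg)
            f = lambda d: triplet_discriminability_if_closed(alpha, m, d, s) - cfg.theta_d
            if res.defined:
                root = optimize.brentq(f, 1e-12, 2 * m * (1 - 1e-9), xtol=1e-12)
                assert res.delta_isi_min == pytest.approx(root, abs=1e-9)
            else:
                assert f(2 * m * (1 - 1e-9)) < 0  # never reaches theta_d in range

    def test_dispatch_and_threshold_property(self, canonical_gif, canonical_if):
        cfg = SensitivityConfig(mean_isi=1.0, amplitude=2.0)
        for model in (canonical_gif, canonical_if):
            res = delta_isi_min(model, cfg)
            assert res.defined
            d = res.delta_isi_min
            # the located delta sits exactly on the threshold
            at = triplet_discriminability(model, 1.0, d, 2.0)
            assert at == pytest.approx(cfg.theta_d, abs=1e-6)

    def test_gif_multiple_crossings_undefined(self):
        # strong oscillations cross the significance threshold several times
        res = delta_isi_min(gif_model(1.0, 3.0), SensitivityConfig(mean_isi=1.0, amplitude=2.0))
        assert not res.defined
        assert res.n_crossings == 3

    def test_if_delta_grows_as_alpha_vanishes(self):
        # slow leak: history lingers but the per-spike difference integrates
        # to a broad plateau, requiring ever larger timing differences
        cfg = SensitivityConfig(mean_isi=3.0, amplitude=2.0)
        vals = [delta_isi_min_if_analytic(a, cfg).delta_isi_min for a in (0.04, 0.02, 0.01)]
        assert all(v is not None for v in vals)
        assert vals[0] < vals[1] < vals[2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SensitivityConfig(theta_d=0.0)
        with pytest.raises(ValueError):
            SensitivityConfig(mean_isi=-1.0)
        with pytest.raises(ValueError):
            SensitivityConfig(n_grid=4)


class TestSweep:
    def test_lam_sweep_columns_and_if_agreement(self):
        cfg = SensitivityConfig(mean_isi=1.0, amplitude=2.0, n_grid=500)
        frame = sweep_sensitivity("lam", [0.5, 1.0, 1.5], cfg)
        assert list(frame["lam"]) == [0.5, 1.0, 1.5]
        assert list(frame["omega"]) == [2.0, 2.0, 2.0]
        for _, row in frame.iterrows():
            ref = delta_isi_min_if_analytic(row["alpha"], cfg)
            if ref.defined:
                assert row["if_delta_isi_min"] == pytest.approx(ref.delta_isi_min)
            else:
                assert np.isnan(row["if_delta_isi_min"])

    def test_ratio_sweep_keeps_damping_fixed(self):
        cfg = SensitivityConfig(mean_isi=1.0, amplitude=2.0, n_grid=200)
        frame = sweep_sensitivity("ratio", [0.5, 1.0, 2.0], cfg, lam0=1.0, omega0=2.0)
        qs = [damping_coefficient(gif_model(r["lam"], r["omega"])) for _, r in frame.iterrows()]
        assert np.allclose(qs, qs[0])
        # the unit scale passes through the canonical model
        row = frame[frame["param"] == 1.0].iloc[0]
        assert row["lam"] == 1.0 and row["omega"] == 2.0

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            sweep_sensitivity("bogus", [1.0], SensitivityConfig())


class TestDoubletMap:
    def test_map_matches_pairwise_computation(self, canonical_gif):
        grid = np.array([0.5, 1.0, 2.0, 3.5])
        D = doublet_map(canonical_gif, grid)
        for i, a in enumerate(grid):
            for j, b in enumerate(grid):
                if i == j:
                    assert D[i, j] == pytest.approx(0.0, abs=1e-15)
                else:
                    assert D[i, j] == pytest.approx(
                        doublet_discriminability(canonical_gif, a, b), rel=1e-10
                    )

    def test_symmetry(self, canonical_gif):
        grid = np.linspace(0.2, 4.0, 12)
        D = doublet_map(canonical_gif, grid)
        assert np.allclose(D, D.T, atol=1e-14)

    def test_if_map_monotone_off_diagonal(self, canonical_if):
        # the IF kernel is monotone, so D = (Kv(i1) - Kv(i2))^2 / (2 alpha)
        # grows monotonically away from the zero diagonal: no interior maximum
        grid = np.linspace(0.2, 6.0, 40)
        D = doublet_map(canonical_if, grid)
        for i in range(len(grid)):
            assert np.all(np.diff(D[i, i:]) >= -1e-14)
            assert np.all(np.diff(D[i, : i + 1]) <= 1e-14)

    def test_positive_grid_required(self, canonical_gif):
        with pytest.raises(ValueError):
            doublet_map(canonical_gif, [0.0, 1.0])


class TestDoubletMaximum:
    def test_canonical_location(self, canonical_gif):
        loc = locate_doublet_maximum(canonical_gif)
        assert loc is not None
        isi1, isi2 = loc
        assert isi1 == pytest.approx(math.pi / 4, abs=1e-4)
        assert isi2 == pytest.approx(3 * math.pi / 4, abs=1e-4)
        # both ISIs below the intrinsic period
        period = 2 * math.pi / canonical_gif.omega
        assert isi1 < period and isi2 < period

    def test_is_coordinatewise_maximum(self, canonical_gif):
        isi1, isi2 = locate_doublet_maximum(canonical_gif)
        d0 = doublet_discriminability(canonical_gif, isi1, isi2)
        h = 1e-3
        assert d0 > doublet_discriminability(canonical_gif, isi1 + h, isi2)
        assert d0 > doublet_discriminability(canonical_gif, isi1 - h, isi2)
        assert d0 > doublet_discriminability(canonical_gif, isi1, isi2 + h)
        assert d0 > doublet_discriminability(canonical_gif, isi1, isi2 - h)

    def test_lower_frequency_moves_maximum_to_longer_isis(self, canonical_gif):
        base = locate_doublet_maximum(canonical_gif)
        slower = locate_doublet_maximum(gif_model(1.0, 1.5))
        assert slower is not None
        assert slower[0] > base[0] and slower[1] > base[1]

    def test_heavy_damping_has_no_maximum(self):
        # at lam = omega the ridge merges into the short-ISI axis
        assert locate_doublet_maximum(gif_model(1.0, 1.0)) is None

    def test_if_model_rejected(self, canonical_if):
        with pytest.raises(ValueError):
            locate_doublet_maximum(canonical_if)


class TestMemoryDecay:
    def test_if_step_ratio(self, canonical_if):
        a = SpikeTrain([-1.0, 0.0])
        b = SpikeTrain([-2.0, 0.0])
        curve = memory_decay_curve(canonical_if, a, b, appended_isi=1.0, n_append=4)
        assert curve[0] == pytest.approx(
            doublet_discriminability(canonical_if, 1.0, 2.0), rel=1e-12
        )
        ratios = curve[1:] / curve[:-1]
        assert np.allclose(ratios, math.exp(-2.0), rtol=1e-10)

    def test_gif_period_ratio_is_q_squared(self, canonical_gif):
        a = SpikeTrain([-1.0, 0.0])
        b = SpikeTrain([-2.0, 0.0])
        period = 2 * math.pi / canonical_gif.omega
        curve = memory_decay_curve(canonical_gif, a, b, appended_isi=period, n_append=3)
        q = damping_coefficient(canonical_gif)
        ratios = curve[1:] / curve[:-1]
        assert np.allclose(ratios, q * q, rtol=1e-10)

    def test_zero_append_is_identity(self, canonical_gif):
        a = SpikeTrain([-1.0, 0.0])
        b = SpikeTrain([-2.0, 0.0])
        curve = memory_decay_curve(canonical_gif, a, b, appended_isi=0.7, n_append=0)
        assert curve.shape == (1,)
        assert curve[0] == pytest.approx(doublet_discriminability(canonical_gif, 1.0, 2.0))

    def test_positive_isi_required(self, canonical_gif):
        with pytest.raises(ValueError):
            memory_decay_curve(
                canonical_gif, SpikeTrain([0.0]), SpikeTrain([0.0]), 0.0, 1
            )
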