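"""Empirical density estimation and evaluation."""

import numpy as np
import pytest

from chronosig.density import (
    BinConfig,
    build_ccdf,
    build_cdf,
    density_at,
    fit_delay_density,
    fit_hour_density,
    fit_joint,
)


class TestDelayDensity:
    def test_degenerate_sample_concentrates_in_one_bin(self):
        cfg = BinConfig()
        centre = cfg.centres()[40]
        d = fit_delay_density(np.full(10, centre), cfg)
        idx = np.searchsorted(cfg.edges(), centre) - 1
        np.testing.assert_allclose(d.raw_density[idx] * d.widths[idx], 1.0)
        assert d.raw_density.sum() == d.raw_density[idx]

    def test_uniform_sample_integrates_to_one(self, rng):
        d = fit_delay_density(rng.uniform(10, 100, 100_000))
        lo, hi = np.searchsorted(d.bin_edges, [10, 100])
        partial = np.sum((d.raw_density * d.widths)[lo - 1:hi])
        assert abs(partial - 1.0) < 0.01
        assert abs(d.integral(pre_floor=True) - 1.0) < 1e-9

    def test_single_delay(self):
        d = fit_delay_density([42.0])
        assert abs(d.integral(pre_floor=True) - 1.0) < 1e-9
        assert np.count_nonzero(d.raw_density) == 1

    def test_non_positive_delay_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_delay_density([10.0, 0.0])

    def test_empty_bins_hold_floor(self):
        d = fit_delay_density([42.0], floor=1e-12)
        assert d.density[d.raw_density == 0].min() == 1e-12


class TestDensityAt:
    def test_bin_centres_are_interpolation_nodes(self, rng):
        d = fit_delay_density(rng.uniform(10, 10_000, 5000))
        centres = d.centres[30:60]
        np.testing.assert_allclose(density_at(d, centres), d.density[30:60],
                                   rtol=1e-9)

    def test_no_overshoot_between_equal_bins(self):
        from chronosig.density import LogBinnedDensity

        cfg = BinConfig()
        # two adjacent bins with identical density: shape preservation keeps
        # the interpolant flat between their centres (no overshoot)
        values = np.full(100, 1e-12)
        values[40] = values[41] = 0.004
        values[39] = 0.001
        d = LogBinnedDensity(bin_edges=cfg.edges(), density=values,
                             floor=1e-12, n_samples=100)
        c = d.centres
        mid = np.sqrt(c[40] * c[41])
        np.testing.assert_allclose(density_at(d, mid), 0.004, rtol=1e-9)

    def test_outside_support_returns_floor(self, rng):
        d = fit_delay_density(rng.uniform(10, 100, 1000))
        assert density_at(d, 10.0**7.5) == d.floor
        assert density_at(d, 0.5) == d.floor

    def test_never_below_floor_or_nan(self, rng):
        d = fit_delay_density(rng.uniform(10, 100, 100))
        queries = np.concatenate([rng.uniform(0.1, 2e7, 1000), d.centres])
        values = density_at(d, queries)
        assert np.all(np.isfinite(values)) and np.all(values >= d.floor)


class TestHourDensity:
    def test_point_mass_hour(self):
        h = fit_hour_density(np.full(50, 21))
        assert h.mass[21] > 0.999
        assert abs(h.mass.sum() - 1.0) < 1e-9

    def test_uniform_hours(self, rng):
        h = fit_hour_density(rng.integers(0, 24, 10_000))
        assert np.all(np.abs(h.mass - 1 / 24) < 0.01)

    def test_single_event(self):
        h = fit_hour_density([7])
        assert h.mass[7] > 0.999

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fit_hour_density([24])


class TestJoint:
    def test_independent_mode_is_product(self, rng):
        delays = rng.uniform(10, 10_000, 2000)
        hours = rng.integers(0, 24, 2000)
        joint = fit_joint(fit_delay_density(delays), fit_hour_density(hours),
                          mode="independent")
        q_d = joint.delay_marginal.centres[20:80:7]
        for h in (0, 9, 21):
            np.testing.assert_allclose(
                joint.evaluate(q_d, np.full(q_d.shape, h)),
                density_at(joint.delay_marginal, q_d) * joint.hour_marginal.mass[h],
            )

    def test_full2d_approaches_outer_product_when_independent(self, rng):
        n = 100_000
        delays = 10 ** rng.uniform(1, 3, n)
        hours = rng.integers(0, 24, n)
        dd, hd = fit_delay_density(delays), fit_hour_density(hours)
        joint = fit_joint(dd, hd, mode="full2d", paired_samples=(delays, hours))
        # compare cell probability masses; sampling error ~ sqrt(p/n) per cell
        mass_2d = joint.grid * dd.widths[:, None]
        mass_prod = (dd.raw_density * dd.widths)[:, None] * hd.mass[None, :]
        assert np.max(np.abs(mass_2d - mass_prod)) < 3e-3

    def test_full2d_detects_perfect_coupling(self, rng):
        cfg = BinConfig()
        centres = cfg.centres()
        hours = rng.integers(0, 24, 5000)
        delays = centres[10 + 2 * hours]  # each hour pinned to one delay bin
        dd = fit_delay_density(delays, cfg)
        hd = fit_hour_density(hours)
        joint = fit_joint(dd, hd, mode="full2d", paired_samples=(delays, hours))
        on = joint.evaluate(centres[10 + 2 * hours[:50]], hours[:50])
        off = joint.evaluate(centres[10 + 2 * hours[:50]], (hours[:50] + 5) % 24)
        assert np.all(on > 1e3 * off)  # off-diagonal cells sit at the floor

    def test_full2d_requires_pairs(self, rng):
        dd = fit_delay_density(rng.uniform(10, 100, 50))
        hd = fit_hour_density(rng.integers(0, 24, 50))
        with pytest.raises(ValueError, match="paired"):
            fit_joint(dd, hd, mode="full2d")

    def test_full2d_marginals_recover_fitted_marginals(self, rng):
        n = 50_000
        delays = 10 ** rng.uniform(0.5, 4, n)
        hours = rng.integers(0, 24, n)
        dd, hd = fit_delay_density(delays), fit_hour_density(hours)
        joint = fit_joint(dd, hd, mode="full2d", paired_samples=(delays, hours))
        hour_marginal = (joint.grid * dd.widths[:, None]).sum(axis=0)
        assert np.max(np.abs(hour_marginal - hd.mass)) < 2 / np.sqrt(n)


class TestEmpiricalCDF:
    def test_step_values(self):
        cdf = build_cdf([10.0, 20.0, 30.0])
        assert cdf(20) == pytest.approx(2 / 3)
        assert cdf(9.99) == 0.0 and cdf(30) == 1.0

    def test_ccdf_complements_cdf(self, rng):
        delays = rng.exponential(100, 500) + 1
        cdf, ccdf = build_cdf(delays), build_ccdf(delays)
        q = rng.uniform(0, 1000, 200)
        np.testing.assert_allclose(cdf(q) + ccdf(q), 1.0)
        assert ccdf(0.0) == 1.0  # CCDF is 1 below the smallest delay

    def test_dkw_agreement_with_true_cdf(self, rng):
        x = rng.exponential(100, 10_000)
        cdf = build_cdf(x)
        grid = np.linspace(0.1, 1000, 2000)
        assert np.max(np.abs(cdf(grid) - (1 - np.exp(-grid / 100)))) < 0.02

    def test_monotone_in_unit_interval(self, rng):
        cdf = build_cdf(rng.uniform(1, 100, 333))
        values = cdf(np.linspace(0, 200, 500))
        assert np.all(np.diff(values) >= 0)
        assert values.min() >= 0 and values.max() <= 1
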