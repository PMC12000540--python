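"""The Poisson SCR model: likelihood pieces, sampler behavior, diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wolfscr.experiments import rectangle_mask
from wolfscr.model import (
    PoissonSCR,
    SCRPosterior,
    density_from_abundance,
    density_surface,
    encounter_rate,
    gof_pvalues,
    log_likelihood,
    rhat,
    summarize,
)
from wolfscr.prep import DetectorGrid, SCRDataset


def toy_detectors(coords=None, effort=None):
    coords = np.asarray(coords if coords is not None else
                        [[0.0, 0.0], [5000.0, 0.0]])
    effort = np.asarray(effort if effort is not None
                        else np.zeros(len(coords)))
    return DetectorGrid(coords=coords, effort=effort, cell_size=2500.0,
                        origin=(0.0, 0.0))


def toy_dataset(y, rng=None, mask_extent=20_000.0, effort=None):
    y = np.asarray(y)
    n, J = y.shape
    coords = np.column_stack([
        np.linspace(2000, mask_extent - 2000, J), np.full(J, mask_extent / 2)])
    det = toy_detectors(coords, effort if effort is not None else np.zeros(J))
    mask = rectangle_mask(mask_extent, 1000.0)
    return SCRDataset(y=y, detectors=det, mask=mask,
                      sexes=np.array(["F", "M"] * (n // 2) + ["U"] * (n % 2),
                                     dtype=object),
                      individual_ids=[f"w{i}" for i in range(n)])


class TestEncounterRate:
    def test_zero_distance_zero_effort(self):
        assert encounter_rate([0, 0], [0, 0], 0.0, alpha0=-1.2, alpha1=0.5,
                              sigma=3000.0) == pytest.approx(np.exp(-1.2))

    def test_one_sigma_distance(self):
        rate = encounter_rate([0, 0], [3000.0, 0.0], 0.0, alpha0=0.0,
                              alpha1=0.0, sigma=3000.0)
        assert rate == pytest.approx(np.exp(-0.5))

    def test_effort_ignored_when_alpha1_zero(self):
        r1 = encounter_rate([0, 0], [1000, 0], 0.0, -1.0, 0.0, 2000.0)
        r2 = encounter_rate([0, 0], [1000, 0], 5.0, -1.0, 0.0, 2000.0)
        assert r1 == pytest.approx(r2)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            encounter_rate([0, 0], [0, 0], 0.0, 0.0, 0.0, sigma=0.0)


class TestLogLikelihood:
    def test_single_cell_poisson_by_hand(self):
        # y = 2 with lambda = 1: log(e^-1 / 2!) = -1 - log 2
        det = toy_detectors([[0.0, 0.0]])
        ll = log_likelihood(np.array([[2]]), z=[1], s=[[0.0, 0.0]],
                            detectors=det, alpha0=0.0, alpha1=0.0,
                            sigma=3000.0)
        assert ll == pytest.approx(-1.0 - np.log(2.0))

    def test_detector_permutation_invariance(self, rng):
        det = toy_detectors([[0, 0], [4000, 0], [0, 4000]])
        y = rng.poisson(1.0, size=(2, 3))
        y[y.sum(axis=1) == 0, 0] = 1
        s = [[1000.0, 1000.0], [3000.0, 500.0]]
        ll = log_likelihood(y, [1, 1], s, det, -0.5, 0.0, 2500.0)
        perm = [2, 0, 1]
        det_p = toy_detectors(det.coords[perm], det.effort[perm])
        ll_p = log_likelihood(y[:, perm], [1, 1], s, det_p, -0.5, 0.0, 2500.0)
        assert ll == pytest.approx(ll_p)

    def test_excluded_individual_with_counts_impossible(self):
        det = toy_detectors([[0.0, 0.0]])
        ll = log_likelihood(np.array([[1]]), z=[0], s=[[0.0, 0.0]],
                            detectors=det, alpha0=0.0, alpha1=0.0, sigma=1e3)
        assert ll == -np.inf

    def test_negative_counts_rejected(self):
        det = toy_detectors([[0.0, 0.0]])
        with pytest.raises(ValueError):
            log_likelihood(np.array([[-1]]), [1], [[0.0, 0.0]], det,
                           0.0, 0.0, 1e3)


class TestRhat:
    def test_identical_chains(self):
        chains = np.tile(np.arange(100.0), (3, 1))
        assert rhat(chains) == pytest.approx(1.0, abs=0.02)

    def test_same_distribution_near_one(self, rng):
        chains = rng.normal(size=(4, 10_000))
        assert rhat(chains) < 1.05

    def test_disjoint_chains_flagged(self, rng):
        chains = np.stack([rng.normal(0, 1, 5000), rng.normal(50, 1, 5000)])
        assert rhat(chains) > 1.1

    def test_single_chain_error(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz_on_stationary_chains(self, rng):
        # arviz computes the rank-normalized split variant; on stationary
        # well-mixed chains both statistics sit within a percent of 1
        import arviz as az

        chains = rng.normal(size=(4, 4000))
        ours = rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert abs(ours - theirs) < 0.01


class TestSampler:
    def test_saturated_detection_collapses_to_n(self, rng):
        y = rng.poisson(8.0, size=(6, 4)) + 1
        ds = toy_dataset(y)
        model = PoissonSCR(M=30, chains=2, iters=2000, burnin=300, thin=5,
                           random_state=5).fit(ds)
        assert summarize(model.posterior_).loc["N", "mean"] == pytest.approx(
            6.0, abs=0.2)

    def test_same_seed_identical_draws(self, rng):
        y = rng.poisson(2.0, size=(4, 3)) + 1
        ds = toy_dataset(y)
        kw = dict(M=20, chains=2, iters=400, burnin=100, thin=5,
                  random_state=99)
        d1 = PoissonSCR(**kw).fit(ds).posterior_.draws
        d2 = PoissonSCR(**kw).fit(ds).posterior_.draws
        pd.testing.assert_frame_equal(d1, d2)

    def test_per_draw_accounting(self, rng):
        y = rng.poisson(2.0, size=(4, 3)) + 1
        ds = toy_dataset(y)
        model = PoissonSCR(M=20, chains=2, iters=600, burnin=100, thin=5,
                           random_state=3).fit(ds)
        draws = model.posterior_.draws
        assert (draws["N"] == draws["N_f"] + draws["N_m"]).all()
        assert (draws["N"] <= 20).all()
        area = ds.mask.area_km2
        np.testing.assert_allclose(draws["D"], draws["N"] / area * 100.0)

    def test_m_not_larger_than_n_rejected(self, rng):
        y = np.ones((4, 2), dtype=int)
        ds = toy_dataset(y)
        with pytest.raises(ValueError):
            PoissonSCR(M=4, chains=2, iters=100, burnin=10).fit(ds)

    def test_retained_draw_count(self, rng):
        y = rng.poisson(2.0, size=(3, 3)) + 1
        ds = toy_dataset(y)
        model = PoissonSCR(M=15, chains=3, iters=500, burnin=100, thin=5,
                           random_state=1).fit(ds)
        assert model.posterior_.n_draws == 3 * (500 // 5)


class TestSummaries:
    def _constant_posterior(self, n_const=70, area_km2=2975.0):
        mask = rectangle_mask(1000.0 * np.sqrt(area_km2), 5000.0)
        n_draws = 200
        d = density_from_abundance(n_const, area_km2)
        draws = pd.DataFrame({
            "chain": np.repeat([0, 1], n_draws // 2),
            "N": n_const, "N_f": 33, "N_m": n_const - 33, "D": d,
            "alpha0": -1.0, "alpha1": 0.5, "sigma": 3333.0,
            "psi": 0.5, "theta": 0.5})
        return SCRPosterior(draws=draws,
                            s_draws=np.zeros((n_draws, 100), dtype=int),
                            z_draws=np.ones((n_draws, 100), dtype=bool),
                            ac_counts=np.zeros(mask.n_cells), mask=mask,
                            n_detected=1, M=100, n_chains=2)

    def test_density_identity_from_constant_draws(self):
        post = self._constant_posterior()
        summ = summarize(post)
        assert round(float(summ.loc["D", "mean"]), 2) == 2.35
        assert summ.loc["D", "mean"] == pytest.approx(70 / 2975 * 100)

    def test_constant_draws_zero_width_bci(self):
        summ = summarize(self._constant_posterior())
        assert summ.loc["N", "bci_lo"] == summ.loc["N", "bci_hi"] == 70

    def test_bci_contains_median(self, rng):
        draws = rng.gamma(5, 10, size=1000)
        post = self._constant_posterior()
        post.draws = post.draws.assign(N=draws[:200])
        summ = summarize(post)
        assert summ.loc["N", "bci_lo"] <= summ.loc["N", "median"] <= \
            summ.loc["N", "bci_hi"]


class TestDensitySurface:
    def test_integral_matches_posterior_mean_n(self, rng):
        y = rng.poisson(3.0, size=(5, 4)) + 1
        ds = toy_dataset(y)
        model = PoissonSCR(M=25, chains=2, iters=1000, burnin=200, thin=5,
                           random_state=11).fit(ds)
        post = model.posterior_
        surface = density_surface(post)
        integral = surface.sum() * post.mask.cell_area_km2 / 100.0
        n_mean = summarize(post).loc["N", "mean"]
        assert integral == pytest.approx(n_mean, rel=1e-3)


class TestTracePlots:
    def test_writes_figure(self, rng, tmp_path):
        y = rng.poisson(2.0, size=(3, 3)) + 1
        ds = toy_dataset(y)
        model = PoissonSCR(M=15, chains=2, iters=400, burnin=100, thin=5,
                           random_state=2).fit(ds)
        from wolfscr.model import plot_traces
        out = tmp_path / "traces.png"
        plot_traces(model.posterior_, out)
        assert out.stat().st_size > 0


class TestGoF:
    def test_pvalues_in_unit_interval_and_misfit_detected(self, rng):
        y = rng.poisson(3.0, size=(6, 5)) + 1
        ds = toy_dataset(y)
        model = PoissonSCR(M=30, chains=2, iters=1500, burnin=300, thin=5,
                           random_state=21).fit(ds)
        pvals = gof_pvalues(ds, model.posterior_, n_ppc=100, seed=1)
        assert all(0.0 <= p <= 1.0 for p in pvals.values())
        inflated = SCRDataset(y=ds.y * 10, detectors=ds.detectors,
                              mask=ds.mask, sexes=ds.sexes,
                              individual_ids=ds.individual_ids)
        pvals_bad = gof_pvalues(inflated, model.posterior_, n_ppc=100, seed=1)
        assert all(p < 0.01 for p in pvals_bad.values())
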