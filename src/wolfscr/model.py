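"""Bayesian data-augmented Poisson spatial capture-recapture.

The model: each of a superpopulation of ``M`` individuals has a latent
activity center ``s_i`` uniform over the habitat mask and an inclusion
indicator ``z_i ~ Bernoulli(psi)``; population size is ``N = sum z_i``.
Encounter counts of individual ``i`` at detector ``j`` are

    y_ij ~ Poisson(lambda_ij),
    lambda_ij = lambda_0j * exp(-d_ij^2 / (2 sigma^2)),
    log lambda_0j = alpha0 + alpha1 * E_j,

with ``d_ij`` the Euclidean distance from ``s_i`` to detector ``j``, ``E_j``
the search effort (km of transect per km^2), and ``sigma`` the spatial scale
of the half-normal detection function.  Sex enters only through the split
``N = N_f + N_m``: detected individuals carry their molecular sex where
known, augmented individuals draw theirs from ``theta`` (probability female).

Fitting is Metropolis-within-Gibbs: random-walk updates for ``alpha0``,
``alpha1`` and ``log sigma`` (proposal scales adapted during burn-in only),
direct categorical Gibbs draws for the activity centers over the discretized
mask, and conjugate/Bernoulli Gibbs updates for ``z``, ``psi``, sex and
``theta``.  Convergence is checked with the Gelman-Rubin statistic and model
fit with three posterior-predictive Bayesian p-values based on the
Freeman-Tukey discrepancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .prep import HabitatMask, SCRDataset

PARAM_COLS = ("N", "N_f", "N_m", "D", "alpha0", "alpha1", "sigma",
              "psi", "theta")


@dataclass
class SCRPriors:
    """Weakly informative defaults: normal slopes, uniform sigma/psi/theta."""

    alpha0_sd: float = 10.0
    alpha1_sd: float = 10.0
    sigma_lo: float = 100.0
    sigma_hi: float = 20_000.0


@dataclass
class SCRPosterior:
    """Thinned posterior draws and bookkeeping for diagnostics."""

    draws: pd.DataFrame              # one row per retained draw, 'chain' column
    s_draws: np.ndarray              # (total_draws, M) mask-cell indices
    z_draws: np.ndarray              # (total_draws, M) inclusion indicators
    ac_counts: np.ndarray            # (C,) summed included-AC counts over draws
    mask: HabitatMask
    n_detected: int
    M: int
    n_chains: int

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def per_chain(self, param: str) -> np.ndarray:
        chains = [g[param].to_numpy()
                  for _, g in self.draws.groupby("chain", sort=True)]
        return np.stack(chains)


def encounter_rate(s, x_j, effort, alpha0, alpha1, sigma):
    """Expected encounter count: exp(a0 + a1*E_j) * exp(-d^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = np.asarray(s, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    d2 = ((s - x_j) ** 2).sum(axis=-1)
    return np.exp(alpha0 + alpha1 * np.asarray(effort)) * np.exp(
        -d2 / (2.0 * sigma ** 2))


def log_likelihood(y, z, s, detectors, alpha0, alpha1, sigma):
    """Poisson log-likelihood of the augmented encounter array.

    ``y`` is (M, J); individuals with ``z == 0`` must have all-zero rows
    (their counts are structural zeros under data augmentation) and contribute
    nothing; any positive count for an excluded individual gives -inf.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("encounter counts must be non-negative")
    z = np.asarray(z, dtype=bool)
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if np.any(y[~z].sum(axis=1) > 0):
        return -np.inf
    lam = np.stack([
        encounter_rate(s[i], detectors.coords, detectors.effort,
                       alpha0, alpha1, sigma)
        for i in np.flatnonzero(z)
    ]) if z.any() else np.zeros((0, y.shape[1]))
    return float(stats.poisson.logpmf(y[z], lam).sum())


def rhat(chains: np.ndarray) -> float:
    """Classic (split-free) Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  With zero between- and within-chain
    variance (identical constant chains) returns 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat needs >= 2 chains of equal length")
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


class PoissonSCR(BaseEstimator):
    """Data-augmented Poisson SCR model with half-normal detection.

    Parameters
    ----------
    M : int or None
        Size of the augmented superpopulation; default 4x the number of
        detected individuals.
    chains, iters, burnin, thin : int
        MCMC schedule.  Burn-in runs before the ``iters`` sampling
        iterations, of which every ``thin``-th is retained, so the posterior
        holds ``chains * iters // thin`` draws.
    priors : SCRPriors
    random_state : int or None
        Seed; per-chain streams are derived deterministically from it.
    """

    def __init__(self, M: int | None = None, chains: int = 3,
                 iters: int = 50_000, burnin: int = 1_000, thin: int = 5,
                 priors: SCRPriors | None = None,
                 random_state: int | None = None):
        self.M = M
        self.chains = chains
        self.iters = iters
        self.burnin = burnin
        self.thin = thin
        self.priors = priors
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, dataset: SCRDataset, y=None):
        priors = self.priors or SCRPriors()
        n, J = dataset.y.shape
        M = self.M if self.M is not None else 4 * n
        if M <= n:
            raise ValueError(f"M={M} must exceed the {n} detected individuals")
        ss = np.random.SeedSequence(self.random_state)
        chain_seeds = ss.spawn(self.chains)

        frames = []
        s_blocks = []
        z_blocks = []
        ac_counts = np.zeros(dataset.mask.n_cells)
        for c in range(self.chains):
            out = self._run_chain(dataset, M, priors,
                                  np.random.default_rng(chain_seeds[c]))
            df = pd.DataFrame(out["params"], columns=list(PARAM_COLS))
            df.insert(0, "chain", c)
            frames.append(df)
            s_blocks.append(out["s_det"])
            z_blocks.append(out["z"])
            ac_counts += out["ac_counts"]

        draws = pd.concat(frames, ignore_index=True)
        self.posterior_ = SCRPosterior(
            draws=draws,
            s_draws=np.concatenate(s_blocks, axis=0),
            z_draws=np.concatenate(z_blocks, axis=0),
            ac_counts=ac_counts,
            mask=dataset.mask,
            n_detected=n,
            M=M,
            n_chains=self.chains,
        )
        self.dataset_ = dataset
        if (draws["N"] > 0.9 * M).mean() > 0.01:
            warnings.warn(
                f"posterior mass of N piles near M={M}; increase M",
                stacklevel=2)
        return self

    # ------------------------------------------------------------------
    def _run_chain(self, dataset: SCRDataset, M: int, priors: SCRPriors,
                   rng: np.random.Generator) -> dict:
        y = dataset.y
        n, J = y.shape
        det = dataset.detectors
        mask = dataset.mask
        C = mask.n_cells
        E = det.effort
        area = mask.area_km2

        # sufficient statistics and precomputed geometry
        D2 = ((mask.coords[:, None, :] - det.coords[None, :, :]) ** 2
              ).sum(axis=2)                              # (C, J)
        G = D2 @ y.T                                     # (C, n), constant
        ytot = float(y.sum())
        yE = float(y.sum(axis=0) @ E)

        sex_obs = dataset.sexes
        sex_known = np.array([sx in ("F", "M") for sx in sex_obs])
        is_f = np.zeros(M, dtype=bool)
        is_f[:n] = sex_obs == "F"

        # initial state (overdispersed across chains via rng)
        a0 = float(np.log(max(ytot / (n * max(J, 1)), 1e-3)) + rng.normal(0, 0.5))
        a1 = float(rng.normal(0, 0.2))
        extent = float((mask.coords.max(axis=0) - mask.coords.min(axis=0)).max())
        sigma = float(np.clip(rng.uniform(0.05, 0.2) * extent,
                              priors.sigma_lo * 1.1, priors.sigma_hi * 0.9))
        psi = min(max(n / M, 0.05), 0.95)
        theta = 0.5
        z = np.ones(M, dtype=bool)
        z[n:] = rng.random(M - n) < psi
        is_f[n:] = rng.random(M - n) < theta
        unknown_det = ~sex_known

        # detected ACs start at the detection centroid's nearest mask cell
        s_idx = np.empty(M, dtype=int)
        for i in range(n):
            w = y[i] / y[i].sum()
            cxy = w @ det.coords
            s_idx[i] = int(((mask.coords - cxy) ** 2).sum(axis=1).argmin())
        s_idx[n:] = rng.integers(0, C, size=M - n)

        def lam_vec(a0_, a1_, K_):
            return K_ @ np.exp(a0_ + a1_ * E)

        K = np.exp(-D2 / (2.0 * sigma ** 2))
        Lam = lam_vec(a0, a1, K)
        Sd = float(G[s_idx[:n], np.arange(n)].sum())

        scales = {"a0": 0.1, "a1": 0.1, "lsig": 0.1}
        accept = {k: 0 for k in scales}
        tries = {k: 0 for k in scales}

        total_iters = self.burnin + self.iters
        n_keep = self.iters // self.thin
        params_out = np.empty((n_keep, len(PARAM_COLS)))
        s_out = np.empty((n_keep, M), dtype=np.int32)
        z_out = np.empty((n_keep, M), dtype=bool)
        ac_counts = np.zeros(C)
        keep = 0

        def loglik(a0_, a1_, sigma_, Lam_, Sd_):
            incl = Lam_[s_idx[z]].sum()
            return (a0_ * ytot + a1_ * yE - Sd_ / (2.0 * sigma_ ** 2) - incl)

        for it in range(total_iters):
            adapting = it < self.burnin

            # --- alpha0, alpha1: random-walk Metropolis -------------------
            for name, cur in (("a0", a0), ("a1", a1)):
                prop = cur + rng.normal(0, scales[name])
                a0_p, a1_p = (prop, a1) if name == "a0" else (a0, prop)
                Lam_p = lam_vec(a0_p, a1_p, K)
                sd_prior = priors.alpha0_sd if name == "a0" else priors.alpha1_sd
                logr = (loglik(a0_p, a1_p, sigma, Lam_p, Sd)
                        - loglik(a0, a1, sigma, Lam, Sd)
                        + (cur ** 2 - prop ** 2) / (2.0 * sd_prior ** 2))
                tries[name] += 1
                if np.log(rng.random()) < logr:
                    accept[name] += 1
                    if name == "a0":
                        a0 = prop
                    else:
                        a1 = prop
                    Lam = Lam_p

            # --- sigma: random walk on log sigma --------------------------
            lsig_p = np.log(sigma) + rng.normal(0, scales["lsig"])
            sigma_p = float(np.exp(lsig_p))
            tries["lsig"] += 1
            if priors.sigma_lo < sigma_p < priors.sigma_hi:
                K_p = np.exp(-D2 / (2.0 * sigma_p ** 2))
                Lam_p = lam_vec(a0, a1, K_p)
                # uniform prior on sigma + log-scale proposal Jacobian
                logr = (loglik(a0, a1, sigma_p, Lam_p, Sd)
                        - loglik(a0, a1, sigma, Lam, Sd)
                        + (np.log(sigma_p) - np.log(sigma)))
                if np.log(rng.random()) < logr:
                    accept["lsig"] += 1
                    sigma, K, Lam = sigma_p, K_p, Lam_p

            if adapting:
                for name in scales:
                    if tries[name] >= 50:
                        rate = accept[name] / tries[name]
                        scales[name] *= float(np.exp((rate - 0.35) * 0.5))
                        accept[name] = tries[name] = 0

            # --- activity centers: categorical Gibbs ----------------------
            logits = -G / (2.0 * sigma ** 2) - Lam[:, None]      # (C, n)
            gumb = rng.gumbel(size=logits.shape)
            s_idx[:n] = np.argmax(logits + gumb, axis=0)
            Sd = float(G[s_idx[:n], np.arange(n)].sum())

            aug = np.arange(n, M)
            on = aug[z[n:]]
            if on.size:
                wgt = np.exp(-(Lam - Lam.min()))
                cdf = np.cumsum(wgt)
                u = rng.random(on.size) * cdf[-1]
                s_idx[on] = np.searchsorted(cdf, u)
            off = aug[~z[n:]]
            if off.size:
                s_idx[off] = rng.integers(0, C, size=off.size)

            # --- inclusion z and psi --------------------------------------
            p_det0 = np.exp(-Lam[s_idx[n:]])
            p1 = psi * p_det0
            z[n:] = rng.random(M - n) < p1 / (p1 + (1.0 - psi))
            nz = int(z.sum())
            psi = rng.beta(1 + nz, 1 + M - nz)

            # --- sexes and theta ------------------------------------------
            is_f[n:] = rng.random(M - n) < theta
            if unknown_det.any():
                is_f[:n][unknown_det] = rng.random(unknown_det.sum()) < theta
            nf_all = int(is_f.sum())
            theta = rng.beta(1 + nf_all, 1 + M - nf_all)

            # --- record ---------------------------------------------------
            if not adapting:
                t = it - self.burnin
                if (t + 1) % self.thin == 0 and keep < n_keep:
                    N = nz
                    Nf = int((z & is_f).sum())
                    params_out[keep] = (
                        N, Nf, N - Nf, N / area * 100.0,
                        a0, a1, sigma, psi, theta)
                    s_out[keep] = s_idx
                    z_out[keep] = z
                    np.add.at(ac_counts, s_idx[z], 1.0)
                    keep += 1

        return {"params": params_out[:keep], "s_det": s_out[:keep],
                "z": z_out[:keep], "ac_counts": ac_counts}

    # ------------------------------------------------------------------
    def summarize(self) -> pd.DataFrame:
        return summarize(self.posterior_)

    def gof_pvalues(self, n_ppc: int = 200, seed: int | None = None,
                    dataset: SCRDataset | None = None) -> dict:
        return gof_pvalues(dataset or self.dataset_, self.posterior_,
                           n_ppc=n_ppc, seed=seed)

    def density_surface(self, report_area_km2: float = 100.0) -> np.ndarray:
        return density_surface(self.posterior_, report_area_km2)

    def rhat_table(self) -> pd.Series:
        post = self.posterior_
        return pd.Series({p: rhat(post.per_chain(p)) for p in PARAM_COLS})


def summarize(posterior: SCRPosterior) -> pd.DataFrame:
    """Posterior mean, sd, median and equal-tailed 95% BCI per parameter."""
    rows = {}
    for p in PARAM_COLS:
        x = posterior.draws[p].to_numpy(dtype=float)
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        rows[p] = {"mean": x.mean(), "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                   "bci_lo": lo, "median": med, "bci_hi": hi}
    return pd.DataFrame(rows).T[["mean", "sd", "bci_lo", "median", "bci_hi"]]


def density_from_abundance(n_individuals: float, area_km2: float,
                           report_area_km2: float = 100.0) -> float:
    """Density identity D = N / area * report_area (per 100 km^2 default)."""
    return n_individuals / area_km2 * report_area_km2


def density_surface(posterior: SCRPosterior,
                    report_area_km2: float = 100.0) -> np.ndarray:
    """Posterior mean density of included activity centers per mask cell,
    rescaled to individuals per ``report_area_km2``.  The integral of the
    surface times cell area / report area equals the posterior mean of N."""
    mean_count = posterior.ac_counts / posterior.n_draws
    return mean_count / posterior.mask.cell_area_km2 * report_area_km2


def plot_traces(posterior: SCRPosterior, path,
                params: tuple = ("N", "D", "sigma", "alpha0", "alpha1")):
    """Per-chain trace plots for visual convergence checks; writes ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(params), 1, figsize=(8, 2 * len(params)),
                             sharex=True)
    for ax, p in zip(np.atleast_1d(axes), params):
        for c, grp in posterior.draws.groupby("chain"):
            ax.plot(grp[p].to_numpy(), lw=0.5, label=f"chain {c}")
        ax.set_ylabel(p)
    np.atleast_1d(axes)[0].legend(loc="upper right", fontsize=8)
    np.atleast_1d(axes)[-1].set_xlabel("retained draw")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _freeman_tukey(obs: np.ndarray, exp: np.ndarray) -> float:
    return float(((np.sqrt(obs) - np.sqrt(exp)) ** 2).sum())


def gof_pvalues(dataset: SCRDataset, posterior: SCRPosterior,
                n_ppc: int = 200, seed: int | None = None) -> dict:
    """Three Bayesian p-values from posterior-predictive replicates.

    For each sampled posterior draw, a replicate encounter array is simulated
    for every *included* individual of the augmented population (detected
    individuals keep their observed rows; included-but-undetected
    individuals contribute structural zero rows, as the data-augmented model
    prescribes).  The Freeman-Tukey discrepancy T = sum (sqrt(obs) -
    sqrt(exp))^2 is compared between replicate and data at three aggregation
    levels: individual-by-detector cells, per-individual totals, and
    per-detector totals.  Values near 0 or 1 flag lack of fit.
    """
    rng = np.random.default_rng(seed)
    n = dataset.n_individuals
    det = dataset.detectors
    n_draws = posterior.n_draws
    take = np.linspace(0, n_draws - 1, min(n_ppc, n_draws)).astype(int)
    a0 = posterior.draws["alpha0"].to_numpy()
    a1 = posterior.draws["alpha1"].to_numpy()
    sig = posterior.draws["sigma"].to_numpy()
    y_aug = np.zeros((posterior.M, det.n_detectors), dtype=int)
    y_aug[:n] = dataset.y
    ge = {"cell": 0, "individual": 0, "detector": 0}
    for t in take:
        incl = posterior.z_draws[t]
        s_xy = posterior.mask.coords[posterior.s_draws[t][incl]]
        d2 = ((s_xy[:, None, :] - det.coords[None, :, :]) ** 2).sum(axis=2)
        lam = np.exp(a0[t] + a1[t] * det.effort) * np.exp(
            -d2 / (2.0 * sig[t] ** 2))
        y_obs = y_aug[incl]
        y_rep = rng.poisson(lam)
        if _freeman_tukey(y_rep, lam) >= _freeman_tukey(y_obs, lam):
            ge["cell"] += 1
        if (_freeman_tukey(y_rep.sum(axis=1), lam.sum(axis=1))
                >= _freeman_tukey(y_obs.sum(axis=1), lam.sum(axis=1))):
            ge["individual"] += 1
        if (_freeman_tukey(y_rep.sum(axis=0), lam.sum(axis=0))
                >= _freeman_tukey(y_obs.sum(axis=0), lam.sum(axis=0))):
            ge["detector"] += 1
    return {k: v / len(take) for k, v in ge.items()}
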