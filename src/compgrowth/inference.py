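"""Bayesian multilevel estimation of the composite growth model.

The observation model is the lognormal measurement likelihood

    ln h_jt ~ Normal( ln(0.012    + eta_jt), sigma_eta )
    ln m_jt ~ Normal( ln(1.02e-6  + mu_jt ), sigma_mu  )

where eta/mu are the five-process composite height and mass trajectories of
person j.  On the transformed scale (log H, log K, logit q, log initiation
increments; 19 coordinates) person j's parameter vector decomposes as

    theta_j = mu + gamma_{g(j)} + u_j ,   u_j,f ~ MVN(0, Sigma_f)

with a family-wise covariance Sigma_f for each of the four parameter
families (offsets covary across the five processes within a family).  The
first group is the reference and has gamma = 0.

Sampling is by an adaptive Metropolis-within-Gibbs scheme written for this
model: vectorized random-walk Metropolis updates of every person's
family blocks (proposal shaped by the current Sigma_f, step sizes adapted
per person during warmup), exact conjugate Gibbs draws for the baseline
means, group offsets and inverse-Wishart covariance updates, and
Metropolis steps on the log measurement SDs under half-normal priors.  The
likelihood factorizes over persons, so all person updates in a sweep are
performed in parallel as array operations.

The height SD prior is deliberately tighter than the weight SD prior
(half-normal scales 0.05 vs 0.25 by default): the cylinder-with-shared-q
body model cannot capture soft-tissue weight variation, so the fit is
steered to honour height more closely than weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from sklearn.base import BaseEstimator

from .data_prep import EGG_HEIGHT_CM, EGG_WEIGHT_G, PreparedDataset
from .presets import reference_theta
from .transforms import (
    FAMILIES,
    FAMILY_SLICES,
    N_TRANSFORMED,
    PARAM_NAMES,
    natural_array,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "GrowthModel",
    "PosteriorDraws",
    "HierarchicalGrowthModel",
    "log_likelihood",
    "build_model",
    "fit",
    "hpdi",
    "contrast",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorConfig:
    """Hyperparameters of the multilevel prior.

    mu0, sd0
        Center and SD of independent normal priors on the 19 transformed
        baseline means.  Defaults: the reference-like preset with SD 0.3 —
        informative priors anchored on a reference population, mirroring the
        priors-from-reference-children workflow this model is estimated
        with (a ±35% band on each rate/increment, ±0.3 on each logit).
    tau_group
        SD of the normal prior on each group-offset coordinate.
    cov_scale, cov_df_extra
        Inverse-Wishart prior on each family covariance: df = dim +
        cov_df_extra, scale matrix (df - dim - 1) * cov_scale**2 * I, so the
        prior mean is cov_scale**2 * I.
    sigma_h_scale, sigma_w_scale
        Half-normal prior scales for the log-scale measurement SDs of
        height and weight.  Height is constrained more tightly by design.
    """

    mu0: Optional[np.ndarray] = None
    sd0: float | np.ndarray = 0.3
    tau_group: float = 0.5
    cov_scale: float = 0.1
    cov_df_extra: int = 3
    sigma_h_scale: float = 0.05
    sigma_w_scale: float = 0.25
    sex: str = "F"

    def resolved_mu0(self) -> np.ndarray:
        mu0 = reference_theta(self.sex) if self.mu0 is None else np.asarray(self.mu0)
        if mu0.shape != (N_TRANSFORMED,):
            raise ValueError(f"mu0 must have shape ({N_TRANSFORMED},)")
        return mu0.astype(float)

    def resolved_sd0(self) -> np.ndarray:
        sd0 = np.broadcast_to(np.asarray(self.sd0, dtype=float), (N_TRANSFORMED,))
        if np.any(sd0 <= 0):
            raise ValueError("sd0 must be positive")
        return np.array(sd0)


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


class GrowthModel:
    """Data plus priors, exposing the unnormalized log posterior pieces.

    Built by :func:`build_model`; consumed by :func:`fit`.  Observations are
    flattened to one row per (record, modality) with precomputed constants,
    so likelihood evaluation is a handful of vectorized array expressions.
    """

    def __init__(
        self,
        data: PreparedDataset,
        priors: Optional[PriorConfig] = None,
        weight_fraction: float = 1.0,
        D: float = 1.0,
    ):
        frame = data.frame
        if frame.empty:
            raise ValueError("cannot build a model from an empty dataset")
        sexes = frame["sex"].unique()
        if len(sexes) > 1:
            raise ValueError(
                f"data contains multiple sexes {sorted(sexes)}; females and males "
                "are fit with separate models — filter before build_model"
            )
        self.priors = priors or PriorConfig()
        self.weight_fraction = float(weight_fraction)
        self.D = float(D)
        self.data = data

        person = data.person_codes()
        t = frame["t"].to_numpy(dtype=float)
        rows_t, rows_j, rows_mod, rows_y = [], [], [], []
        for col, mod in (("height_cm", 0), ("weight_g", 1)):
            vals = frame[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if np.any(vals[ok] <= 0):
                raise ValueError(f"nonpositive {col} observation cannot enter the "
                                 "lognormal likelihood")
            rows_t.append(t[ok])
            rows_j.append(person[ok])
            rows_mod.append(np.full(ok.sum(), mod))
            rows_y.append(np.log(vals[ok]))
        self.t_obs = np.concatenate(rows_t)
        self.person_obs = np.concatenate(rows_j)
        self.is_weight = np.concatenate(rows_mod).astype(bool)
        self.ln_y = np.concatenate(rows_y)
        if self.t_obs.size == 0:
            raise ValueError("no usable height or weight observations")
        if self.is_weight.all() or not self.is_weight.any():
            logger.warning("only one measurement modality present in the data")

        self.n_persons = data.n_persons
        self.n_groups = data.n_groups
        self.person_group = data.person_group_codes()
        self.group_labels = list(data.group_index)
        self.person_labels = list(data.person_index)

    # -- model evaluation ---------------------------------------------------

    def model_log_means(self, thetas: np.ndarray) -> np.ndarray:
        """ln(0.012 + h) / ln(1.02e-6 + w_frac * m) per observation row."""
        nat = natural_array(thetas)  # (J, 4, 5)
        j = self.person_obs
        H, K, q, i0 = (nat[j, k, :] for k in range(4))
        t = self.t_obs[:, None]
        lam = K * q / (1.0 + 2.0 * q)
        arg = np.minimum(lam * (i0 - t), 0.0)  # gated below; avoids overflow
        b = (2.0 * H / (self.D * K)) * np.clip(1.0 - np.exp(arg), 0.0, None)
        b = np.where(t >= i0, b, 0.0)
        h = b ** (1.0 / q)
        comp_h = h.sum(axis=1)
        # b^(1/q + 2) == h * b^2, saving a second fractional power
        comp_m = self.D * np.pi * (h * b * b).sum(axis=1)
        return np.where(
            self.is_weight,
            np.log(EGG_WEIGHT_G + self.weight_fraction * comp_m),
            np.log(EGG_HEIGHT_CM + comp_h),
        )

    def person_loglik(
        self, log_means: np.ndarray, sigma_h: float, sigma_w: float
    ) -> np.ndarray:
        """Per-person log likelihood given precomputed observation means."""
        sig = np.where(self.is_weight, sigma_w, sigma_h)
        ll = -np.log(sig) - 0.5 * _LOG2PI - 0.5 * ((self.ln_y - log_means) / sig) ** 2
        return np.bincount(self.person_obs, weights=ll, minlength=self.n_persons)

    def residual_stats(self, log_means: np.ndarray) -> tuple[float, int, float, int]:
        """(SS_height, n_height, SS_weight, n_weight) of log residuals."""
        r2 = (self.ln_y - log_means) ** 2
        w = self.is_weight
        return (
            float(r2[~w].sum()),
            int((~w).sum()),
            float(r2[w].sum()),
            int(w.sum()),
        )


def log_likelihood(
    data: PreparedDataset,
    person_params: dict,
    sigma_h: float,
    sigma_w: float,
    weight_fraction: float = 1.0,
) -> float:
    """Total measurement log likelihood for explicit per-person parameters.

    ``person_params`` maps person_id -> :class:`CompositeParams`.  Heights
    use the egg-cell offset 0.012 cm and SD ``sigma_h``; weights the offset
    1.02e-6 g and SD ``sigma_w``; a missing modality contributes nothing.
    """
    from .transforms import to_transformed

    model = GrowthModel(data, weight_fraction=weight_fraction)
    thetas = np.empty((model.n_persons, N_TRANSFORMED))
    for pid, code in data.person_index.items():
        thetas[code] = to_transformed(person_params[pid])
    means = model.model_log_means(thetas)
    return float(model.person_loglik(means, sigma_h, sigma_w).sum())


def build_model(
    data: PreparedDataset,
    priors: Optional[PriorConfig] = None,
    weight_fraction: float = 1.0,
    D: float = 1.0,
) -> GrowthModel:
    """Assemble the posterior object for :func:`fit`."""
    return GrowthModel(data, priors=priors, weight_fraction=weight_fraction, D=D)


# -- posterior container ----------------------------------------------------


@dataclass
class PosteriorDraws:
    """Draw-indexed arrays of every model quantity, plus diagnostics.

    Shapes: ``mu`` (chains, draws, 19); ``gamma`` (chains, draws, groups,
    19) with the reference group identically zero; ``covs[fam]`` (chains,
    draws, p, p); ``theta`` (chains, draws, persons, 19); ``sigma_h`` /
    ``sigma_w`` (chains, draws).
    """

    mu: np.ndarray
    gamma: np.ndarray
    covs: dict
    sigma_h: np.ndarray
    sigma_w: np.ndarray
    theta: np.ndarray
    group_labels: list
    person_labels: list
    person_group: np.ndarray
    accept_rate: np.ndarray
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    def copy(self) -> "PosteriorDraws":
        return PosteriorDraws(
            mu=self.mu.copy(),
            gamma=self.gamma.copy(),
            covs={k: v.copy() for k, v in self.covs.items()},
            sigma_h=self.sigma_h.copy(),
            sigma_w=self.sigma_w.copy(),
            theta=self.theta.copy(),
            group_labels=list(self.group_labels),
            person_labels=list(self.person_labels),
            person_group=self.person_group.copy(),
            accept_rate=self.accept_rate.copy(),
            seed=self.seed,
            diagnostics=dict(self.diagnostics),
        )

    def group_code(self, group: str) -> int:
        try:
            return self.group_labels.index(group)
        except ValueError:
            raise KeyError(
                f"unknown group {group!r}; valid groups: {self.group_labels}"
            ) from None

    def group_level(self, group: str) -> np.ndarray:
        """Transformed group-level parameters mu + gamma_g, flattened over
        chains: shape (chains*draws, 19)."""
        g = self.group_code(group)
        out = self.mu + self.gamma[:, :, g, :]
        return out.reshape(-1, N_TRANSFORMED)

    def population_draws(self, name: str, group: Optional[str] = None) -> np.ndarray:
        """Flattened draws of one named transformed parameter.

        ``name`` is one of :data:`~compgrowth.transforms.PARAM_NAMES`
        (e.g. ``log_K2``); with ``group`` the group offset is added.
        """
        k = PARAM_NAMES.index(name)
        if group is None:
            return self.mu[:, :, k].reshape(-1)
        return self.group_level(group)[:, k]

    def to_frame(self, include_persons: bool = False) -> pd.DataFrame:
        """Tidy long table (chain, draw, parameter, value)."""
        rows = []
        C, S = self.n_chains, self.n_draws
        chain_col = np.repeat(np.arange(C), S)
        draw_col = np.tile(np.arange(S), C)
        for k, name in enumerate(PARAM_NAMES):
            rows.append(
                pd.DataFrame(
                    {
                        "chain": chain_col,
                        "draw": draw_col,
                        "parameter": f"mu[{name}]",
                        "value": self.mu[:, :, k].reshape(-1),
                    }
                )
            )
            for g, lab in enumerate(self.group_labels):
                if g == 0:
                    continue
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": chain_col,
                            "draw": draw_col,
                            "parameter": f"gamma[{lab},{name}]",
                            "value": self.gamma[:, :, g, k].reshape(-1),
                        }
                    )
                )
        for nm, arr in (("sigma_h", self.sigma_h), ("sigma_w", self.sigma_w)):
            rows.append(
                pd.DataFrame(
                    {
                        "chain": chain_col,
                        "draw": draw_col,
                        "parameter": nm,
                        "value": arr.reshape(-1),
                    }
                )
            )
        if include_persons:
            for jj, pid in enumerate(self.person_labels):
                for k, name in enumerate(PARAM_NAMES):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": chain_col,
                                "draw": draw_col,
                                "parameter": f"theta[{pid},{name}]",
                                "value": self.theta[:, :, jj, k].reshape(-1),
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)

    def compute_diagnostics(self) -> dict:
        """R-hat and bulk ESS of the population-level parameters (arviz)."""
        import arviz as az

        post = {f"mu[{n}]": self.mu[:, :, k] for k, n in enumerate(PARAM_NAMES)}
        post["sigma_h"] = self.sigma_h
        post["sigma_w"] = self.sigma_w
        idata = az.from_dict(posterior=post)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        self.diagnostics.update(
            max_rhat=float(
                max(float(rhat[v].values) for v in rhat.data_vars)
            ),
            min_ess=float(min(float(ess[v].values) for v in ess.data_vars)),
            mean_accept=float(self.accept_rate.mean()),
        )
        return self.diagnostics

    def check_constraints(self) -> bool:
        """Every stored draw satisfies positivity, q in (0,1), i ordering."""
        nat = natural_array(self.theta)  # (C, S, J, 4, 5)
        H, K, q, i = (nat[..., k, :] for k in range(4))
        ok = (
            np.all(H > 0)
            and np.all(K > 0)
            and np.all((q > 0) & (q < 1))
            and np.all(np.diff(i, axis=-1) > 0)
            and np.all(i[..., 0] == 0.0)
            and np.all(self.sigma_h > 0)
            and np.all(self.sigma_w > 0)
        )
        return bool(ok)


# -- sampler ----------------------------------------------------------------


def _run_chain(
    model: GrowthModel,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    adapt_target: float = 0.3,
    mh_steps: int = 6,
) -> dict:
    pri = model.priors
    J, G = model.n_persons, model.n_groups
    mu0, sd0 = pri.resolved_mu0(), pri.resolved_sd0()
    fam_slices = [FAMILY_SLICES[f] for f in FAMILIES]
    fam_dims = [sl.stop - sl.start for sl in fam_slices]

    # state
    theta = np.tile(mu0, (J, 1)) + 0.05 * rng.standard_normal((J, N_TRANSFORMED))
    mu = mu0 + 0.05 * rng.standard_normal(N_TRANSFORMED)
    gamma = np.zeros((G, N_TRANSFORMED))
    covs = {
        f: np.eye(d) * pri.cov_scale**2 for f, d in zip(FAMILIES, fam_dims)
    }
    sigma_h = 0.5 * pri.sigma_h_scale
    sigma_w = 0.5 * pri.sigma_w_scale
    log_step = {f: np.full(J, np.log(0.5)) for f in FAMILIES}
    # scalar step sizes for the interweaved location (rigid-shift) moves:
    # one per family for mu, one per (group > 0, family) for gamma
    log_shift_mu = {f: np.log(0.05) for f in FAMILIES}
    log_shift_gamma = {(g, f): np.log(0.05) for g in range(1, G) for f in FAMILIES}

    means = model.model_log_means(theta)
    ll = model.person_loglik(means, sigma_h, sigma_w)

    n_keep = draws
    out = {
        "mu": np.empty((n_keep, N_TRANSFORMED)),
        "gamma": np.empty((n_keep, G, N_TRANSFORMED)),
        "covs": {f: np.empty((n_keep, d, d)) for f, d in zip(FAMILIES, fam_dims)},
        "sigma_h": np.empty(n_keep),
        "sigma_w": np.empty(n_keep),
        "theta": np.empty((n_keep, J, N_TRANSFORMED)),
    }
    acc_count = {f: np.zeros(J) for f in FAMILIES}
    acc_sweeps = 0

    iw_nu0 = {f: d + pri.cov_df_extra for f, d in zip(FAMILIES, fam_dims)}
    iw_psi0 = {
        f: (iw_nu0[f] - d - 1) * pri.cov_scale**2 * np.eye(d)
        for f, d in zip(FAMILIES, fam_dims)
    }

    group_of = model.person_group
    total = warmup + draws
    for sweep in range(total):
        adapting = sweep < warmup
        # --- person-level family-block Metropolis (vectorized over persons)
        for _ in range(mh_steps):
            for f, sl, d in zip(FAMILIES, fam_slices, fam_dims):
                L = np.linalg.cholesky(covs[f] + 1e-12 * np.eye(d))
                step = np.exp(log_step[f])
                prop = theta.copy()
                prop[:, sl] = theta[:, sl] + step[:, None] * (
                    rng.standard_normal((J, d)) @ L.T
                )
                means_prop = model.model_log_means(prop)
                ll_prop = model.person_loglik(means_prop, sigma_h, sigma_w)

                center = mu[sl] + gamma[group_of][:, sl]
                u_cur = solve_triangular(L, (theta[:, sl] - center).T, lower=True)
                u_prop = solve_triangular(L, (prop[:, sl] - center).T, lower=True)
                lp_cur = -0.5 * (u_cur**2).sum(axis=0)
                lp_prop = -0.5 * (u_prop**2).sum(axis=0)

                log_alpha = (ll_prop + lp_prop) - (ll + lp_cur)
                accept = np.log(rng.uniform(size=J)) < log_alpha
                theta[accept, sl] = prop[accept, sl]
                ll = np.where(accept, ll_prop, ll)
                obs_accept = accept[model.person_obs]
                means = np.where(obs_accept, means_prop, means)
                if adapting:
                    rate = np.exp(np.minimum(log_alpha, 0.0))
                    lr = (sweep + 10.0) ** -0.6
                    log_step[f] += lr * (rate - adapt_target)
                    np.clip(log_step[f], np.log(1e-3), np.log(20.0), out=log_step[f])
                else:
                    acc_count[f] += accept / mh_steps
        if not adapting:
            acc_sweeps += 1

        # --- baseline means mu_f | theta, gamma, Sigma_f  (conjugate normal)
        for f, sl, d in zip(FAMILIES, fam_slices, fam_dims):
            lam = np.linalg.inv(covs[f])
            prec = np.diag(1.0 / sd0[sl] ** 2) + J * lam
            resid = (theta[:, sl] - gamma[group_of][:, sl]).sum(axis=0)
            rhs = mu0[sl] / sd0[sl] ** 2 + lam @ resid
            cf = cho_factor(prec)
            mean = cho_solve(cf, rhs)
            Lp = solve_triangular(np.linalg.cholesky(prec), np.eye(d), lower=True)
            mu[sl] = mean + Lp.T @ rng.standard_normal(d)

        # --- group offsets gamma_{g>0} | theta, mu, Sigma_f
        for g in range(1, G):
            sel = group_of == g
            ng = int(sel.sum())
            for f, sl, d in zip(FAMILIES, fam_slices, fam_dims):
                lam = np.linalg.inv(covs[f])
                prec = np.eye(d) / pri.tau_group**2 + ng * lam
                rhs = lam @ (theta[sel][:, sl] - mu[sl]).sum(axis=0)
                cf = cho_factor(prec)
                mean = cho_solve(cf, rhs)
                Lp = solve_triangular(np.linalg.cholesky(prec), np.eye(d), lower=True)
                gamma[g, sl] = mean + Lp.T @ rng.standard_normal(d)

        # --- interweaved location moves (non-centered rigid shifts):
        # holding individual offsets fixed, translate a location parameter
        # and every affected person's theta together.  This decouples the
        # population location from the person blocks, which is what limits
        # mixing when many persons carry only one or two measurements.
        lr = (sweep + 10.0) ** -0.6
        for f, sl, d in zip(FAMILIES, fam_slices, fam_dims):
            # mu shift (moves every person)
            eta = np.exp(log_shift_mu[f]) * rng.standard_normal(d)
            prop = theta.copy()
            prop[:, sl] += eta
            means_prop = model.model_log_means(prop)
            ll_prop = model.person_loglik(means_prop, sigma_h, sigma_w)
            mu_new = mu[sl] + eta
            dprior = -0.5 * np.sum(((mu_new - mu0[sl]) / sd0[sl]) ** 2) + 0.5 * np.sum(
                ((mu[sl] - mu0[sl]) / sd0[sl]) ** 2
            )
            log_alpha = float(ll_prop.sum() - ll.sum() + dprior)
            if np.log(rng.uniform()) < log_alpha:
                theta = prop
                mu[sl] = mu_new
                ll = ll_prop
                means = means_prop
            if adapting:
                log_shift_mu[f] += lr * (np.exp(min(log_alpha, 0.0)) - 0.25)
                log_shift_mu[f] = float(np.clip(log_shift_mu[f], np.log(1e-4), np.log(2.0)))
            # gamma shifts (move one group's persons)
            for g in range(1, G):
                sel = group_of == g
                eta = np.exp(log_shift_gamma[(g, f)]) * rng.standard_normal(d)
                prop = theta.copy()
                prop[np.ix_(sel, np.arange(sl.start, sl.stop))] += eta
                means_prop = model.model_log_means(prop)
                ll_prop = model.person_loglik(means_prop, sigma_h, sigma_w)
                g_new = gamma[g, sl] + eta
                dprior = (
                    -0.5 * np.sum((g_new / pri.tau_group) ** 2)
                    + 0.5 * np.sum((gamma[g, sl] / pri.tau_group) ** 2)
                )
                log_alpha = float(
                    ll_prop[sel].sum() - ll[sel].sum() + dprior
                )
                if np.log(rng.uniform()) < log_alpha:
                    theta = prop
                    gamma[g, sl] = g_new
                    ll = np.where(sel, ll_prop, ll)
                    means = np.where(sel[model.person_obs], means_prop, means)
                if adapting:
                    log_shift_gamma[(g, f)] += lr * (np.exp(min(log_alpha, 0.0)) - 0.25)
                    log_shift_gamma[(g, f)] = float(
                        np.clip(log_shift_gamma[(g, f)], np.log(1e-4), np.log(2.0))
                    )

        # --- family covariances | offsets  (conjugate inverse-Wishart)
        for f, sl, d in zip(FAMILIES, fam_slices, fam_dims):
            u = theta[:, sl] - mu[sl] - gamma[group_of][:, sl]
            scale = iw_psi0[f] + u.T @ u
            covs[f] = stats.invwishart.rvs(df=iw_nu0[f] + J, scale=scale,
                                           random_state=rng)

        # --- measurement SDs (Metropolis on the log scale, half-normal prior)
        ssh, nh, ssw, nw = model.residual_stats(means)
        for _ in range(2):
            for which in ("h", "w"):
                cur = sigma_h if which == "h" else sigma_w
                ss, n = (ssh, nh) if which == "h" else (ssw, nw)
                scale = pri.sigma_h_scale if which == "h" else pri.sigma_w_scale
                prop_s = cur * np.exp(0.1 * rng.standard_normal())
                def _lp(s):
                    return (-n * np.log(s) - ss / (2.0 * s**2)
                            + _halfnormal_logpdf(s, scale) + np.log(s))
                if np.log(rng.uniform()) < _lp(prop_s) - _lp(cur):
                    if which == "h":
                        sigma_h = prop_s
                    else:
                        sigma_w = prop_s
        ll = model.person_loglik(means, sigma_h, sigma_w)

        if not adapting:
            k = sweep - warmup
            out["mu"][k] = mu
            out["gamma"][k] = gamma
            for f in FAMILIES:
                out["covs"][f][k] = covs[f]
            out["sigma_h"][k] = sigma_h
            out["sigma_w"][k] = sigma_w
            out["theta"][k] = theta

    out["accept_rate"] = np.array(
        [acc_count[f] / max(acc_sweeps, 1) for f in FAMILIES]
    )
    return out


def fit(
    model: GrowthModel,
    chains: int = 2,
    iterations: tuple[int, int] = (500, 500),
    seed: int = 0,
    adapt_target: float = 0.3,
    mh_steps: int = 6,
) -> PosteriorDraws:
    """Sample the posterior; returns draws with attached diagnostics.

    ``iterations`` is (warmup, retained draws) per chain.  The seed drives
    every chain through independent spawned generators, so a fixed seed
    yields bit-identical draws.
    """
    warmup, draws = iterations
    if chains < 1 or warmup < 0 or draws < 1:
        raise ValueError("need chains >= 1, warmup >= 0, draws >= 1")
    results = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(chains):
        rng = np.random.default_rng(child)
        results.append(_run_chain(model, warmup, draws, rng, adapt_target, mh_steps))

    post = PosteriorDraws(
        mu=np.stack([r["mu"] for r in results]),
        gamma=np.stack([r["gamma"] for r in results]),
        covs={
            f: np.stack([r["covs"][f] for r in results]) for f in FAMILIES
        },
        sigma_h=np.stack([r["sigma_h"] for r in results]),
        sigma_w=np.stack([r["sigma_w"] for r in results]),
        theta=np.stack([r["theta"] for r in results]),
        group_labels=model.group_labels,
        person_labels=model.person_labels,
        person_group=model.person_group,
        accept_rate=np.stack([r["accept_rate"] for r in results]),
        seed=seed,
    )
    try:
        post.compute_diagnostics()
    except Exception as err:  # pragma: no cover - diagnostics are best-effort
        logger.warning("diagnostics failed: %s", err)
    return post


# -- interval machinery ------------------------------------------------------


def hpdi(draws: np.ndarray, mass: float = 0.9) -> tuple[float, float]:
    """Highest posterior density interval of a scalar sample.

    The shortest contiguous window of sorted draws spanning at least the
    requested mass of the empirical distribution (window length
    ``ceil(mass*(n-1)) + 1``); the earliest window wins ties.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    w = int(np.ceil(mass * (n - 1))) + 1
    w = min(max(w, 2), n)
    widths = x[w - 1 :] - x[: n - w + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + w - 1])


@dataclass(frozen=True)
class ContrastResult:
    """Draws of a difference A - B with its HPDI-based detection flag."""

    draws: np.ndarray
    interval: tuple[float, float]
    detectable: bool
    mass: float = 0.9


def contrast(
    draws_a: np.ndarray, draws_b: np.ndarray, mass: float = 0.9
) -> ContrastResult:
    """Elementwise difference of two draw vectors and whether its HPDI
    excludes zero (the detectable-difference rule)."""
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.size != b.size:
        n = min(a.size, b.size)
        logger.info("contrast: resampling %d/%d draws to common count %d",
                    a.size, b.size, n)
        a = a[np.linspace(0, a.size - 1, n).astype(int)]
        b = b[np.linspace(0, b.size - 1, n).astype(int)]
    diff = a - b
    if np.allclose(diff, diff[0]):
        iv = (float(diff[0]), float(diff[0]))
        return ContrastResult(diff, iv, detectable=not iv[0] <= 0.0 <= iv[1],
                              mass=mass)
    lo, hi = hpdi(diff, mass)
    return ContrastResult(diff, (lo, hi), detectable=not lo <= 0.0 <= hi, mass=mass)


# -- sklearn-style front end --------------------------------------------------


class HierarchicalGrowthModel(BaseEstimator):
    """Scikit-learn style estimator wrapping build_model + fit.

    Parameters mirror :class:`PriorConfig` and the sampler settings; after
    :meth:`fit`, the posterior is available as ``posterior_`` and sampler
    diagnostics as ``diagnostics_``.

    Examples
    --------
    >>> est = HierarchicalGrowthModel(chains=2, warmup=200, draws=200, seed=1)
    >>> est.fit(prepared_dataset)            # doctest: +SKIP
    >>> est.posterior_.group_level("reference").shape   # doctest: +SKIP
    (400, 19)
    """

    def __init__(
        self,
        priors: Optional[PriorConfig] = None,
        chains: int = 2,
        warmup: int = 500,
        draws: int = 500,
        seed: int = 0,
        weight_fraction: float = 1.0,
        adapt_target: float = 0.3,
    ):
        self.priors = priors
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.weight_fraction = weight_fraction
        self.adapt_target = adapt_target

    def fit(self, X: PreparedDataset, y=None) -> "HierarchicalGrowthModel":
        """Sample the posterior for a prepared dataset (single sex)."""
        self.model_ = build_model(
            X, priors=self.priors, weight_fraction=self.weight_fraction
        )
        self.posterior_ = fit(
            self.model_,
            chains=self.chains,
            iterations=(self.warmup, self.draws),
            seed=self.seed,
            adapt_target=self.adapt_target,
        )
        self.diagnostics_ = dict(self.posterior_.diagnostics)
        self.groups_ = list(self.posterior_.group_labels)
        return self

    def predict(self, X, group: Optional[str] = None) -> np.ndarray:
        """Posterior-mean population height (cm) at total ages ``X``.

        ``X`` is an array-like of total ages (a single column is accepted).
        ``group`` defaults to the reference (first) group.
        """
        from .summaries import group_mean_curve

        if not hasattr(self, "posterior_"):
            raise AttributeError("estimator is not fitted yet")
        ages = np.asarray(X, dtype=float).reshape(-1)
        group = group or self.groups_[0]
        return group_mean_curve(self.posterior_, group, ages, kind="height").mean(
            axis=0
        )
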