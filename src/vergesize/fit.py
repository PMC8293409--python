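"""Bayesian posterior inference for the four-parameter logistic.

Two sklearn-style estimators:

* :class:`IndividualPsychometricModel` — one observer's (alpha, log10 beta,
  gamma, lambda) under a Bernoulli likelihood with diffuse normal priors on
  bias and log-slope and Beta(1, 10) priors on both lapse parameters.
* :class:`HierarchicalPsychometricModel` — a multilevel model in which each
  subject's bias and log10 slope are drawn from population normals
  (mu_alpha, sigma_alpha) and (mu_beta, sigma_beta); the population bias
  mu_alpha is the scientific quantity of interest.

Sampling uses the affine-invariant ensemble sampler (emcee) with a
non-centred parameterisation for the subject effects; convergence is
summarised by split-R-hat and bulk ESS (arviz), and a fit whose R-hat
exceeds the threshold is flagged and warned about, never silently
returned.  The default 15,000 retained draws match the study's posterior
sample size.
"""

from __future__ import annotations

import warnings

import arviz as az
import emcee
import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .psychometric import PFParams
from .synth import SubjectData

__all__ = [
    "IndividualPsychometricModel",
    "HierarchicalPsychometricModel",
    "fit_individual",
    "fit_hierarchical",
    "credible_interval",
    "ConvergenceWarning",
]

_P_CLIP = 1e-12

#: Default upper bound on the floor/ceiling lapse parameters.
DEFAULT_LAPSE_MAX = 0.1


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat exceeds the convergence threshold."""


def _bernoulli_loglik(alpha, beta_log10, gamma, lam, x, y):
    """Vectorised log-likelihood; parameter args are (W,) arrays, x/y (n,)."""
    # slopes beyond 10^6 per % are saturated step functions; clipping keeps
    # the diffuse prior's tails from overflowing the exponent
    beta = 10.0 ** np.clip(beta_log10, -12.0, 6.0)
    p = gamma[:, None] + (1.0 - gamma - lam)[:, None] * expit(
        beta[:, None] * (x[None, :] - alpha[:, None])
    )
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return np.log(p) @ y + np.log1p(-p) @ (1 - y)


def _lapse_logprior(v, lapse_max):
    """Beta(1, 10) on [0, 1], truncated to [0, lapse_max]; up to a constant."""
    out = np.where((v >= 0) & (v <= lapse_max),
                   9.0 * np.log1p(-np.minimum(v, 0.999)), -np.inf)
    return out


def _diagnostics(chain, n_groups: int = 4):
    """Split-R-hat and bulk ESS from an emcee chain (steps, walkers, dim).

    Ensemble walkers are far shorter than independent MCMC chains, so
    per-walker R-hat is dominated by within-walker autocorrelation rather
    than genuine non-mixing.  Walkers are therefore pooled into
    ``n_groups`` super-chains (each group's walkers concatenated
    walker-major, preserving their time ordering) and split-R-hat / ESS
    are computed over those.
    """
    steps, nw, dim = chain.shape
    wpg = nw // n_groups
    grouped = np.stack(
        [
            chain[:, g * wpg:(g + 1) * wpg, :]
            .transpose(1, 0, 2)
            .reshape(wpg * steps, dim)
            for g in range(n_groups)
        ]
    )  # (group, draws, dim)
    data = {f"p{j}": grouped[:, :, j] for j in range(dim)}
    idata = az.convert_to_dataset(data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    return (
        np.array([float(rhat[f"p{j}"].values) for j in range(dim)]),
        np.array([float(ess[f"p{j}"].values) for j in range(dim)]),
    )


def _validate_xy(X, y):
    x = np.asarray(X, dtype=float).reshape(-1)
    yy = np.asarray(y)
    if yy.dtype.kind in "UO":
        yy = (yy == "bigger").astype(int)
    yy = yy.astype(int).reshape(-1)
    if x.shape[0] != yy.shape[0]:
        raise ValueError("X and y must have the same length")
    if x.size and not np.all(np.isin(yy, [0, 1])):
        raise ValueError("responses must be binary (0/1 or 'smaller'/'bigger')")
    return x, yy


def credible_interval(draws, level: float = 0.95, sided: str = "two",
                      direction: str = "positive"):
    """Central quantile credible interval of posterior draws.

    Quantiles use linear interpolation (type 7).  ``sided="two"`` returns
    (lower, upper) of the central ``level`` interval.  ``sided="one"``
    returns the directional bound of the central ``level`` interval — the
    upper bound for ``direction="positive"``, the lower for "negative" —
    i.e. the one-sided (1+level)/2 bound, the construction used for
    inferiority testing against a directional margin.
    """
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("draws must be non-empty")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    lo, hi = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    if sided == "two":
        return float(np.quantile(d, lo)), float(np.quantile(d, hi))
    if sided == "one":
        if direction == "positive":
            return float(np.quantile(d, hi))
        if direction == "negative":
            return float(np.quantile(d, lo))
        raise ValueError("direction must be 'positive' or 'negative'")
    raise ValueError("sided must be 'two' or 'one'")


class _MCMCPsychometricBase(BaseEstimator):
    """Shared emcee plumbing for the psychometric estimators."""

    def _map_start(self, log_prob, x0, bounds):
        """Posterior mode found by L-BFGS-B; walkers start jittered around it.

        Starting the ensemble near the mode removes most of the warm-up
        transient, which is what dominates wall time for these smooth,
        unimodal posteriors.
        """
        from scipy.optimize import minimize

        res = minimize(
            lambda t: -float(log_prob(t[None, :])[0]), x0,
            method="L-BFGS-B", bounds=bounds,
        )
        return res.x if np.isfinite(res.fun) else x0

    def _run_sampler(self, log_prob, p0, seed):
        n_walkers, ndim = p0.shape
        thin = getattr(self, "thin", 1)
        steps = thin * int(np.ceil(self.n_draws / n_walkers))
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        rng = np.random.default_rng(seed)
        sampler.random_state = np.random.RandomState(rng.integers(2**31)).get_state()
        state = sampler.run_mcmc(p0, self.n_warmup + steps, progress=False)
        del state
        chain = sampler.get_chain(discard=self.n_warmup, thin=thin)
        rhat, ess = _diagnostics(chain)  # chain: (steps, walkers, dim)
        flat = chain.reshape(-1, chain.shape[2])
        return flat, rhat, ess

    def _check_convergence(self, rhat, names):
        self.converged_ = bool(np.all(rhat < self.rhat_threshold))
        if not self.converged_:
            bad = [n for n, r in zip(names, rhat) if r >= self.rhat_threshold]
            warnings.warn(
                f"MCMC may not have converged: R-hat >= {self.rhat_threshold} "
                f"for {bad}", ConvergenceWarning,
            )


class IndividualPsychometricModel(_MCMCPsychometricBase):
    """Posterior for one observer's four-parameter logistic.

    Parameters
    ----------
    alpha_prior_sd, beta_log10_prior_sd : float
        SDs of the zero-mean normal priors on the bias (% size change) and
        the log10 slope.
    n_draws : int
        Retained posterior draws (across all walkers) after warm-up.
    n_walkers, n_warmup : int
        Ensemble size and discarded warm-up steps.
    rhat_threshold : float
        Convergence flag threshold on split-R-hat.
    random_state : int or None
        Seed for the sampler.

    Fitted attributes: ``draws_`` (dict of parameter -> array of draws),
    posterior means ``alpha_``, ``beta_log10_``, ``gamma_``, ``lambda_``,
    diagnostics ``rhat_``, ``ess_`` and the flag ``converged_``.
    """

    _PARAM_NAMES = ("alpha", "beta_log10", "gamma", "lambda_")

    def __init__(self, alpha_prior_sd=100.0, beta_log10_prior_sd=100.0,
                 lapse_max=DEFAULT_LAPSE_MAX,
                 n_draws=15_000, n_walkers=32, n_warmup=800, thin=2,
                 rhat_threshold=1.01, random_state=None):
        self.alpha_prior_sd = alpha_prior_sd
        self.beta_log10_prior_sd = beta_log10_prior_sd
        self.lapse_max = lapse_max
        self.n_draws = n_draws
        self.n_walkers = n_walkers
        self.n_warmup = n_warmup
        self.thin = thin
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    def _log_prob(self, theta, x, y):
        alpha, b, g, l = theta.T
        lp = (
            -0.5 * (alpha / self.alpha_prior_sd) ** 2
            - 0.5 * (b / self.beta_log10_prior_sd) ** 2
            + _lapse_logprior(g, self.lapse_max)
            + _lapse_logprior(l, self.lapse_max)
        )
        ok = np.isfinite(lp)
        out = np.full(theta.shape[0], -np.inf)
        if x.size and ok.any():
            ll = _bernoulli_loglik(alpha[ok], b[ok], g[ok], l[ok], x, y)
            out[ok] = lp[ok] + ll
        else:
            out[ok] = lp[ok]
        return out

    def fit(self, X, y):
        """Sample the posterior given stimuli ``X`` (%) and binary responses
        ``y``.  With zero trials the posterior is the prior."""
        x, yy = _validate_xy(X, y)
        rng = np.random.default_rng(self.random_state)
        if x.size == 0:
            # prior sampling: spread the walkers over the prior scale
            p0 = np.column_stack([
                rng.normal(0.0, self.alpha_prior_sd, self.n_walkers),
                rng.normal(0.0, self.beta_log10_prior_sd, self.n_walkers),
                rng.uniform(0.2, 0.8, self.n_walkers) * self.lapse_max,
                rng.uniform(0.2, 0.8, self.n_walkers) * self.lapse_max,
            ])
        else:
            mode = self._map_start(
                lambda t: self._log_prob(t, x, yy),
                np.array([0.0, -0.7, 0.02, 0.02]),
                [(-20, 20), (-2, 1), (1e-4, 0.9 * self.lapse_max),
                 (1e-4, 0.9 * self.lapse_max)],
            )
            p0 = mode[None, :] + np.column_stack([
                rng.normal(0.0, 0.5, self.n_walkers),
                rng.normal(0.0, 0.15, self.n_walkers),
                rng.normal(0.0, 0.01, self.n_walkers),
                rng.normal(0.0, 0.01, self.n_walkers),
            ])
            p0[:, 2:] = np.clip(p0[:, 2:], 1e-4, 0.95 * self.lapse_max)
        flat, rhat, ess = self._run_sampler(
            lambda t: self._log_prob(t, x, yy), p0, rng.integers(2**31)
        )
        self.draws_ = {n: flat[:, j] for j, n in enumerate(self._PARAM_NAMES)}
        self.rhat_ = dict(zip(self._PARAM_NAMES, rhat))
        self.ess_ = dict(zip(self._PARAM_NAMES, ess))
        self._check_convergence(rhat, self._PARAM_NAMES)
        self.alpha_ = float(flat[:, 0].mean())
        self.beta_log10_ = float(flat[:, 1].mean())
        self.gamma_ = float(flat[:, 2].mean())
        self.lambda_ = float(flat[:, 3].mean())
        self.n_draws_ = flat.shape[0]
        return self

    @property
    def params_(self) -> PFParams:
        """Posterior-mean parameters as a PFParams."""
        return PFParams(self.alpha_, 10.0 ** self.beta_log10_,
                        min(self.gamma_, 0.4999), min(self.lambda_, 0.4999))

    def predict_proba(self, X):
        """P(smaller), P(bigger) at the posterior-mean parameters."""
        from .psychometric import pf_prob

        p = np.atleast_1d(pf_prob(self.params_, np.asarray(X, dtype=float).reshape(-1)))
        return np.column_stack([1.0 - p, p])


class HierarchicalPsychometricModel(_MCMCPsychometricBase):
    """Multilevel posterior for a multi-subject experiment.

    Subject-level bias and log10 slope are normal draws from population
    parameters (mu_alpha, sigma_alpha) and (mu_beta_log10, sigma_beta_log10)
    with diffuse normal hyperpriors on the means and half-normal
    (scale ``sigma_prior_scale``) hyperpriors on the SDs; lapse parameters
    are subject-level with Beta(1, 10) priors.  Subject effects are
    sampled non-centred (z-scores).

    Fitted attributes: ``draws_`` with population draws (``mu_alpha``,
    ``sigma_alpha``, ``mu_beta_log10``, ``sigma_beta_log10``),
    ``subject_draws_`` (dict subject -> dict of parameter draws), posterior
    means ``mu_alpha_`` etc., ``rhat_``, ``ess_``, ``converged_``.
    """

    def __init__(self, mu_prior_sd=100.0, sigma_prior_scale=10.0,
                 lapse_max=DEFAULT_LAPSE_MAX,
                 n_draws=15_000, n_walkers=None, n_warmup=2000, thin=10,
                 rhat_threshold=1.02, random_state=None):
        self.mu_prior_sd = mu_prior_sd
        self.sigma_prior_scale = sigma_prior_scale
        self.lapse_max = lapse_max
        self.n_draws = n_draws
        self.n_walkers = n_walkers
        self.n_warmup = n_warmup
        self.thin = thin
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    def _log_prob(self, theta, data):
        W = theta.shape[0]
        x, y, idx, S = data
        mu_a, mu_b = theta[:, 0], theta[:, 1]
        sig_a, sig_b = theta[:, 2], theta[:, 3]
        z_a = theta[:, 4:4 + S]
        z_b = theta[:, 4 + S:4 + 2 * S]
        g = theta[:, 4 + 2 * S:4 + 3 * S]
        l = theta[:, 4 + 3 * S:4 + 4 * S]
        lp = (
            -0.5 * (mu_a / self.mu_prior_sd) ** 2
            - 0.5 * (mu_b / self.mu_prior_sd) ** 2
            - 0.5 * np.sum(z_a**2, axis=1)
            - 0.5 * np.sum(z_b**2, axis=1)
            + np.sum(_lapse_logprior(g, self.lapse_max), axis=1)
            + np.sum(_lapse_logprior(l, self.lapse_max), axis=1)
        )
        lp = np.where(
            (sig_a >= 0) & (sig_b >= 0),
            lp
            - 0.5 * (sig_a / self.sigma_prior_scale) ** 2
            - 0.5 * (sig_b / self.sigma_prior_scale) ** 2,
            -np.inf,
        )
        ok = np.isfinite(lp)
        out = np.full(W, -np.inf)
        if not ok.any():
            return out
        # expand subject-level parameters to trial level in one shot
        alpha_s = mu_a[ok, None] + sig_a[ok, None] * z_a[ok]
        b_s = mu_b[ok, None] + sig_b[ok, None] * z_b[ok]
        beta_t = 10.0 ** np.clip(b_s[:, idx], -12.0, 6.0)
        g_t, l_t = g[ok][:, idx], l[ok][:, idx]
        p = g_t + (1.0 - g_t - l_t) * expit(beta_t * (x[None, :] - alpha_s[:, idx]))
        p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
        out[ok] = lp[ok] + np.log(p) @ y + np.log1p(-p) @ (1 - y)
        return out

    def fit(self, X, y, groups=None):
        """Sample the multilevel posterior.

        ``X``: stimuli (%), ``y``: binary responses, ``groups``: subject
        label per trial (at least two distinct subjects).
        """
        x, yy = _validate_xy(X, y)
        if groups is None:
            raise ValueError("groups (subject labels) are required")
        groups = np.asarray(groups)
        if groups.shape[0] != x.shape[0]:
            raise ValueError("groups must have one label per trial")
        self.subjects_ = list(dict.fromkeys(groups.tolist()))
        S = len(self.subjects_)
        if S < 2:
            raise ValueError("hierarchical fit requires at least 2 subjects")
        pos = {s: i for i, s in enumerate(self.subjects_)}
        idx = np.fromiter((pos[g] for g in groups.tolist()), dtype=int,
                          count=groups.shape[0])
        data = (x, yy, idx, S)
        ndim = 4 + 4 * S
        n_walkers = self.n_walkers or 2 * ndim + 4
        rng = np.random.default_rng(self.random_state)
        # initialise from per-subject individual MAPs: the marginal MAP of
        # the non-centred model itself is degenerate (it inflates sigma),
        # so the hierarchy's start point is assembled bottom-up instead
        helper = IndividualPsychometricModel(
            alpha_prior_sd=self.mu_prior_sd, beta_log10_prior_sd=self.mu_prior_sd,
            lapse_max=self.lapse_max,
        )
        maps = np.array([
            helper._map_start(
                lambda t: helper._log_prob(t, xs, ys),
                np.array([0.0, -0.7, 0.02, 0.02]),
                [(-20, 20), (-2, 1), (1e-4, 0.9 * self.lapse_max),
                 (1e-4, 0.9 * self.lapse_max)],
            )
            for xs, ys in ((x[idx == s], yy[idx == s]) for s in range(S))
        ])
        mu_a0, mu_b0 = maps[:, 0].mean(), maps[:, 1].mean()
        sig_a0 = max(maps[:, 0].std(), 0.1)
        sig_b0 = max(maps[:, 1].std(), 0.05)
        x0 = np.concatenate([
            [mu_a0, mu_b0, sig_a0, sig_b0],
            (maps[:, 0] - mu_a0) / sig_a0,
            (maps[:, 1] - mu_b0) / sig_b0,
            maps[:, 2], maps[:, 3],
        ])
        p0 = x0[None, :] + np.column_stack(
            [
                rng.normal(0.0, 0.3, n_walkers),
                rng.normal(0.0, 0.1, n_walkers),
                rng.normal(0.0, 0.1, n_walkers),
                rng.normal(0.0, 0.05, n_walkers),
            ]
            + [rng.normal(0.0, 0.3, n_walkers) for _ in range(2 * S)]
            + [rng.normal(0.0, 0.01, n_walkers) for _ in range(2 * S)]
        )
        p0[:, 2:4] = np.clip(p0[:, 2:4], 1e-3, 10.0)
        p0[:, 4 + 2 * S:] = np.clip(p0[:, 4 + 2 * S:], 1e-4, 0.95 * self.lapse_max)
        flat, rhat, ess = self._run_sampler(
            lambda t: self._log_prob(t, data), p0, rng.integers(2**31)
        )
        pop_names = ("mu_alpha", "mu_beta_log10", "sigma_alpha", "sigma_beta_log10")
        self.draws_ = {
            "mu_alpha": flat[:, 0],
            "mu_beta_log10": flat[:, 1],
            "sigma_alpha": flat[:, 2],
            "sigma_beta_log10": flat[:, 3],
        }
        self.subject_draws_ = {}
        for s_idx, sid in enumerate(self.subjects_):
            self.subject_draws_[sid] = {
                "alpha": flat[:, 0] + flat[:, 2] * flat[:, 4 + s_idx],
                "beta_log10": flat[:, 1] + flat[:, 3] * flat[:, 4 + S + s_idx],
                "gamma": flat[:, 4 + 2 * S + s_idx],
                "lambda_": flat[:, 4 + 3 * S + s_idx],
            }
        self.rhat_ = dict(zip(pop_names, rhat[:4]))
        self.ess_ = dict(zip(pop_names, ess[:4]))
        self._check_convergence(rhat, [f"p{j}" for j in range(ndim)])
        self.mu_alpha_ = float(flat[:, 0].mean())
        self.mu_beta_log10_ = float(flat[:, 1].mean())
        self.sigma_alpha_ = float(flat[:, 2].mean())
        self.sigma_beta_log10_ = float(flat[:, 3].mean())
        self.n_draws_ = flat.shape[0]
        return self

    def population_interval(self, level=0.95, sided="two", direction="positive"):
        """Credible interval of the population bias mu_alpha."""
        return credible_interval(self.draws_["mu_alpha"], level, sided, direction)

    def predict_proba(self, X):
        """P(smaller), P(bigger) at the population-mean parameters
        (lapses at their across-subject posterior mean)."""
        from .psychometric import pf_prob

        g = float(np.mean([d["gamma"].mean() for d in self.subject_draws_.values()]))
        l = float(np.mean([d["lambda_"].mean() for d in self.subject_draws_.values()]))
        params = PFParams(self.mu_alpha_, 10.0 ** self.mu_beta_log10_,
                          min(g, 0.4999), min(l, 0.4999))
        p = np.atleast_1d(pf_prob(params, np.asarray(X, dtype=float).reshape(-1)))
        return np.column_stack([1.0 - p, p])


def fit_individual(data: SubjectData, random_state=None, **kwargs) -> IndividualPsychometricModel:
    """Fit one subject's session; thin wrapper over the estimator."""
    model = IndividualPsychometricModel(random_state=random_state, **kwargs)
    return model.fit(data.stimuli, data.responses)


def fit_hierarchical(dataset: list[SubjectData], random_state=None, **kwargs) -> HierarchicalPsychometricModel:
    """Fit the multilevel model to a multi-subject dataset."""
    if len(dataset) < 2:
        raise ValueError("hierarchical fit requires at least 2 subjects")
    x = np.concatenate([s.stimuli for s in dataset])
    y = np.concatenate([s.responses for s in dataset])
    groups = np.concatenate([[s.subject_id] * len(s.trials) for s in dataset])
    model = HierarchicalPsychometricModel(random_state=random_state, **kwargs)
    return model.fit(x, y, groups=groups)
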