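"""Hierarchical Bayesian shrinkage-prior estimation over an ROI.

Every mask voxel i carries a transformed parameter vector

    theta_i = (F, D, D*, R2, V)
            = (logit f, log d, log d*, log r2fb, logit v)

drawn a priori from a shared multivariate Gaussian N(mu, Sigma) whose
hyperparameters are estimated from the ROI itself. Inference is
Metropolis-within-Gibbs: a Gaussian random-walk update of each theta_i
against the S0- and noise-marginalized likelihood, then conjugate draws of
mu (Gaussian, flat hyperprior) and Sigma (inverse-Wishart, Jeffreys-type
hyperprior). Voxels whose signal is noise-dominated are thereby shrunk
toward the ROI distribution; high-SNR voxels stay data-driven.

RNG discipline: voxels are processed in a canonical order (sorted by voxel
id), and all draws come from a single seeded generator consumed in that
order, so results are bit-reproducible and invariant to the order in which
the caller supplies voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import invwishart

from .model import DecideParams, ModelConstants, decide_signal
from .nonlinear_fit import VolumeFit, nls_fit_volume
from .protocol import AcquisitionProtocol
from .series import SignalSeries

__all__ = [
    "McmcConfig",
    "RoiHyperparams",
    "PosteriorSummary",
    "theta_from_params",
    "params_from_theta",
    "log_likelihood",
    "log_prior",
    "gibbs_update_mu",
    "gibbs_update_sigma",
    "mh_update_theta",
    "bsp_fit_signals",
    "bsp_fit_roi",
]

THETA_NAMES = ("f", "d", "d_star", "t2fb", "v")
_EPS = 1e-6


def theta_from_params(f, d, d_star, t2fb, v) -> np.ndarray:
    """Natural parameters -> transformed sampling coordinates (stacked last axis)."""
    f = np.clip(np.asarray(f, float), _EPS, 1 - _EPS)
    v = np.clip(np.asarray(v, float), _EPS, 1 - _EPS)
    return np.stack(
        [
            np.log(f) - np.log1p(-f),
            np.log(np.asarray(d, float)),
            np.log(np.asarray(d_star, float)),
            -np.log(np.asarray(t2fb, float)),  # log r2fb = -log T2fb
            np.log(v) - np.log1p(-v),
        ],
        axis=-1,
    )


def params_from_theta(theta: np.ndarray) -> dict[str, np.ndarray]:
    """Inverse of :func:`theta_from_params`; returns natural-unit arrays."""
    theta = np.asarray(theta, float)
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return {
        "f": expit(theta[..., 0]),
        "d": np.exp(theta[..., 1]),
        "d_star": np.exp(theta[..., 2]),
        "t2fb": np.exp(-theta[..., 3]),
        "v": expit(theta[..., 4]),
    }


def _model_unit_signal(
    thetas: np.ndarray, constants: ModelConstants, protocol: AcquisitionProtocol
) -> np.ndarray:
    """Expected signal g with S0 = 1 for transformed parameters (..., 5)."""
    p = params_from_theta(thetas)
    params = DecideParams(s0=np.ones(np.shape(thetas)[:-1]), **p)
    return decide_signal(params, constants, protocol)


def _log_likelihood_many(
    signals: np.ndarray, thetas: np.ndarray,
    constants: ModelConstants, protocol: AcquisitionProtocol,
) -> np.ndarray:
    """-(N/2) log(S'S - (S'g)^2 / g'g) for stacked voxels.

    The residual term is floored at a relative epsilon of S'S, so an exactly
    proportional signal yields a large finite guard value rather than +inf
    (keeping Metropolis arithmetic well-defined). Degenerate parameter values
    whose model signal overflows map to -inf (always rejected).
    """
    g = _model_unit_signal(thetas, constants, protocol)
    sts = np.sum(signals * signals, axis=-1)
    with np.errstate(over="ignore", invalid="ignore"):
        stg = np.sum(signals * g, axis=-1)
        gtg = np.sum(g * g, axis=-1)
        resid = sts - stg**2 / gtg
    n = signals.shape[-1]
    floor = 1e-15 * sts
    bad = ~np.isfinite(resid)
    out = -(n / 2.0) * np.log(np.maximum(np.where(bad, 1.0, resid), floor))
    return np.where(bad, -np.inf, out)


def log_likelihood(
    signal: np.ndarray,
    theta: np.ndarray,
    protocol: AcquisitionProtocol,
    constants: ModelConstants,
) -> float:
    """Marginal log-likelihood of one voxel's signal given transformed theta.

    The baseline amplitude S0 is profiled out analytically and the noise SD is
    marginalized, leaving -(N/2)*log(S'S - (S'g)^2/(g'g)) up to an additive
    constant, with g the unit-amplitude model signal. In the measure-zero
    case where the signal is exactly proportional to the model vector the
    divergent value is guarded: the residual is floored at 1e-15 * S'S, so a
    large finite value is returned and sampling stays well-defined.
    """
    signal = np.asarray(signal, float)
    if np.linalg.norm(signal) == 0:
        raise ValueError("signal must be nonzero")
    return float(
        _log_likelihood_many(signal[None], np.asarray(theta, float)[None], constants, protocol)[0]
    )


@dataclass
class RoiHyperparams:
    """ROI-level mean and covariance of the transformed parameters."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.mu.shape != (5,) or self.sigma.shape != (5, 5):
            raise ValueError("mu must be length-5, sigma 5x5")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(self.sigma) <= 0):
            raise ValueError("sigma must be positive-definite")


def log_prior(theta: np.ndarray, hyper: RoiHyperparams) -> float:
    """Multivariate Gaussian log-density of theta under the ROI hyperparameters."""
    theta = np.asarray(theta, float)
    diff = theta - hyper.mu
    chol = np.linalg.cholesky(hyper.sigma)
    half = np.linalg.solve(chol, diff)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (5 * np.log(2 * np.pi) + logdet + half @ half))


def _log_prior_many(thetas: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    chol = np.linalg.cholesky(sigma)
    diff = thetas - mu
    half = np.linalg.solve(chol, diff.T).T
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (5 * np.log(2 * np.pi) + logdet + np.sum(half * half, axis=-1))


def gibbs_update_mu(
    thetas: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw mu ~ N(mean(theta), Sigma/M) — the conditional under a flat hyperprior."""
    thetas = np.asarray(thetas, float)
    m = thetas.shape[0]
    if m < 2:
        raise ValueError("need at least two voxels to update mu")
    theta_bar = thetas.mean(axis=0)
    chol = np.linalg.cholesky(np.asarray(sigma, float) / m)
    return theta_bar + chol @ rng.standard_normal(5)


def gibbs_update_sigma(
    thetas: np.ndarray, mu: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw Sigma ~ InvWishart(df=M, scale=sum_i (theta_i-mu)(theta_i-mu)').

    The Jeffreys-type hyperprior conditional. A singular scatter matrix
    (e.g. all voxels identical) is regularized with a small ridge.
    """
    thetas = np.asarray(thetas, float)
    m = thetas.shape[0]
    if m < 7:
        raise ValueError("need at least 7 voxels for a proper 5-D inverse-Wishart draw")
    diff = thetas - np.asarray(mu, float)
    scale = diff.T @ diff
    try:
        np.linalg.cholesky(scale)
    except np.linalg.LinAlgError:
        warnings.warn("singular scatter matrix; ridge added", stacklevel=2)
        scale = scale + 1e-8 * np.eye(5)
    draw = invwishart.rvs(df=m, scale=scale, random_state=rng)
    return 0.5 * (draw + draw.T)


def mh_update_theta(
    theta: np.ndarray,
    signal: np.ndarray,
    hyper: RoiHyperparams,
    step: np.ndarray | float,
    protocol: AcquisitionProtocol,
    constants: ModelConstants,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One Gaussian random-walk Metropolis update of a single voxel's theta."""
    theta = np.asarray(theta, float)
    step = np.broadcast_to(np.asarray(step, float), (5,))
    if np.any(step <= 0):
        raise ValueError("step must be > 0")
    proposal = theta + step * rng.standard_normal(5)
    lp_cur = log_likelihood(signal, theta, protocol, constants) + log_prior(theta, hyper)
    lp_new = log_likelihood(signal, proposal, protocol, constants) + log_prior(proposal, hyper)
    if np.log(rng.random()) < lp_new - lp_cur:
        return proposal, True
    return theta.copy(), False


@dataclass
class McmcConfig:
    n_burn: int = 2000
    n_keep: int = 3000
    thin: int = 1
    proposal_scale: float = 0.25
    adapt_window: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_burn, self.n_keep, self.thin, self.adapt_window) < 1:
            raise ValueError("all MCMC counts must be >= 1")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be > 0")


@dataclass
class VoxelPosterior:
    """Per-voxel posterior summaries in natural units, caller voxel order."""

    median: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    acceptance_rate: np.ndarray
    mu_trace: np.ndarray
    sigma_trace: np.ndarray
    rhat: np.ndarray
    flags: dict[str, bool] = field(default_factory=dict)
    samples: np.ndarray | None = None  # (n_keep, M, 5) transformed-space draws


def _split_rhat(trace: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction per column of (n, k) trace."""
    n = trace.shape[0] // 2
    if n < 2:
        return np.full(trace.shape[1], np.nan)
    halves = np.stack([trace[:n], trace[n : 2 * n]])  # (2, n, k)
    w = halves.var(axis=1, ddof=1).mean(axis=0)
    b = n * halves.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / w)


def bsp_fit_signals(
    signals: np.ndarray,
    protocol: AcquisitionProtocol,
    constants: ModelConstants,
    config: McmcConfig,
    init_thetas: np.ndarray,
    *,
    voxel_ids: np.ndarray | None = None,
    use_likelihood: bool = True,
    fixed_hyper: RoiHyperparams | None = None,
    return_samples: bool = False,
) -> VoxelPosterior:
    """Run the Metropolis-within-Gibbs sampler on stacked voxel signals.

    signals : (M, N) array, one row per voxel.
    init_thetas : (M, 5) transformed-space initial values (typically from the
        voxelwise least-squares fit, nudged off any bound).
    voxel_ids : sortable per-voxel identifiers; processing happens in sorted
        id order so permuting the caller's voxel order (with matching ids)
        leaves every output bit-identical.
    use_likelihood : disable to sample the prior alone (validation mode).
    fixed_hyper : freeze (mu, Sigma) and skip the Gibbs steps (used for the
        small-ROI fallback and prior-recovery checks).
    """
    signals = np.asarray(signals, float)
    init_thetas = np.asarray(init_thetas, float)
    m = signals.shape[0]
    if voxel_ids is None:
        voxel_ids = np.arange(m)
    order = np.argsort(np.asarray(voxel_ids), kind="stable")
    inverse = np.empty(m, dtype=int)
    inverse[order] = np.arange(m)

    sig = signals[order]
    theta = init_thetas[order].copy()

    update_hyper = fixed_hyper is None
    if update_hyper:
        mu = theta.mean(axis=0)
        sigma = np.cov(theta, rowvar=False)
        sigma = np.atleast_2d(sigma) + 1e-4 * np.eye(5)
    else:
        mu, sigma = fixed_hyper.mu.copy(), fixed_hyper.sigma.copy()

    rng = np.random.default_rng(config.seed)
    # joint random-walk proposal shaped by the current prior covariance:
    # theta' = theta + s_i * scale * L z with L = chol(Sigma). A coordinatewise
    # walk mixes pathologically here because the Gibbs-sampled Sigma is
    # typically strongly correlated across parameters.
    base_scale = config.proposal_scale * 2.38 / np.sqrt(5.0)
    adapt = np.ones(m)  # per-voxel step multipliers, tuned toward ~30% acceptance

    n_iter = config.n_burn + config.n_keep * config.thin
    kept = np.empty((config.n_keep, m, 5))
    mu_trace = np.empty((config.n_keep, 5))
    sigma_trace = np.empty((config.n_keep, 5, 5))
    accept_post = np.zeros(m)
    accept_window = np.zeros(m)
    kept_i = 0

    if use_likelihood:
        ll = _log_likelihood_many(sig, theta, constants, protocol)
    else:
        ll = np.zeros(m)
    lp = _log_prior_many(theta, mu, sigma)

    for it in range(n_iter):
        chol = np.linalg.cholesky(sigma)
        noise = rng.standard_normal((m, 5)) @ chol.T
        u = np.log(rng.random(m))
        proposal = theta + (adapt * base_scale)[:, None] * noise
        if use_likelihood:
            ll_new = _log_likelihood_many(sig, proposal, constants, protocol)
        else:
            ll_new = np.zeros(m)
        lp_new = _log_prior_many(proposal, mu, sigma)
        with np.errstate(invalid="ignore"):
            accept = u < (ll_new + lp_new) - (ll + lp)
        accept &= np.isfinite(lp_new)
        theta[accept] = proposal[accept]
        ll = np.where(accept, ll_new, ll)
        lp = np.where(accept, lp_new, lp)
        accept_window += accept
        if it >= config.n_burn:
            accept_post += accept

        if update_hyper:
            mu = gibbs_update_mu(theta, sigma, rng)
            sigma = gibbs_update_sigma(theta, mu, rng)
            lp = _log_prior_many(theta, mu, sigma)

        burn = it < config.n_burn
        if burn and (it + 1) % config.adapt_window == 0:
            rate = accept_window / config.adapt_window
            adapt *= np.exp(1.5 * (rate - 0.3))
            adapt = np.clip(adapt, 1e-3, 1e3)
            accept_window[:] = 0.0
        if not burn:
            j = it - config.n_burn
            if (j + 1) % config.thin == 0:
                kept[kept_i] = theta
                mu_trace[kept_i] = mu
                sigma_trace[kept_i] = sigma
                kept_i += 1

    accept_rate = accept_post / (config.n_keep * config.thin)

    med_t = np.median(kept, axis=0)  # (m, 5) transformed-space median
    median = params_from_theta(med_t)
    nat_all = params_from_theta(kept)
    mean = {k: nat_all[k].mean(axis=0) for k in THETA_NAMES}
    sd = {k: nat_all[k].std(axis=0, ddof=1) for k in THETA_NAMES}

    rhat = _split_rhat(mu_trace) if update_hyper else np.full(5, np.nan)
    flags: dict[str, bool] = {}
    if update_hyper and np.any(rhat > 1.1):
        flags["rhat_exceeded"] = True
        warnings.warn("split-Rhat > 1.1 on hyperparameter mean; chain may not have converged")

    def _unsort(arr: np.ndarray) -> np.ndarray:
        return arr[inverse]

    return VoxelPosterior(
        median={k: _unsort(v) for k, v in median.items()},
        mean={k: _unsort(v) for k, v in mean.items()},
        sd={k: _unsort(v) for k, v in sd.items()},
        acceptance_rate=_unsort(accept_rate),
        mu_trace=mu_trace,
        sigma_trace=sigma_trace,
        rhat=rhat,
        flags=flags,
        samples=kept[:, inverse, :] if return_samples else None,
    )


@dataclass
class PosteriorSummary:
    """ROI posterior summaries as 3D maps (zero outside the mask)."""

    median: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    acceptance_rate: np.ndarray
    mu_trace: np.ndarray
    sigma_trace: np.ndarray
    rhat: np.ndarray
    flags: dict[str, bool]


#: broad fallback prior for ROIs too small to support the hierarchy
_FALLBACK_HYPER = RoiHyperparams(
    mu=theta_from_params(0.2, 0.0015, 0.04, 160.0, 0.3),
    sigma=np.diag([4.0, 1.0, 1.0, 0.5, 4.0]),
)


def bsp_fit_roi(
    series: SignalSeries,
    mask: np.ndarray,
    protocol: AcquisitionProtocol,
    constants: ModelConstants,
    config: McmcConfig | None = None,
    *,
    lsq_fit: VolumeFit | None = None,
) -> PosteriorSummary:
    """Shrinkage-prior fit of all mask voxels, initialized from the LSQ maps.

    ROIs with fewer than 7 voxels cannot support the 5-D inverse-Wishart
    update; they fall back to independent voxelwise fits under a fixed broad
    prior and are flagged.
    """
    config = config or McmcConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if lsq_fit is None:
        lsq_fit = nls_fit_volume(series, mask, protocol, constants, seed=config.seed)

    signals = series.data[mask]
    m = signals.shape[0]
    p = lsq_fit.params
    init_thetas = theta_from_params(
        np.clip(np.asarray(p.f)[mask], 1e-3, 1 - 1e-3),
        np.clip(np.asarray(p.d)[mask], 1e-5, 0.999),
        np.clip(np.asarray(p.d_star)[mask], 1e-5, 0.999),
        np.clip(np.asarray(p.t2fb)[mask], 1.0, 499.0),
        np.clip(np.asarray(p.v)[mask], 1e-3, 1 - 1e-3),
    )

    flags: dict[str, bool] = {}
    fixed = None
    if m < 7:
        warnings.warn("ROI smaller than 7 voxels; using fixed broad prior fallback")
        fixed = _FALLBACK_HYPER
        flags["small_roi_fallback"] = True

    post = bsp_fit_signals(
        signals, protocol, constants, config, init_thetas, fixed_hyper=fixed
    )
    flags.update(post.flags)

    def _to_map(values: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape, dtype=float)
        out[mask] = values
        return out

    return PosteriorSummary(
        median={k: _to_map(v) for k, v in post.median.items()},
        mean={k: _to_map(v) for k, v in post.mean.items()},
        sd={k: _to_map(v) for k, v in post.sd.items()},
        acceptance_rate=_to_map(post.acceptance_rate),
        mu_trace=post.mu_trace,
        sigma_trace=post.sigma_trace,
        rhat=post.rhat,
        flags=flags,
    )
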