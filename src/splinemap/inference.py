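"""Posterior sampling, diagnostics and model-comparison statistics.

The sampler is Metropolis-within-Gibbs.  Coefficient blocks (intercept plus
all spline coefficients) use an iterated-weighted-least-squares Gaussian
approximation as a Metropolis-Hastings proposal, which mixes well for
log-link count models.  Site-level effects (iid heterogeneity, ICAR fields)
use vectorized single-site proposals of the same type; smoothing precisions
and the iid variance have conjugate Gamma updates; remaining scalars use
adaptive random-walk steps (adapted during burn-in only, so the retained
chain is a valid time-homogeneous Markov chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import expit, gammaln, logsumexp

from .spatial_models import ModelSpec, bym2_scaling_factor, graph_components

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorSamples",
    "VarianceDecomposition",
    "run_mcmc",
    "variance_proportion",
    "waic",
    "mae",
]

_ETA_CAP = 30.0
_W_FLOOR = 1e-8
_MAX_INIT_ATTEMPTS = 20
_SCALAR_SWEEPS = 5


# ---------------------------------------------------------------------------
# likelihood families


def _mu(family, eta, trials):
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    if family == "binomial":
        return trials * expit(eta)
    return np.exp(eta)


def _loglik(family, y, eta, psi, trials):
    """Pointwise log-likelihood at linear predictor eta."""
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    if family == "poisson":
        mu = np.exp(eta)
        return y * eta - mu - gammaln(y + 1.0)
    if family == "negbin":
        mu = np.exp(eta)
        return (
            gammaln(y + psi)
            - gammaln(psi)
            - gammaln(y + 1.0)
            + psi * np.log(psi / (psi + mu))
            + y * np.log(mu / (psi + mu))
        )
    p = expit(eta)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return gammaln(trials + 1.0) - gammaln(y + 1.0) - gammaln(trials - y + 1.0) + y * np.log(p) + (trials - y) * np.log1p(-p)


def _score_weight(family, y, eta, psi, trials):
    """Gradient d loglik / d eta and expected information per observation."""
    eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
    if family == "poisson":
        mu = np.exp(eta)
        return y - mu, np.maximum(mu, _W_FLOOR)
    if family == "negbin":
        mu = np.exp(eta)
        f = psi / (psi + mu)
        return (y - mu) * f, np.maximum(mu * f, _W_FLOOR)
    p = expit(eta)
    return y - trials * p, np.maximum(trials * p * (1.0 - p), _W_FLOOR)


# ---------------------------------------------------------------------------
# results containers


@dataclass
class PosteriorSamples:
    """Retained MCMC draws.

    ``draws`` maps parameter names to arrays with the draw index first;
    ``terms`` maps random-term labels to (draws, n) arrays of per-area values;
    ``mu`` holds the per-draw mean function E(y_i) and ``loglik`` the
    pointwise log-likelihood.  ``meta`` records chains/iterations/burnin/thin/
    seed and acceptance rates.
    """

    draws: dict
    terms: dict
    mu: np.ndarray
    loglik: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[0]

    def by_chain(self, name: str) -> np.ndarray:
        """Reshape a scalar parameter's draws to (chains, draws_per_chain)."""
        x = np.asarray(self.draws[name])
        return x.reshape(self.meta["chains"], -1, *x.shape[1:])

    def rhat(self, name: str) -> float:
        """Split-R-hat convergence diagnostic for a scalar parameter."""
        import arviz as az

        with np.errstate(invalid="ignore"):
            return float(az.rhat(self.by_chain(name)))

    def credible_interval(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        x = np.asarray(self.draws[name])
        a = (1.0 - prob) / 2.0
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))


@dataclass
class VarianceDecomposition:
    """Posterior summary of per-term variance proportions.

    ``summary`` maps each label to {"mean", "lo95", "hi95"}; ``proportions``
    keeps the per-draw proportion series; ``n_dropped`` counts draws discarded
    for zero total variance.
    """

    summary: dict
    proportions: dict
    n_dropped: int = 0


# ---------------------------------------------------------------------------
# building blocks


def _chol_safe(A: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter on failure."""
    scale = np.mean(np.diag(A))
    jitter = 0.0
    for _ in range(12):
        try:
            return cholesky(A + jitter * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * max(scale, 1.0))
    raise np.linalg.LinAlgError("matrix not positive definite even with jitter")


def _logq_gauss(x, mean, chol_prec):
    """Log-density of N(mean, prec^-1) with prec = L L' given via its Cholesky."""
    d = x - mean
    half = chol_prec.T @ d
    logdet = 2.0 * np.sum(np.log(np.diag(chol_prec)))
    return 0.5 * logdet - 0.5 * len(x) * np.log(2.0 * np.pi) - 0.5 * half @ half


def _iwls_update(rng, theta, X, Qp, y, fixed, family, psi, trials):
    """One MH step for a coefficient block using the IWLS Gaussian proposal."""

    def proposal(th):
        eta = fixed + X @ th
        s, w = _score_weight(family, y, eta, psi, trials)
        z = X @ th + s / w
        A = (X.T * w) @ X + Qp
        L = _chol_safe(A)
        b = X.T @ (w * z)
        m = cho_solve((L, True), b)
        return eta, m, L

    eta0, m0, L0 = proposal(theta)
    noise = rng.standard_normal(len(theta))
    theta_new = m0 + solve_triangular(L0.T, noise, lower=False)
    eta1, m1, L1 = proposal(theta_new)

    def logpost(th, eta):
        return np.sum(_loglik(family, y, eta, psi, trials)) - 0.5 * th @ Qp @ th

    logr = (
        logpost(theta_new, eta1)
        - logpost(theta, eta0)
        + _logq_gauss(theta, m1, L1)
        - _logq_gauss(theta_new, m0, L0)
    )
    if np.log(rng.uniform()) < logr:
        return theta_new, eta1, True
    return theta, eta0, False


def _site_update(rng, x, coef, prior_mean, prior_prec, idx, eta, y, family, psi, trials):
    """Vectorized single-site MH updates for sites `idx` of a latent vector.

    The sites must be conditionally independent given the rest of the state
    (iid effects, or one colour class of an ICAR field).  `coef` multiplies
    the latent value inside the linear predictor.
    """
    yi = y[idx]
    ti = trials[idx] if trials is not None else None
    e0 = eta[idx]
    x0 = x[idx]

    def prop(xcur, ecur):
        s, w = _score_weight(family, yi, ecur, psi, ti)
        info = coef**2 * w
        target = xcur + s / (coef * w)
        cp = info + prior_prec
        mp = (info * target + prior_prec * prior_mean) / cp
        return mp, cp

    m0, c0 = prop(x0, e0)
    x1 = m0 + rng.standard_normal(len(idx)) / np.sqrt(c0)
    e1 = e0 + coef * (x1 - x0)
    m1, c1 = prop(x1, e1)

    ll0 = _loglik(family, yi, e0, psi, ti)
    ll1 = _loglik(family, yi, e1, psi, ti)
    logr = (
        ll1
        - ll0
        - 0.5 * prior_prec * (x1 - prior_mean) ** 2
        + 0.5 * prior_prec * (x0 - prior_mean) ** 2
        + (0.5 * np.log(c1) - 0.5 * c1 * (x0 - m1) ** 2)
        - (0.5 * np.log(c0) - 0.5 * c0 * (x1 - m0) ** 2)
    )
    accept = np.log(rng.uniform(size=len(idx))) < logr
    x_new = x.copy()
    x_new[idx] = np.where(accept, x1, x0)
    eta_new = eta.copy()
    eta_new[idx] = np.where(accept, e1, e0)
    return x_new, eta_new, accept


class _AdaptiveScale:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, scale=0.5, target=0.44):
        self.scale = scale
        self.target = target
        self.t = 0

    def update(self, accepted: bool, adapting: bool):
        if adapting:
            self.t += 1
            step = min(0.5, 1.0 / np.sqrt(self.t + 1.0))
            self.scale *= np.exp(step * ((1.0 if accepted else 0.0) - self.target))
            self.scale = float(np.clip(self.scale, 1e-4, 50.0))


def _greedy_coloring(W: np.ndarray) -> list[np.ndarray]:
    """Partition graph nodes into independent sets (colour classes)."""
    n = W.shape[0]
    order = np.argsort(-W.sum(axis=1), kind="stable")
    colors = -np.ones(n, dtype=int)
    for i in order:
        used = {colors[j] for j in np.flatnonzero(W[i]) if colors[j] >= 0}
        c = 0
        while c in used:
            c += 1
        colors[i] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]


# ---------------------------------------------------------------------------
# samplers


def _spline_chain(spec: ModelSpec, y, iterations, burnin, thin, rng, keep):
    pr = spec.priors
    n = spec.n
    family = spec.family
    trials = spec.trials
    base = spec.offset if family != "binomial" else np.zeros(n)

    labels = [lab for lab, _ in spec.smooth_terms]
    bases = [b for _, b in spec.smooth_terms]
    blocks = [1] + [b.ncol for b in bases]
    p = sum(blocks)
    starts = np.cumsum([0] + blocks)

    X = np.ones((n, p))
    for k, b in enumerate(bases):
        X[:, starts[k + 1] : starts[k + 2]] = b.X

    def q_prior(lam0s, lam1s):
        Q = np.zeros((p, p))
        Q[0, 0] = 1.0 / pr["alpha_sd"] ** 2
        for k, b in enumerate(bases):
            sl = slice(starts[k + 1], starts[k + 2])
            Q[sl, sl] = lam0s[k] * b.P0 + lam1s[k] * b.P1
        return Q

    # initial values; re-draw if the likelihood is non-finite
    for attempt in range(_MAX_INIT_ATTEMPTS):
        theta = np.zeros(p)
        if family == "binomial":
            theta[0] = float(np.log((y.sum() + 0.5) / (trials.sum() - y.sum() + 0.5)))
        else:
            theta[0] = float(np.log((y.sum() + 0.5) / np.exp(spec.offset).sum()))
        if attempt > 0:
            theta += 0.1 * rng.standard_normal(p)
        v = np.zeros(n)
        eta = base + X @ theta + v
        if np.all(np.isfinite(_loglik(family, y, eta, 1.0, trials))):
            break
    else:
        raise RuntimeError("could not find finite-likelihood initial values")

    lam0s = np.ones(len(bases))
    lam1s = np.ones(len(bases))
    sigma_v_fixed = pr.get("sigma_v_fixed")
    prec_v = 1.0 / sigma_v_fixed**2 if sigma_v_fixed else 1.0
    psi_fixed = pr.get("psi_fixed")
    psi = float(psi_fixed) if psi_fixed else 1.0
    psi_step = _AdaptiveScale()

    all_idx = np.arange(n)
    ranks1 = [np.linalg.matrix_rank(b.P1, tol=1e-8) for b in bases]
    acc_theta = 0

    out = {"alpha": [], "v": [], "sigma_v": [], "psi": []}
    for lab in labels:
        out[f"beta_{lab}"] = []
        out[f"lambda0_{lab}"] = []
        out[f"lambda1_{lab}"] = []
    terms = {lab: [] for lab in labels}
    if spec.include_iid:
        terms["iid"] = []
    mus, logliks = [], []

    for it in range(iterations):
        adapting = it < burnin
        Qp = q_prior(lam0s, lam1s)
        theta, eta, acc = _iwls_update(rng, theta, X, Qp, y, base + v, family, psi, trials)
        acc_theta += acc

        if spec.include_iid:
            v, eta, _ = _site_update(
                rng, v, 1.0, 0.0, prec_v, all_idx, eta, y, family, psi, trials
            )
            if sigma_v_fixed is None:
                prec_v = rng.gamma(
                    pr["sigma_v_prec_shape"] + 0.5 * n,
                    1.0 / (pr["sigma_v_prec_rate"] + 0.5 * v @ v),
                )

        for k, b in enumerate(bases):
            beta_k = theta[starts[k + 1] : starts[k + 2]]
            lam1s[k] = rng.gamma(
                pr["lambda_shape"] + 0.5 * ranks1[k],
                1.0 / (pr["lambda_rate"] + 0.5 * beta_k @ b.P1 @ beta_k),
            )
            lam0s[k] = rng.gamma(
                pr["lambda_shape"] + 1.0,
                1.0 / (pr["lambda_rate"] + 0.5 * beta_k @ b.P0 @ beta_k),
            )

        if family == "negbin" and psi_fixed is None:
            lpsi_new = np.log(psi) + psi_step.scale * rng.standard_normal()
            psi_new = float(np.exp(lpsi_new))
            ll_new = np.sum(_loglik(family, y, eta, psi_new, trials))
            ll_old = np.sum(_loglik(family, y, eta, psi, trials))
            a, bb = pr["psi_shape"], pr["psi_rate"]
            logr = ll_new - ll_old + a * (lpsi_new - np.log(psi)) - bb * (psi_new - psi)
            acc_psi = np.log(rng.uniform()) < logr
            if acc_psi:
                psi = psi_new
            psi_step.update(acc_psi, adapting)

        if it >= burnin and (it - burnin) % thin == 0 and keep:
            out["alpha"].append(theta[0])
            out["v"].append(v.copy())
            out["sigma_v"].append(1.0 / np.sqrt(prec_v))
            out["psi"].append(psi)
            for k, lab in enumerate(labels):
                beta_k = theta[starts[k + 1] : starts[k + 2]]
                out[f"beta_{lab}"].append(beta_k.copy())
                out[f"lambda0_{lab}"].append(lam0s[k])
                out[f"lambda1_{lab}"].append(lam1s[k])
                terms[lab].append(bases[k].X @ beta_k)
            if spec.include_iid:
                terms["iid"].append(v.copy())
            mus.append(_mu(family, eta, trials))
            logliks.append(_loglik(family, y, eta, psi, trials))

    meta = {"accept_theta": acc_theta / iterations}
    return out, terms, mus, logliks, meta


def _bym2_chain(spec: ModelSpec, y, iterations, burnin, thin, rng, keep):
    pr = spec.priors
    n = spec.n
    family = spec.family
    trials = spec.trials
    base = spec.offset if family != "binomial" else np.zeros(n)

    W = np.asarray(spec.adjacency, dtype=float)
    deg = W.sum(axis=1)
    labels_cc = graph_components(W)
    sf = bym2_scaling_factor(W)
    islands = deg == 0
    if islands.any():
        logger.warning("%d island area(s): independent N(0,1) structured effects", islands.sum())
    colors = _greedy_coloring(W)
    comp_sizes = np.bincount(labels_cc)
    single_component = len(comp_sizes) == 1

    alpha = float(np.log((y.sum() + 0.5) / np.exp(base).sum())) if family != "binomial" else 0.0
    u = np.zeros(n)
    v = np.zeros(n)
    phi, tau = 0.5, 1.0
    psi_fixed = pr.get("psi_fixed")
    psi = float(psi_fixed) if psi_fixed else 1.0
    steps = {"phi": _AdaptiveScale(), "tau": _AdaptiveScale(), "psi": _AdaptiveScale()}

    def combine(phi_, tau_):
        return np.sqrt(phi_ / tau_), np.sqrt((1.0 - phi_) / tau_)

    a, b = combine(phi, tau)
    eta = base + alpha + a * u + b * v
    alpha_prec = 1.0 / pr["alpha_sd"] ** 2
    ones_col = np.ones((n, 1))

    out = {"alpha": [], "phi": [], "tau": [], "psi": [], "u_star": [], "v_star": []}
    terms = {"structured": [], "iid": []}
    mus, logliks = [], []

    for it in range(iterations):
        adapting = it < burnin

        # intercept (1-column IWLS block)
        th, eta, _ = _iwls_update(
            rng,
            np.array([alpha]),
            ones_col,
            np.array([[alpha_prec]]),
            y,
            base + a * u + b * v,
            family,
            psi,
            trials,
        )
        alpha = float(th[0])
        eta = base + alpha + a * u + b * v

        # structured field, one colour class at a time
        for idx in colors:
            isl = islands[idx]
            if (~isl).any():
                ii = idx[~isl]
                prior_mean = (W[ii] @ u) / deg[ii]
                u, eta, _ = _site_update(
                    rng, u, a, prior_mean, sf * deg[ii], ii, eta, y, family, psi, trials
                )
            if isl.any():
                ii = idx[isl]
                u, eta, _ = _site_update(
                    rng, u, a, 0.0, 1.0, ii, eta, y, family, psi, trials
                )
        # sum-to-zero: centre u; with one component the shift is folded into alpha
        if single_component:
            ubar = u.mean()
            u = u - ubar
            alpha += a * ubar
        else:
            for c in np.unique(labels_cc):
                m = labels_cc == c
                if m.sum() > 1:
                    u[m] -= u[m].mean()
            eta = base + alpha + a * u + b * v

        # unstructured field
        v, eta, _ = _site_update(
            rng, v, b, 0.0, 1.0, np.arange(n), eta, y, family, psi, trials
        )

        # mixing parameter phi (logit random walk, Uniform(0,1) prior) and
        # precision-scale tau (log random walk, Gamma prior): several cheap
        # scalar sweeps per iteration to offset random-walk autocorrelation
        for _ in range(_SCALAR_SWEEPS):
            t0 = np.log(phi) - np.log1p(-phi)
            t1 = t0 + steps["phi"].scale * rng.standard_normal()
            phi_new = float(expit(t1))
            a_new, b_new = combine(phi_new, tau)
            eta_new = base + alpha + a_new * u + b_new * v
            logr = (
                np.sum(_loglik(family, y, eta_new, psi, trials))
                - np.sum(_loglik(family, y, eta, psi, trials))
                + np.log(phi_new * (1 - phi_new))
                - np.log(phi * (1 - phi))
            )
            acc = np.log(rng.uniform()) < logr
            if acc:
                phi, a, b, eta = phi_new, a_new, b_new, eta_new
            steps["phi"].update(acc, adapting)

            s0 = np.log(tau)
            s1 = s0 + steps["tau"].scale * rng.standard_normal()
            tau_new = float(np.exp(s1))
            a_new, b_new = combine(phi, tau_new)
            eta_new = base + alpha + a_new * u + b_new * v
            logr = (
                np.sum(_loglik(family, y, eta_new, psi, trials))
                - np.sum(_loglik(family, y, eta, psi, trials))
                + pr["tau_shape"] * (s1 - s0)
                - pr["tau_rate"] * (tau_new - tau)
            )
            acc = np.log(rng.uniform()) < logr
            if acc:
                tau, a, b, eta = tau_new, a_new, b_new, eta_new
            steps["tau"].update(acc, adapting)

        if family == "negbin" and psi_fixed is None:
            lpsi_new = np.log(psi) + steps["psi"].scale * rng.standard_normal()
            psi_new = float(np.exp(lpsi_new))
            logr = (
                np.sum(_loglik(family, y, eta, psi_new, trials))
                - np.sum(_loglik(family, y, eta, psi, trials))
                + pr["psi_shape"] * (lpsi_new - np.log(psi))
                - pr["psi_rate"] * (psi_new - psi)
            )
            acc = np.log(rng.uniform()) < logr
            if acc:
                psi = psi_new
            steps["psi"].update(acc, adapting)

        if it >= burnin and (it - burnin) % thin == 0 and keep:
            out["alpha"].append(alpha)
            out["phi"].append(phi)
            out["tau"].append(tau)
            out["psi"].append(psi)
            out["u_star"].append(u.copy())
            out["v_star"].append(v.copy())
            terms["structured"].append(a * u)
            terms["iid"].append(b * v)
            mus.append(_mu(family, eta, trials))
            logliks.append(_loglik(family, y, eta, psi, trials))

    return out, terms, mus, logliks, {}


def run_mcmc(
    spec: ModelSpec,
    counts: np.ndarray,
    chains: int = 4,
    iterations: int = 2000,
    burnin: int = 1000,
    thin: int = 1,
    seed: int = 0,
) -> PosteriorSamples:
    """Sample the posterior of a ModelSpec given observed counts.

    Returns retained draws from all chains concatenated (chain-major order)
    along with per-draw random-term values, mean function and pointwise
    log-likelihoods.  A fixed seed yields identical output on the same
    platform.
    """
    y = np.asarray(counts, dtype=float)
    if y.shape != (spec.n,):
        raise ValueError(f"counts have shape {y.shape}, expected ({spec.n},)")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if iterations <= burnin:
        raise ValueError("iterations must exceed burnin")

    chain_fn = _bym2_chain if spec.comparator == "bym2" else _spline_chain
    seeds = np.random.SeedSequence(seed).spawn(chains)

    merged_out, merged_terms, mus, logliks = None, None, [], []
    meta_acc = []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        out, terms, mu_c, ll_c, meta_c = chain_fn(spec, y, iterations, burnin, thin, rng, True)
        meta_acc.append(meta_c)
        if merged_out is None:
            merged_out = {k: list(vv) for k, vv in out.items()}
            merged_terms = {k: list(vv) for k, vv in terms.items()}
        else:
            for k in merged_out:
                merged_out[k].extend(out[k])
            for k in merged_terms:
                merged_terms[k].extend(terms[k])
        mus.extend(mu_c)
        logliks.extend(ll_c)

    draws = {k: np.asarray(vv) for k, vv in merged_out.items() if len(vv)}
    terms = {k: np.asarray(vv) for k, vv in merged_terms.items()}
    loglik = np.asarray(logliks)
    if not np.all(np.isfinite(loglik)):
        raise RuntimeError("non-finite pointwise log-likelihood in retained draws")
    meta = {
        "chains": chains,
        "iterations": iterations,
        "burnin": burnin,
        "thin": thin,
        "seed": seed,
        "acceptance": meta_acc,
        "model": "bym2" if spec.comparator == "bym2" else "spline",
        "family": spec.family,
    }
    return PosteriorSamples(draws=draws, terms=terms, mu=np.asarray(mus), loglik=loglik, meta=meta)


# ---------------------------------------------------------------------------
# posterior summaries


def variance_proportion(samples: PosteriorSamples, term_labels=None) -> VarianceDecomposition:
    """Per-draw share of the total random-term variance carried by each term.

    For every retained draw the population variance (divide by n) over areas
    is computed for each term and for the elementwise sum of all random
    terms; the proportion is var(term) / var(sum).  Draws with zero total
    variance are dropped (logged).  Each label is summarized by the posterior
    mean and the equal-tailed 95% interval.
    """
    if term_labels is None:
        term_labels = list(samples.terms)
    missing = [t for t in term_labels if t not in samples.terms]
    if missing:
        raise KeyError(f"terms not present in draws: {missing}")

    total = np.sum([samples.terms[k] for k in samples.terms], axis=0)
    denom = total.var(axis=1)  # population variance per draw
    ok = denom > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropping %d draw(s) with zero total random-term variance", n_dropped)
    summary, proportions = {}, {}
    for lab in term_labels:
        num = samples.terms[lab].var(axis=1)
        prop = num[ok] / denom[ok]
        proportions[lab] = prop
        summary[lab] = {
            "mean": float(prop.mean()),
            "lo95": float(np.quantile(prop, 0.025)),
            "hi95": float(np.quantile(prop, 0.975)),
        }
    return VarianceDecomposition(summary=summary, proportions=proportions, n_dropped=n_dropped)


def waic(loglik: np.ndarray) -> float:
    """WAIC = -2 (lppd - p_waic) from a draws x observations log-likelihood matrix."""
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2) x n log-likelihood matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("log-likelihood contains non-finite entries")
    S = ll.shape[0]
    lppd = np.sum(logsumexp(ll, axis=0) - np.log(S))
    p_waic = np.sum(ll.var(axis=0, ddof=1))
    return float(-2.0 * (lppd - p_waic))


def mae(samples: PosteriorSamples, observed: np.ndarray) -> float:
    """Mean absolute error of the posterior-mean fitted values."""
    y = np.asarray(observed, dtype=float)
    yhat = samples.mu.mean(axis=0)
    if y.shape != yhat.shape:
        raise ValueError("observed counts do not match the fitted dimension")
    return float(np.mean(np.abs(y - yhat)))
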