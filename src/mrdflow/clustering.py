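"""Model-based functional clustering of sparse MRD trajectories.

The model treats each patient's log10 MRD series as noisy observations of a
latent smooth curve drawn from a Gaussian mixture over spline coefficients:

    y_i = S_i (lambda0 + Lambda alpha_{z_i} + gamma_i) + eps_i

where S_i is the natural-spline design matrix at patient i's observation
times, z_i the latent cluster label with priors pi_k, gamma_i ~ N(0, Gamma)
a subject-level random effect in coefficient space, and eps_i ~ N(0,
sigma2 I) measurement noise.  Marginally, within cluster k,

    y_i ~ N(S_i eta_k,  S_i Gamma S_i' + sigma2 I),    eta_k = lambda0 + Lambda alpha_k.

Estimation is by EM with cluster memberships as missing data; the mean
structure is re-estimated by cluster-weighted generalized least squares each
M step and the variance components by their conditional EM updates, so the
observed-data log-likelihood is non-decreasing.  The low-rank mean-space
parametrization (Lambda p x h, alpha_k in R^h, h <= G-1) is recovered after
each M step by a prior-weighted SVD of the centered cluster means; alpha is
centered (sum_k pi_k alpha_k = 0) and Lambda kept column-orthonormal for
identifiability.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .basis import NaturalCubicBasis, build_basis
from .data import Cohort, MrdTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "FcmModel",
    "FitResult",
    "fit_fcm",
    "posterior_membership",
    "predict_curve",
    "select_model",
    "fdb_index",
    "discriminant_functions",
    "save_model",
    "load_model",
]

_LOG2PI = float(np.log(2.0 * np.pi))
MODEL_FORMAT_VERSION = 1


@dataclass
class FcmModel:
    """Fitted functional clustering model parameters."""

    basis: NaturalCubicBasis
    G: int
    h: int
    lambda0: np.ndarray          # (p,) grand-mean spline coefficients
    Lambda: np.ndarray           # (p, h) orthonormal mean-space directions
    alpha: np.ndarray            # (G, h) cluster scores, prior-weighted mean zero
    Gamma: np.ndarray            # (p, p) PSD random-effect covariance
    sigma2: float                # measurement noise variance
    priors: np.ndarray           # (G,) mixture weights on the simplex

    @property
    def p(self) -> int:
        return self.basis.dimension

    @property
    def cluster_coefficients(self) -> np.ndarray:
        """(G, p) spline coefficients eta_k of the cluster mean curves."""
        return self.lambda0[None, :] + self.alpha @ self.Lambda.T

    def mean_curves(self, times) -> np.ndarray:
        """(G, n) cluster mean curves evaluated at the query times."""
        return self.cluster_coefficients @ self.basis.evaluate(times).T


@dataclass
class FitResult:
    """Outcome of one EM fit: model, memberships, and diagnostics."""

    model: FcmModel
    memberships: np.ndarray      # (n, G) posterior membership probabilities
    assignments: np.ndarray      # (n,) argmax labels (lowest index on ties)
    patient_ids: list[str]
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


# ---------------------------------------------------------------------------
# numerics

def _chol_with_jitter(M: np.ndarray, label: str = "covariance"):
    """Cholesky factor of M, ridge-stabilizing if numerically singular."""
    jitter = 0.0
    for attempt in range(6):
        try:
            return cho_factor(M + jitter * np.eye(M.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = 10.0 ** (attempt - 8) * max(1.0, np.trace(M) / M.shape[0])
            logger.info("singular %s: retrying with jitter %.1e", label, jitter)
    raise np.linalg.LinAlgError(f"{label} not positive definite even with jitter")


def _psd_clip(M: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.clip(w, 0.0, None)) @ V.T


def _subject_designs(cohort: Cohort, basis: NaturalCubicBasis):
    S = [basis.evaluate(t.times) for t in cohort.trajectories]
    y = [np.asarray(t.values, dtype=float) for t in cohort.trajectories]
    return S, y


class _Pattern:
    """Subjects sharing one observation-time pattern, batched.

    Sparse protocol sampling means many subjects attend the same subset of
    scheduled visits; they share the design matrix S and hence the marginal
    covariance, so each EM pass needs one Cholesky per pattern, not per
    subject."""

    __slots__ = ("S", "Y", "idx", "n_obs", "m")

    def __init__(self, S: np.ndarray, Y: np.ndarray, idx: np.ndarray):
        self.S = S
        self.Y = Y                      # (m subjects, n_obs)
        self.idx = idx
        self.n_obs = S.shape[0]
        self.m = Y.shape[0]


def _make_patterns(S_list, y_list) -> list[_Pattern]:
    groups: dict[tuple, list[int]] = {}
    for i, y in enumerate(y_list):
        key = tuple(np.round(S_list[i][:, 1], 9))  # column 1 of the basis is t
        groups.setdefault(key, []).append(i)
    return [
        _Pattern(S_list[idx[0]], np.stack([y_list[i] for i in idx]), np.asarray(idx))
        for idx in groups.values()
    ]


def _log_marginal_per_cluster(
    S: np.ndarray, y: np.ndarray, eta: np.ndarray, Gamma: np.ndarray, sigma2: float
) -> np.ndarray:
    """log N(y; S eta_k, S Gamma S' + sigma2 I) for every cluster k."""
    n = y.size
    Sigma = S @ Gamma @ S.T + sigma2 * np.eye(n)
    c = _chol_with_jitter(Sigma, "marginal covariance")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    R = y[None, :] - eta @ S.T                      # (G, n) residuals
    sol = cho_solve(c, R.T)                         # (n, G)
    quad = np.einsum("ng,ng->g", sol, R.T)
    return -0.5 * (n * _LOG2PI + logdet + quad)


def _pattern_chols(patterns, Gamma, sigma2):
    return [
        _chol_with_jitter(
            pat.S @ Gamma @ pat.S.T + sigma2 * np.eye(pat.n_obs), "marginal covariance"
        )
        for pat in patterns
    ]


def _estep(patterns, n, eta, Gamma, sigma2, log_priors):
    G = eta.shape[0]
    logw = np.empty((n, G))
    chols = _pattern_chols(patterns, Gamma, sigma2)
    for pat, c in zip(patterns, chols):
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        mu = eta @ pat.S.T                            # (G, n_obs)
        for k in range(G):
            R = pat.Y - mu[k][None, :]                # (m, n_obs)
            X = cho_solve(c, R.T)                     # (n_obs, m)
            quad = np.einsum("nm,nm->m", X, R.T)
            logw[pat.idx, k] = log_priors[k] - 0.5 * (
                pat.n_obs * _LOG2PI + logdet + quad
            )
    norm = logsumexp(logw, axis=1)
    return np.exp(logw - norm[:, None]), float(norm.sum())


def _mstep_means(patterns, W, Gamma, sigma2, p, chols):
    """Cluster-weighted GLS update of the mean coefficients eta_k."""
    G = W.shape[1]
    A = np.zeros((G, p, p))
    b = np.zeros((G, p))
    for pat, c in zip(patterns, chols):
        SiS = pat.S.T @ cho_solve(c, pat.S)           # (p, p)
        SiY = pat.S.T @ cho_solve(c, pat.Y.T)         # (p, m)
        Wg = W[pat.idx]                               # (m, G)
        A += Wg.sum(axis=0)[:, None, None] * SiS[None]
        b += (SiY @ Wg).T
    eta = np.empty((G, p))
    for k in range(G):
        eta[k] = np.linalg.solve(A[k] + 1e-10 * np.eye(p), b[k])
    return eta


def _mstep_variances(patterns, n, W, eta, Gamma, sigma2, p, chols):
    """EM updates of Gamma and sigma2 given cluster means and memberships."""
    G = eta.shape[0]
    G_sum = np.zeros((p, p))
    sse = 0.0
    n_obs = 0
    for pat, c in zip(patterns, chols):
        n_obs += pat.m * pat.n_obs
        GS = Gamma @ pat.S.T                          # (p, n_obs)
        C = Gamma - GS @ cho_solve(c, GS.T)           # conditional cov of gamma_i
        trSCS = float(np.einsum("ij,ji->", pat.S @ C, pat.S.T))
        # memberships of one subject sum to 1, so the shared conditional
        # covariance terms contribute once per subject
        G_sum += pat.m * C
        sse += pat.m * trSCS
        mu = eta @ pat.S.T
        for k in range(G):
            w = W[pat.idx, k]                         # (m,)
            R = pat.Y - mu[k][None, :]                # (m, n_obs)
            M = GS @ cho_solve(c, R.T)                # (p, m) conditional means
            G_sum += (M * w[None, :]) @ M.T
            res = R.T - pat.S @ M                     # (n_obs, m)
            sse += float(np.einsum("nm,nm,m->", res, res, w))
    Gamma_new = _psd_clip(G_sum / n)
    sigma2_new = max(sse / n_obs, 1e-8)
    return Gamma_new, sigma2_new


def _decompose_means(eta: np.ndarray, priors: np.ndarray, h: int):
    """Split cluster means into (lambda0, Lambda, alpha) with the
    identifiability constraints: prior-weighted alpha mean is zero and
    Lambda has orthonormal columns."""
    lambda0 = priors @ eta
    B = eta - lambda0[None, :]
    M = np.sqrt(priors)[:, None] * B
    U, D, Vt = np.linalg.svd(M, full_matrices=False)
    keep = min(h, Vt.shape[0])
    Lambda = Vt[:keep].T                              # (p, h) orthonormal
    alpha = B @ Lambda                                # (G, h)
    if keep < h:
        Lambda = np.pad(Lambda, ((0, 0), (0, h - keep)))
        alpha = np.pad(alpha, ((0, 0), (0, h - keep)))
    return lambda0, Lambda, alpha


# ---------------------------------------------------------------------------
# fitting

def _ridge_curve_init(S_list, y_list, basis):
    """Per-subject ridge spline fits: coefficients, fitted values on a small
    grid (the k-means feature space) and a residual-based sigma2 guess."""
    n = len(S_list)
    p = basis.dimension
    B0 = np.empty((n, p))
    resid2, n_obs = 0.0, 0
    for i, (S, y) in enumerate(zip(S_list, y_list)):
        coef = np.linalg.solve(S.T @ S + 0.1 * np.eye(p), S.T @ y)
        B0[i] = coef
        resid2 += float(np.sum((y - S @ coef) ** 2))
        n_obs += y.size
    # k-means features: raw observations interpolated onto a common grid
    # (flat extension outside each subject's range); smoothed spline curves
    # extrapolate too wildly for 3-point subjects to cluster on
    grid = np.linspace(basis.knots[0], basis.knots[-1], max(p, 8))
    F0 = np.stack(
        [np.interp(grid, S[:, 1], y) for S, y in zip(S_list, y_list)]
    )
    sigma2 = max(resid2 / max(n_obs, 1), 1e-4)
    return B0, F0, sigma2


def _init_state(F0, B0, sigma2_0, G, rng):
    n, p = B0.shape
    if G > 1:
        km = KMeans(n_clusters=G, n_init=4, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(F0)
    else:
        labels = np.zeros(n, dtype=int)
    W = np.zeros((n, G))
    W[np.arange(n), labels] = 1.0
    # within-cluster coefficient spread: a total-covariance start would let
    # the random effect absorb the cluster structure before EM can see it
    R = B0 - np.stack([B0[labels == k].mean(axis=0) for k in range(G)])[labels]
    Gamma = _psd_clip(R.T @ R / max(n - G, 1)) * 0.5 + 1e-4 * np.eye(p)
    return W, Gamma, sigma2_0


def _run_em(patterns, n, G, h, basis, state, tol, max_iter, exact_rank):
    """EM iterations from a (W, Gamma, sigma2) state; resumable."""
    p = basis.dimension
    W, Gamma, sigma2 = state
    eta = np.zeros((G, p))
    trace = []
    converged = False
    for _ in range(max_iter):
        priors = np.clip(W.mean(axis=0), 1e-12, None)
        priors /= priors.sum()
        chols = _pattern_chols(patterns, Gamma, sigma2)
        eta = _mstep_means(patterns, W, Gamma, sigma2, p, chols)
        if not exact_rank:
            # enforce the rank-h mean space before the variance update
            lambda0, Lambda, alpha = _decompose_means(eta, priors, h)
            eta = lambda0[None, :] + alpha @ Lambda.T
        Gamma, sigma2 = _mstep_variances(
            patterns, n, W, eta, Gamma, sigma2, p, chols
        )
        W, ll = _estep(patterns, n, eta, Gamma, sigma2, np.log(priors))
        trace.append(ll)
        if len(trace) > 1:
            rel = (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0)
            if abs(rel) < tol:
                converged = True
                break

    # keep the priors used in the final E-step so scoring a training
    # trajectory against the stored model reproduces its membership exactly
    lambda0, Lambda, alpha = _decompose_means(eta, priors, h)
    model = FcmModel(
        basis=basis, G=G, h=h, lambda0=lambda0, Lambda=Lambda, alpha=alpha,
        Gamma=Gamma, sigma2=float(sigma2), priors=priors,
    )
    degenerate = bool(np.any(priors < 1.0 / (10.0 * n))) if G > 1 else False
    return model, W, np.asarray(trace), converged, degenerate


def fit_fcm(
    cohort: Cohort,
    G: int,
    p: int = 5,
    h: Optional[int] = None,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Fit the G-cluster functional model by EM, best of ``n_starts``.

    Parameters
    ----------
    cohort : filtered cohort; every trajectory needs at least 2 points.
    G : number of clusters.
    p : spline basis dimension (knots at quantiles of pooled times).
    h : mean-space dimension, default min(G-1, p) (1 when G=1).
    n_starts : independent k-means initializations; the fit with the best
        final log-likelihood wins.  All randomness flows from ``seed``.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if any(len(t) < 2 for t in cohort.trajectories):
        raise ValueError("every trajectory must have at least 2 points; filter first")
    h_max = max(G - 1, 1)
    if h is None:
        h = min(h_max, p)
    if not (1 <= h <= h_max):
        raise ValueError(f"need 1 <= h <= {h_max}, got {h}")
    all_times = np.concatenate([t.times for t in cohort.trajectories])
    basis = build_basis(all_times, p)
    S_list, y_list = _subject_designs(cohort, basis)
    patterns = _make_patterns(S_list, y_list)
    n = len(S_list)
    # with h = G-1 the rank-h constraint is vacuous (centered means always
    # have rank <= G-1), so the EM stays exactly monotone
    exact_rank = h >= G - 1
    B0, F0, sigma2_0 = _ridge_curve_init(S_list, y_list, basis)

    # short burn-in from every start, then refine the best to convergence
    master = np.random.default_rng(seed)
    burn_iter = min(40, max_iter)
    best = None
    for start in range(max(n_starts, 1)):
        rng = np.random.default_rng(master.integers(2**31))
        state = _init_state(F0, B0, sigma2_0, G, rng)
        out = _run_em(patterns, n, G, h, basis, state, tol, burn_iter, exact_rank)
        if out[4]:  # degenerate cluster: one fresh restart of this start
            logger.warning("start %d produced a degenerate cluster; restarting", start)
            state = _init_state(F0, B0, sigma2_0, G, rng)
            out = _run_em(patterns, n, G, h, basis, state, tol, burn_iter, exact_rank)
        model_b, W_b, trace_b, conv_b, _ = out
        if best is None or trace_b[-1] > best[2][-1]:
            best = (model_b, W_b, trace_b, conv_b)

    model, W, trace, converged = best
    if not converged:
        state = (W, model.Gamma, model.sigma2)
        model, W, trace2, converged, degenerate = _run_em(
            patterns, n, G, h, basis, state, tol, max_iter - len(trace), exact_rank
        )
        trace = np.concatenate([trace, trace2])
        if degenerate:
            logger.warning("refined fit has a degenerate cluster (prior < 1/(10n))")
    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)
    assignments = np.argmax(W, axis=1)  # argmax: lowest index wins on ties
    return FitResult(
        model=model,
        memberships=W,
        assignments=assignments,
        patient_ids=cohort.patient_ids(),
        loglik_trace=trace,
        converged=converged,
        n_iter=len(trace),
    )


# ---------------------------------------------------------------------------
# posterior quantities

def posterior_membership(model: FcmModel, trajectory: MrdTrajectory) -> np.ndarray:
    """Posterior cluster membership probabilities for one trajectory."""
    S = model.basis.evaluate(trajectory.times)
    y = np.asarray(trajectory.values, dtype=float)
    logw = np.log(np.clip(model.priors, 1e-300, None)) + _log_marginal_per_cluster(
        S, y, model.cluster_coefficients, model.Gamma, model.sigma2
    )
    w = np.exp(logw - logsumexp(logw))
    return w / w.sum()


def predict_curve(
    model: FcmModel,
    trajectory: MrdTrajectory,
    query_times,
    memberships: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Membership-weighted BLUP reconstruction of the latent MRD curve.

    For each cluster the conditional mean of the subject's spline
    coefficients given the observed series is evaluated at the query times;
    the reconstruction averages those curves with the posterior memberships.
    """
    q = np.atleast_1d(np.asarray(query_times, dtype=float))
    if q.size == 0:
        return np.empty(0)
    if memberships is None:
        memberships = posterior_membership(model, trajectory)
    S = model.basis.evaluate(trajectory.times)
    y = np.asarray(trajectory.values, dtype=float)
    Sq = model.basis.evaluate(q)
    eta = model.cluster_coefficients
    c = _chol_with_jitter(S @ model.Gamma @ S.T + model.sigma2 * np.eye(y.size))
    GS = model.Gamma @ S.T
    out = np.zeros(q.size)
    for k in range(model.G):
        r = y - S @ eta[k]
        coef_k = eta[k] + GS @ cho_solve(c, r)
        out += memberships[k] * (Sq @ coef_k)
    return out


def discriminant_functions(model: FcmModel, time_grid) -> np.ndarray:
    """Functional discriminant curves on a time grid, one per mean-space
    dimension (min(h, G-1) curves).

    Each column of the returned (n_grid, h) array is the covariance-whitened
    projection Sigma_T^{-1} S_T Lambda_j; large magnitudes mark the time
    intervals that carry the most information for cluster assignment.
    Returns an empty array when G = 1.
    """
    if model.G == 1:
        return np.empty((np.atleast_1d(time_grid).size, 0))
    grid = np.atleast_1d(np.asarray(time_grid, dtype=float))
    S = model.basis.evaluate(grid)
    Sigma = S @ model.Gamma @ S.T + model.sigma2 * np.eye(grid.size)
    c = _chol_with_jitter(Sigma, "grid covariance")
    n_disc = min(model.h, model.G - 1)
    return cho_solve(c, S @ model.Lambda[:, :n_disc])


# ---------------------------------------------------------------------------
# model selection

def fdb_index(fit: FitResult, cohort: Cohort, n_grid: int = 200) -> float:
    """Functional Davies-Bouldin index of a fit.

    Within-cluster dispersion S_k is the mean L2 distance of the fitted
    (reconstructed) curves of cluster-k subjects to the cluster-k mean
    curve; separation M_kj is the L2 distance between mean curves; both on a
    fixed dense grid over the observed time range, so the index is
    deterministic given a fit.  Lower is better; identical mean curves give
    +inf.
    """
    model = fit.model
    if model.G < 2:
        raise ValueError("fDB requires at least 2 clusters")
    t_max = max(float(t.times.max()) for t in cohort.trajectories)
    grid = np.linspace(0.0, t_max, n_grid)
    means = model.mean_curves(grid)                       # (G, n_grid)

    def l2(f, g):
        return float(np.sqrt(np.trapezoid((f - g) ** 2, grid)))

    S_k = np.zeros(model.G)
    counts = np.zeros(model.G, dtype=int)
    for i, traj in enumerate(cohort.trajectories):
        k = fit.assignments[i]
        curve = predict_curve(model, traj, grid, memberships=fit.memberships[i])
        S_k[k] += l2(curve, means[k])
        counts[k] += 1
    with np.errstate(invalid="ignore"):
        S_k = np.where(counts > 0, S_k / np.maximum(counts, 1), 0.0)

    ratio_max = np.zeros(model.G)
    for k in range(model.G):
        for j in range(model.G):
            if j == k:
                continue
            M = l2(means[k], means[j])
            if M == 0.0:
                warnings.warn("identical cluster mean curves: fDB is infinite")
                return float("inf")
            ratio_max[k] = max(ratio_max[k], (S_k[k] + S_k[j]) / M)
    return float(ratio_max.mean())


def _cv_loglik_p(cohort: Cohort, p: int, n_folds: int, seed: int) -> float:
    """Leave-subjects-out cross-validated log-likelihood of the G=1 model."""
    n = len(cohort.trajectories)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, min(n_folds, n))
    total = 0.0
    for fold in folds:
        test = set(int(i) for i in fold)
        train = cohort.subset(
            t for i, t in enumerate(cohort.trajectories) if i not in test
        )
        fit = fit_fcm(train, G=1, p=p, n_starts=1, seed=seed, max_iter=200)
        m = fit.model
        eta = m.cluster_coefficients
        for i in test:
            traj = cohort.trajectories[i]
            S = m.basis.evaluate(traj.times)
            y = np.asarray(traj.values, dtype=float)
            total += float(
                _log_marginal_per_cluster(S, y, eta, m.Gamma, m.sigma2)[0]
            )
    return total


def select_model(
    cohort: Cohort,
    p_grid: Sequence[int],
    G_grid: Sequence[int],
    h_rule: Optional[int] = None,
    seed: int = 0,
    n_folds: int = 5,
    n_starts: int = 5,
) -> tuple[int, int, int, dict]:
    """Select the basis dimension, cluster count and mean-space dimension.

    p* maximizes the cross-validated log-likelihood of the single-cluster
    mixed model (leave-subjects-out folds); G* minimizes the fDB index over
    repeated fits among G >= 2; h* = min(h_rule, G*-1).  The fDB index is
    undefined for a single cluster, so when 1 is in the grid the G* fit is
    additionally compared against the G=1 fit by BIC and a single cluster
    is declared when the mixture does not pay for its extra parameters.
    Ties break to the smallest p, then the smallest G.
    """
    p_grid = sorted(set(int(p) for p in p_grid))
    G_grid = sorted(set(int(G) for G in G_grid))
    if not p_grid or not G_grid:
        raise ValueError("p_grid and G_grid must be nonempty")

    cv = {p: _cv_loglik_p(cohort, p, n_folds, seed) for p in p_grid}
    p_star = max(p_grid, key=lambda p: (cv[p], -p))

    def _bic(fit: FitResult) -> float:
        mdl = fit.model
        p_, G_, h_ = mdl.p, mdl.G, (mdl.h if mdl.G > 1 else 0)
        k = p_ + p_ * h_ + G_ * h_ + p_ * (p_ + 1) // 2 + 1 + (G_ - 1)
        return -2.0 * fit.loglik + k * np.log(len(cohort.trajectories))

    fdb = {}
    fits = {}
    for G in G_grid:
        if G < 2:
            continue
        fit = fit_fcm(cohort, G=G, p=p_star, n_starts=n_starts, seed=seed)
        fits[G] = fit
        fdb[G] = fdb_index(fit, cohort)
    if fdb:
        G_star = min((G for G in fdb), key=lambda G: (fdb[G], G))
        if 1 in G_grid:
            fit1 = fit_fcm(cohort, G=1, p=p_star, n_starts=1, seed=seed)
            fits[1] = fit1
            if _bic(fit1) <= _bic(fits[G_star]):
                G_star = 1
    else:
        G_star = G_grid[0]

    h_max = max(G_star - 1, 1)
    h_star = min(h_rule, h_max) if h_rule is not None else h_max
    diagnostics = {"cv_loglik": cv, "fdb": fdb, "fits": fits}
    return p_star, G_star, h_star, diagnostics


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(model: FcmModel, meta: Optional[dict] = None) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "knots": model.basis.knots.tolist(),
        "G": model.G,
        "h": model.h,
        "lambda0": model.lambda0.tolist(),
        "Lambda": model.Lambda.tolist(),
        "alpha": model.alpha.tolist(),
        "Gamma": model.Gamma.tolist(),
        "sigma2": model.sigma2,
        "priors": model.priors.tolist(),
        "meta": meta or {},
    }


def model_from_dict(d: dict) -> FcmModel:
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {d.get('format_version')}")
    return FcmModel(
        basis=NaturalCubicBasis(np.asarray(d["knots"], dtype=float)),
        G=int(d["G"]),
        h=int(d["h"]),
        lambda0=np.asarray(d["lambda0"], dtype=float),
        Lambda=np.asarray(d["Lambda"], dtype=float),
        alpha=np.asarray(d["alpha"], dtype=float),
        Gamma=np.asarray(d["Gamma"], dtype=float),
        sigma2=float(d["sigma2"]),
        priors=np.asarray(d["priors"], dtype=float),
    )


def save_model(model: FcmModel, path, meta: Optional[dict] = None) -> None:
    """Serialize a fitted model to versioned JSON (exact float round-trip)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, meta), fh, indent=1)


def load_model(path) -> FcmModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
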