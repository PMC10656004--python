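"""Comparison resampling methods for correlated binary traits.

Six alternatives to the quasi-likelihood permutation scheme:

* ``Naive`` — fit the linear mixed model Y = X beta + e with
  e ~ MVN(0, sigma1^2 Phi + sigma2^2 I), permute the raw residuals and add
  back the fitted mean.  Ignores both the residual correlation and the
  binary mean-variance relationship.
* ``MVNpermute`` — the Gaussian analog of the decorrelating transform: the
  LMM residuals are whitened with a factorization of the fitted covariance,
  projected onto the complement of the working covariates, permuted there
  and back-transformed.
* ``LogMM-PQL`` — fit a logistic mixed model by penalized quasi-likelihood
  (iterated working linear mixed models) and sample binary replicates from
  the fitted model: u ~ MVN(0, sigma^2 Phi), Y_i ~ Bernoulli(expit(x_i beta + u_i)).
* the ``*_mod`` variants — any real-valued replicate set can be binarized by
  thresholding each replicate so the case count matches the observed trait
  exactly (:func:`binarize_replicates`).

The LMM is fitted by REML with a single eigendecomposition of Phi (profile
likelihood in the variance ratio); PQL alternates a working-response linear
mixed model with a REML update of the variance component, with the dispersion
fixed at 1 as is conventional for binary data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .model_core import (
    CLAMP_EPS,
    KinshipEigen,
    kinship_eigen,
    logistic_irls,
    validate_covariates,
    validate_phenotype,
)
from .transform import ReplicateSet

__all__ = [
    "LmmFit",
    "LogmmFit",
    "fit_lmm_null",
    "naive_replicates",
    "mvnpermute_replicates",
    "pql_fit",
    "logmm_sample_replicates",
    "binarize_replicates",
]


# ---------------------------------------------------------------------------
# linear mixed model (REML)

@dataclass
class LmmFit:
    """REML fit of Y = X beta + e, e ~ MVN(0, sigma1^2 Phi + sigma2^2 I)."""

    y: np.ndarray
    x: np.ndarray
    eig: KinshipEigen
    beta_hat: np.ndarray
    sigma1_sq: float   # relatedness component
    sigma2_sq: float   # identity component
    converged: bool

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.x @ self.beta_hat

    @property
    def cov_eigvals(self) -> np.ndarray:
        """Eigenvalues of sigma1^2 Phi + sigma2^2 I in the Phi eigenbasis."""
        return self.sigma1_sq * self.eig.lam + self.sigma2_sq


def fit_lmm_null(
    y: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray | None = None,
    *,
    eig: KinshipEigen | None = None,
) -> LmmFit:
    """REML variance components via profile likelihood in h = sigma1^2 / total.

    With Phi = I the model collapses to ordinary least squares with white
    noise; the split between the two components is then unidentifiable and
    the fit returns sigma1_sq = 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = validate_covariates(x, n=y.size)
    if eig is None:
        if phi is None:
            raise ValueError("provide either phi or its eigendecomposition")
        eig = kinship_eigen(phi)
    n, k = x.shape
    lam, q = eig.lam, eig.vectors
    yt = q.T @ y
    xt = q.T @ x

    def profile(h: float):
        kv = h * lam + (1.0 - h)
        w = 1.0 / kv
        m = xt.T @ (xt * w[:, None])
        beta = np.linalg.solve(m, xt.T @ (yt * w))
        r = yt - xt @ beta
        s2 = float((r * w) @ r) / (n - k)
        nll = (n - k) * np.log(max(s2, 1e-300)) + np.sum(np.log(kv)) \
            + np.linalg.slogdet(m)[1]
        return nll, beta, s2

    if eig.is_identity:
        h_opt, converged = 0.0, True
    else:
        res = optimize.minimize_scalar(
            lambda h: profile(h)[0], bounds=(0.0, 1.0 - 1e-8), method="bounded",
            options={"xatol": 1e-10},
        )
        h_opt = float(res.x)
        converged = bool(res.success)
        # the bounded search can stall just inside a boundary; compare endpoints
        for h_end in (0.0,):
            if profile(h_end)[0] < profile(h_opt)[0]:
                h_opt = h_end
    nll, beta, s2 = profile(h_opt)
    return LmmFit(
        y=y, x=x, eig=eig, beta_hat=beta,
        sigma1_sq=h_opt * s2, sigma2_sq=(1.0 - h_opt) * s2, converged=converged,
    )


# ---------------------------------------------------------------------------
# permutation-based comparators

def naive_replicates(
    lmm: LmmFit, n_reps: int, seed: int | None = None, *,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Permute the raw LMM residuals and add back the fitted mean."""
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    resid = lmm.residuals
    permuted = rng.permuted(np.broadcast_to(resid, (n_reps, resid.size)), axis=1)
    reps = (lmm.x @ lmm.beta_hat)[None, :] + permuted
    return ReplicateSet(replicates=reps, seed=seed, binary=False, method="naive")


def mvnpermute_replicates(
    lmm: LmmFit,
    x: np.ndarray | None = None,
    phi: np.ndarray | None = None,
    n_reps: int = 1,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Whiten LMM residuals, project out the covariates, permute, back-transform.

    The fitted covariance sigma1^2 Phi + sigma2^2 I is factorized as
    C_L^T C_L in the Phi eigenbasis; replicates are
    X beta + C_L^T V_L Pi V_L^T C_L^{-T} (Y - X beta).
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = lmm.x if x is None else np.asarray(x, dtype=float)
    n, k = x.shape
    d = lmm.cov_eigvals
    if d.min() <= 0.0:
        raise np.linalg.LinAlgError("fitted LMM covariance is singular")
    sd = np.sqrt(d)
    q = lmm.eig.vectors

    w = (q.T @ x) / sd[:, None]              # C_L^{-T} X
    qr_q, qr_r = np.linalg.qr(w, mode="complete")
    diag_r = np.abs(np.diag(qr_r[:k, :k]))
    if diag_r.min() < 1e-12 * max(1.0, diag_r.max()):
        raise np.linalg.LinAlgError("whitened covariates are rank deficient")
    v = qr_q[:, k:]
    zeta = v.T @ ((q.T @ lmm.residuals) / sd)
    c_t_v = q @ (sd[:, None] * v)            # C_L^T V_L
    permuted = rng.permuted(np.broadcast_to(zeta, (n_reps, zeta.size)), axis=1)
    reps = (x @ lmm.beta_hat)[None, :] + permuted @ c_t_v.T
    return ReplicateSet(replicates=reps, seed=seed, binary=False, method="mvnpermute")


# ---------------------------------------------------------------------------
# logistic mixed model via PQL

@dataclass
class LogmmFit:
    """PQL fit of the logistic mixed model logit(m) = X beta + u, u ~ MVN(0, sigma^2 Phi)."""

    y: np.ndarray
    x: np.ndarray
    eig: KinshipEigen
    beta_hat: np.ndarray
    sigma_sq: float
    u_hat: np.ndarray
    m_hat: np.ndarray
    working_converged: bool


def pql_fit(
    y: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray | None = None,
    *,
    eig: KinshipEigen | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
    sigma_max: float = 50.0,
    eps: float = CLAMP_EPS,
) -> LogmmFit:
    """Penalized quasi-likelihood: iterate working-response LMMs to convergence.

    Outer loop: form the working response z = eta + Gamma(m)^{-1} (y - m) with
    weights Gamma(m) = diag(m_i (1 - m_i)); inner step: REML-optimize sigma^2
    for z ~ N(X beta, sigma^2 Phi + Gamma^{-1}) and solve the mixed-model
    equations for (beta, u).  The variance component is floored at 0.

    PQL is fast but known to bias sigma^2 downward for binary traits; that
    bias is a property of the approximation, not of this implementation, and
    is checked behaviorally in the test suite.
    """
    y = validate_phenotype(y, binary=True)
    x = validate_covariates(x, n=y.size)
    if eig is None:
        if phi is None:
            raise ValueError("provide either phi or its eigendecomposition")
        eig = kinship_eigen(phi)
    n = y.size
    lam, q = eig.lam, eig.vectors
    phi_mat = (q * lam) @ q.T

    beta = logistic_irls(y, x, eps=eps)
    u = np.zeros(n)
    sigma2 = 0.5
    eta = x @ beta
    converged = False

    for _ in range(max_iter):
        m = np.clip(expit(eta), eps, 1.0 - eps)
        gam = m * (1.0 - m)
        z = eta + (y - m) / gam
        inv_gam = 1.0 / gam

        def reml_nll(s2: float) -> float:
            sw = s2 * phi_mat + np.diag(inv_gam)
            cf = cho_factor(sw, lower=True)
            si_x = cho_solve(cf, x)
            mmat = x.T @ si_x
            bet = np.linalg.solve(mmat, si_x.T @ z)
            r = z - x @ bet
            sir = cho_solve(cf, r)
            logdet_sw = 2.0 * np.sum(np.log(np.diag(cf[0])))
            return logdet_sw + np.linalg.slogdet(mmat)[1] + float(r @ sir)

        res = optimize.minimize_scalar(
            reml_nll, bounds=(0.0, sigma_max), method="bounded",
            options={"xatol": 1e-6},
        )
        sigma2_new = float(res.x)
        if reml_nll(0.0) <= res.fun:
            sigma2_new = 0.0
        if sigma2_new < 1e-8:
            sigma2_new = 0.0

        sw = sigma2_new * phi_mat + np.diag(inv_gam)
        cf = cho_factor(sw, lower=True)
        si_x = cho_solve(cf, x)
        mmat = x.T @ si_x
        beta_new = np.linalg.solve(mmat, si_x.T @ z)
        r = z - x @ beta_new
        u = sigma2_new * (phi_mat @ cho_solve(cf, r))
        eta = x @ beta_new + u

        dbeta = float(np.max(np.abs(beta_new - beta)))
        dsig = abs(sigma2_new - sigma2) / (1.0 + sigma2)
        beta, sigma2 = beta_new, sigma2_new
        if dbeta < tol and dsig < tol:
            converged = True
            break

    if not converged:
        warnings.warn("PQL did not converge; returning last iterate", RuntimeWarning)
    m = np.clip(expit(eta), eps, 1.0 - eps)
    return LogmmFit(
        y=y, x=x, eig=eig, beta_hat=beta, sigma_sq=sigma2, u_hat=u, m_hat=m,
        working_converged=converged,
    )


def logmm_sample_replicates(
    fit: LogmmFit,
    x: np.ndarray | None = None,
    phi: np.ndarray | None = None,
    n_reps: int = 1,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Binary replicates drawn from the fitted logistic mixed model.

    Per replicate: u ~ MVN(0, sigma_hat^2 Phi) via the cached eigenbasis,
    then Y_i ~ Bernoulli(expit(x_i beta_hat + u_i)) independently given u.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = fit.x if x is None else np.asarray(x, dtype=float)
    n = x.shape[0]
    lam, q = fit.eig.lam, fit.eig.vectors
    sd = np.sqrt(fit.sigma_sq * np.maximum(lam, 0.0))
    eta_fixed = x @ fit.beta_hat
    u = q @ (sd[:, None] * rng.standard_normal((n, n_reps)))
    p = expit(eta_fixed[:, None] + u)
    reps = (rng.random((n, n_reps)) < p).T.astype(float)
    return ReplicateSet(replicates=reps, seed=seed, binary=True, method="logmm-pql")


# ---------------------------------------------------------------------------
# binarization ("_mod" variants)

def binarize_replicates(reps: ReplicateSet, y: np.ndarray) -> ReplicateSet:
    """Threshold each real-valued replicate to match the observed case count.

    The ceil(#cases) largest entries of each replicate become 1, the rest 0.
    Ties at the threshold are broken by stable sample-index order (the
    lower-index sample becomes a case).
    """
    if reps.binary:
        raise ValueError("replicates are already binary")
    y = validate_phenotype(y)
    r = reps.replicates
    if r.shape[1] != y.size:
        raise ValueError("replicate width does not match phenotype length")
    n_case = int(np.ceil(y.sum()))
    order = np.argsort(-r, axis=1, kind="stable")
    out = np.zeros_like(r)
    np.put_along_axis(out, order[:, :n_case], 1.0, axis=1)
    return ReplicateSet(
        replicates=out, seed=reps.seed, binary=True, method=reps.method + "-mod",
        metadata=dict(reps.metadata),
    )
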