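"""Quasi-likelihood null model for a correlated binary trait.

The trait is modeled through its first two conditional moments only::

    E(Y | X)   = mu    = expit(X beta)
    Var(Y | X) = Omega = Gamma^{1/2} Sigma Gamma^{1/2}

where ``Gamma = diag(mu_i (1 - mu_i))`` carries the binomial mean-variance
relationship and ``Sigma = xi * Phi + (1 - xi) * I`` mixes a genetic
relatedness matrix ``Phi`` with the identity.  The scalar ``xi`` in [0, 1]
plays the role of a heritability parameter: at ``xi = 0`` subjects are
uncorrelated given covariates; at ``xi = 1`` the trait correlation tracks
relatedness fully.

Fitting is by estimating equations under the null of no genetic effect:
the quasi-score for ``beta`` must vanish,

    X^T Gamma Omega^{-1} (Y - mu) = 0,

and ``xi`` solves the method-of-moments equation

    (Y-mu)^T Gamma^{-1/2} Sigma^{-1} (Phi - I) Sigma^{-1} Gamma^{-1/2} (Y-mu)
        = trace(Sigma^{-1} (Phi - I)).

The solver alternates a one-dimensional root-find for ``xi`` with Fisher
scoring for ``beta``, both expressed in the eigenbasis of ``Phi`` so each
``xi`` evaluation is O(n) and each ``beta`` step is O(n^2 k).

A vectorized variant (:func:`fit_null_model_batch`) refits the same model on
many trait vectors at once (e.g. thousands of permutation replicates sharing
one covariate matrix and relatedness matrix); it is algebraically the same
solver with the root-find done by bisection across the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit

__all__ = [
    "CLAMP_EPS",
    "KinshipEigen",
    "NullModelFit",
    "BatchNullModelFit",
    "inverse_logit_mean",
    "build_sigma",
    "build_omega",
    "validate_phenotype",
    "validate_covariates",
    "validate_kinship",
    "kinship_eigen",
    "fit_null_model",
    "fit_null_model_batch",
]

#: default clamp keeping fitted means strictly inside (0, 1) so Gamma stays invertible
CLAMP_EPS = 1e-10


# ---------------------------------------------------------------------------
# input validation

def validate_phenotype(y: np.ndarray, *, binary: bool = True) -> np.ndarray:
    """Check a phenotype vector (0/1 with both classes present) and return it as float."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("phenotype vector needs at least two subjects")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains missing/non-finite values")
    if binary:
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("phenotype entries must be 0 or 1")
        if y.sum() == 0 or y.sum() == y.size:
            raise ValueError("need at least one case and one control")
    return y


def validate_covariates(x: np.ndarray, n: int | None = None) -> np.ndarray:
    """Check a covariate matrix: finite, full column rank, fewer columns than rows."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and n is not None and n > 1:
        x = x.T
    if n is not None and x.shape[0] != n:
        raise ValueError(f"covariate matrix has {x.shape[0]} rows, expected {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate matrix contains missing/non-finite values")
    if x.shape[1] >= x.shape[0]:
        raise ValueError("need fewer covariates than subjects (k < n)")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear columns)")
    return x


def validate_kinship(phi: np.ndarray, *, sym_tol: float = 1e-10,
                     psd_tol: float = -1e-8) -> np.ndarray:
    """Check symmetry and (numerical) positive semi-definiteness of a kinship/GRM matrix."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
        raise ValueError("kinship matrix must be square")
    if np.max(np.abs(phi - phi.T)) > sym_tol:
        raise ValueError("kinship matrix is not symmetric")
    w = np.linalg.eigvalsh(phi)
    if w.min() < psd_tol:
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {w.min():.3e})")
    return phi


@dataclass(frozen=True)
class KinshipEigen:
    """Cached symmetric eigendecomposition Phi = Q diag(lam) Q^T."""

    lam: np.ndarray
    vectors: np.ndarray

    @property
    def n(self) -> int:
        return self.lam.size

    @property
    def is_identity(self) -> bool:
        return bool(np.max(np.abs(self.lam - 1.0)) < 1e-12)

    def sigma_eigvals(self, xi) -> np.ndarray:
        """Eigenvalues of Sigma(xi) = xi Phi + (1-xi) I (same eigenvectors as Phi)."""
        return np.asarray(xi) * self.lam + (1.0 - np.asarray(xi))


def kinship_eigen(phi: np.ndarray, *, validate: bool = True) -> KinshipEigen:
    """Eigendecompose a kinship matrix once; all Sigma(xi) factorizations derive from it."""
    if validate:
        phi = validate_kinship(phi)
    lam, q = np.linalg.eigh(phi)
    return KinshipEigen(lam=np.maximum(lam, 0.0), vectors=q)


# ---------------------------------------------------------------------------
# elementary model pieces

def inverse_logit_mean(x: np.ndarray, beta: np.ndarray, eps: float = CLAMP_EPS) -> np.ndarray:
    """Mean vector mu_i = expit(x_i beta), clamped to [eps, 1-eps]."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape[-1] != beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: covariates have {x.shape[-1]} columns, beta has {beta.shape[0]}"
        )
    return np.clip(expit(x @ beta), eps, 1.0 - eps)


def build_sigma(phi: np.ndarray, xi: float) -> np.ndarray:
    """Sigma = xi * Phi + (1 - xi) * I, the relatedness/identity mixture."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must lie in [0, 1], got {xi}")
    phi = np.asarray(phi, dtype=float)
    return xi * phi + (1.0 - xi) * np.eye(phi.shape[0])


def build_omega(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Omega = Gamma^{1/2} Sigma Gamma^{1/2} with Gamma = diag(mu (1 - mu)).

    Callers that only need the action of Omega^{-1} should use
    :meth:`NullModelFit.omega_inv_apply` instead of materializing this matrix.
    """
    mu = np.asarray(mu, dtype=float).ravel()
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        bad = int(np.argmin(np.minimum(mu, 1.0 - mu)))
        raise ValueError(f"mean touches {{0,1}} at index {bad} (mu={mu[bad]!r}); clamp first")
    s = np.sqrt(mu * (1.0 - mu))
    return s[:, None] * np.asarray(sigma, dtype=float) * s[None, :]


# ---------------------------------------------------------------------------
# plain logistic regression (initializer; also the xi = 0 special case)

def logistic_irls(y: np.ndarray, x: np.ndarray, *, eps: float = CLAMP_EPS,
                  max_iter: int = 60, tol: float = 1e-10) -> np.ndarray:
    """Iteratively reweighted least squares for logit(E Y) = X beta.

    Accepts real-valued ``y`` (quasi-binomial working response), which is
    needed when refitting the model on non-binary trait replicates.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    beta = np.zeros(x.shape[1])
    ybar = np.clip(y.mean(), 0.05, 0.95)
    # start from the intercept-only solution if an all-ones column exists
    ones = np.where(np.all(x == 1.0, axis=0))[0]
    if ones.size:
        beta[ones[0]] = np.log(ybar / (1.0 - ybar))
    for _ in range(max_iter):
        mu = np.clip(expit(x @ beta), eps, 1.0 - eps)
        gam = mu * (1.0 - mu)
        xg = x * gam[:, None]
        score = x.T @ (y - mu)
        info = x.T @ xg
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # crude step-halving guard against overshoot on extreme inputs
        nrm = np.max(np.abs(step))
        if nrm > 10.0:
            step *= 10.0 / nrm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# the variance-parameter estimating equation in the eigenbasis

def _xi_residual(xi, et2, lam):
    """Moment-equation residual f(xi); et2 = squared entries of Q^T Gamma^{-1/2}(y-mu)."""
    d = xi * lam + (1.0 - xi)
    return float(np.sum(et2 * (lam - 1.0) / d**2) - np.sum((lam - 1.0) / d))


def _solve_xi_scalar(et2: np.ndarray, lam: np.ndarray) -> tuple[float, bool]:
    """Root of the moment equation on [0, 1]; boundary with smaller |residual| if no sign change.

    Returns (xi, at_boundary).
    """
    hi = 1.0 if lam.min() > 1e-8 else 1.0 - 1e-8
    f0 = _xi_residual(0.0, et2, lam)
    f1 = _xi_residual(hi, et2, lam)
    if f0 == 0.0:
        return 0.0, True
    if np.sign(f0) != np.sign(f1):
        xi = optimize.brentq(_xi_residual, 0.0, hi, args=(et2, lam), xtol=1e-12)
        return float(xi), False
    return (0.0, True) if abs(f0) <= abs(f1) else (min(hi, 1.0), True)


# ---------------------------------------------------------------------------
# fitted-model containers

@dataclass
class NullModelFit:
    """Fitted quasi-likelihood null model (single trait vector).

    Derived matrices are never stored densely: ``Sigma``, ``Omega`` and their
    inverses act through the cached eigendecomposition of ``Phi``.
    """

    y: np.ndarray
    x: np.ndarray
    eig: KinshipEigen
    beta_hat: np.ndarray
    xi_hat: float
    mu_hat: np.ndarray
    converged: bool
    n_iter: int
    score_inf_norm: float
    xi_at_boundary: bool
    eps: float = CLAMP_EPS

    @property
    def gamma_diag(self) -> np.ndarray:
        """Diagonal of Gamma: mu_i (1 - mu_i)."""
        return self.mu_hat * (1.0 - self.mu_hat)

    @property
    def sigma_eigvals(self) -> np.ndarray:
        """Eigenvalues of Sigma(xi_hat)."""
        return self.eig.sigma_eigvals(self.xi_hat)

    def sigma_matrix(self) -> np.ndarray:
        q = self.eig.vectors
        return (q * self.sigma_eigvals) @ q.T

    def omega_matrix(self) -> np.ndarray:
        return build_omega(self.mu_hat, self.sigma_matrix())

    def omega_inv_apply(self, v: np.ndarray) -> np.ndarray:
        """Omega^{-1} v via Gamma^{-1/2} Q D^{-1} Q^T Gamma^{-1/2} v (v may be n x m)."""
        v = np.asarray(v, dtype=float)
        sg = np.sqrt(self.gamma_diag)
        d = self.sigma_eigvals
        q = self.eig.vectors
        w = q.T @ (v / (sg[:, None] if v.ndim == 2 else sg))
        w = w / (d[:, None] if v.ndim == 2 else d)
        out = q @ w
        return out / (sg[:, None] if v.ndim == 2 else sg)

    def score(self) -> np.ndarray:
        """Quasi-score X^T Gamma Omega^{-1} (Y - mu_hat) at the fitted parameters."""
        r = self.omega_inv_apply(self.y - self.mu_hat)
        return self.x.T @ (self.gamma_diag * r)


@dataclass
class BatchNullModelFit:
    """Vectorized null-model fits for L trait vectors sharing (X, Phi)."""

    x: np.ndarray
    eig: KinshipEigen
    beta_hat: np.ndarray     # (k, L)
    xi_hat: np.ndarray       # (L,)
    mu_hat: np.ndarray       # (n, L)
    converged: np.ndarray    # (L,) bool
    n_iter: int

    def omega_inv_apply_each(self, v: np.ndarray) -> np.ndarray:
        """Apply each replicate's Omega^{-1} to the matching column of v (n x L)."""
        gam = self.mu_hat * (1.0 - self.mu_hat)
        sg = np.sqrt(gam)
        # (n, L) with entry (i, l) = xi_l * lam_i + (1 - xi_l)
        d = self.xi_hat[None, :] * self.eig.lam[:, None] + (1.0 - self.xi_hat[None, :])
        q = self.eig.vectors
        w = q.T @ (v / sg)
        out = q @ (w / d)
        return out / sg


# ---------------------------------------------------------------------------
# scalar fit

def _beta_inner(y, x, lam, q, xi, beta, eps, max_inner=40, tol=1e-11):
    """Fisher scoring for beta at fixed xi, in the Phi eigenbasis."""
    d = xi * lam + (1.0 - xi)
    mu = np.clip(expit(x @ beta), eps, 1.0 - eps)
    for _ in range(max_inner):
        gam = mu * (1.0 - mu)
        sg = np.sqrt(gam)
        a = q.T @ (x * sg[:, None])
        b = q.T @ ((y - mu) / sg)
        ad = a / d[:, None]
        score = ad.T @ b
        info = ad.T @ a
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        nrm = np.max(np.abs(step))
        if not np.isfinite(nrm):
            raise FloatingPointError("Fisher scoring diverged (non-finite step)")
        if nrm > 10.0:
            step *= 10.0 / nrm
        beta = beta + step
        mu = np.clip(expit(x @ beta), eps, 1.0 - eps)
        if np.max(np.abs(step)) < tol:
            break
    return beta, mu


def fit_null_model(
    y: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray | None = None,
    *,
    eig: KinshipEigen | None = None,
    tol: float = 1e-6,
    score_tol: float = 1e-9,
    max_iter: int = 100,
    eps: float = CLAMP_EPS,
    binary: bool = True,
) -> NullModelFit:
    """Jointly solve the estimating equations for (beta, xi) under no genetic effect.

    Parameters
    ----------
    y
        Trait vector; 0/1 unless ``binary=False`` (real-valued trait replicates).
    x
        n x k covariate matrix including an intercept column.
    phi, eig
        Relatedness matrix, or its precomputed :func:`kinship_eigen` (pass the
        latter when fitting repeatedly with the same Phi).
    tol, score_tol
        Convergence requires max(|dbeta|, |dxi|) < ``tol`` and the quasi-score
        inf-norm below ``score_tol``.

    Notes
    -----
    With ``Phi = I`` the variance equation degenerates (both sides vanish for
    every xi); by convention ``xi_hat = 0`` and the fit reduces to ordinary
    logistic regression.
    """
    y = validate_phenotype(y, binary=binary)
    x = validate_covariates(x, n=y.size)
    if eig is None:
        if phi is None:
            raise ValueError("provide either phi or its eigendecomposition")
        eig = kinship_eigen(phi)
    if eig.n != y.size:
        raise ValueError("kinship dimension does not match phenotype length")
    lam, q = eig.lam, eig.vectors

    beta = logistic_irls(y, x, eps=eps)
    xi = 0.0 if eig.is_identity else 0.5
    xi_boundary = eig.is_identity
    mu = np.clip(expit(x @ beta), eps, 1.0 - eps)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # (a) variance-parameter root-find at current mean
        if eig.is_identity:
            xi_new, xi_boundary = 0.0, True
        else:
            sg = np.sqrt(mu * (1.0 - mu))
            et = q.T @ ((y - mu) / sg)
            xi_new, xi_boundary = _solve_xi_scalar(et**2, lam)
        dxi = abs(xi_new - xi)
        xi = xi_new
        # (b) Fisher scoring for beta at the new xi
        beta_new, mu = _beta_inner(y, x, lam, q, xi, beta, eps)
        dbeta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        # quasi-score at the current iterate
        sg = np.sqrt(mu * (1.0 - mu))
        d = xi * lam + (1.0 - xi)
        a = q.T @ (x * sg[:, None])
        b = q.T @ ((y - mu) / sg)
        score_inf = float(np.max(np.abs((a / d[:, None]).T @ b)))
        if dbeta < tol and dxi < tol and score_inf < score_tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"null-model fit did not converge in {max_iter} iterations "
            f"(|dbeta| last={dbeta:.2e}, score={score_inf:.2e})",
            RuntimeWarning,
        )
    if binary and np.any((mu <= 2 * eps) | (mu >= 1.0 - 2 * eps)):
        warnings.warn(
            "fitted means pinned at the clamp boundary; possible separation",
            RuntimeWarning,
        )
    return NullModelFit(
        y=y, x=x, eig=eig, beta_hat=beta, xi_hat=float(xi), mu_hat=mu,
        converged=converged, n_iter=it, score_inf_norm=score_inf,
        xi_at_boundary=xi_boundary, eps=eps,
    )


# ---------------------------------------------------------------------------
# batched fit

def _solve_xi_batch(et2: np.ndarray, lam: np.ndarray, n_bisect: int = 30) -> np.ndarray:
    """Vectorized root-find of the moment equation for each column of et2 (n x L)."""
    hi0 = 1.0 if lam.min() > 1e-8 else 1.0 - 1e-8
    dl = lam - 1.0

    def f(xi_vec):
        d = xi_vec[None, :] * lam[:, None] + (1.0 - xi_vec[None, :])
        return np.sum(et2 * dl[:, None] / d**2, axis=0) - np.sum(dl[:, None] / d, axis=0)

    L = et2.shape[1]
    lo = np.zeros(L)
    hi = np.full(L, hi0)
    flo = f(lo)
    fhi = f(hi)
    no_root = np.sign(flo) == np.sign(fhi)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        take_lo = np.sign(fm) == np.sign(flo)
        lo = np.where(take_lo, mid, lo)
        flo = np.where(take_lo, fm, flo)
        hi = np.where(take_lo, hi, mid)
    xi = 0.5 * (lo + hi)
    # no sign change: boundary with the smaller |residual|
    bnd = np.where(np.abs(flo) <= np.abs(fhi), 0.0, min(hi0, 1.0))
    return np.where(no_root, bnd, xi)


def fit_null_model_batch(
    ys: np.ndarray,
    x: np.ndarray,
    eig: KinshipEigen,
    *,
    beta0: np.ndarray | None = None,
    xi0: np.ndarray | float | None = None,
    tol: float = 1e-6,
    max_iter: int = 60,
    eps: float = CLAMP_EPS,
) -> BatchNullModelFit:
    """Fit the null model to every column of ``ys`` (n x L) simultaneously.

    Intended for refitting thousands of trait replicates that share the same
    covariates and relatedness matrix; warm-start from the observed-data fit
    via ``beta0``/``xi0``.  Columns may be real-valued.
    """
    ys = np.asarray(ys, dtype=float)
    if ys.ndim != 2:
        raise ValueError("ys must be n x L")
    n, L = ys.shape
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    lam, q = eig.lam, eig.vectors
    identity = eig.is_identity

    if beta0 is None:
        beta = np.tile(logistic_irls(ys.mean(axis=1), x, eps=eps)[:, None], (1, L))
    else:
        beta0 = np.asarray(beta0, dtype=float)
        beta = np.tile(beta0[:, None], (1, L)) if beta0.ndim == 1 else beta0.copy()
    if identity:
        xi = np.zeros(L)
    elif xi0 is None:
        xi = np.full(L, 0.5)
    else:
        xi = np.broadcast_to(np.asarray(xi0, dtype=float), (L,)).copy()

    conv = np.zeros(L, dtype=bool)
    active = np.arange(L)
    it = 0
    for it in range(1, max_iter + 1):
        la = active.size
        ya = ys[:, active]
        ba = beta[:, active]
        mu = np.clip(expit(x @ ba), eps, 1.0 - eps)
        gam = mu * (1.0 - mu)
        sg = np.sqrt(gam)
        # xi update (cheap: O(n la) per bisection step, no matmul beyond Q^T)
        if identity:
            dxi = np.zeros(la)
            xia = xi[active]
        else:
            et = q.T @ ((ya - mu) / sg)
            xia = _solve_xi_batch(et**2, lam)
            dxi = np.abs(xia - xi[active])
            xi[active] = xia
        d = xia[None, :] * lam[:, None] + (1.0 - xia[None, :])
        # one Fisher step for every active column (batched BLAS)
        a = (q.T @ (x[:, None, :] * sg[:, :, None]).reshape(n, la * k)).reshape(n, la, k)
        b = q.T @ ((ya - mu) / sg)
        ad = a / d[:, :, None]
        at = ad.transpose(1, 2, 0)                     # la x k x n
        u = np.matmul(at, b.T[:, :, None])[:, :, 0]    # la x k
        info = np.matmul(at, a.transpose(1, 0, 2))     # la x k x k
        try:
            step = np.linalg.solve(info, u[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack([
                np.linalg.lstsq(info[j], u[j], rcond=None)[0] for j in range(la)
            ])
        nrm = np.max(np.abs(step), axis=1)
        big = nrm > 10.0
        if np.any(big):
            step[big] *= (10.0 / nrm[big])[:, None]
        beta[:, active] = ba + step.T
        dbeta = np.max(np.abs(step), axis=1)
        done = (dbeta < tol) & (dxi < tol)
        conv[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    mu = np.clip(expit(x @ beta), eps, 1.0 - eps)
    return BatchNullModelFit(
        x=x, eig=eig, beta_hat=beta, xi_hat=xi, mu_hat=mu, converged=conv, n_iter=it
    )
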