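"""Decorrelating transform and permutation replicates for a binary trait.

Given a fitted quasi-likelihood null model, the residual vector ``Y - mu_hat``
is mapped to a lower-dimensional vector ``zeta`` whose entries are
approximately second-order exchangeable (equal mean and variance, mutually
uncorrelated), permuted there, and mapped back:

    Y_pi = mu_hat + C^T V  Pi  V^T C^{-T} (Y - mu_hat)

where ``C`` factorizes the fitted trait covariance (``C^T C = Omega_hat``)
and the columns of ``V`` span the orthogonal complement of
``W = C^{-T} Gamma_hat X``.  The ``C^{-T}`` step strips the correlation
induced by relatedness; the projection onto ``V`` strips the correlation
introduced by estimating the mean (the residuals live in the subspace
orthogonal to the covariates on the working scale, so the residual covariance
is the idempotent rank n-k matrix ``I - W (W^T W)^{-1} W^T``).

Under the identity permutation the original trait vector is recovered
exactly, up to the convergence tolerance of the null fit.  Replicates are
real-valued; see :func:`brass.comparators.binarize_replicates` for the
case-count-preserving binary conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import NullModelFit

__all__ = ["BrassTransform", "ReplicateSet", "residual_covariance",
           "build_transform", "generate_replicates"]


@dataclass
class ReplicateSet:
    """A bundle of trait replicates (L x n), with provenance metadata."""

    replicates: np.ndarray
    seed: int | None
    binary: bool
    method: str
    metadata: dict = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.replicates.shape[1]


@dataclass
class BrassTransform:
    """The decorrelating map (C, W, V, zeta_hat) built from a null-model fit.

    ``c_t_v`` caches the back-transform matrix ``C^T V`` so generating L
    replicates costs a single (n x (n-k)) @ ((n-k) x L) product.
    """

    v: np.ndarray          # n x (n-k), orthonormal basis of the complement of col(W)
    w: np.ndarray          # n x k working-scale covariates C^{-T} Gamma X
    zeta_hat: np.ndarray   # (n-k,) transformed residuals
    mu_hat: np.ndarray
    c_t_v: np.ndarray      # n x (n-k) back-transform C^T V
    sqrt_d: np.ndarray     # eigenvalue square roots of Sigma(xi_hat)
    sqrt_gamma: np.ndarray
    eigvecs: np.ndarray    # eigenvectors of Phi (shared with the fit)

    def c_matrix(self) -> np.ndarray:
        """Dense C with C^T C = Omega_hat (diagnostic; not used on the fast path)."""
        return (self.sqrt_d[:, None] * self.eigvecs.T) * self.sqrt_gamma[None, :]

    def c_inv_t_apply(self, v: np.ndarray) -> np.ndarray:
        """C^{-T} v = D^{-1/2} Q^T Gamma^{-1/2} v."""
        v = np.asarray(v, dtype=float)
        sg = self.sqrt_gamma if v.ndim == 1 else self.sqrt_gamma[:, None]
        sd = self.sqrt_d if v.ndim == 1 else self.sqrt_d[:, None]
        return (self.eigvecs.T @ (v / sg)) / sd


def residual_covariance(fit: NullModelFit) -> np.ndarray:
    """First-order approximation to Var(Y - mu_hat) at the fitted parameters.

    Omega - Gamma X (X^T Gamma Omega^{-1} Gamma X)^{-1} X^T Gamma: the fitted
    covariance deflated by the uncertainty of the estimated mean.  Dense and
    O(n^2); intended for diagnostics and validation rather than the replicate
    path, which never materializes it.
    """
    if not fit.converged:
        raise ValueError("null-model fit did not converge; refit before use")
    omega = fit.omega_matrix()
    gx = fit.gamma_diag[:, None] * fit.x
    inner = gx.T @ fit.omega_inv_apply(gx)
    try:
        middle = np.linalg.solve(inner, gx.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X^T Gamma Omega^{-1} Gamma X is singular (collinear covariates)"
        ) from exc
    return omega - gx @ middle


def build_transform(fit: NullModelFit) -> BrassTransform:
    """Construct C, W, V and the transformed residual vector zeta_hat.

    ``V`` is taken as the trailing n-k columns of a full QR decomposition of
    ``W`` — an orthonormal basis of the eigenvalue-1 space of the residual
    projector ``I - W (W^T W)^{-1} W^T`` obtained without forming it.  Any
    orthonormal basis of that complement is equivalent (only V V^T enters the
    replicate map).
    """
    if not fit.converged:
        raise ValueError("null-model fit did not converge; refit before use")
    n, k = fit.x.shape
    if k >= n:
        raise ValueError("need k < n covariates to build the transform")
    d = fit.sigma_eigvals
    if d.min() <= 0.0:
        raise np.linalg.LinAlgError("Sigma(xi_hat) is singular; cannot factorize")
    sqrt_d = np.sqrt(d)
    gam = fit.gamma_diag
    sqrt_gamma = np.sqrt(gam)
    q = fit.eig.vectors

    # W = C^{-T} Gamma X = D^{-1/2} Q^T Gamma^{1/2} X
    w = (q.T @ (fit.x * sqrt_gamma[:, None])) / sqrt_d[:, None]
    qr_q, qr_r = np.linalg.qr(w, mode="complete")
    diag_r = np.abs(np.diag(qr_r[:k, :k]))
    if diag_r.min() < 1e-12 * max(1.0, diag_r.max()):
        raise np.linalg.LinAlgError("W is rank deficient (collinear covariates)")
    v = qr_q[:, k:]

    c_inv_t_resid = (q.T @ ((fit.y - fit.mu_hat) / sqrt_gamma)) / sqrt_d
    zeta = v.T @ c_inv_t_resid
    # C^T V = Gamma^{1/2} Q D^{1/2} V
    c_t_v = sqrt_gamma[:, None] * (q @ (sqrt_d[:, None] * v))
    return BrassTransform(
        v=v, w=w, zeta_hat=zeta, mu_hat=fit.mu_hat, c_t_v=c_t_v,
        sqrt_d=sqrt_d, sqrt_gamma=sqrt_gamma, eigvecs=q,
    )


def generate_replicates(
    y: np.ndarray,
    fit: NullModelFit,
    transform: BrassTransform,
    n_reps: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Draw ``n_reps`` permutation replicates of the trait.

    Each replicate permutes the entries of ``zeta_hat`` with an independent
    uniform-random permutation and back-transforms; replicates are
    real-valued.  Reproducible from ``seed`` (or pass an explicit ``rng``).
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    y = np.asarray(y, dtype=float).ravel()
    if y.size != transform.mu_hat.size:
        raise ValueError("phenotype length does not match the transform")
    if rng is None:
        rng = np.random.default_rng(seed)
    zeta = transform.zeta_hat
    permuted = rng.permuted(np.broadcast_to(zeta, (n_reps, zeta.size)), axis=1)
    reps = transform.mu_hat[None, :] + permuted @ transform.c_t_v.T
    return ReplicateSet(
        replicates=reps, seed=seed, binary=False, method="brass",
        metadata={"xi_hat": fit.xi_hat, "beta_hat": fit.beta_hat.tolist()},
    )
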