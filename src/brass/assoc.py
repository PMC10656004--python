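"""Retrospective quasi-score association test for binary traits and their replicates.

The genotype is treated as random given the trait (retrospective view): under
the null, G = Z b + e with Var(e) = sigma_g^2 Phi_adj, where Z stacks the D
principal components removed from the GRM and a ones column.  Writing
A = I - Z (Z^T Phi_adj^{-1} Z)^{-1} Z^T Phi_adj^{-1} for the GLS
residual-maker of the regression of G on Z (in the Phi_adj^{-1} metric), the
single-marker statistic is

    T = (R^T A G)^2 / (sigma_g^2 * R^T A Phi_adj A^T R),
    R = Omega_hat^{-1} (Y - mu_hat),

referred to chi-square with 1 df.  The numerator has retrospective mean zero
(A annihilates the genotype's structured mean) and the denominator is the
matching conditional variance.  ``R`` comes from the quasi-likelihood null
fit; because only the first two moments of the trait enter, the test applies
unchanged to real-valued trait replicates.

Two estimators of the genotype variance sigma_g^2 are available:

* ``"original"`` — the binomial value 2 f (1 - f) with f = mean(G) / 2;
* ``"modified"`` — G^T P G / (n - D - 1) with
  P = Phi_adj^{-1} - Phi_adj^{-1} Z (Z^T Phi_adj^{-1} Z)^{-1} Z^T Phi_adj^{-1}
    = Phi_adj^{-1} A,
  i.e. the GLS residual variance of G on Z.  This discounts genotype
  variance explained by relatedness and the removed PCs, which keeps the
  test calibrated under population structure.

The statistic is invariant to affine rescaling of G (with the modified
estimator), and a genotype lying in the span of Z is untestable (p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .model_core import NullModelFit
from .structure import StructureModel

__all__ = [
    "ScoreTestResult",
    "genotype_variance_original",
    "genotype_variance_modified",
    "carat_test",
    "min_p_scan",
]

_SIGMA_G_TOL = 1e-12


@dataclass
class ScoreTestResult:
    statistic: float
    p_value: float
    sigma_g_sq: float
    estimator_kind: str
    testable: bool = True


def genotype_variance_original(g: np.ndarray) -> float:
    """Binomial genotype variance 2 f (1 - f), f = mean(G) / 2."""
    g = np.asarray(g, dtype=float).ravel()
    f = g.mean() / 2.0
    return float(2.0 * f * (1.0 - f))


def _p_solver(structure: StructureModel):
    """Cached pieces for applying the Phi_adj^{-1}-based projection complement P."""
    cache = structure._p_cache
    if "cf" not in cache:
        cf = cho_factor(structure.phi_adj, lower=True)
        phi_inv_z = cho_solve(cf, structure.z)
        zz = structure.z.T @ phi_inv_z
        cache["cf"] = cf
        cache["phi_inv_z"] = phi_inv_z
        cache["zz"] = zz
    return cache["cf"], cache["phi_inv_z"], cache["zz"]


def p_apply(structure: StructureModel, g: np.ndarray) -> np.ndarray:
    """P g for a vector or n x m matrix of genotypes."""
    g = np.asarray(g, dtype=float)
    cf, phi_inv_z, zz = _p_solver(structure)
    phi_inv_g = cho_solve(cf, g)
    coef = np.linalg.solve(zz, structure.z.T @ phi_inv_g)
    return phi_inv_g - phi_inv_z @ coef


def adjust_genotype(structure: StructureModel, g: np.ndarray) -> np.ndarray:
    """GLS residual A g of the regression of G on Z under the Phi_adj^{-1} metric."""
    g = np.asarray(g, dtype=float)
    cf, phi_inv_z, zz = _p_solver(structure)
    coef = np.linalg.solve(zz, phi_inv_z.T @ g)
    return g - structure.z @ coef


def _adjusted_quad(structure: StructureModel, r: np.ndarray) -> np.ndarray:
    """R^T A Phi_adj A^T R = R^T Phi_adj R - (Z^T R)^T (Z^T Phi_adj^{-1} Z)^{-1} Z^T R.

    ``r`` may be a vector or an n x B matrix (one column per replicate).
    """
    _, _, zz = _p_solver(structure)
    zr = structure.z.T @ r
    full = np.einsum("n...,n...->...", r, structure.phi_adj @ r)
    corr = np.einsum("d...,d...->...", zr, np.linalg.solve(zz, zr))
    return full - corr


def genotype_variance_modified(g: np.ndarray, structure: StructureModel) -> float:
    """sigma_g^2 = G^T P G / (n - D - 1); zero when G lies in the span of Z."""
    g = np.asarray(g, dtype=float).ravel()
    n = structure.n
    if g.size != n:
        raise ValueError("genotype length does not match the structure model")
    val = float(g @ p_apply(structure, g)) / (n - structure.d - 1)
    return max(val, 0.0)


def carat_test(
    y_or_replicate: np.ndarray,
    x: np.ndarray,
    g: np.ndarray,
    structure: StructureModel,
    fit: NullModelFit,
    estimator_kind: str = "modified",
) -> ScoreTestResult:
    """Quasi-score test of one marker against a trait vector or replicate.

    ``fit`` must be the null-model fit for this trait vector with the same
    covariates and adjusted GRM (the fit does not involve the genotype, so
    one fit serves all markers).
    """
    y = np.asarray(y_or_replicate, dtype=float).ravel()
    g = np.asarray(g, dtype=float).ravel()
    if estimator_kind == "modified":
        sg2 = genotype_variance_modified(g, structure)
    elif estimator_kind == "original":
        sg2 = genotype_variance_original(g)
    else:
        raise ValueError("estimator_kind must be 'modified' or 'original'")
    r = fit.omega_inv_apply(y - fit.mu_hat)
    quad = float(_adjusted_quad(structure, r))
    g_adj = adjust_genotype(structure, g)
    if sg2 <= _SIGMA_G_TOL or quad <= 0.0 or float(g_adj @ g_adj) <= _SIGMA_G_TOL:
        return ScoreTestResult(0.0, 1.0, sg2, estimator_kind, testable=False)
    t = float(r @ g_adj) ** 2 / (sg2 * quad)
    return ScoreTestResult(t, float(chi2.sf(t, 1)), sg2, estimator_kind)


def min_p_scan(
    y_or_replicate: np.ndarray,
    x: np.ndarray,
    panel: np.ndarray,
    structure: StructureModel,
    fit: NullModelFit,
    estimator_kind: str = "modified",
) -> float:
    """Smallest per-marker p-value over an n x m genotype panel.

    Untestable markers (degenerate genotype variance) are excluded; if every
    marker is untestable an error is raised.
    """
    panel = np.atleast_2d(np.asarray(panel, dtype=float))
    if panel.shape[0] != structure.n:
        panel = panel.T
    if panel.shape[1] < 1:
        raise ValueError("empty genotype panel")
    best = np.inf
    any_testable = False
    for j in range(panel.shape[1]):
        res = carat_test(y_or_replicate, x, panel[:, j], structure, fit, estimator_kind)
        if res.testable:
            any_testable = True
            best = min(best, res.p_value)
    if not any_testable:
        raise ValueError("all markers untestable (degenerate genotype variance)")
    return float(best)


# ---------------------------------------------------------------------------
# vectorized internals shared with the experiment pipeline

def panel_sigma_g(panel: np.ndarray, structure: StructureModel) -> np.ndarray:
    """Modified genotype-variance estimates for every column of an n x m panel."""
    panel = np.asarray(panel, dtype=float)
    pg = p_apply(structure, panel)
    vals = np.einsum("nm,nm->m", panel, pg) / (structure.n - structure.d - 1)
    return np.maximum(vals, 0.0)


def scan_min_p_batch(
    residuals: np.ndarray,
    panel: np.ndarray,
    sigma_g: np.ndarray,
    structure: StructureModel,
) -> np.ndarray:
    """Min-p over a marker panel for many replicates at once.

    ``residuals`` is n x B with column b = Omega_hat^{-1} (Y_b - mu_hat_b)
    from the per-replicate null fits.  Untestable markers are excluded.
    """
    testable = sigma_g > _SIGMA_G_TOL
    if not np.any(testable):
        raise ValueError("all markers untestable (degenerate genotype variance)")
    g_adj = adjust_genotype(structure, panel[:, testable])
    numer = residuals.T @ g_adj                         # B x m'
    quad = _adjusted_quad(structure, residuals)         # (B,)
    t = numer**2 / (sigma_g[None, testable] * quad[:, None])
    p = chi2.sf(t, 1)
    return p.min(axis=1)
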