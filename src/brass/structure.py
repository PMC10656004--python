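"""Genetic relatedness matrices, principal-component adjustment, LOCO GRMs.

The GRM is the standard centered-and-scaled estimator

    Phi = (1/M) sum_m (g_m - 2 f_m)(g_m - 2 f_m)^T / (2 f_m (1 - f_m)),

with f_m the sample allele frequency of marker m.  Top principal components
of Phi can be moved into fixed-effect covariates; the GRM is then adjusted by
the symmetric projection Phi_adj = (I - U U^T) Phi (I - U U^T) + delta I so
that the removed directions carry no residual structure (the small ridge
delta restores positive definiteness).  Leave-one-chromosome-out (LOCO) GRMs
avoid proximal contamination when replicating or testing a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StructureModel", "compute_grm", "remove_top_pcs", "loco_grms"]

DEFAULT_RIDGE = 1e-6


@dataclass
class StructureModel:
    """GRM, its PC-adjusted form, the removed PCs and the testing design Z = [U | 1]."""

    phi: np.ndarray
    phi_adj: np.ndarray
    pcs: np.ndarray            # n x d, orthonormal
    d: int
    z: np.ndarray              # n x (d+1): removed eigenvectors plus ones column
    ridge: float
    loco: dict | None = None
    _p_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.phi.shape[0]


def compute_grm(
    genotypes: np.ndarray,
    *,
    maf_min: float | None = None,
    impute_missing: bool = False,
) -> np.ndarray:
    """GCTA-style GRM from an n x M dosage matrix (minor-allele counts in [0, 2]).

    Monomorphic markers (and markers below ``maf_min`` if given) are skipped
    with a warning.  Missing dosages are rejected unless ``impute_missing``,
    in which case they are replaced by the marker mean (with a warning).
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[1] < 2:
        raise ValueError("need an n x M dosage matrix with M >= 2")
    if np.any(np.isnan(g)):
        if not impute_missing:
            raise ValueError("missing dosages present; pass impute_missing=True to mean-impute")
        warnings.warn("mean-imputing missing dosages", RuntimeWarning)
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g = g.copy()
        g[idx] = np.take(col_mean, idx[1])
    f = g.mean(axis=0) / 2.0
    keep = (f > 0.0) & (f < 1.0)
    if maf_min is not None:
        maf = np.minimum(f, 1.0 - f)
        keep &= maf >= maf_min
    n_skipped = int((~keep).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} monomorphic/filtered markers", RuntimeWarning)
    if keep.sum() < 1:
        raise ValueError("no polymorphic markers left to build a GRM")
    gk = g[:, keep]
    fk = f[keep]
    z = (gk - 2.0 * fk) / np.sqrt(2.0 * fk * (1.0 - fk))
    return (z @ z.T) / keep.sum()


def remove_top_pcs(phi: np.ndarray, d: int, *, ridge: float = DEFAULT_RIDGE) -> StructureModel:
    """Move the top d eigenvectors of Phi into covariates; adjust the GRM.

    With d = 0 the GRM is returned unchanged (no ridge) and Z is just the
    ones column.  Applying the adjustment twice with the same eigenvectors
    changes nothing beyond accumulating the ridge.
    """
    phi = np.asarray(phi, dtype=float)
    n = phi.shape[0]
    if d < 0 or d >= n:
        raise ValueError("need 0 <= d < n")
    ones = np.ones((n, 1))
    if d == 0:
        return StructureModel(
            phi=phi, phi_adj=phi, pcs=np.empty((n, 0)), d=0, z=ones, ridge=0.0
        )
    lam, q = np.linalg.eigh(phi)
    u = q[:, ::-1][:, :d]              # top-d eigenvectors
    proj = np.eye(n) - u @ u.T
    phi_adj = proj @ phi @ proj
    phi_adj = 0.5 * (phi_adj + phi_adj.T) + ridge * np.eye(n)
    return StructureModel(
        phi=phi, phi_adj=phi_adj, pcs=u, d=d, z=np.hstack([u, ones]), ridge=ridge
    )


def loco_grms(
    genotypes: np.ndarray,
    chrom_labels: np.ndarray,
    **grm_kwargs,
) -> dict:
    """Leave-one-chromosome-out GRMs: for each chromosome, a GRM from all other markers."""
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(chrom_labels)
    if labels.size != g.shape[1]:
        raise ValueError("need one chromosome label per marker")
    chroms = np.unique(labels)
    if chroms.size < 2:
        raise ValueError("LOCO requires markers on at least two chromosomes")
    out = {}
    for c in chroms:
        mask = labels != c
        if not mask.any():
            raise ValueError(f"chromosome {c!r} holds all markers; cannot leave it out")
        out[c] = compute_grm(g[:, mask], **grm_kwargs)
    return out
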