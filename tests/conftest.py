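"""Shared fixtures: small kinship structures and simulated datasets."""

import numpy as np
import pytest

from brass import model_core, simdata, structure


class IdentityPermutationRng:
    """Generator stub whose 'permutations' are all the identity.

    Used to exercise the identity-permutation exactness contract of the
    permutation-based resampling methods through their public interface.
    """

    def permuted(self, x, axis=None):
        return np.array(x, copy=True)


@pytest.fixture
def identity_rng():
    return IdentityPermutationRng()


def sib_block_phi(n_blocks: int, block_size: int = 4, rho: float = 0.5) -> np.ndarray:
    """Block-diagonal kinship: within-block correlation rho, PSD for rho in [0,1]."""
    block = np.full((block_size, block_size), rho) + (1 - rho) * np.eye(block_size)
    return np.kron(np.eye(n_blocks), block)


@pytest.fixture(scope="session")
def block_phi():
    return sib_block_phi(20)          # n = 80


@pytest.fixture(scope="session")
def block_fit(block_phi):
    """A converged null-model fit on structured binary data (n = 80, k = 3)."""
    rng = np.random.default_rng(42)
    n = block_phi.shape[0]
    x = np.column_stack([np.ones(n), rng.standard_normal(n),
                         (rng.random(n) < 0.5).astype(float)])
    # trait with real familial correlation: block-shared logit effects
    u = np.repeat(rng.normal(0, 1.2, n // 4), 4)
    from scipy.special import expit
    y = (rng.random(n) < expit(-0.4 + 0.5 * x[:, 1] + u)).astype(float)
    fit = model_core.fit_null_model(y, x, block_phi)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def sim_dataset():
    """A small pedigree dataset with GRM/structure/covariates/null fit (n = 96)."""
    rng = np.random.default_rng(11)
    ped = simdata.default_three_generation_pedigree()
    freqs = simdata.simulate_subpop_frequencies(220, 0.01, rng=rng)
    geno, subpop, pedlab = simdata.gene_drop_pedigrees(freqs, ped, 6, rng=rng)
    cov = simdata.simulate_covariates(geno.shape[0], rng=rng)
    spec = simdata.TraitModelSpec(
        model="logistic", intercept=-1.0, betas=(0.8, 1.2, 0.3),
        sigma_a_sq=4.0, sigma_e_sq=None, covariate_fraction=0.4,
        prevalence_target=0.3, error_share_target=0.2,
    )
    y = simdata.simulate_trait(spec, geno[:, :200], cov, rng=rng)
    phi = structure.compute_grm(geno[:, :200].astype(float))
    sm = structure.remove_top_pcs(phi, 1)
    n = y.size
    x = np.column_stack([np.ones(n), sm.pcs, cov[["age", "sex", "normal"]].to_numpy()])
    eig = model_core.kinship_eigen(sm.phi_adj, validate=False)
    fit = model_core.fit_null_model(y, x, eig=eig)
    assert fit.converged
    return {
        "geno": geno, "panel": geno[:, 200:].astype(float), "cov": cov, "y": y,
        "x": x, "phi": phi, "sm": sm, "eig": eig, "fit": fit,
        "subpop": subpop, "pedlab": pedlab,
    }
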