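"""Synthetic genotype/covariate/trait generator for structured binary-trait studies.

Genotypes come from a two-subpopulation Balding–Nichols model: ancestral
allele frequencies are uniform on (.2, .8) and each subpopulation's frequency
is Beta(p (1-F)/F, (1-p)(1-F)/F) with differentiation F (default .01).
Pedigrees of a fixed three-generation configuration are assigned in equal
numbers to the two subpopulations; founder alleles are drawn from the
pedigree's subpopulation and gene dropping (Mendelian transmission, one
allele from each parent chosen uniformly and independently per marker)
determines the rest.  Markers are unlinked.

Traits follow either a logistic model,

    Y_i | X_i, W_i, alpha ~ Bernoulli(p_i),   logit(p_i) = X_i beta + W_i alpha,

or a liability-threshold model Y_i = 1{X_i beta + W_i alpha + eps_i > 0},
where W holds the standardized causal genotypes, alpha ~ MVN(0, sigma^2 I)
with total polygenic variance sigma_a^2 = sigma^2 M_c, and
eps ~ MVN(0, sigma_e^2 I).  :func:`calibrate_trait_model` chooses the
intercept and a common scale for (beta, sigma_a^2) by stochastic
root-finding so that (i) covariates explain a prescribed fraction of the
linear-predictor variance, (ii) the Bernoulli (or threshold) error explains
a prescribed share of the total phenotypic variance, and (iii) the
prevalence hits its target; the standard-normal covariate's effect is pinned
so that its mixed-model Wald test averages a prescribed p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, ndtr
from scipy.stats import norm

__all__ = [
    "PedigreeConfig",
    "TraitModelSpec",
    "SimulatedDataset",
    "default_three_generation_pedigree",
    "simulate_subpop_frequencies",
    "gene_drop_pedigrees",
    "simulate_covariates",
    "calibrate_trait_model",
    "simulate_trait",
    "ascertain_sample",
]


# ---------------------------------------------------------------------------
# pedigree structure

@dataclass(frozen=True)
class PedigreeConfig:
    """A pedigree as a parent map: entry i is None (founder) or (father, mother).

    Parents must precede children (indices ordered topologically), which also
    guarantees acyclicity; every non-founder has exactly two in-pedigree
    parents.
    """

    parents: tuple

    def __post_init__(self):
        for i, pr in enumerate(self.parents):
            if pr is None:
                continue
            if len(pr) != 2:
                raise ValueError(f"member {i}: need exactly two parents or None")
            fa, mo = pr
            if fa >= i or mo >= i or fa < 0 or mo < 0 or fa == mo:
                raise ValueError(f"member {i}: parents must be distinct earlier members")

    @property
    def n_members(self) -> int:
        return len(self.parents)

    @property
    def founders(self) -> tuple:
        return tuple(i for i, pr in enumerate(self.parents) if pr is None)

    @property
    def n_generations(self) -> int:
        depth = {}
        for i, pr in enumerate(self.parents):
            depth[i] = 0 if pr is None else 1 + max(depth[pr[0]], depth[pr[1]])
        return max(depth.values()) + 1


def default_three_generation_pedigree() -> PedigreeConfig:
    """16-member, three-generation pedigree.

    Two founder couples (0,1) and (2,3) each have two children (4-7); each
    child marries an unrelated founder-like spouse (8-11) and each such
    couple has one grandchild (12-15).
    """
    parents = (
        None, None, None, None,        # founders
        (0, 1), (0, 1), (2, 3), (2, 3),  # children
        None, None, None, None,        # married-in spouses
        (4, 8), (5, 9), (6, 10), (7, 11),  # grandchildren
    )
    return PedigreeConfig(parents=parents)


# ---------------------------------------------------------------------------
# genotypes

def simulate_subpop_frequencies(
    n_snps: int,
    f_st: float = 0.01,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    n_subpops: int = 2,
    ancestral_range: tuple = (0.2, 0.8),
) -> np.ndarray:
    """Balding–Nichols subpopulation allele frequencies, shape (n_subpops, n_snps).

    Ancestral frequencies are uniform on ``ancestral_range``; each
    subpopulation draws Beta(p (1-F)/F, (1-p)(1-F)/F) independently.
    """
    if not 0.0 < f_st < 1.0:
        raise ValueError("need 0 < F < 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = ancestral_range
    p = rng.uniform(lo, hi, size=n_snps)
    a = p * (1.0 - f_st) / f_st
    b = (1.0 - p) * (1.0 - f_st) / f_st
    return rng.beta(a, b, size=(n_subpops, n_snps))


def gene_drop_pedigrees(
    freqs: np.ndarray,
    ped_config: PedigreeConfig,
    n_pedigrees: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
):
    """Genotypes for ``n_pedigrees`` pedigrees split equally between subpopulations.

    Founder haplotypes are i.i.d. Bernoulli(subpopulation frequency) per
    marker; each child receives one allele from each parent, chosen uniformly
    and independently per marker (markers unlinked).

    Returns ``(genotypes, subpop_labels, pedigree_labels)`` with genotypes of
    shape (n_pedigrees * n_members, n_snps), pedigree-major order.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    n_subpops, n_snps = freqs.shape
    if n_pedigrees % n_subpops:
        raise ValueError("n_pedigrees must divide evenly between the subpopulations")
    per = n_pedigrees // n_subpops
    n_mem = ped_config.n_members

    geno_blocks = []
    subpop_labels = []
    ped_labels = []
    ped_offset = 0
    for s in range(n_subpops):
        f = freqs[s]
        haps = {}
        for i, pr in enumerate(ped_config.parents):
            if pr is None:
                h1 = (rng.random((per, n_snps)) < f).astype(np.int8)
                h2 = (rng.random((per, n_snps)) < f).astype(np.int8)
            else:
                fa, mo = pr
                pick1 = rng.random((per, n_snps)) < 0.5
                pick2 = rng.random((per, n_snps)) < 0.5
                h1 = np.where(pick1, haps[fa][0], haps[fa][1])
                h2 = np.where(pick2, haps[mo][0], haps[mo][1])
            haps[i] = (h1, h2)
        block = np.stack([haps[i][0] + haps[i][1] for i in range(n_mem)], axis=1)
        geno_blocks.append(block.reshape(per * n_mem, n_snps))
        subpop_labels.append(np.full(per * n_mem, s))
        ped_labels.append(np.repeat(np.arange(ped_offset, ped_offset + per), n_mem))
        ped_offset += per
    return (
        np.concatenate(geno_blocks, axis=0),
        np.concatenate(subpop_labels),
        np.concatenate(ped_labels),
    )


# ---------------------------------------------------------------------------
# covariates

def simulate_covariates(
    n: int, seed: int | None = None, *, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Covariate table: standardized age (from Uniform(20, 80)), sex (0/1), N(0,1)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    age_raw = rng.uniform(20.0, 80.0, size=n)
    age = (age_raw - 50.0) / np.sqrt(60.0**2 / 12.0)   # exact U(20,80) moments
    sex = (rng.random(n) < 0.5).astype(float)
    normal = rng.standard_normal(n)
    return pd.DataFrame({"age": age, "sex": sex, "normal": normal})


# ---------------------------------------------------------------------------
# trait model specification and calibration

@dataclass(frozen=True)
class TraitModelSpec:
    """Calibrated generative trait model.

    ``betas`` are the covariate effects on the (logit or liability) scale for
    the columns (age, sex, normal) as produced by :func:`simulate_covariates`
    (sex raw 0/1, others standardized).  For the liability model the residual
    scale is fixed at sigma_e_sq = 1 (the trait is scale-invariant).
    """

    model: str                  # "logistic" or "liability"
    intercept: float
    betas: tuple                # (beta_age, beta_sex, beta_normal)
    sigma_a_sq: float
    sigma_e_sq: float | None
    covariate_fraction: float
    prevalence_target: float
    error_share_target: float

    @property
    def beta_vector(self) -> np.ndarray:
        return np.asarray(self.betas, dtype=float)


def _mean_wald_p(lam: float) -> float:
    """E[two-sided normal p-value] when the Wald z-statistic ~ N(lam, 1)."""
    z, wts = np.polynomial.hermite_e.hermegauss(101)
    vals = 2.0 * ndtr(-np.abs(z + lam))
    return float((wts @ vals) / wts.sum())


def wald_noncentrality(p_target: float = 0.05) -> float:
    """Mean Wald-test noncentrality giving an average two-sided p of ``p_target``."""
    return float(optimize.brentq(lambda l: _mean_wald_p(l) - p_target, 0.0, 10.0))


def _pinned_normal_effect(prevalence: float, error_share: float, n: int,
                          wald_p: float, model: str) -> float:
    """Generative effect of the N(0,1) covariate matching an average Wald p-value.

    The marginal linear effect of the covariate on the 0/1 trait is the
    generative effect scaled by the mean derivative of the response curve
    (E[p(1-p)] for logit; the threshold density for probit); the Wald z of
    that linear effect in a sample of size n has noncentrality
    effect_Y * sqrt(n) / sd(Y).
    """
    lam = wald_noncentrality(wald_p)
    var_y = prevalence * (1.0 - prevalence)
    effect_y = lam * np.sqrt(var_y) / np.sqrt(n)
    mean_deriv = error_share * var_y if model == "logistic" else None
    if model == "logistic":
        # E[p(1-p)] equals the Bernoulli-error share of Var(Y)
        return effect_y / mean_deriv
    # probit: mean derivative ~ threshold density scaled by the liability sd,
    # approximating var(eps)/var(liability) by the phenotypic error share
    return effect_y / max(norm.pdf(norm.ppf(prevalence)) * np.sqrt(error_share), 1e-6)


def calibrate_trait_model(
    model: str = "logistic",
    covariate_fraction: float = 0.4,
    prevalence: float = 0.30,
    error_share: float = 0.20,
    *,
    wald_p_target: float = 0.05,
    wald_sample_size: int = 1000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> TraitModelSpec:
    """Solve for the intercept and the common (beta, sigma_a^2) scale by Monte Carlo.

    Constraints: the covariate share of Var(linear predictor) equals
    ``covariate_fraction``; the Bernoulli/threshold error share of the total
    phenotypic variance equals ``error_share``; the prevalence equals
    ``prevalence``.  Since Var(Y) = prev (1 - prev) for a binary trait, the
    last two reduce to E[p] = prev and E[p(1-p)] = error_share * prev * (1-prev).
    A fixed Monte-Carlo sample (common random numbers) makes the root-find
    smooth and reproducible.
    """
    if model not in ("logistic", "liability"):
        raise ValueError("model must be 'logistic' or 'liability'")
    if not 0.0 < covariate_fraction < 1.0:
        raise ValueError("covariate_fraction must be in (0, 1)")
    link = expit if model == "logistic" else ndtr

    rng = np.random.default_rng(seed)
    cov = simulate_covariates(n_mc, rng=rng)
    age = cov["age"].to_numpy()
    sex_c = cov["sex"].to_numpy()
    normal = cov["normal"].to_numpy()
    zg = rng.standard_normal(n_mc)      # polygenic score on the standard scale
    sd_sex = 0.5                         # sd of Bernoulli(.5)

    beta_n = _pinned_normal_effect(prevalence, error_share, wald_sample_size,
                                   wald_p_target, model)
    target_epq = error_share * prevalence * (1.0 - prevalence)

    def components(b0: float, s: float):
        v_c = covariate_fraction * s**2
        rem = max(v_c - beta_n**2, 0.0)
        b_age = np.sqrt(rem / 2.0)
        b_sex = np.sqrt(rem / 2.0) / sd_sex
        sigma_a = np.sqrt((1.0 - covariate_fraction)) * s
        eta = b0 + b_age * age + b_sex * sex_c + beta_n * normal + sigma_a * zg
        p = link(eta)
        return p, (b_age, b_sex, beta_n), sigma_a**2

    # the pinned normal-covariate effect sets a floor on the overall scale:
    # the covariate budget c * s^2 must at least cover beta_n^2
    s_min = abs(beta_n) / np.sqrt(covariate_fraction)

    def s_of(t: float) -> float:
        return s_min * (1.0 + np.exp(t))

    def residual(params):
        b0, t = params
        out = components(b0, s_of(t))
        p, _, _ = out
        return np.array([p.mean() - prevalence,
                         np.mean(p * (1.0 - p)) - target_epq])

    x0 = np.array([np.log(prevalence / (1 - prevalence)) if model == "logistic"
                   else norm.ppf(prevalence), 0.0])
    sol = optimize.root(residual, x0, method="hybr", options={"xtol": 1e-12})
    if not sol.success or np.max(np.abs(residual(sol.x))) > 5e-4:
        raise RuntimeError(
            f"trait-model calibration failed: residual {residual(sol.x)}, "
            f"targets prevalence={prevalence}, error_share={error_share}, "
            f"covariate_fraction={covariate_fraction}"
        )
    b0, s = float(sol.x[0]), float(s_of(sol.x[1]))
    _, betas, sigma_a_sq = components(b0, s)
    return TraitModelSpec(
        model=model, intercept=b0, betas=tuple(float(b) for b in betas),
        sigma_a_sq=float(sigma_a_sq),
        sigma_e_sq=None if model == "logistic" else 1.0,
        covariate_fraction=covariate_fraction,
        prevalence_target=prevalence, error_share_target=error_share,
    )


# ---------------------------------------------------------------------------
# trait simulation

def linear_predictor(
    spec: TraitModelSpec,
    genotypes_causal: np.ndarray,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """X beta + W alpha for one dataset (alpha drawn once).

    Causal markers are standardized to sample mean 0 and variance 1;
    monomorphic columns are dropped with the per-marker variance sigma^2
    rescaled so the total polygenic variance sigma_a^2 is preserved.
    """
    g = np.asarray(genotypes_causal, dtype=float)
    sd = g.std(axis=0)
    keep = sd > 0.0
    gk = g[:, keep]
    w = (gk - gk.mean(axis=0)) / gk.std(axis=0)
    m_used = int(keep.sum())
    if m_used == 0:
        raise ValueError("all causal markers are monomorphic")
    alpha = rng.normal(0.0, np.sqrt(spec.sigma_a_sq / m_used), size=m_used)
    xmat = covariates[["age", "sex", "normal"]].to_numpy()
    return spec.intercept + xmat @ spec.beta_vector + w @ alpha


def simulate_trait(
    spec: TraitModelSpec,
    genotypes_causal: np.ndarray,
    covariates: pd.DataFrame,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one binary trait vector from the calibrated generative model."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eta = linear_predictor(spec, genotypes_causal, covariates, rng)
    n = eta.size
    if spec.model == "logistic":
        return (rng.random(n) < expit(eta)).astype(float)
    eps = rng.normal(0.0, np.sqrt(spec.sigma_e_sq), size=n)
    return (eta + eps > 0.0).astype(float)


def ascertain_sample(
    trait: np.ndarray,
    ratio: tuple,
    n_keep: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniformly subsample exact case/control counts implied by ratio x n_keep.

    ``ratio = (cases, controls)``, e.g. (1, 1) or (3, 7).  Raises if the
    source population lacks enough cases or controls.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(trait, dtype=float).ravel()
    a, b = ratio
    n_cases = int(round(n_keep * a / (a + b)))
    n_controls = n_keep - n_cases
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size < n_cases:
        raise ValueError(f"need {n_cases} cases but population has {cases.size}")
    if controls.size < n_controls:
        raise ValueError(f"need {n_controls} controls but population has {controls.size}")
    idx = np.concatenate([
        rng.choice(cases, size=n_cases, replace=False),
        rng.choice(controls, size=n_controls, replace=False),
    ])
    return np.sort(idx)


# ---------------------------------------------------------------------------
# dataset container

@dataclass
class SimulatedDataset:
    """One stage-(1) dataset: genotypes, covariates, trait, labels, provenance."""

    genotypes_causal: np.ndarray
    genotypes_null: np.ndarray
    chrom_labels: np.ndarray
    covariates: pd.DataFrame
    trait: np.ndarray
    subpop_labels: np.ndarray
    pedigree_labels: np.ndarray
    spec: TraitModelSpec
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.trait.size

    def to_dir(self, path) -> None:
        """Write the dataset as plain-text files plus a truth JSON."""
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ids = [f"S{i:06d}" for i in range(self.n)]
        geno = np.hstack([self.genotypes_causal, self.genotypes_null])
        pd.DataFrame(geno, index=pd.Index(ids, name="IID")).to_csv(
            path / "genotypes.tsv", sep="\t")
        pd.DataFrame({"chrom": self.chrom_labels}).to_csv(
            path / "chrom_map.tsv", sep="\t", index_label="marker")
        cov = self.covariates.copy()
        cov.insert(0, "IID", ids)
        cov.to_csv(path / "covariates.tsv", sep="\t", index=False)
        pd.DataFrame({"IID": ids, "trait": self.trait.astype(int)}).to_csv(
            path / "trait.tsv", sep="\t", index=False)
        truth = {
            "model": self.spec.model,
            "intercept": self.spec.intercept,
            "betas": list(self.spec.betas),
            "sigma_a_sq": self.spec.sigma_a_sq,
            "sigma_e_sq": self.spec.sigma_e_sq,
            "covariate_fraction": self.spec.covariate_fraction,
            "prevalence_target": self.spec.prevalence_target,
            "error_share_target": self.spec.error_share_target,
            "seed": self.seed,
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=2))
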