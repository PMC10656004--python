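"""Null-simulation study: replicate generation, empirical thresholds, type-1 error.

The study pipeline mirrors a four-stage design: (1) simulate a structured
dataset under the null of no association (:mod:`brass.simdata`); (2) for each
resampling method, draw L trait replicates; (3) test every replicate against
the panel of null markers with the retrospective quasi-score test, record the
minimum p-value per replicate, and set the genome-wide threshold at the
empirical 100*alpha-th percentile of those minima; (4) compare the observed
minimum p-value to the threshold and, across datasets, test whether the
rejection proportion differs from alpha by a binomial z-test.

Per-replicate association testing refits the null model on the replicate
(the test's residuals come from that fit); the refits are vectorized across
all replicates of a dataset via :func:`brass.model_core.fit_null_model_batch`,
warm-started at the observed-data fit.

The same covariate matrix (top PC of the GRM plus the simulated covariates)
and the same PC-adjusted GRM feed every resampling method, so differences in
the resulting type-1 error are attributable to the methods themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from . import comparators, simdata, transform
from .assoc import panel_sigma_g, scan_min_p_batch
from .model_core import fit_null_model, fit_null_model_batch, kinship_eigen
from .structure import compute_grm, remove_top_pcs

__all__ = [
    "METHODS",
    "ExperimentConfig",
    "ExperimentResult",
    "estimate_threshold",
    "evaluate_type1",
    "mc_error_variance",
    "adaptive_stop",
    "run_stage_pipeline",
    "headline_config",
]

METHODS = (
    "brass", "brass-mod", "mvnpermute", "mvnpermute-mod",
    "naive", "naive-mod", "logmm-pql",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one null-simulation study."""

    methods: tuple = ("brass",)
    n_datasets: int = 100
    n_replicates: int = 200
    alpha: float = 0.01
    # dataset generation
    n_pedigrees: int = 12
    m_causal: int = 500
    m_null: int = 20
    f_st: float = 0.01
    trait_model: str = "logistic"
    covariate_fraction: float = 0.4
    prevalence: float = 0.30
    error_share: float = 0.20
    ascertainment: tuple | None = None   # e.g. ((1, 1), 1000)
    missing_covariate: bool = False
    n_pcs_removed: int = 1
    seed: int = 0
    adaptive: bool = False
    adaptive_batch: int = 100
    calibration_n_mc: int = 100_000

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; choose from {METHODS}")
        if self.n_replicates < 1.0 / self.alpha:
            warnings.warn(
                f"n_replicates={self.n_replicates} < 1/alpha={1.0/self.alpha:.0f}: "
                "threshold estimates will be coarse", RuntimeWarning,
            )


@dataclass
class ExperimentResult:
    """Per-dataset thresholds/rejections and per-method type-1-error summary."""

    per_dataset: pd.DataFrame
    summary: pd.DataFrame
    config: ExperimentConfig


def mc_error_variance(alpha: float, n_datasets: int) -> float:
    """Monte-Carlo variance alpha (1 - alpha) / N of the empirical type-1-error rate."""
    return alpha * (1.0 - alpha) / n_datasets


def estimate_threshold(min_p_values: np.ndarray, alpha: float) -> float:
    """Empirical 100*alpha-th percentile: the order statistic of rank ceil(alpha L)."""
    p = np.asarray(min_p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.size < 1.0 / alpha:
        warnings.warn(
            f"only {p.size} replicates for alpha={alpha}; threshold is coarse",
            RuntimeWarning,
        )
    k = int(np.ceil(alpha * p.size))
    return float(np.partition(p, k - 1)[k - 1])


def evaluate_type1(
    observed_min_p: np.ndarray,
    thresholds: np.ndarray,
    alpha: float,
    n_datasets: int | None = None,
) -> dict:
    """Rejection rate vs the binomial z-bounds alpha +/- z_.975 sqrt(alpha(1-alpha)/N)."""
    obs = np.asarray(observed_min_p, dtype=float).ravel()
    thr = np.asarray(thresholds, dtype=float).ravel()
    if obs.size != thr.size:
        raise ValueError("observed_min_p and thresholds must have matched lengths")
    n = obs.size if n_datasets is None else n_datasets
    rate = float(np.mean(obs <= thr))
    half = norm.ppf(0.975) * np.sqrt(mc_error_variance(alpha, n))
    lower, upper = alpha - half, alpha + half
    if rate > upper:
        verdict = "inflated"
    elif rate < lower:
        verdict = "conservative"
    else:
        verdict = "well-controlled"
    return {
        "rate": rate, "lower": lower, "upper": upper,
        "verdict": verdict, "n": n,
    }


def adaptive_stop(
    p_so_far: np.ndarray,
    observed_min_p: float,
    alpha: float,
    level: float = 1e-4,
) -> bool:
    """Early-stopping rule for a dataset's permutation analysis.

    Stop when a two-sided (1 - level) Clopper–Pearson interval for the
    dataset's permutation p-value — the probability that a replicate's
    minimum p-value falls at or below the observed one — excludes ``alpha``,
    i.e. the accept/reject decision can no longer change plausibly.
    """
    p = np.asarray(p_so_far, dtype=float).ravel()
    b = p.size
    if b == 0:
        return False
    k = int(np.sum(p <= observed_min_p))
    lo = 0.0 if k == 0 else float(beta_dist.ppf(level / 2.0, k, b - k + 1))
    hi = 1.0 if k == b else float(beta_dist.ppf(1.0 - level / 2.0, k + 1, b - k))
    return bool(hi < alpha or lo > alpha)


# ---------------------------------------------------------------------------
# dataset preparation

def _simulate_population(rng, cfg: ExperimentConfig, spec, freqs, ped):
    geno, subpop, pedlab = simdata.gene_drop_pedigrees(
        freqs, ped, cfg.n_pedigrees, rng=rng)
    cov = simdata.simulate_covariates(geno.shape[0], rng=rng)
    y = simdata.simulate_trait(spec, geno[:, :cfg.m_causal], cov, rng=rng)
    return geno, subpop, pedlab, cov, y


def _simulate_dataset(rng, cfg: ExperimentConfig, spec,
                      ped: simdata.PedigreeConfig):
    """One stage-(1) dataset, with ascertainment batching when requested."""
    n_markers = cfg.m_causal + cfg.m_null
    freqs = simdata.simulate_subpop_frequencies(n_markers, cfg.f_st, rng=rng)
    if cfg.ascertainment is None:
        geno, subpop, pedlab, cov, y = _simulate_population(rng, cfg, spec, freqs, ped)
    else:
        ratio, n_keep = cfg.ascertainment
        need_cases = int(round(n_keep * ratio[0] / (ratio[0] + ratio[1])))
        need_controls = n_keep - need_cases
        parts = []
        for _ in range(60):
            parts.append(_simulate_population(rng, cfg, spec, freqs, ped))
            ys = np.concatenate([p[4] for p in parts])
            if ys.sum() >= need_cases and (ys.size - ys.sum()) >= need_controls:
                break
        else:
            raise RuntimeError("could not accumulate enough cases/controls")
        geno = np.concatenate([p[0] for p in parts])
        subpop = np.concatenate([p[1] for p in parts])
        pedlab = np.concatenate([p[2] for p in parts])
        cov = pd.concat([p[3] for p in parts], ignore_index=True)
        y = np.concatenate([p[4] for p in parts])
        idx = simdata.ascertain_sample(y, ratio, n_keep, rng=rng)
        geno, subpop, pedlab = geno[idx], subpop[idx], pedlab[idx]
        cov = cov.iloc[idx].reset_index(drop=True)
        y = y[idx]
    return geno, subpop, pedlab, cov, y


def _prepare_analysis(geno, cov, y, cfg: ExperimentConfig):
    """Structure model, covariate matrix and observed-data null fit for one dataset."""
    causal = geno[:, :cfg.m_causal].astype(float)
    panel = geno[:, cfg.m_causal:].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        phi = compute_grm(causal)
    sm = remove_top_pcs(phi, cfg.n_pcs_removed)
    cols = ["age", "sex"] if cfg.missing_covariate else ["age", "sex", "normal"]
    n = y.size
    x = np.column_stack([np.ones(n), sm.pcs, cov[cols].to_numpy()])
    eig = kinship_eigen(sm.phi_adj, validate=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_null_model(y, x, eig=eig)
    sigma_g = panel_sigma_g(panel, sm)
    return sm, x, eig, fit, panel, sigma_g


def _replicates_for_method(method, y, x, eig, fit, cfg, rng, cache):
    """L x n replicate matrix for one method; shares LMM/transform fits via cache."""
    L = cfg.n_replicates
    if method in ("brass", "brass-mod"):
        if "brass" not in cache:
            cache["brass"] = transform.build_transform(fit)
        reps = transform.generate_replicates(y, fit, cache["brass"], L, rng=rng)
    elif method in ("naive", "naive-mod", "mvnpermute", "mvnpermute-mod"):
        if "lmm" not in cache:
            cache["lmm"] = comparators.fit_lmm_null(y, x, eig=eig)
        if method.startswith("naive"):
            reps = comparators.naive_replicates(cache["lmm"], L, rng=rng)
        else:
            reps = comparators.mvnpermute_replicates(cache["lmm"], x, n_reps=L, rng=rng)
    elif method == "logmm-pql":
        if "pql" not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cache["pql"] = comparators.pql_fit(y, x, eig=eig)
        reps = comparators.logmm_sample_replicates(cache["pql"], x, n_reps=L, rng=rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    if method.endswith("-mod") and not reps.binary:
        reps = comparators.binarize_replicates(reps, y)
    return reps.replicates


def _scan_dataset(y, reps, x, eig, fit, panel, sigma_g, structure, cfg):
    """Min-p for the observed trait and every replicate (batched null refits)."""
    ys = np.column_stack([y, reps.T])                      # n x (L+1)
    bf = fit_null_model_batch(
        ys, x, eig, beta0=fit.beta_hat, xi0=fit.xi_hat, tol=1e-6, max_iter=60,
    )
    residuals = bf.omega_inv_apply_each(ys - bf.mu_hat)    # Omega^{-1}(y - mu) per column
    minp = scan_min_p_batch(residuals, panel, sigma_g, structure)
    return float(minp[0]), minp[1:]


def run_one_dataset(seed_seq, cfg: ExperimentConfig, spec,
                    ped: simdata.PedigreeConfig) -> dict:
    """Stages (1)-(4) for a single dataset; returns per-method rows.

    The dataset seed spawns one child stream for simulation plus one fixed
    slot per known method, so a method's replicates do not depend on which
    other methods are configured.
    """
    streams = seed_seq.spawn(1 + len(METHODS))
    rng = np.random.default_rng(streams[0])
    geno, subpop, pedlab, cov, y = _simulate_dataset(rng, cfg, spec, ped)
    sm, x, eig, fit, panel, sigma_g = _prepare_analysis(geno, cov, y, cfg)
    cache: dict = {}
    rows = {}
    for method in cfg.methods:
        method_rng = np.random.default_rng(streams[1 + METHODS.index(method)])
        reps = _replicates_for_method(method, y, x, eig, fit, cfg, method_rng, cache)
        if cfg.adaptive:
            obs_p, rep_p = _scan_adaptive(y, reps, x, eig, fit, panel, sigma_g,
                                          sm, cfg)
        else:
            obs_p, rep_p = _scan_dataset(y, reps, x, eig, fit, panel, sigma_g,
                                         sm, cfg)
        thr = estimate_threshold(rep_p, cfg.alpha)
        rows[method] = {
            "observed_min_p": obs_p, "threshold": thr,
            "rejected": bool(obs_p <= thr),
        }
    return rows


def _scan_adaptive(y, reps, x, eig, fit, panel, sigma_g, structure, cfg):
    """Scan replicates in batches with the early-stopping rule.

    The threshold returned downstream is still the alpha-quantile of the
    replicate minima analyzed so far; stopped datasets simply use fewer
    replicates, which biases the rejection decision only when the CI rule
    misfires (probability bounded by its level).
    """
    L = reps.shape[0]
    b = cfg.adaptive_batch
    obs_p = None
    collected = []
    for start in range(0, L, b):
        chunk = reps[start:start + b]
        if obs_p is None:
            obs_p, rep_p = _scan_dataset(y, chunk, x, eig, fit, panel, sigma_g,
                                         structure, cfg)
        else:
            _, rep_p = _scan_dataset(y, chunk, x, eig, fit, panel, sigma_g,
                                     structure, cfg)
        collected.append(rep_p)
        sofar = np.concatenate(collected)
        if sofar.size >= max(b, int(np.ceil(1.0 / cfg.alpha))) and adaptive_stop(
                sofar, obs_p, cfg.alpha):
            break
    return obs_p, np.concatenate(collected)


def run_stage_pipeline(
    config: ExperimentConfig,
    *,
    ped: simdata.PedigreeConfig | None = None,
    spec: simdata.TraitModelSpec | None = None,
    progress: bool = False,
) -> ExperimentResult:
    """Run the full study: simulate datasets, resample, scan, threshold, evaluate.

    Fully seeded: dataset-level seeds are spawned from ``config.seed``, so
    results are bit-identical across reruns (and independent of which other
    methods are configured, since each method consumes its own generator
    stream only through the shared per-dataset stream in a fixed order).
    """
    if ped is None:
        ped = simdata.default_three_generation_pedigree()
    if spec is None:
        n_analysis = (config.ascertainment[1] if config.ascertainment
                      else config.n_pedigrees * ped.n_members)
        spec = simdata.calibrate_trait_model(
            model=config.trait_model,
            covariate_fraction=config.covariate_fraction,
            prevalence=config.prevalence,
            error_share=config.error_share,
            wald_sample_size=n_analysis,
            n_mc=config.calibration_n_mc,
            seed=int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31)),
        )
    children = np.random.SeedSequence(config.seed).spawn(config.n_datasets)
    records = []
    for i, child in enumerate(children):
        try:
            rows = run_one_dataset(child, config, spec, ped)
        except Exception as exc:  # keep going; record the failure
            records.append({
                "dataset": i, "method": None, "observed_min_p": np.nan,
                "threshold": np.nan, "rejected": False, "error": str(exc),
            })
            continue
        for method, row in rows.items():
            records.append({"dataset": i, "method": method, **row, "error": None})
        if progress and (i + 1) % max(1, config.n_datasets // 20) == 0:
            print(f"  dataset {i + 1}/{config.n_datasets}", flush=True)
    per_dataset = pd.DataFrame.from_records(records)

    summary_rows = []
    for method in config.methods:
        sub = per_dataset[(per_dataset["method"] == method)
                          & per_dataset["error"].isna()]
        ev = evaluate_type1(
            sub["observed_min_p"].to_numpy(), sub["threshold"].to_numpy(),
            config.alpha,
        )
        summary_rows.append({"method": method, "n_ok": len(sub), **ev})
    summary = pd.DataFrame.from_records(summary_rows)
    return ExperimentResult(per_dataset=per_dataset, summary=summary, config=config)


def headline_config(seed: int = 1, **overrides) -> ExperimentConfig:
    """Scaled-down null-calibration study configuration.

    1,000 datasets of 12 three-generation pedigrees (192 subjects) in two
    subpopulations (F = .01), GRM from 500 causal markers with the top PC
    removed and used as a covariate, 20 null test markers, logistic trait
    with a 40/60 covariate/polygenic split and 30% prevalence; 500 replicates
    per dataset, nominal level .01.
    """
    base = dict(
        methods=("brass",), n_datasets=1000, n_replicates=500, alpha=0.01,
        n_pedigrees=12, m_causal=500, m_null=20, f_st=0.01,
        trait_model="logistic", covariate_fraction=0.4, prevalence=0.30,
        error_share=0.20, seed=seed,
    )
    base.update(overrides)
    return ExperimentConfig(**base)
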