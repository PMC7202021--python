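"""REML variance partitioning of traits into genetic and methylation components.

The trait model for plant-level observations y is the nested pair

    reduced:  y = 1 mu + Z_g v + e,            v ~ N(0, s2_g G)
    full:     y = 1 mu + Z_g v + Z_m r + e,    r ~ N(0, s2_m M)

with Z_g allocating plants to clone groups (carrying the genomic relatedness
G) and Z_m allocating plants to accessions (carrying the CG-methylation
similarity M).  Fitting maximizes the restricted likelihood of

    V = s2_g Z_g G Z_g' + s2_m Z_m M Z_m' + s2_e I

over log-variances, so components are non-negative by construction.  The
support for the methylation component is a likelihood-ratio test of the full
against the reduced model referred to chi-squared with one degree of freedom
— conservative at the s2_m = 0 boundary, where the true null is a
half-and-half mixture of chi0 and chi1.  Reported summaries are
mean-standardized (Houle's I = s2 / ybar^2, printed x100) and variance
fractions H2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .io_formats import PhenotypeTable
from .relatedness import CovarianceStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VariancePartition",
    "StandardizedReport",
    "build_model_spec",
    "incidence_matrix",
    "fit_reduced",
    "fit_full",
    "marginal_methylation_fit",
    "lrt",
    "lrt_pvalue",
    "standardize",
    "heritability_from_components",
    "restricted_loglik",
    "blup",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-10  # relative to Var(y); hard lower bound of the search
_BOUNDARY_TOL = 1e-6  # relative to Var(y); below this a component is "at boundary"


def incidence_matrix(groups: list[str], labels: list[str]) -> np.ndarray:
    """0/1 matrix allocating observations (rows) to group levels (columns)."""
    index = {lab: j for j, lab in enumerate(labels)}
    z = np.zeros((len(groups), len(labels)))
    for i, g in enumerate(groups):
        if g not in index:
            raise KeyError(f"group {g!r} has no row in the covariance structure")
        z[i, index[g]] = 1.0
    return z


@dataclass
class ModelSpec:
    """Data and structure for one trait/environment variance-partition fit."""

    y: np.ndarray
    plant_ids: list[str]
    z_g: np.ndarray | None = None
    k_g: CovarianceStructure | None = None
    z_m: np.ndarray | None = None
    k_m: CovarianceStructure | None = None
    trait: str = "trait"
    environment: str | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        n = self.y.size
        n_levels = 1  # intercept
        for z, k, name in ((self.z_g, self.k_g, "genetic"), (self.z_m, self.k_m, "methylation")):
            if (z is None) != (k is None):
                raise ValueError(f"{name}: incidence and covariance must be supplied together")
            if z is not None:
                if z.shape[0] != n:
                    raise ValueError(f"{name} incidence has {z.shape[0]} rows for {n} observations")
                if z.shape[1] != k.n:
                    raise ValueError(f"{name} incidence columns do not match covariance dimension")
                n_levels += z.shape[1]
        if self.z_g is None and self.z_m is None:
            raise ValueError("model needs at least one random-effect structure")
        if n < n_levels + 3:
            warnings.warn(
                f"only {n} observations for {n_levels} fixed+group levels; "
                "variance components will be weakly identified",
                stacklevel=2,
            )

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def y_mean(self) -> float:
        return float(self.y.mean())


@dataclass
class VariancePartition:
    """Fitted variance components of one REML model."""

    sigma2_g: float | None
    sigma2_m: float | None
    sigma2_e: float
    reml_loglik: float
    converged: bool
    iterations: int
    n_obs: int = 0
    boundary: dict = field(default_factory=dict)
    cov_scale: dict = field(default_factory=dict)
    degenerate: bool = False

    def components(self) -> dict[str, float]:
        out = {}
        if self.sigma2_g is not None:
            out["genetic"] = self.sigma2_g
        if self.sigma2_m is not None:
            out["methylation"] = self.sigma2_m
        out["residual"] = self.sigma2_e
        return out

    def fractions(self) -> dict[str, float]:
        """Variance fractions on the observation scale.

        Each component is weighted by the mean diagonal of its induced
        covariance Z K Z' (recorded at fit time), so the fractions sum the
        per-plant variance each effect actually contributes even when K is
        not scaled to unit mean diagonal.
        """
        weights = {}
        for name, s2 in self.components().items():
            weights[name] = s2 * self.cov_scale.get(name, 1.0)
        total = sum(weights.values())
        if total <= 0:
            return {name: 0.0 for name in weights}
        return {name: w / total for name, w in weights.items()}


@dataclass
class StandardizedReport:
    """Mean-standardized components (x100) and variance fractions for one trait."""

    i_a: float
    i_m: float
    i_res: float
    h2_snp: float
    h2_cg: float
    lrt_stat: float | None = None
    lrt_p: float | None = None


def build_model_spec(
    pheno: PhenotypeTable,
    trait: str,
    environment: str,
    grm: CovarianceStructure | None = None,
    methmat: CovarianceStructure | None = None,
) -> ModelSpec:
    """Assemble y and the incidence structures for one trait/environment.

    Plants with a missing value for this trait are dropped for this fit only.
    Covariance structures are taken as given; PSD bending happens inside the
    fit when needed.
    """
    if trait not in pheno.trait_names:
        raise KeyError(f"trait {trait!r} not in phenotype table (have {pheno.trait_names})")
    d = pheno.data
    d = d.loc[(d["environment"] == environment) & d[trait].notna()]
    if d.empty:
        raise ValueError(f"no observations for trait {trait!r} in environment {environment!r}")
    y = d[trait].to_numpy(dtype=float)
    z_g = k_g = z_m = k_m = None
    if grm is not None:
        z_g = incidence_matrix(d["clone_group"].tolist(), grm.labels)
        k_g = grm
    if methmat is not None:
        z_m = incidence_matrix(d["accession_id"].tolist(), methmat.labels)
        k_m = methmat
    return ModelSpec(
        y=y,
        plant_ids=d["plant_id"].tolist(),
        z_g=z_g,
        k_g=k_g,
        z_m=z_m,
        k_m=k_m,
        trait=trait,
        environment=environment,
    )


# --- restricted likelihood machinery -------------------------------------------------

def _reml_nll_grad(theta: np.ndarray, y: np.ndarray, covs: list[np.ndarray]):
    """Negative restricted log-likelihood and its gradient on the log-variance scale.

    Fixed effects are intercept-only.  Returns (+inf, 0-gradient) when V is
    numerically indefinite so the optimizer backs off.
    """
    n = y.size
    s2 = np.exp(theta)
    v = np.zeros((n, n))
    for s, k in zip(s2, covs):
        v += s * k
    try:
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    vi_one = vi.sum(axis=1)
    xtvix = float(vi_one.sum())
    if xtvix <= 0:
        return np.inf, np.zeros_like(theta)
    p = vi - np.outer(vi_one, vi_one) / xtvix
    py = p @ y
    ypy = float(y @ py)
    nll = 0.5 * ((n - 1) * _LOG2PI + logdet_v + np.log(xtvix) + ypy)
    grad = np.empty_like(theta)
    for j, k in enumerate(covs):
        tr_pk = float(np.sum(p * k))
        quad = float(py @ (k @ py))
        grad[j] = 0.5 * s2[j] * (tr_pk - quad)
    return nll, grad


def _fit_reml(
    y: np.ndarray,
    covs: list[np.ndarray],
    names: list[str],
    max_iter: int = 200,
) -> dict:
    """Maximize the restricted likelihood over log variance components.

    Components are parameterized as log(sigma2) with a hard floor, giving
    non-negativity; quasi-Newton steps use the analytic gradient, with a
    derivative-free polish if the gradient-based search reports failure.
    y is standardized internally for conditioning and estimates mapped back.
    """
    n = y.size
    vary = float(np.var(y))
    if vary <= 0.0 or not np.isfinite(vary):
        return {
            "sigma2": {name: 0.0 for name in names},
            "loglik": np.nan,
            "converged": True,
            "iterations": 0,
            "boundary": {name: True for name in names},
            "degenerate": True,
        }
    scale = np.sqrt(vary)
    ys = y / scale
    k = len(covs)
    lo, hi = np.log(_VAR_FLOOR), np.log(1e4)
    x0 = np.full(k, np.log(1.0 / k))
    res = optimize.minimize(
        _reml_nll_grad,
        x0,
        args=(ys, covs),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * k,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    theta, nll, n_iter, ok = res.x, res.fun, res.nit, bool(res.success)
    if not ok:
        polish = optimize.minimize(
            lambda t: _reml_nll_grad(t, ys, covs)[0],
            theta,
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-10, "fatol": 1e-12},
        )
        if polish.fun <= nll:
            theta, nll = polish.x, polish.fun
            n_iter += polish.nit
            ok = bool(polish.success)
    theta = np.clip(theta, lo, hi)
    s2_scaled = np.exp(theta)
    sigma2 = {name: float(s * vary) for name, s in zip(names, s2_scaled)}
    boundary = {name: bool(s <= _BOUNDARY_TOL) for name, s in zip(names, s2_scaled)}
    loglik = -nll - (n - 1) * np.log(scale)
    if not ok:
        logger.warning("REML did not report convergence after %d iterations", n_iter)
    return {
        "sigma2": sigma2,
        "loglik": float(loglik),
        "converged": ok,
        "iterations": int(n_iter),
        "boundary": boundary,
        "degenerate": False,
    }


def _induced_cov(z: np.ndarray, k: CovarianceStructure) -> np.ndarray:
    kb = k.bend()
    return z @ kb.values @ z.T


def _assemble(spec: ModelSpec, use_g: bool, use_m: bool):
    covs, names, scales = [], [], {}
    n = spec.n_obs
    if use_g:
        if spec.k_g is None:
            raise ValueError("model requires a genomic relatedness structure")
        c = _induced_cov(spec.z_g, spec.k_g)
        covs.append(c)
        names.append("genetic")
        scales["genetic"] = float(np.trace(c)) / n
    if use_m:
        if spec.k_m is None:
            raise ValueError("model requires a methylation similarity structure")
        c = _induced_cov(spec.z_m, spec.k_m)
        covs.append(c)
        names.append("methylation")
        scales["methylation"] = float(np.trace(c)) / n
    covs.append(np.eye(n))
    names.append("residual")
    scales["residual"] = 1.0
    return covs, names, scales


def _package(fit: dict, names: list[str], scales: dict, n_obs: int) -> VariancePartition:
    s2 = fit["sigma2"]
    return VariancePartition(
        sigma2_g=s2.get("genetic"),
        sigma2_m=s2.get("methylation"),
        sigma2_e=s2["residual"],
        reml_loglik=fit["loglik"],
        converged=fit["converged"],
        iterations=fit["iterations"],
        n_obs=n_obs,
        boundary=fit["boundary"],
        cov_scale=scales,
        degenerate=fit["degenerate"],
    )


def fit_reduced(spec: ModelSpec, max_iter: int = 200) -> VariancePartition:
    """Genetics-only model: V = s2_g Z_g G Z_g' + s2_e I."""
    covs, names, scales = _assemble(spec, use_g=True, use_m=False)
    return _package(_fit_reml(spec.y, covs, names, max_iter), names, scales, spec.n_obs)


def fit_full(spec: ModelSpec, max_iter: int = 200) -> VariancePartition:
    """Joint model: V = s2_g Z_g G Z_g' + s2_m Z_m M Z_m' + s2_e I."""
    covs, names, scales = _assemble(spec, use_g=True, use_m=True)
    return _package(_fit_reml(spec.y, covs, names, max_iter), names, scales, spec.n_obs)


def marginal_methylation_fit(spec: ModelSpec, max_iter: int = 200) -> VariancePartition:
    """Methylation-only model, used to demonstrate confounding with genetics.

    When methylation similarity tracks the clone-group structure, this fit
    absorbs genetic variance into the methylation component; only the joint
    model separates the two.
    """
    covs, names, scales = _assemble(spec, use_g=False, use_m=True)
    return _package(_fit_reml(spec.y, covs, names, max_iter), names, scales, spec.n_obs)


def restricted_loglik(
    spec: ModelSpec,
    sigma2_g: float | None = None,
    sigma2_m: float | None = None,
    sigma2_e: float = 1.0,
) -> float:
    """Evaluate the restricted log-likelihood at fixed variance components."""
    covs, names, _ = _assemble(spec, use_g=sigma2_g is not None, use_m=sigma2_m is not None)
    s2 = [s for s in (sigma2_g, sigma2_m) if s is not None] + [sigma2_e]
    n = spec.n_obs
    v = np.zeros((n, n))
    for s, k in zip(s2, covs):
        v += float(s) * k
    c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    vi_one = vi.sum(axis=1)
    xtvix = float(vi_one.sum())
    p = vi - np.outer(vi_one, vi_one) / xtvix
    ypy = float(spec.y @ (p @ spec.y))
    return -0.5 * ((n - 1) * _LOG2PI + logdet_v + np.log(xtvix) + ypy)


def lrt(full: VariancePartition, reduced: VariancePartition) -> tuple[float, float]:
    """Likelihood-ratio test of the extra variance component.

    stat = 2 (ll_full - ll_reduced), clipped at zero, referred to chi2(1).
    REML likelihoods are comparable here because both models share the same
    (intercept-only) fixed effects.
    """
    if not (full.converged and reduced.converged):
        warnings.warn("LRT computed from a non-converged fit", stacklevel=2)
    diff = full.reml_loglik - reduced.reml_loglik
    if diff < -1e-6:
        warnings.warn(
            f"full-model log-likelihood is below the reduced model by {-diff:.3g}; "
            "optimizer failure suspected, statistic clipped to 0",
            stacklevel=2,
        )
    stat = max(0.0, 2.0 * diff)
    return stat, lrt_pvalue(stat)


def lrt_pvalue(stat: float, df: int = 1) -> float:
    """Upper-tail chi-squared probability of the LRT statistic."""
    if stat < 0:
        raise ValueError("LRT statistic must be non-negative")
    return float(stats.chi2.sf(stat, df))


def heritability_from_components(i_a: float, i_m: float, i_res: float) -> tuple[float, float]:
    """Variance fractions from (mean-standardized) components; scaling cancels."""
    total = i_a + i_m + i_res
    if total <= 0:
        raise ValueError("total variance must be positive")
    return i_a / total, i_m / total


def standardize(
    fit: VariancePartition,
    y_mean: float,
    lrt_result: tuple[float, float] | None = None,
) -> StandardizedReport:
    """Mean-standardized components I = 100 s2 / ybar^2 and variance fractions."""
    if y_mean == 0:
        raise ValueError("mean-standardization undefined for a zero trait mean")
    if fit.degenerate:
        raise ValueError("cannot standardize a degenerate (zero-variance) fit")
    s2_g = fit.sigma2_g or 0.0
    s2_m = fit.sigma2_m or 0.0
    s2_e = fit.sigma2_e
    m2 = y_mean**2
    h2_snp, h2_cg = heritability_from_components(s2_g, s2_m, s2_e)
    stat, p = lrt_result if lrt_result is not None else (None, None)
    return StandardizedReport(
        i_a=100.0 * s2_g / m2,
        i_m=100.0 * s2_m / m2,
        i_res=100.0 * s2_e / m2,
        h2_snp=h2_snp,
        h2_cg=h2_cg,
        lrt_stat=stat,
        lrt_p=p,
    )


def blup(spec: ModelSpec, fit: VariancePartition) -> dict[str, np.ndarray]:
    """Best linear unbiased predictions of the group-level random effects.

    u_hat = s2 K Z' V^{-1} (y - 1 mu_hat) per component.  Exposed for
    completeness; the headline reports use only the variance components.
    """
    covs, names, _ = _assemble(spec, use_g=fit.sigma2_g is not None, use_m=fit.sigma2_m is not None)
    s2_list = [fit.components()[name] for name in names]
    n = spec.n_obs
    v = np.zeros((n, n))
    for s, k in zip(s2_list, covs):
        v += s * k
    c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    one = np.ones(n)
    vi_y = linalg.cho_solve((c, low), spec.y, check_finite=False)
    vi_one = linalg.cho_solve((c, low), one, check_finite=False)
    mu = float(one @ vi_y) / float(one @ vi_one)
    resid = spec.y - mu
    vi_resid = linalg.cho_solve((c, low), resid, check_finite=False)
    out: dict[str, np.ndarray] = {}
    if fit.sigma2_g is not None:
        out["genetic"] = fit.sigma2_g * (spec.k_g.bend().values @ (spec.z_g.T @ vi_resid))
    if fit.sigma2_m is not None:
        out["methylation"] = fit.sigma2_m * (spec.k_m.bend().values @ (spec.z_m.T @ vi_resid))
    return out
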