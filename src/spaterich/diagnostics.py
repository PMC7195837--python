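"""Model comparison and post-fit summaries.

DIC compares the spatial-error structures (mesh + square vs square-only
vs mesh-only), the variance partition quantifies how much of the random
effect variation the structured field absorbs relative to the iid
square effects, and partial-effect curves trace the predicted response
along one covariate (e.g. the nitrogen-deposition gradient) with every
other covariate held at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .inference import DEFAULT_SEED, FitResult

__all__ = [
    "DicResult",
    "VariancePartition",
    "PartialEffectCurve",
    "dic",
    "variance_partition",
    "percentile_grid",
    "partial_effect",
]


@dataclass(frozen=True)
class DicResult:
    """Deviance information criterion pieces: DIC = dhat + 2 pd."""

    dbar: float   # posterior mean deviance
    dhat: float   # deviance at the plug-in (posterior mean linear predictor)
    pd: float     # effective number of parameters, dbar - dhat
    dic: float
    pd_negative: bool  # flagged, never hidden

    def delta(self, other: "DicResult") -> float:
        return self.dic - other.dic


def _deviance(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """-2 log PoissonPMF(y | exp(eta)); eta may be (draws, n) or (n,)."""
    lam = np.exp(eta)
    ll = y * eta - lam - special.gammaln(y + 1.0)
    return -2.0 * ll.sum(axis=-1)


def dic(fit_result: FitResult, n_draws: int = 1000, seed: int = DEFAULT_SEED) -> DicResult:
    """DIC with the plug-in deviance evaluated at the posterior mean of eta.

    The hierarchical-model convention (plug in the mean *linear
    predictor*, not the mean rate) keeps the effective parameter count
    non-negative in practice; a negative ``pd`` is still reported and
    flagged rather than clipped.
    """
    y = fit_result.y
    eta = fit_result.eta_draws(n_draws=n_draws, seed=seed)
    dbar = float(_deviance(y, eta).mean())
    dhat = float(_deviance(y, fit_result.eta_mean()))
    pd_ = dbar - dhat
    return DicResult(dbar=dbar, dhat=dhat, pd=pd_, dic=dhat + 2.0 * pd_,
                     pd_negative=pd_ < 0)


@dataclass(frozen=True)
class VariancePartition:
    """Share of random-effect variance captured by the structured field.

    Both variances are empirical variances of posterior means evaluated
    at the plot locations (one defensible definition among several; see
    the methods note).
    """

    var_structured: float
    var_iid: float

    @property
    def percent_structured(self) -> float:
        tot = self.var_structured + self.var_iid
        if tot == 0:
            return 100.0  # both components flat: attribute all (of nothing)
        return round(100.0 * self.var_structured / tot, 1)


def variance_partition(fit_result: FitResult) -> VariancePartition:
    spec = fit_result.spec
    if not (spec.has_mesh and spec.has_square):
        raise ValueError(
            f"structure {spec.structure!r} lacks one of the two random components; "
            "use the posterior sd of the single component instead"
        )
    asm = fit_result._asm
    state = fit_result.state_mean()
    field_at_plots = np.asarray(asm.A @ state.w)
    iid_at_plots = state.u[asm.membership]
    vs = float(np.var(field_at_plots))
    vi = float(np.var(iid_at_plots))
    return VariancePartition(var_structured=vs, var_iid=vi)


def percentile_grid(values: np.ndarray) -> np.ndarray:
    """0th, 10th, ..., 100th percentiles (linear interpolation), deduplicated."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.all(v == v.flat[0]):
        raise ValueError("need at least two distinct values for a percentile grid")
    grid = np.percentile(v, np.arange(0, 101, 10))
    return np.unique(grid)  # sorted, strictly increasing


@dataclass(frozen=True)
class PartialEffectCurve:
    covariate: str
    grid: np.ndarray
    median: np.ndarray
    mean: np.ndarray
    lower: np.ndarray   # 2.5%
    upper: np.ndarray   # 97.5%


def partial_effect(
    fit_result: FitResult,
    covariate: str,
    grid: np.ndarray | None = None,
    n_draws: int = 4000,
    seed: int = DEFAULT_SEED,
) -> PartialEffectCurve:
    """Predicted response exp(beta0 + beta_cov * x) along ``grid``.

    Joint posterior draws of (beta0, beta_cov) preserve their
    correlation; all other covariates sit at zero, so the absolute
    level is the baseline-plot prediction, not a population mean.
    By construction the curve at x = 0 is the posterior summary of
    exp(beta0).
    """
    names = fit_result.fixed_names()
    if covariate not in names[1:]:
        raise KeyError(f"unknown covariate {covariate!r}; available: {names[1:]}")
    j = names.index(covariate)
    if grid is None:
        asm = fit_result._asm
        col = list(fit_result.spec.covariates).index(covariate)
        grid = percentile_grid(asm.X[:, col])
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    rng = np.random.default_rng(seed)
    means, covs = fit_result.fixed_joint()
    if fit_result.method == "mcmc":
        draws_full = fit_result.latent_draws(n_draws, seed=seed)
        fs = fit_result._asm.fixed_slice
        b0 = draws_full[:, fs.start]
        bj = draws_full[:, fs.start + j]
    else:
        counts = rng.multinomial(n_draws, fit_result.grid_weights)
        b0_parts, bj_parts = [], []
        idx = np.array([0, j])
        for k, c in enumerate(counts):
            if c == 0:
                continue
            mu = means[k][idx]
            S = covs[k][np.ix_(idx, idx)]
            d = rng.multivariate_normal(mu, S, size=c)
            b0_parts.append(d[:, 0])
            bj_parts.append(d[:, 1])
        b0 = np.concatenate(b0_parts)
        bj = np.concatenate(bj_parts)

    eta = b0[:, None] + bj[:, None] * grid[None, :]
    pred = np.exp(eta)
    return PartialEffectCurve(
        covariate=covariate,
        grid=grid,
        median=np.quantile(pred, 0.5, axis=0),
        mean=pred.mean(axis=0),
        lower=np.quantile(pred, 0.025, axis=0),
        upper=np.quantile(pred, 0.975, axis=0),
    )
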