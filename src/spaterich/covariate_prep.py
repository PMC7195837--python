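"""Covariate preparation for gradient-survey regression tables.

Turns raw plot-level covariates into an analysis-ready design matrix:
divisor rescaling (so coefficients read as "change in richness per 100 m
of altitude", "per 250 mm of rainfall", ...), pairwise collinearity
screening, mean imputation of missing values, PCA compression of a block
of strongly inter-correlated climate variables, and variance inflation
factors.  Screening only *reports*; no column is ever dropped
automatically — collinear pollutant pairs stay in the model because they
are the scientific question, and stepwise selection is deliberately
unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "CovariateSpec",
    "DesignMatrix",
    "rescale_covariate",
    "correlation_screen",
    "mean_impute",
    "climate_pca",
    "vif",
    "encode_grazing",
    "prepare_design",
]

_ROLES = ("pollutant", "climate", "terrain", "soil", "management")


@dataclass(frozen=True)
class CovariateSpec:
    """Metadata for one covariate: units and the divisor used to rescale it.

    ``divisor`` is the amount of the original unit that one rescaled unit
    represents (altitude in m with divisor 100 -> coefficient per 100 m).
    """

    name: str
    original_units: str = ""
    divisor: float = 1.0
    role: str = "terrain"

    def __post_init__(self) -> None:
        if not np.isfinite(self.divisor) or self.divisor <= 0:
            raise ValueError(f"divisor must be > 0, got {self.divisor!r}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")


@dataclass
class DesignMatrix:
    """An ordered, complete (no-missing) covariate matrix.

    Column order is part of the contract: coefficients are reported in
    this order and it is recorded in provenance logs.
    """

    columns: list[str]
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"{len(self.columns)} column names but {self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValueError(f"non-finite design entries at (row, col) {bad[:5].tolist()}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return len(self.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)


def rescale_covariate(
    values: np.ndarray, spec: CovariateSpec, decimals: int = 2
) -> np.ndarray:
    """Divide ``values`` by ``spec.divisor`` and round to ``decimals``.

    Rounding matches how rescaled ranges are reported; keep
    ``decimals`` large (or use the unrounded quotient) when full
    precision is needed internally.
    """
    v = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isfinite(v))
    if bad.size:
        raise ValueError(f"non-finite value for {spec.name!r} at row {int(bad[0])}")
    return np.round(v / spec.divisor, decimals)


def correlation_screen(
    X: DesignMatrix | pd.DataFrame, threshold: float = 0.7
) -> list[tuple[tuple[str, str], float]]:
    """All covariate pairs with \\|Pearson r\\| above ``threshold``.

    Returns ``[((name_a, name_b), r), ...]`` sorted by descending \\|r\\|.
    Zero-variance columns are excluded from pairing (and named in the
    provenance of a :class:`DesignMatrix` input).  Nothing is dropped:
    the caller decides what, if anything, to do about collinearity.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    df = X.to_frame() if isinstance(X, DesignMatrix) else X
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need at least 2 columns and 3 rows")
    sd = df.std(ddof=1)
    degenerate = list(sd.index[sd == 0])
    live = df.drop(columns=degenerate)
    if isinstance(X, DesignMatrix):
        for name in degenerate:
            X.provenance.append(f"correlation_screen: zero-variance column {name!r} excluded")
    corr = live.corr(method="pearson")
    out: list[tuple[tuple[str, str], float]] = []
    cols = list(corr.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(corr.iloc[i, j])
            if abs(r) > threshold:
                out.append(((cols[i], cols[j]), r))
    out.sort(key=lambda pr: -abs(pr[1]))
    return out


def mean_impute(values: np.ndarray, name: str = "column") -> np.ndarray:
    """Replace NaNs by the mean of the observed entries."""
    v = np.asarray(values, dtype=float).copy()
    miss = np.isnan(v)
    if miss.all():
        raise ValueError(f"column {name!r} is entirely missing; cannot impute")
    if miss.any():
        v[miss] = v[~miss].mean()
    return v


def climate_pca(
    Z: np.ndarray | pd.DataFrame, column_names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First two principal components of a block of climate covariates.

    The block is standardized column-wise first (the inputs mix units —
    mm, degrees C — so the correlation matrix is the right metric), and each
    component's sign is fixed so that its loading on the first input
    column is non-negative.  Returns ``(scores, loadings,
    variance_fractions)`` where ``scores`` has the two columns
    ``Climate PC1`` / ``Climate PC2`` in order.
    """
    if isinstance(Z, pd.DataFrame):
        column_names = list(Z.columns)
        Z = Z.to_numpy(dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 3:
        raise ValueError("need a 2-D block with at least 3 rows")
    if np.isnan(Z).any():
        raise ValueError("impute missing values before PCA")
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        name = column_names[idx] if column_names else f"column {idx}"
        raise ValueError(f"constant climate column {name!r} cannot be standardized")
    Zs = (Z - Z.mean(axis=0)) / sd
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Zs)
    loadings = pca.components_
    # sign convention: loading on the first input variable >= 0
    for k in range(2):
        if loadings[k, 0] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    fractions = pca.explained_variance_ratio_
    return scores, loadings, fractions


def vif(
    X: DesignMatrix | pd.DataFrame, group: np.ndarray | None = None
) -> pd.Series:
    """Variance inflation factor of each column.

    Classical definition: ``VIF_m = 1 / (1 - R^2_m)`` with ``R^2_m`` from
    the OLS regression of column *m* on an intercept plus every other
    column.  With ``group`` (e.g. 1-km-square ids) the auxiliary
    regressions additionally condition on group means, a linear proxy
    for the random-intercept models sometimes used for this check.
    Perfectly collinear columns get ``inf``.
    """
    df = X.to_frame() if isinstance(X, DesignMatrix) else X
    n, m = df.shape
    if n <= m:
        raise ValueError(f"need more rows ({n}) than columns ({m})")
    sd = df.std(ddof=1)
    if np.any(sd == 0):
        raise ValueError(f"constant column {sd.index[np.argmin(sd.to_numpy())]!r}")
    V = df.to_numpy(dtype=float)
    extra = np.empty((n, 0))
    if group is not None:
        codes, _ = pd.factorize(np.asarray(group))
        gm = np.zeros((n, m))
        for g in range(codes.max() + 1):
            mask = codes == g
            gm[mask] = V[mask].mean(axis=0)
        extra = gm
    out = {}
    for j, name in enumerate(df.columns):
        y = V[:, j]
        others = np.delete(V, j, axis=1)
        design = np.column_stack([np.ones(n), others, extra])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def encode_grazing(levels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Treatment-code a low/medium/high intensity factor, 'low' as reference."""
    s = pd.Series(levels).astype(str).str.lower()
    unknown = sorted(set(s) - {"low", "medium", "high"})
    if unknown:
        raise ValueError(f"unknown grazing levels {unknown}; expected low/medium/high")
    return pd.DataFrame(
        {
            "grazing_medium": (s == "medium").astype(float).to_numpy(),
            "grazing_high": (s == "high").astype(float).to_numpy(),
        }
    )


def prepare_design(
    table: pd.DataFrame,
    specs: list[CovariateSpec],
    climate_block: list[str] | None = None,
    grazing_column: str | None = None,
    screen_threshold: float = 0.7,
) -> DesignMatrix:
    """Full preparation pipeline: impute -> rescale -> PCA -> assemble.

    ``specs`` fixes the column order of the plain covariates; the two
    climate principal components (if ``climate_block`` is given) and the
    grazing indicators (if ``grazing_column`` is given) are appended.
    Rescaled values keep full precision here; 2-decimal rounding is for
    reporting only.  A provenance log records every transformation plus
    the correlation screen and VIFs.
    """
    log: list[str] = []
    cols: list[str] = []
    mats: list[np.ndarray] = []
    for spec in specs:
        if spec.name not in table.columns:
            raise KeyError(f"covariate {spec.name!r} missing from table")
        v = table[spec.name].to_numpy(dtype=float)
        if np.isnan(v).any():
            n_miss = int(np.isnan(v).sum())
            v = mean_impute(v, spec.name)
            log.append(f"imputed {n_miss} missing values in {spec.name!r} by the column mean")
        if spec.divisor != 1.0:
            v = v / spec.divisor
            log.append(f"rescaled {spec.name!r} by divisor {spec.divisor}")
        cols.append(spec.name)
        mats.append(v)
    if climate_block:
        cols_block = []
        for c in climate_block:
            v = table[c].to_numpy(dtype=float)
            n_miss = int(np.isnan(v).sum())
            if n_miss:
                v = mean_impute(v, c)
                log.append(f"imputed {n_miss} missing values in {c!r} by the column mean")
            cols_block.append(v)
        block = np.column_stack(cols_block)
        scores, _, frac = climate_pca(block, list(climate_block))
        log.append(
            f"PCA combined {climate_block} -> Climate PC1/PC2 "
            f"(variance fractions {frac[0]:.3f}, {frac[1]:.3f})"
        )
        cols += ["Climate PC1", "Climate PC2"]
        mats += [scores[:, 0], scores[:, 1]]
    if grazing_column:
        gz = encode_grazing(table[grazing_column])
        log.append(f"treatment-coded {grazing_column!r} (reference: low)")
        cols += list(gz.columns)
        mats += [gz[c].to_numpy() for c in gz.columns]
    X = DesignMatrix(columns=cols, values=np.column_stack(mats), provenance=log)
    pairs = correlation_screen(X, screen_threshold)
    for (a, b), r in pairs:
        log.append(f"high correlation retained: {a!r} ~ {b!r}, r = {r:.3f}")
    vifs = vif(X)
    log.append("VIFs: " + ", ".join(f"{k}={v:.2f}" for k, v in vifs.items()))
    return X
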