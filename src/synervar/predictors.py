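"""Environmental predictor sets: zonal summaries, Shannon land-cover
diversity, linear + quadratic terms, per-set PCA and VIF diagnostics.

Each raw environmental variable is standardized, its square appended (the
square of the centered variable, which keeps linear and quadratic terms
nearly orthogonal), and a PCA is run on the combined matrix; the first k
component-score columns become the set's variables in all downstream models.
PCA is on the correlation matrix — variables are on incommensurate units
(degrees C, mm, m) — and the axis sign is fixed by forcing each axis's
largest-magnitude loading positive, so outputs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy
from sklearn.decomposition import PCA

from .errors import InputError, NumericalError

__all__ = [
    "PredictorSet",
    "zonal_summary",
    "shannon_diversity",
    "build_set",
    "vif",
]

SET_NAMES = ("climatic", "topographic", "biotic", "spatial")


# ---------------------------------------------------------------------------
# zonal statistics
# ---------------------------------------------------------------------------

def zonal_summary(samples, statistic: str) -> pd.Series:
    """Per-cell summary of pixel-level values.

    ``samples`` maps cell id -> 1-D array of pixel values (a dict or a
    DataFrame with ``cell_id``/``value`` columns).  Statistics: ``mean``,
    ``range`` (max - min), ``sd`` (sample, ddof=1) and ``cv`` (sd / mean).
    A cell whose mean is zero has an undefined cv and is returned as NaN
    with a warning so the caller can drop it.
    """
    if statistic not in ("mean", "range", "sd", "cv"):
        raise InputError(f"unknown statistic {statistic!r}")
    if isinstance(samples, pd.DataFrame):
        grouped = {k: v["value"].to_numpy() for k, v in samples.groupby("cell_id")}
    else:
        grouped = {k: np.asarray(v, dtype=float) for k, v in samples.items()}

    out = {}
    dropped = []
    for cell, v in grouped.items():
        if statistic == "mean":
            out[cell] = v.mean()
        elif statistic == "range":
            out[cell] = v.max() - v.min()
        elif statistic == "sd":
            out[cell] = v.std(ddof=1) if v.size > 1 else 0.0
        else:  # cv
            m = v.mean()
            if m == 0:
                out[cell] = np.nan
                dropped.append(cell)
            else:
                out[cell] = (v.std(ddof=1) if v.size > 1 else 0.0) / m
    if dropped:
        warnings.warn(f"cv undefined (zero mean) for cells {dropped}; returned NaN")
    return pd.Series(out, name=statistic)


def shannon_diversity(proportions) -> np.ndarray | float:
    """Shannon index H = -sum p_i ln p_i of class proportions.

    Accepts a single proportion vector or a (cells x classes) matrix; rows
    must be non-negative and sum to 1 (zeros allowed, 0 ln 0 := 0).
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise InputError("proportions must be non-negative")
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise InputError("proportions must sum to 1")
    h = entropy(p, axis=-1)  # natural log, handles zeros
    return float(h) if p.ndim == 1 else h


# ---------------------------------------------------------------------------
# predictor sets
# ---------------------------------------------------------------------------

@dataclass
class PredictorSet:
    """A named predictor set after transformation and PCA axis extraction."""

    name: str
    columns: pd.DataFrame          # standardized linear + quadratic terms
    scores: np.ndarray             # first k PCA component scores (cells x k)
    varexp: np.ndarray             # variance share of every axis (sums to 1)
    vif: np.ndarray                # VIF of each retained axis
    loadings: np.ndarray           # component loadings (variables x k)

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


def build_set(raw: pd.DataFrame, name: str, k: int = 3) -> PredictorSet:
    """Standardize variables, append squared terms, PCA, retain k axes.

    Constant columns are dropped with a warning.  Rank-deficient inputs are
    allowed (trailing axes then carry ~0 variance), but k may not exceed the
    number of columns or n - 1.
    """
    if raw.isna().any().any():
        raise InputError(f"predictor set {name!r} has missing values")
    x = raw.to_numpy(dtype=float)
    keep = np.ptp(x, axis=0) > 0
    if not keep.all():
        dropped = list(raw.columns[~keep])
        warnings.warn(f"dropping constant column(s) {dropped} from set {name!r}")
        x = x[:, keep]
        raw = raw.loc[:, keep]
    if x.shape[1] == 0:
        raise InputError(f"predictor set {name!r} has no non-constant columns")

    z = _standardize(x)
    sq = z**2
    sq_keep = np.ptp(sq, axis=0) > 0
    sq = _standardize(sq[:, sq_keep])
    cols = np.column_stack([z, sq])
    names = [f"{c}" for c in raw.columns] + [f"{c}^2" for c in raw.columns[sq_keep]]
    design = pd.DataFrame(cols, index=raw.index, columns=names)

    n, p = cols.shape
    if k > min(p, n - 1):
        raise InputError(f"k={k} exceeds available rank for set {name!r} (p={p}, n={n})")

    pca = PCA(n_components=p)
    scores_full = pca.fit_transform(cols)
    varexp = pca.explained_variance_ratio_
    load = pca.components_.T  # variables x axes
    # fix axis signs: largest-magnitude loading positive
    flip = load[np.argmax(np.abs(load), axis=0), np.arange(p)] < 0
    load[:, flip] *= -1.0
    scores_full[:, flip] *= -1.0

    scores = scores_full[:, :k]
    return PredictorSet(
        name=name,
        columns=design,
        scores=scores,
        varexp=varexp,
        vif=vif(scores),
        loadings=load[:, :k],
    )


def vif(columns) -> np.ndarray:
    """Variance inflation factor per column: 1 / (1 - R2_j).

    R2_j comes from regressing column j on the other columns plus an
    intercept.  Perfect collinearity yields +inf rather than an exception.
    """
    x = np.asarray(columns, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InputError("VIF needs at least 2 columns")
    n, p = x.shape
    if n <= p + 1:
        raise InputError("VIF needs n > p + 1")
    out = np.empty(p)
    for j in range(p):
        yj = x[:, j]
        design = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss <= 0:
            raise NumericalError("constant column in VIF input")
        r2 = 1.0 - resid @ resid / tss
        out[j] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return out
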