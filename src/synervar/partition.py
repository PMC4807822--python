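"""OLS variation partitioning (commonality analysis) over 2-4 predictor sets.

The explained variation of species richness is decomposed into the 2^k - 1
unique and shared adjusted-R2 fractions of a k-set Venn diagram.  Fractions
are solved by Moebius inversion of the all-subset adjusted R2 values: for
each nonempty union U of sets, adjR2(U) equals the sum of every fraction
whose membership intersects U; inverting that system gives one fraction per
nonempty subset of sets.  Adjusted R2 (not raw R2) is partitioned because
the sets carry unequal numbers of predictors; negative fractions are
reported as computed, never clamped, as is standard commonality-analysis
practice.

Fraction labels follow the conventional lower-case lettering of the k-set
Venn diagram: for four sets in order (s1, s2, s3, s4) the letters a..o, with
a-d the unique fractions, e-j the pairwise, k-n the three-way, and o the
fraction common to all four; for three sets the letters a..g.  Reordering
the sets permutes the labels consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError

__all__ = [
    "OLSFit",
    "PartitionResult",
    "fit_ols",
    "adjusted_r2",
    "solve_fractions",
    "partition",
    "total_importance",
    "run_model_suite",
]


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    """Least-squares fit with R2 and adjusted R2 = 1 - (1-R2)(n-1)/(n-p-1)."""

    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    adj_r2: float
    n: int
    p: int


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R2 with p predictors (intercept excluded from p)."""
    if n <= p + 1:
        raise InputError("insufficient degrees of freedom")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_ols(y: np.ndarray, x: np.ndarray) -> OLSFit:
    """OLS of y on predictors x (intercept added internally).

    A rank-deficient design is fit through the pseudo-inverse with a
    warning.  The adjusted-R2 penalty uses p = effective rank of the design
    excluding the intercept — for full-rank designs this is the column
    count, while duplicated or collinear columns consume no extra degrees
    of freedom (so a predictor set that merely repeats information cannot
    change the adjusted R2 of a union).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape[0], x.shape[1]
    if y.size != n:
        raise InputError("y and design row counts differ")
    if n <= p + 1:
        raise InputError("insufficient degrees of freedom")
    design = np.column_stack([np.ones(n), x]) if p else np.ones((n, 1))
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(f"rank-deficient design (rank {rank} < {design.shape[1]}); pseudo-inverse fit")
    fitted = design @ coef
    resid = y - fitted
    tss = np.sum((y - y.mean()) ** 2)
    if tss <= 0:
        raise NumericalError("constant response")
    r2 = 1.0 - resid @ resid / tss
    p_eff = max(int(rank) - 1, 0)
    return OLSFit(coef=coef, fitted=fitted, residuals=resid, r2=float(r2),
                  adj_r2=adjusted_r2(float(r2), n, p_eff), n=n, p=p_eff)


# ---------------------------------------------------------------------------
# fraction lettering
# ---------------------------------------------------------------------------

def _subset_order(k: int) -> list[tuple[int, ...]]:
    """Nonempty subsets of {0..k-1}: singletons, then pairs, ... (each in a
    fixed conventional order so letters match the standard Venn labelling)."""
    if k == 4:
        return [
            (0,), (1,), (2,), (3,),            # a b c d
            (0, 1), (1, 2), (0, 2),            # e f g
            (0, 3), (1, 3), (2, 3),            # h i j
            (0, 1, 3), (0, 1, 2), (1, 2, 3), (0, 2, 3),  # k l m n
            (0, 1, 2, 3),                      # o
        ]
    if k == 3:
        return [(0,), (1,), (2,), (0, 1), (1, 2), (0, 2), (0, 1, 2)]
    if k == 2:
        return [(0,), (1,), (0, 1)]
    raise InputError("partition supports 2 <= k <= 4 sets")


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------

@dataclass
class PartitionResult:
    """Labelled adjusted-R2 fractions of a k-set variation partitioning."""

    set_names: tuple[str, ...]
    labels: tuple[str, ...]
    membership: dict[str, tuple[str, ...]]   # label -> member set names
    values: dict[str, float]                 # label -> fraction
    adj_r2_union: dict[tuple[int, ...], float]  # all-subset model fits
    residual: float                          # 1 - adjR2(full)

    @property
    def adj_r2_full(self) -> float:
        return 1.0 - self.residual

    def total_importance(self, set_name: str) -> float:
        """Sum of all fractions whose membership includes ``set_name``."""
        if set_name not in self.set_names:
            raise InputError(f"unknown set {set_name!r}")
        return float(
            sum(v for lab, v in self.values.items() if set_name in self.membership[lab])
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": lab, "member_sets": "+".join(self.membership[lab]), "value": self.values[lab]}
            for lab in self.labels
        ]
        rows.append({"label": "residual", "member_sets": "", "value": self.residual})
        return pd.DataFrame(rows)


def solve_fractions(
    adj_r2: dict[tuple[int, ...], float], k: int
) -> tuple[tuple[str, ...], list[tuple[int, ...]], np.ndarray]:
    """Invert the union system into unique/shared fractions in closed form.

    ``adj_r2`` maps every nonempty subset of set indices (sorted tuples) to
    the adjusted R2 of that union's model.  Returns (labels, memberships,
    values) where values[i] is the fraction wholly attributable to exactly
    the sets in memberships[i].  The inversion is the Moebius formula over
    the subset lattice of g(V) = adjR2(full) - adjR2(complement of V).
    """
    full = tuple(range(k))
    subsets = _subset_order(k)
    a_full = adj_r2[full]

    def g(v: tuple[int, ...]) -> float:
        if len(v) == 0:
            return 0.0
        if len(v) == k:
            return a_full
        comp = tuple(i for i in range(k) if i not in v)
        return a_full - adj_r2[comp]

    labels = tuple("abcdefghijklmno"[: 2**k - 1])
    values = np.empty(len(subsets))
    for idx, s in enumerate(subsets):
        f = 0.0
        for size in range(0, len(s) + 1):
            for v in combinations(s, size):
                f += (-1) ** (len(s) - size) * g(v)
        values[idx] = f
    return labels, subsets, values


def partition(y: np.ndarray, sets: dict[str, np.ndarray]) -> PartitionResult:
    """Decompose adjusted R2 into the 2^k - 1 unique/shared fractions.

    ``sets`` maps set name -> (cells x variables) matrix; a set may be empty
    (zero columns), in which case every fraction unique to it is exactly 0.
    All 2^k - 1 union models are refit from scratch; the fraction system is
    then solved in closed form by Moebius inversion over the subset lattice.
    """
    names = tuple(sets.keys())
    k = len(names)
    if not 2 <= k <= 4:
        raise InputError("partition supports 2 <= k <= 4 sets")
    mats = [np.asarray(sets[nm], dtype=float) for nm in names]
    mats = [m[:, None] if m.ndim == 1 else m for m in mats]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise InputError("all sets must be defined on the same cells")

    full = tuple(range(k))
    subsets = _subset_order(k)

    # adjusted R2 of every nonempty union of sets
    a: dict[tuple[int, ...], float] = {}
    for size in range(1, k + 1):
        for u in combinations(range(k), size):
            xu = np.column_stack([mats[i] for i in u])
            a[u] = fit_ols(y, xu).adj_r2

    a_full = a[full]

    labels, subsets, frac_values = solve_fractions(a, k)
    values = {lab: float(v) for lab, v in zip(labels, frac_values)}
    membership = {
        lab: tuple(names[i] for i in s) for lab, s in zip(labels, subsets)
    }

    total = sum(values.values())
    if abs(total - a_full) > 1e-8:
        raise NumericalError("fraction system inconsistent with full-model adjusted R2")
    negatives = [lab for lab, v in values.items() if v < -1e-12]
    if negatives:
        warnings.warn(f"negative fraction(s) {negatives}: reported as computed, not clamped")

    return PartitionResult(
        set_names=names,
        labels=labels,
        membership=membership,
        values=values,
        adj_r2_union=a,
        residual=1.0 - a_full,
    )


def total_importance(result: PartitionResult, set_name: str) -> float:
    """Sum of all fractions related to ``set_name`` (unique plus shared)."""
    return result.total_importance(set_name)


# ---------------------------------------------------------------------------
# model suite: environmental and environmental + spatial partitions
# ---------------------------------------------------------------------------

@dataclass
class ModelSuiteResult:
    env_partition: PartitionResult        # 3 environmental sets, labels a..g
    full_partition: PartitionResult       # + spatial filters, labels a..o
    selection: "object"                   # SelectionResult from spatial filtering
    correlogram_before: "object"
    correlogram_after: "object"


def run_model_suite(y, env_sets: dict[str, np.ndarray], basis, coords, cfg=None) -> ModelSuiteResult:
    """Run the full modelling sequence for one richness response.

    1. Partition y over the environmental sets alone (no spatial filters).
    2. Select MEM spatial filters on the residuals of the all-environment
       OLS model until their residual Moran's I drops below threshold.
    3. Partition y over the environmental sets plus the selected filters as
       the spatial set.  With no spatially structured signal beyond the
       environment, zero filters are selected and every spatial fraction
       is exactly zero.
    """
    from .spatial import DistanceClasses, FilterSelectionConfig, correlogram, select_filters

    if cfg is None:
        cfg = FilterSelectionConfig()
    y = np.asarray(y, dtype=float).ravel()
    env_partition = partition(y, env_sets)

    x_env = np.column_stack([np.asarray(m, dtype=float) for m in env_sets.values()])
    sel_classes = DistanceClasses(coords, n_classes=cfg.n_classes, style=cfg.class_style)
    rep_classes = DistanceClasses(coords, n_classes=cfg.n_classes, style="equal_width")
    fit = fit_ols(y, x_env)
    corr_before = correlogram(fit.residuals, coords, classes=rep_classes)
    sel = select_filters(y, x_env, basis, coords, cfg=cfg, classes=sel_classes)
    corr_after = (
        correlogram(sel.residuals, coords, classes=rep_classes)
        if np.ptp(sel.residuals) > 0
        else corr_before
    )

    spatial = basis.vectors[:, sel.selected] if sel.selected else np.empty((y.size, 0))
    full_sets = dict(env_sets)
    full_sets["spatial"] = spatial
    full_partition = partition(y, full_sets)

    return ModelSuiteResult(
        env_partition=env_partition,
        full_partition=full_partition,
        selection=sel,
        correlogram_before=corr_before,
        correlogram_after=corr_after,
    )
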