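"""Beta-diversity statistics: dissimilarities, ANOSIM, NMDS, effect sizes.

ANOSIM follows the classic rank formulation: all n(n-1)/2 dissimilarities are
ranked ascending with mid-ranks for ties, and

    R = (mean between-group rank - mean within-group rank) / (M / 2)

with M = n(n-1)/2, so R lies in [-1, 1]. Significance comes from a seeded
label permutation test with the add-one estimator p = (b + 1) / (N + 1)
where b counts permuted R >= the observed R (the observed labelling counts
as one permutation, so p is never 0).

NMDS minimises Kruskal stress-1 by nonmetric SMACOF: disparities are the
isotonic (pool-adjacent-violators) regression of the configuration distances
on the dissimilarity order, and the configuration is updated by the Guttman
transform. The best of several seeded random starts is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import isotonic_regression

from ._util import condensed_pairs
from .profiles import CountTable

__all__ = [
    "DistanceMatrix",
    "AnosimResult",
    "NmdsResult",
    "EffectSize",
    "bray_curtis",
    "euclidean",
    "distance_matrix",
    "anosim",
    "nmds",
    "bonferroni",
    "partial_eta_squared",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample identifiers."""

    sample_ids: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match "
                             f"{n} sample ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int | None
    group_labels: list
    group_sizes: dict
    tied_constant: bool = False

    def to_dict(self) -> dict:
        return {
            "R": self.R,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "group_sizes": self.group_sizes,
            "tied_constant": self.tied_constant,
        }


@dataclass
class NmdsResult:
    configuration: np.ndarray
    stress: float
    n_starts: int
    seed: int | None
    converged: bool
    stress_trace: list = field(default_factory=list, repr=False)


@dataclass
class EffectSize:
    ss_effect: float
    ss_error: float
    eta_p2: float
    label: str


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray–Curtis undefined for two all-zero samples")
    return float(np.abs(x - y).sum() / denom)


def euclidean(x, y) -> float:
    """Euclidean distance sqrt(sum (x-y)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(((x - y) ** 2).sum()))


_METRICS = {"bray_curtis": bray_curtis, "euclidean": euclidean}


def distance_matrix(table: CountTable | pd.DataFrame,
                    metric: str = "bray_curtis") -> DistanceMatrix:
    """All-pairs dissimilarity matrix of a count (or relative) table."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; "
                         f"choose from {sorted(_METRICS)}")
    df = table.data if isinstance(table, CountTable) else table
    n = df.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    X = df.to_numpy(dtype=float)
    if metric == "euclidean":
        cond = pdist(X, metric="euclidean")
    else:
        ids = list(df.index)
        iu, ju = condensed_pairs(n)
        sums = np.abs(X[iu] - X[ju]).sum(axis=1)
        denoms = (X[iu] + X[ju]).sum(axis=1)
        zero = denoms == 0
        if zero.any():
            a, b = ids[iu[zero.argmax()]], ids[ju[zero.argmax()]]
            raise ValueError(
                f"Bray–Curtis undefined for all-zero sample pair ({a}, {b})"
            )
        cond = sums / denoms
    return DistanceMatrix(list(df.index), squareform(cond), metric)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    return float(
        (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)
    )


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Rank-based ANOSIM with a seeded permutation p-value.

    ``groups`` is one label per sample, aligned with ``dm.sample_ids``.
    Every group needs at least 2 samples. A constant distance matrix (all
    dissimilarities tied) yields R = 0 with a warning.
    """
    labels = np.asarray(list(groups))
    if labels.size != dm.n:
        raise ValueError("one group label per sample is required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    cond = dm.condensed()
    ranks = rankdata(cond)  # mid-ranks for ties
    iu, ju = condensed_pairs(dm.n)
    within = labels[iu] == labels[ju]
    tied_constant = bool(np.ptp(cond) == 0)
    if tied_constant:
        warnings.warn("all dissimilarities are tied; ANOSIM R is 0",
                      stacklevel=2)

    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, labels.size), dtype=labels.dtype)
    for k in range(n_permutations):
        perms[k] = rng.permutation(labels)
    within_perm = perms[:, iu] == perms[:, ju]  # (N, M) boolean
    n_within = within.sum()  # group sizes fixed under permutation
    m = ranks.size
    sum_within = within_perm @ ranks
    mean_within = sum_within / n_within
    mean_between = (ranks.sum() - sum_within) / (m - n_within)
    r_perm = (mean_between - mean_within) / (m / 2.0)
    b = int((r_perm >= r_obs - 1e-12).sum())
    p = (b + 1) / (n_permutations + 1)
    return AnosimResult(
        R=r_obs,
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        group_labels=labels.tolist(),
        group_sizes={str(u): int(c) for u, c in zip(uniq, counts)},
        tied_constant=tied_constant,
    )


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_config**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_config - disparities) ** 2).sum() / denom))


def _nmds_single_start(
    diss: np.ndarray,
    order: np.ndarray,
    n: int,
    k: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, bool, list[float]]:
    X = rng.standard_normal((n, k))
    iu, ju = condensed_pairs(n)
    best_stress = np.inf
    best_X = X
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        d = np.sqrt(((X[iu] - X[ju]) ** 2).sum(axis=1))
        dhat = np.empty_like(d)
        dhat[order] = isotonic_regression(d[order])
        stress = _stress1(d, dhat)
        if stress >= best_stress:
            # normalised stress stalled; keep the best configuration seen
            converged = True
            break
        improvement = best_stress - stress
        best_stress = stress
        best_X = X
        trace.append(stress)
        if improvement < tol or stress < 1e-12:
            converged = True
            break
        # Guttman transform with disparities dhat
        ratio = np.where(d > 0, dhat / d, 0.0)
        B = squareform(-ratio)
        np.fill_diagonal(B, squareform(ratio).sum(axis=1))
        X = (B @ X) / n
        X = X - X.mean(axis=0)
    return best_X, float(best_stress), converged, trace


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> NmdsResult:
    """Nonmetric multidimensional scaling minimising Kruskal stress-1.

    Runs ``n_starts`` seeded random initialisations and keeps the
    configuration with the lowest stress. Non-convergence within
    ``max_iter`` iterations flags the result instead of raising.
    """
    n = dm.n
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} samples, got {n}")
    diss = dm.condensed()
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    best: NmdsResult | None = None
    for _ in range(n_starts):
        X, stress, conv, trace = _nmds_single_start(
            diss, order, n, k, max_iter, tol, rng
        )
        if best is None or stress < best.stress:
            best = NmdsResult(
                configuration=X,
                stress=stress,
                n_starts=n_starts,
                seed=seed,
                converged=conv,
                stress_trace=trace,
            )
    assert best is not None
    return best


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni family-wise correction.

    Returns (adjusted p-values capped at 1, reject flags). Rejection uses
    the raw p against alpha/m with a strict inequality.
    """
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    adjusted = np.minimum(1.0, p * m)
    reject = p < alpha / m if m else np.array([], dtype=bool)
    return adjusted, reject


_ETA_LABELS = [(0.14, "large"), (0.06, "medium"), (0.01, "small")]


def partial_eta_squared(ss_effect: float, ss_error: float) -> EffectSize:
    """Partial eta-squared SS_effect / (SS_effect + SS_error), with the
    conventional qualitative label (<0.01 very small; >=0.01 small;
    >=0.06 medium; >=0.14 large)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial eta-squared undefined when both sums of "
                         "squares are zero")
    eta = ss_effect / (ss_effect + ss_error)
    label = "very small"
    for cut, name in _ETA_LABELS:
        if eta >= cut:
            label = name
            break
    return EffectSize(float(ss_effect), float(ss_error), float(eta), label)
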