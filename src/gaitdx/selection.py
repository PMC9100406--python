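"""Correlation-based feature pruning and the four filter-type feature rankers:
chi-square, mRMR, ReliefF, and NCA feature selection.

All rankers consume a numeric feature table (DataFrame) plus class labels and
return a :class:`RankedFeatureList`. Ties are broken by input column order
everywhere, and every ranker is deterministic (NCA optimizes a smooth objective
from a fixed initialization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, RankingError

RANKER_NAMES = ("chi2", "mrmr", "relieff", "nca")


@dataclass
class RankedFeatureList:
    """Feature names ordered best-first with the scores that produced the order."""

    method: str
    names: list[str]
    scores: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != len(self.scores):
            raise RankingError("names/scores length mismatch")
        if len(set(self.names)) != len(self.names):
            raise RankingError("duplicate feature names in ranking")

    def top(self, k: int) -> list[str]:
        return self.names[:k]


def _order_desc(scores: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending, ties broken by input column order."""
    return np.argsort(-np.asarray(scores, dtype=float), kind="stable")


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------

def drop_correlated(
    table: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, list[str]]:
    """Drop the later of every column pair with |Pearson r| > threshold.

    Pairs are scanned in input column order (i < j); column j is dropped only if
    neither column has been dropped already, making the result order-deterministic
    and the operation idempotent. Zero-variance columns correlate with nothing,
    are retained, and trigger a warning.
    """
    if table.shape[0] < 2:
        raise RankingError("correlation pruning needs >= 2 rows")
    X = table.to_numpy(dtype=float)
    std = X.std(axis=0)
    degenerate = [c for c, s in zip(table.columns, std) if s == 0.0]
    if degenerate:
        warnings.warn(f"zero-variance columns retained: {degenerate}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    cols = list(table.columns)
    dropped: set[int] = set()
    for i in range(len(cols)):
        if i in dropped:
            continue
        for j in range(i + 1, len(cols)):
            if j in dropped:
                continue
            if abs(corr[i, j]) > threshold:
                dropped.add(j)
    keep = [c for k, c in enumerate(cols) if k not in dropped]
    return table[keep], [cols[k] for k in sorted(dropped)]


# ---------------------------------------------------------------------------
# discretization + mutual information helpers (natural-log MI)
# ---------------------------------------------------------------------------

def _bin_codes(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization into at most n_bins codes."""
    codes = pd.qcut(col, q=n_bins, labels=False, duplicates="drop")
    codes = np.asarray(codes)
    if np.all(pd.isna(codes)):  # constant column: a single occupied bin
        return np.zeros(len(col), dtype=int)
    return codes.astype(int)


def _encode_labels(y) -> np.ndarray:
    _, codes = np.unique(np.asarray(y), return_inverse=True)
    return codes


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) between two small nonnegative integer codes."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    mask = pj > 0
    return float((pj[mask] * np.log(pj[mask] / (pa @ pb)[mask])).sum())


def _check_labels(y) -> np.ndarray:
    codes = _encode_labels(y)
    if len(np.unique(codes)) < 2:
        raise RankingError("ranking requires at least two classes")
    return codes


# ---------------------------------------------------------------------------
# rankers
# ---------------------------------------------------------------------------

def rank_chi2(X: pd.DataFrame, y, n_bins: int = 10) -> RankedFeatureList:
    """Chi-square statistic of the (equal-frequency bin x class) contingency table."""
    yc = _check_labels(y)
    n_classes = yc.max() + 1
    scores = np.empty(X.shape[1])
    for k, col in enumerate(X.columns):
        codes = _bin_codes(X[col].to_numpy(dtype=float), n_bins)
        obs = np.bincount(codes * n_classes + yc, minlength=(codes.max() + 1) * n_classes)
        obs = obs.reshape(-1, n_classes).astype(float)
        obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
        if obs.shape[0] < 2 or obs.shape[1] < 2:
            scores[k] = 0.0
            continue
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        scores[k] = float(((obs - expected) ** 2 / expected).sum())
    order = _order_desc(scores)
    return RankedFeatureList("chi2", [X.columns[i] for i in order], scores[order])


def mrmr_criterion(
    relevance: np.ndarray, redundancy: np.ndarray, selected: list[int], candidate: int
) -> float:
    """The MID (mutual-information difference) greedy criterion for one candidate."""
    if not selected:
        return float(relevance[candidate])
    return float(relevance[candidate] - redundancy[candidate, selected].mean())


def rank_mrmr(X: pd.DataFrame, y, n_bins: int = 10) -> RankedFeatureList:
    """Greedy minimum-redundancy maximum-relevance (MID criterion) full ordering."""
    yc = _check_labels(y)
    if X.shape[1] < 1:
        raise RankingError("empty feature table")
    d = X.shape[1]
    codes = [_bin_codes(X[c].to_numpy(dtype=float), n_bins) for c in X.columns]
    relevance = np.array([_mi(c, yc) for c in codes])
    redundancy = np.full((d, d), np.nan)

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(d))
    while remaining:
        best_j, best_val = remaining[0], -np.inf
        for j in remaining:
            if selected:
                last = selected[-1]
                if np.isnan(redundancy[j, last]):
                    redundancy[j, last] = redundancy[last, j] = _mi(codes[j], codes[last])
            val = mrmr_criterion(relevance, redundancy, selected, j)
            if val > best_val:
                best_j, best_val = j, val
        selected.append(best_j)
        scores.append(best_val)
        remaining.remove(best_j)
    return RankedFeatureList("mrmr", [X.columns[i] for i in selected], np.array(scores))


def rank_relieff(X: pd.DataFrame, y, k: int = 10) -> RankedFeatureList:
    """Multi-class ReliefF: every sample contributes k nearest hits and k nearest
    misses per other class (miss contributions weighted by class prior), feature
    differences scaled by feature range."""
    yc = _check_labels(y)
    Xv = X.to_numpy(dtype=float)
    n, d = Xv.shape
    classes, counts = np.unique(yc, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt <= k:
            label = np.unique(np.asarray(y))[cls]
            raise ParameterError(f"class {label!r} has {cnt} members, needs > k={k}")
    rng_span = np.ptp(Xv, axis=0)
    rng_span[rng_span == 0.0] = 1.0
    Xs = Xv / rng_span
    priors = counts / n

    nn_by_class = {
        cls: NearestNeighbors(metric="cityblock").fit(Xs[yc == cls]) for cls in classes
    }
    idx_by_class = {cls: np.flatnonzero(yc == cls) for cls in classes}
    W = np.zeros(d)
    for cls in classes:
        members = idx_by_class[cls]
        # hits: k nearest same-class neighbors, excluding self
        _, hit_idx = nn_by_class[cls].kneighbors(Xs[members], n_neighbors=k + 1)
        for row, i in enumerate(members):
            hits = idx_by_class[cls][hit_idx[row][hit_idx[row] != row][:k]]
            W -= np.abs(Xs[i] - Xs[hits]).mean(axis=0) / n
        for other in classes:
            if other == cls:
                continue
            w_other = priors[other] / (1.0 - priors[cls])
            _, miss_idx = nn_by_class[other].kneighbors(Xs[members], n_neighbors=k)
            for row, i in enumerate(members):
                misses = idx_by_class[other][miss_idx[row]]
                W += w_other * np.abs(Xs[i] - Xs[misses]).mean(axis=0) / n
    order = _order_desc(W)
    return RankedFeatureList("relieff", [X.columns[i] for i in order], W[order])


def _nca_objective(
    w: np.ndarray, Xs: np.ndarray, same: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Negative NCA objective and gradient.

    Maximizes sum_i p_i - lam * sum_r w_r^2 where p_i is the soft leave-one-out
    probability of a correct nearest-neighbor classification under the weighted
    Manhattan distance d_w(i,j) = sum_r w_r^2 |x_ir - x_jr|.
    """
    n, d = Xs.shape
    w2 = w**2
    dist = np.zeros((n, n))
    for r in range(d):
        dist += w2[r] * np.abs(Xs[:, r, None] - Xs[None, :, r])
    np.fill_diagonal(dist, np.inf)
    # softmax over negative distances, row-wise
    logits = -dist
    logits -= logits.max(axis=1, keepdims=True)
    expd = np.exp(logits)
    P = expd / expd.sum(axis=1, keepdims=True)
    p_i = (P * same).sum(axis=1)
    obj = p_i.sum() - lam * np.sum(w2)

    # dF/dw_r = 2 w_r * sum_ij (p_i * P_ij - P_ij * same_ij) D_ijr - 2 lam w_r
    M = P * p_i[:, None] - P * same
    grad = np.empty(d)
    for r in range(d):
        grad[r] = 2.0 * w[r] * np.sum(M * np.abs(Xs[:, r, None] - Xs[None, :, r]))
    grad -= 2.0 * lam * w
    return -obj, -grad


def rank_nca(
    X: pd.DataFrame,
    y,
    lambda_reg: float | None = None,
    max_iter: int = 100,
    seed: int = 0,
) -> RankedFeatureList:
    """Neighborhood-component-analysis feature weights.

    Learns per-feature weights maximizing the expected soft leave-one-out
    nearest-neighbor accuracy minus an L2 penalty (lambda defaults to
    1/n_samples); features are standardized internally and ranked by squared
    weight. Deterministic given the data (fixed all-ones initialization; the seed
    argument is accepted for interface symmetry).
    """
    yc = _check_labels(y)
    Xv = X.to_numpy(dtype=float)
    std = Xv.std(axis=0)
    if np.any(std == 0.0):
        std = np.where(std == 0.0, 1.0, std)
    Xs = (Xv - Xv.mean(axis=0)) / std
    n, d = Xs.shape
    lam = 1.0 / n if lambda_reg is None else float(lambda_reg)
    same = (yc[:, None] == yc[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    w0 = np.ones(d)
    res = optimize.minimize(
        _nca_objective,
        w0,
        args=(Xs, same, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"NCA did not converge in {max_iter} iterations", stacklevel=2)
    weights = res.x**2
    order = _order_desc(weights)
    return RankedFeatureList(
        "nca", [X.columns[i] for i in order], weights[order], converged=converged
    )


_RANKERS = {
    "chi2": rank_chi2,
    "mrmr": rank_mrmr,
    "relieff": rank_relieff,
    "nca": rank_nca,
}


def rank_features(method: str, X: pd.DataFrame, y, **kwargs) -> RankedFeatureList:
    """Dispatch to one of the four rankers by name."""
    if method not in _RANKERS:
        raise RankingError(f"unknown ranking method {method!r}; choose from {RANKER_NAMES}")
    return _RANKERS[method](X, y, **kwargs)
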