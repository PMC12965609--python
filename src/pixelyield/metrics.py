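"""Evaluation statistics: error metrics, rank tests, spatial autocorrelation.

Covers the full validation machinery: R^2 / adjusted R^2 / RMSE / MAE /
MAPE on observed-vs-predicted tables; the Friedman chi-square rank test
across blocks of model scores with the Nemenyi critical-difference
post-hoc; global Moran's I with k-nearest-neighbour spatial weights and
permutation inference; and the village/block validation report layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import chi2, rankdata


__all__ = [
    "MetricReport",
    "regression_metrics",
    "RankTest",
    "friedman_test",
    "nemenyi_cd",
    "SpatialWeights",
    "knn_weights",
    "morans_i",
    "validation_report",
]


@dataclass
class MetricReport:
    """Agreement between observed and predicted values at one support."""

    r2: float
    adj_r2: float
    rmse: float
    mae: float
    mape: float            # percent
    n: int
    p: int
    mape_excluded: int     # zero-valued observations excluded from MAPE
    diffs: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict[str, float]:
        return {
            "R2": self.r2, "adj_R2": self.adj_r2, "RMSE": self.rmse,
            "MAE": self.mae, "MAPE": self.mape,
        }


def regression_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    p: int = 1,
) -> MetricReport:
    """Standard agreement metrics between observed and predicted values.

    R^2 = 1 - SS_res/SS_tot; adjusted R^2 = 1 - (n-1)/(n-p-1) * (1-R^2)
    with ``p`` predictors; RMSE and MAE in the data units; MAPE in
    percent, with zero-valued observations excluded (counted in
    ``mape_excluded``) since their relative error is undefined.
    """
    y = np.asarray(observed, float)
    yhat = np.asarray(predicted, float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted lengths differ")
    n = len(y)
    if n < 2:
        raise ValueError("need at least two observations")
    err = y - yhat
    ss_res = float(np.sum(err ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    adj = 1.0 - (n - 1) / (n - p - 1) * (1.0 - r2) if n - p - 1 > 0 else np.nan
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    nonzero = y != 0
    with np.errstate(over="ignore"):
        mape = float(100.0 * np.mean(np.abs(err[nonzero] / y[nonzero]))) if nonzero.any() else np.nan
    diffs = pd.DataFrame({"observed": y, "predicted": yhat, "error": err})
    return MetricReport(r2, adj, rmse, mae, mape, n, p, int((~nonzero).sum()), diffs)


@dataclass
class RankTest:
    """Friedman rank test over N blocks x k treatments, with Nemenyi CD."""

    ranks: np.ndarray        # (N, k) within-block ranks (mid-ranks for ties)
    avg_ranks: np.ndarray    # (k,)
    statistic: float         # chi-square_F
    p_value: float
    n_blocks: int
    k: int
    cd: float | None = None  # set when a significance level is supplied

    def pairwise_significant(self) -> np.ndarray:
        """Boolean (k, k) matrix: |avg rank difference| exceeds the CD."""
        if self.cd is None:
            raise ValueError("no critical difference computed")
        d = np.abs(self.avg_ranks[:, None] - self.avg_ranks[None, :])
        return d > self.cd


def friedman_test(
    scores: np.ndarray,
    lower_is_better: bool = True,
    alpha: float | None = None,
) -> RankTest:
    """Friedman chi-square test on an N x k score matrix.

    Each block (row) is ranked with mid-ranks for ties — rank 1 going to
    the best treatment, i.e. the smallest score when ``lower_is_better``
    (error metrics) or the largest otherwise (R^2-like scores).  The
    statistic is

        chi2_F = 12N / (k(k+1)) * [sum_j Rbar_j^2 - k(k+1)^2 / 4]

    referred to a chi-square with k-1 degrees of freedom.  A fully tied
    matrix gives a statistic of zero.  When ``alpha`` is given the
    Nemenyi critical difference is attached for post-hoc comparisons.
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2:
        raise ValueError("scores must be N blocks x k treatments")
    n_blocks, k = scores.shape
    if n_blocks < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    signed = scores if lower_is_better else -scores
    ranks = np.apply_along_axis(rankdata, 1, signed)
    avg = ranks.mean(axis=0)
    stat = 12.0 * n_blocks / (k * (k + 1)) * (np.sum(avg ** 2) - k * (k + 1) ** 2 / 4.0)
    stat = max(stat, 0.0)  # guard round-off on fully tied input
    pval = float(chi2.sf(stat, k - 1))
    cd = nemenyi_cd(k, n_blocks, alpha) if alpha is not None else None
    return RankTest(ranks, avg, float(stat), pval, n_blocks, k, cd)


# Nemenyi constants q_alpha = q_(alpha, k, inf)/sqrt(2) from the studentized
# range distribution at infinite degrees of freedom, k = 2..20.
_Q_ALPHA = {
    0.05: (
        1.959964, 2.343701, 2.569032, 2.727774, 2.849705, 2.948320, 3.030878,
        3.101730, 3.163684, 3.218654, 3.268004, 3.312739, 3.353618, 3.391230,
        3.426041, 3.458425, 3.488685, 3.517073, 3.543799,
    ),
    0.10: (
        1.644854, 2.052293, 2.291341, 2.459516, 2.588521, 2.692732, 2.779884,
        2.854606, 2.919889, 2.977768, 3.029694, 3.076733, 3.119693, 3.159199,
        3.195743, 3.229723, 3.261461, 3.291224, 3.319233,
    ),
}


def nemenyi_cd(k: int, n_blocks: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference CD = q_alpha * sqrt(k(k+1) / (6N)).

    Two treatments differ significantly when their average ranks differ
    by more than the CD.  ``k`` is the number of treatments compared and
    ``N`` the number of blocks they were ranked over; q_alpha comes from
    the embedded studentized-range table (k = 2..20, alpha 0.05 or 0.10).
    """
    if alpha not in _Q_ALPHA:
        raise ValueError("alpha must be 0.05 or 0.10")
    if not 2 <= k <= 20:
        raise ValueError("k outside the embedded table (2..20)")
    if n_blocks < 1:
        raise ValueError("need at least one block")
    q = _Q_ALPHA[alpha][k - 2]
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n_blocks)))


@dataclass
class SpatialWeights:
    """Sparse binary spatial weights from symmetrized k-nearest neighbours."""

    rows: np.ndarray     # pair indices i
    cols: np.ndarray     # pair indices j
    weights: np.ndarray  # w_ij > 0
    n: int
    k: int

    @property
    def s0(self) -> float:
        return float(self.weights.sum())


def knn_weights(points: np.ndarray, k: int = 8) -> SpatialWeights:
    """Binary k-nearest-neighbour weights, symmetrized by max(W, W^T).

    No self-neighbours; each point contributes edges to its k nearest
    points and any point that counts it among *its* k nearest.
    """
    points = np.asarray(points, float).reshape(-1, 2)
    n = len(points)
    if n <= k:
        raise ValueError("need more points than neighbours")
    tree = cKDTree(points)
    _, nbr = tree.query(points, k=k + 1)
    nbr = nbr[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k)
    cols = nbr.ravel()
    # symmetrize: keep an edge if it appears in either direction
    pairs = set(zip(rows.tolist(), cols.tolist()))
    pairs |= {(j, i) for i, j in pairs}
    rr = np.array([p[0] for p in sorted(pairs)])
    cc = np.array([p[1] for p in sorted(pairs)])
    return SpatialWeights(rr, cc, np.ones(len(rr)), n, k)


def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Global Moran's I with a permutation test.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values and S0 the total weight.  The expectation under spatial
    randomness is -1/(n-1); the p-value is the one-sided permutation
    fraction (I at least as extreme on the side of the observed
    deviation), floored at 1/(n_permutations + 1).

    Returns ``(I, expected_I, p_value)``.
    """
    z = np.asarray(values, float)
    if len(z) != weights.n:
        raise ValueError("values and weights disagree in length")
    if np.var(z) == 0:
        raise ValueError("Moran's I is undefined for a constant field")
    z = z - z.mean()

    def stat(zv: np.ndarray) -> float:
        num = float(np.sum(weights.weights * zv[weights.rows] * zv[weights.cols]))
        return weights.n / weights.s0 * num / float(np.sum(zv ** 2))

    i_obs = stat(z)
    e_i = -1.0 / (weights.n - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        i_perm = stat(rng.permutation(z))
        if (i_obs >= e_i and i_perm >= i_obs) or (i_obs < e_i and i_perm <= i_obs):
            count += 1
    pval = (count + 1) / (n_permutations + 1)
    return float(i_obs), float(e_i), float(pval)


def validation_report(
    observed_village: pd.DataFrame,
    predictions_village: dict[str, pd.DataFrame],
    observed_block: pd.DataFrame | None = None,
    predictions_block: dict[str, pd.DataFrame] | None = None,
    n_predictors: int = 1,
) -> pd.DataFrame:
    """Per-method validation table at village and block support.

    Inputs are frames with ``village_id``/``block_id`` and a yield column
    (``mean`` or ``yield_q_ha``); predictions are matched to observations
    by ID.  Village rows report R^2, adjusted R^2, RMSE, MAE and MAPE;
    block rows report RMSE, MAE and MAPE only — with few blocks relative
    to the predictor count, block-level R^2 is unstable and deliberately
    omitted.
    """
    def _col(df: pd.DataFrame) -> str:
        for c in ("mean", "yield_q_ha", "true_mean", "yield"):
            if c in df.columns:
                return c
        raise ValueError("no yield column found")

    rows = []
    for level, obs, preds, id_col in (
        ("village", observed_village, predictions_village, "village_id"),
        ("block", observed_block, predictions_block, "block_id"),
    ):
        if obs is None or preds is None:
            continue
        ocol = _col(obs)
        for method, pdf in preds.items():
            pcol = _col(pdf)
            merged = obs[[id_col, ocol]].merge(
                pdf[[id_col, pcol]], on=id_col, suffixes=("_obs", "_pred")
            ).dropna()
            oc = ocol + "_obs" if ocol == pcol else ocol
            pc = pcol + "_pred" if ocol == pcol else pcol
            rep = regression_metrics(merged[oc].values, merged[pc].values, p=n_predictors)
            row = {"level": level, "method": method, "n": rep.n,
                   "RMSE": rep.rmse, "MAE": rep.mae, "MAPE": rep.mape}
            if level == "village":
                row["R2"] = rep.r2
                row["adj_R2"] = rep.adj_r2
            rows.append(row)
    out = pd.DataFrame(rows)
    cols = ["level", "method", "n", "R2", "adj_R2", "RMSE", "MAE", "MAPE"]
    return out[[c for c in cols if c in out.columns]]
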