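"""Rank correlations, multiplicity control and small summary statistics.

Kendall's tau-b is implemented by direct pair counting with tie corrections,

    tau_b = (C - D) / sqrt((n0 - n1) (n0 - n2)),

where C/D are the concordant/discordant pair counts, ``n0 = n(n-1)/2`` and
``n1``/``n2`` are the tied-pair counts within x and y.  P-values use the
large-sample normal approximation with the tie-corrected null variance; an
exact permutation p-value is available for very small n.  Vectors with all
values tied have undefined correlation and propagate as NaN, never as 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "kendall_tau_b",
    "kendall_tau_b_many",
    "bh_adjust",
    "ols_summary",
    "RegressionSummary",
    "score_similarity",
    "cluster_scores",
    "selection_overlap",
]


def _tie_counts(v: np.ndarray) -> tuple[float, float, float]:
    """(sum t(t-1)/2, sum t(t-1)(t-2), sum t(t-1)(2t+5)) over tie groups."""
    _, counts = np.unique(v, return_counts=True)
    t = counts[counts > 1].astype(float)
    return (
        float(np.sum(t * (t - 1) / 2)),
        float(np.sum(t * (t - 1) * (t - 2))),
        float(np.sum(t * (t - 1) * (2 * t + 5))),
    )


def kendall_tau_b(x, y, method: str = "normal") -> tuple[float, float]:
    """Kendall's tau-b with tie correction; returns ``(tau_b, p_value)``.

    ``method="normal"`` uses the tie-corrected normal approximation;
    ``method="exact"`` enumerates permutations (n <= 8 only).  Returns
    ``(nan, nan)`` when either vector is entirely tied.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return (math.nan, math.nan)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = float(np.sum(dx[iu] * dy[iu]))  # C - D
    n0 = n * (n - 1) / 2
    n1, vx1, vx2 = _tie_counts(x)
    n2, vy1, vy2 = _tie_counts(y)
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    tau = s / denom
    if method == "exact":
        if n > 8:
            raise ValueError("exact p-value limited to n <= 8")
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            sp = float(np.sum(dx[iu] * np.sign(y[list(perm)][:, None] - y[list(perm)][None, :])[iu]))
            total += 1
            if abs(sp) >= abs(s) - 1e-12:
                hits += 1
        return (tau, hits / total)
    # tie-corrected variance of S under the null (as in standard tau-b tests)
    v0 = n * (n - 1) * (2 * n + 5)
    var_s = (
        (v0 - vx2 - vy2) / 18
        + vx1 * vy1 / (9 * n * (n - 1) * (n - 2))
        + (2 * n1 * 2 * n2) / (2 * n * (n - 1))
    )
    if var_s <= 0:
        return (tau, math.nan)
    z = s / math.sqrt(var_s)
    p = 2 * sps.norm.sf(abs(z))
    return (tau, float(min(p, 1.0)))


def kendall_tau_b_many(x, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """tau-b (and normal-approximation p) of one x against many columns of Y.

    Vectorized pair counting shared across columns; used for the per-bin
    fingerprint correlations where Y has thousands of columns.  Columns with
    zero variance come back NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    if x.shape[0] != n:
        raise ValueError("x length must match Y rows")
    if n < 3:
        raise ValueError("need at least 3 observations")
    iu = np.triu_indices(n, k=1)
    dx = np.sign(x[:, None] - x[None, :])[iu]  # (P,)
    dY = np.sign(Y[iu[0], :] - Y[iu[1], :])  # (P, m)
    s = dx @ dY  # C - D per column
    n0 = n * (n - 1) / 2
    n1, vx1, vx2 = _tie_counts(x)
    taus = np.full(m, np.nan)
    ps = np.full(m, np.nan)
    if np.unique(x).size == 1:
        return taus, ps
    v0 = n * (n - 1) * (2 * n + 5)
    tie_pairs = (dY == 0).sum(axis=0)  # sum t(t-1)/2 per column
    defined = tie_pairs < n0  # constant columns have every pair tied
    # continuous data rarely ties, so vectorize the no-ties case and fall
    # back to per-column tie bookkeeping only where needed
    no_ties = defined & (tie_pairs == 0)
    denom = np.sqrt((n0 - n1) * n0)
    taus[no_ties] = s[no_ties] / denom
    var_s0 = (v0 - vx2) / 18
    if var_s0 > 0:
        z = s[no_ties] / math.sqrt(var_s0)
        ps[no_ties] = np.minimum(2 * sps.norm.sf(np.abs(z)), 1.0)
    for k in np.flatnonzero(defined & (tie_pairs > 0)):
        n2, vy1, vy2 = _tie_counts(Y[:, k])
        taus[k] = s[k] / math.sqrt((n0 - n1) * (n0 - n2))
        var_s = (
            (v0 - vx2 - vy2) / 18
            + vx1 * vy1 / (9 * n * (n - 1) * (n - 2))
            + (2 * n1 * 2 * n2) / (2 * n * (n - 1))
        )
        if var_s > 0:
            ps[k] = min(2 * sps.norm.sf(abs(s[k]) / math.sqrt(var_s)), 1.0)
    return taus, ps


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries (undefined tests) are excluded from the denominator and stay
    NaN in the output.  Adjusted values are monotone-enforced and clipped at 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    out = np.full(p.shape, np.nan)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[valid] = restored
    return out


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    p_value: float
    n: int


def ols_summary(x, y) -> RegressionSummary:
    """Single-predictor OLS with adjusted R² = 1 - (1 - R²)(n - 1)/(n - 2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n or n < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if np.std(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    fit = sps.linregress(x, y)
    r2 = fit.rvalue**2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(r2),
        adjusted_r2=float(adj),
        p_value=float(fit.pvalue),
        n=n,
    )


def score_similarity(scores_a: pd.Series, scores_b: pd.Series) -> tuple[float, float]:
    """Pearson correlation between two RL score vectors on their common taxa.

    Returns ``(nan, nan)`` when either restricted vector has zero variance.
    """
    common = scores_a.index.intersection(scores_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common taxa")
    a = scores_a.loc[common].to_numpy(dtype=float)
    b = scores_b.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return (math.nan, math.nan)
    r, p = sps.pearsonr(a, b)
    return (float(r), float(p))


def cluster_scores(score_matrix: pd.DataFrame) -> tuple[list, str, np.ndarray]:
    """Complete-linkage hierarchical clustering of RL score rows.

    Euclidean distances, deterministic leaf order (scipy's ordering with ties
    resolved by row index).  Returns ``(leaf_order_labels, newick, linkage_matrix)``.
    """
    if score_matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(score_matrix.to_numpy(dtype=float), method="complete", metric="euclidean")
    order = leaves_list(Z)
    labels = [str(lbl) for lbl in score_matrix.index]

    def newick(node: int) -> str:
        n = score_matrix.shape[0]
        if node < n:
            return labels[node]
        a, b, h, _ = Z[node - n]
        return f"({newick(int(a))},{newick(int(b))}):{h:.6g}"

    nwk = newick(2 * score_matrix.shape[0] - 2) + ";"
    return [labels[i] for i in order], nwk, Z


def selection_overlap(selections: dict[str, set | list]) -> pd.DataFrame:
    """Pairwise overlap of per-system selected-taxon sets.

    Row/column entries give ``|A ∩ B|`` and, as a percentage, the share of
    system A's selection also present in system B (the row set is the
    denominator).  Empty selections yield NaN percentages.
    """
    systems = list(selections)
    if len(systems) < 2:
        raise ValueError("need at least 2 systems")
    sets = {k: set(v) for k, v in selections.items()}
    rows = []
    for a in systems:
        for b in systems:
            inter = len(sets[a] & sets[b])
            pct = 100.0 * inter / len(sets[a]) if sets[a] else math.nan
            rows.append({"system_a": a, "system_b": b, "n_overlap": inter, "pct_of_a": pct})
    return pd.DataFrame(rows)
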