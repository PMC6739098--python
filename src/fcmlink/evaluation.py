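"""Blocked cross-validated evaluation of taxon subsets.

All predictive performance in this package is the *pooled* out-of-group R²
from leave-one-group-out (LOGO) cross-validation over site-by-year blocks:
held-out predictions from every fold are concatenated and scored as
``1 - SSE/SST`` against the concatenated truth (``RCV²``; may be negative).
Pooling is also used in the nested scheme (``RNCV²``), where the outer loop
holds out one group while the inner loop runs stability selection, ranks
taxa, eliminates recursively and picks the minimal-optimal subset — all
without ever seeing the held-out group.

Within every fold the Lasso penalty is chosen on a per-training-set grid of
``n_lambda = 400`` values spanning ``eps = 1e-4`` of the critical penalty
(the smallest penalty with an all-zero solution), mirroring the standard
coordinate-descent CV grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solver import lasso_path_gram
from .stability import RandomizedLasso, StabilityConfig

__all__ = [
    "rcv2",
    "pooled_r2",
    "RecursiveElimination",
    "EliminationResults",
    "NestedGroupCV",
    "NestedCVResults",
    "elimination_sizes",
    "geometric_sizes",
]


def pooled_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """``1 - SSE/SST`` on concatenated held-out predictions (can be < 0)."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("pooled truth has zero variance; R² undefined")
    return 1.0 - sse / sst


def _inner_group_folds(tr: np.ndarray, groups_tr: np.ndarray, n_folds: int):
    """Group-blocked folds for penalty selection within a training set.

    Training groups are dealt round-robin into up to ``n_folds`` blocks (the
    reference CV for the penalty used 3 folds); every block stays a union of
    whole groups, so the penalty choice never sees within-group leakage.
    """
    uniq = list(pd.unique(groups_tr))
    if len(uniq) < 2:
        return []
    k = min(n_folds, len(uniq))
    blocks = [uniq[i::k] for i in range(k)]
    folds = []
    for block in blocks:
        mask = np.isin(groups_tr, block)
        folds.append((tr[~mask], tr[mask]))
    return folds


def _check_groups(groups, n: int) -> np.ndarray:
    g = np.asarray(groups)
    if g.shape[0] != n:
        raise ValueError("groups length must match number of samples")
    uniq = pd.unique(g)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct groups for blocked CV")
    for u in uniq:
        if np.sum(g == u) == n:
            raise ValueError(f"group {u!r} contains all samples")
    return g


class _Split:
    """Standardized training design plus a held-out block, at full p.

    Both X columns and y are standardized on the training rows (predictions
    are mapped back to the original scale), which keeps coordinate-descent
    tolerances and the relative penalty grid meaningful regardless of the
    response's physical units (cells/ml can be ~1e5-1e6).
    """

    __slots__ = ("G", "c", "mu", "sd", "ybar", "ysd", "Xva_std", "yva", "va_idx")

    def __init__(self, X, y, tr_idx, va_idx):
        Xtr = X[tr_idx]
        ytr = y[tr_idx]
        self.mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        Z = (Xtr - self.mu) / self.sd
        self.ybar = ytr.mean()
        ysd = ytr.std()
        self.ysd = ysd if ysd > 0 else 1.0
        yc = (ytr - self.ybar) / self.ysd
        self.G = Z.T @ Z
        self.c = Z.T @ yc
        self.va_idx = va_idx
        if va_idx is not None:
            self.Xva_std = (X[va_idx] - self.mu) / self.sd
            self.yva = y[va_idx]
        else:
            self.Xva_std = None
            self.yva = None

    def predict(self, sub: np.ndarray, beta_std: np.ndarray) -> np.ndarray:
        return self.ysd * (self.Xva_std[:, sub] @ beta_std) + self.ybar


class _PooledGroupLassoCV:
    """LOGO-CV engine with cached Gram matrices, sliceable by column subset.

    Building the engine precomputes, for every outer group g, the training
    split (train = all other groups, validate = g) and the inner LOGO splits
    of that training set used to pick the penalty.  ``run(subset)`` then
    evaluates any column subset cheaply by slicing the cached Grams, which is
    what makes per-variable recursive elimination affordable.
    """

    def __init__(self, X, y, groups, eps=1e-4, n_lambda=400, tol=1e-5,
                 max_iter=1_000, inner_folds=3):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.X.shape[0]
        self.groups = _check_groups(groups, n)
        self.eps = float(eps)
        self.n_lambda = int(n_lambda)
        self.tol = tol
        self.max_iter = max_iter
        self._outer = []
        uniq = pd.unique(self.groups)
        all_idx = np.arange(n)
        for g in uniq:
            te = all_idx[self.groups == g]
            tr = all_idx[self.groups != g]
            refit = _Split(self.X, self.y, tr, te)
            inner = [
                _Split(self.X, self.y, itr, iva)
                for itr, iva in _inner_group_folds(tr, self.groups[tr], inner_folds)
            ]
            self._outer.append((g, refit, inner))

    def _grid(self, c_sub: np.ndarray) -> np.ndarray:
        lam_max = 2.0 * float(np.max(np.abs(c_sub))) if c_sub.size else 0.0
        if lam_max <= 0:
            return np.array([])
        # descending grid down to eps * lam_max
        return lam_max * np.logspace(0.0, math.log10(self.eps), self.n_lambda)

    def run(self, subset: np.ndarray | None = None):
        """Pooled LOGO predictions for a column subset; returns (rcv2, preds, fold_lams)."""
        p = self.X.shape[1]
        sub = np.arange(p) if subset is None else np.asarray(subset, dtype=np.intp)
        preds = np.empty_like(self.y)
        fold_lams = {}
        for g, refit, inner in self._outer:
            grid = self._grid(refit.c[sub])
            if grid.size == 0:
                preds[refit.va_idx] = refit.ybar
                fold_lams[g] = np.nan
                continue
            if inner:
                sse = np.zeros(grid.size)
                for spl in inner:
                    Gs = spl.G[np.ix_(sub, sub)]
                    cs = spl.c[sub]
                    betas = lasso_path_gram(Gs, cs, grid, tol=self.tol, max_iter=self.max_iter)
                    pv = spl.ysd * (spl.Xva_std[:, sub] @ betas.T) + spl.ybar
                    sse += ((pv - spl.yva[:, None]) ** 2).sum(axis=0)
                li = int(np.argmin(sse))  # ties -> largest penalty
            else:
                li = grid.size - 1
            Gs = refit.G[np.ix_(sub, sub)]
            betas = lasso_path_gram(Gs, refit.c[sub], grid[: li + 1], tol=self.tol, max_iter=self.max_iter)
            preds[refit.va_idx] = refit.predict(sub, betas[-1])
            fold_lams[g] = float(grid[li])
        return pooled_r2(self.y, preds), preds, fold_lams


def rcv2(X, y, groups, eps: float = 1e-4, n_lambda: int = 400, subset=None) -> float:
    """Pooled out-of-group R² of a LOGO-CV-tuned Lasso on (a subset of) X."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    engine = _PooledGroupLassoCV(X, y, groups, eps=eps, n_lambda=n_lambda)
    score, _, _ = engine.run(subset)
    return score


def elimination_sizes(p: int, step: int = 1) -> list[int]:
    """Retained sizes p, p-step, ..., always ending at 1."""
    if step >= p:
        raise ValueError("step must be < p")
    sizes = list(range(p, 0, -step))
    if sizes[-1] != 1:
        sizes.append(1)
    return sizes


def geometric_sizes(p: int, ratio: float = 0.8) -> list[int]:
    """Geometric retained-size schedule from p down to 1 (coarse traces)."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    sizes = [p]
    while sizes[-1] > 1:
        nxt = min(sizes[-1] - 1, int(math.floor(sizes[-1] * ratio)))
        sizes.append(max(nxt, 1))
    return sizes


class RecursiveElimination:
    """Recursive variable elimination ranked by RL score.

    Starting from all taxa, the lowest-scored taxa are dropped (``step`` at a
    time, or following an explicit ``sizes`` schedule) and the blocked RCV²
    is recorded at each retained size.  The optimum is *minimal-optimal*: the
    smallest retained size achieving the maximal RCV².  Ties in score are
    broken by original column order.
    """

    def __init__(
        self,
        X,
        y,
        groups,
        scores,
        step: int = 1,
        sizes: list[int] | None = None,
        eps: float = 1e-4,
        n_lambda: int = 400,
    ):
        if isinstance(X, pd.DataFrame):
            self.taxon_ids = list(X.columns)
            X = X.to_numpy()
        else:
            X = np.asarray(X, dtype=float)
            self.taxon_ids = [f"x{j}" for j in range(X.shape[1])]
        p = X.shape[1]
        if p < 2:
            raise ValueError("need at least 2 taxa to eliminate")
        s = scores.to_numpy() if isinstance(scores, pd.Series) else np.asarray(scores, float)
        if s.shape[0] != p:
            raise ValueError("scores length must equal number of columns")
        self.order = np.argsort(-s, kind="stable")  # descending score, stable ties
        self.sizes = sizes if sizes is not None else elimination_sizes(p, step)
        if any(b >= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly decreasing")
        self._engine = _PooledGroupLassoCV(X, y, groups, eps=eps, n_lambda=n_lambda)
        self.scores = s

    def fit(self) -> "EliminationResults":
        trace = []
        for k in self.sizes:
            sub = self.order[:k]
            score, _, _ = self._engine.run(sub)
            trace.append((k, score))
        df = pd.DataFrame(trace, columns=["n_retained", "rcv2"])
        return EliminationResults(trace=df, order=self.order, taxon_ids=self.taxon_ids)


@dataclass
class EliminationResults:
    trace: pd.DataFrame  # columns n_retained (descending), rcv2
    order: np.ndarray  # column indices, descending RL score
    taxon_ids: list[str]

    @property
    def k_opt(self) -> int:
        """Smallest retained size achieving the maximal RCV² (minimal-optimal)."""
        vals = self.trace["rcv2"].to_numpy()
        best = vals.max()
        ok = self.trace["n_retained"].to_numpy()[vals >= best - 1e-12]
        return int(ok.min())

    @property
    def rcv2_opt(self) -> float:
        return float(self.trace["rcv2"].max())

    @property
    def rcv2_full(self) -> float:
        """RCV² with every taxon retained (first trace point)."""
        return float(self.trace["rcv2"].iloc[0])

    @property
    def selected_indices(self) -> np.ndarray:
        return self.order[: self.k_opt]

    @property
    def selected_taxa(self) -> list[str]:
        return [self.taxon_ids[j] for j in self.selected_indices]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_retained": [int(self.trace["n_retained"].iloc[0]), self.k_opt],
                "rcv2": [self.rcv2_full, self.rcv2_opt],
            },
            index=["all_taxa", "minimal_optimal"],
        )

    def plot_trace(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace["n_retained"], self.trace["rcv2"], marker=".")
        ax.axvline(self.k_opt, ls="--", color="grey")
        ax.set_xlabel("taxa retained")
        ax.set_ylabel(r"RCV$^2$")
        ax.invert_xaxis()
        return ax

    def to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


class NestedGroupCV:
    """Nested leave-one-group-out validation of the whole selection pipeline.

    For every outer group: stability selection and recursive elimination run
    on the training groups alone; the final Lasso is fitted on the selected
    subset (penalty tuned by LOGO CV within training) and predicts the
    held-out group.  Concatenated predictions give RNCV².

    The inner elimination uses a geometric retained-size schedule by default
    (``sizes="geometric"``); pass ``sizes="full"`` for per-variable removal.
    """

    def __init__(
        self,
        X,
        y,
        groups,
        stability_config: StabilityConfig | None = None,
        sizes: str | list[int] = "geometric",
        eps: float = 1e-4,
        n_lambda: int = 400,
    ):
        if isinstance(X, pd.DataFrame):
            self.taxon_ids = list(X.columns)
            self.sample_ids = list(X.index)
            X = X.to_numpy()
        else:
            X = np.asarray(X, dtype=float)
            self.taxon_ids = [f"x{j}" for j in range(X.shape[1])]
            self.sample_ids = list(range(X.shape[0]))
        self.X = X
        self.y = np.asarray(y, dtype=float).ravel()
        self.groups = _check_groups(groups, X.shape[0])
        if len(pd.unique(self.groups)) < 3:
            raise ValueError("nested CV needs >= 3 groups (inner CV needs >= 2)")
        self.stability_config = stability_config or StabilityConfig()
        self.sizes = sizes
        self.eps = eps
        self.n_lambda = n_lambda

    def _schedule(self, p: int) -> list[int]:
        if isinstance(self.sizes, str):
            if self.sizes == "geometric":
                return geometric_sizes(p)
            if self.sizes == "full":
                return elimination_sizes(p, 1)
            raise ValueError(f"unknown sizes schedule {self.sizes!r}")
        return list(self.sizes)

    def fit(self, seed: int | None = 0) -> "NestedCVResults":
        n, p = self.X.shape
        uniq = list(pd.unique(self.groups))
        fold_seeds = np.random.SeedSequence(seed).spawn(len(uniq))
        preds = np.empty(n)
        fold_of = np.empty(n, dtype=object)
        selections: dict = {}
        all_idx = np.arange(n)
        for g, fs in zip(uniq, fold_seeds):
            te = all_idx[self.groups == g]
            tr = all_idx[self.groups != g]
            Xtr, ytr, gtr = self.X[tr], self.y[tr], self.groups[tr]
            res = RandomizedLasso(
                Xtr, ytr, taxon_ids=self.taxon_ids, config=self.stability_config
            ).fit(seed=int(fs.generate_state(1)[0] % (2**31)))
            elim = RecursiveElimination(
                Xtr, ytr, gtr, res.scores.to_numpy(),
                sizes=self._schedule(p), eps=self.eps, n_lambda=self.n_lambda,
            ).fit()
            sub = elim.selected_indices
            selections[g] = [self.taxon_ids[j] for j in sub]
            preds[te] = _predict_heldout(
                self.X, self.y, tr, te, gtr, sub, self.eps, self.n_lambda
            )
            fold_of[te] = g
        frame = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "outer_group": fold_of,
                "y_true": self.y,
                "y_pred": preds,
            }
        )
        return NestedCVResults(predictions=frame, fold_selections=selections, seed=seed)


def _predict_heldout(X, y, tr, te, groups_tr, subset, eps, n_lambda):
    """Tune the penalty by LOGO CV within training, refit, predict held-out rows."""
    sub = np.asarray(subset, dtype=np.intp)
    refit = _Split(X, y, tr, te)
    c_sub = refit.c[sub]
    lam_max = 2.0 * float(np.max(np.abs(c_sub))) if c_sub.size else 0.0
    if lam_max <= 0:
        return np.full(len(te), refit.ybar)
    grid = lam_max * np.logspace(0.0, math.log10(eps), n_lambda)
    sse = np.zeros(grid.size)
    n_inner = 0
    for itr, iva in _inner_group_folds(tr, groups_tr, 3):
        spl = _Split(X, y, itr, iva)
        betas = lasso_path_gram(spl.G[np.ix_(sub, sub)], spl.c[sub], grid)
        pv = spl.ysd * (spl.Xva_std[:, sub] @ betas.T) + spl.ybar
        sse += ((pv - spl.yva[:, None]) ** 2).sum(axis=0)
        n_inner += 1
    li = int(np.argmin(sse)) if n_inner else grid.size - 1
    betas = lasso_path_gram(refit.G[np.ix_(sub, sub)], refit.c[sub], grid[: li + 1])
    return refit.predict(sub, betas[-1])


@dataclass
class NestedCVResults:
    predictions: pd.DataFrame  # sample_id, outer_group, y_true, y_pred
    fold_selections: dict
    seed: int | None = None

    @property
    def rncv2(self) -> float:
        return pooled_r2(self.predictions["y_true"], self.predictions["y_pred"])

    def summary(self) -> pd.DataFrame:
        sizes = {g: len(s) for g, s in self.fold_selections.items()}
        return pd.DataFrame(
            {
                "n_selected": pd.Series(sizes),
                "n_test": self.predictions.groupby("outer_group").size(),
            }
        ).assign(rncv2_pooled=self.rncv2)

    def to_csv(self, path) -> None:
        self.predictions.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
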