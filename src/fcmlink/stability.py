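"""Randomized-Lasso stability selection.

The estimator repeatedly fits the weighted Lasso to random half-subsamples
of the data, with per-variable penalty multipliers drawn from {alpha, 1}
("weakness" randomization), across a logarithmic penalty grid.  A variable's
selection frequency at each penalty forms its *stability path*; its RL score
is the maximum of that path.  Under the theory of stability selection the
number of falsely selected variables is controlled when variables are kept
at scores above 0.5.

Defaults reproduce the published operating point: B = 500 subsample repeats,
weakness alpha = 0.5, and 100 log-spaced penalties between 1e-3 and 1e3.
Columns are standardized (and y centered) within each subsample so that a
single penalty grid is meaningful across taxa of very different scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import lasso_path_gram, standardize_train

__all__ = ["StabilityConfig", "RandomizedLasso", "StabilityResults", "select_by_score"]


@dataclass
class StabilityConfig:
    """Operating parameters for the randomized Lasso."""

    B: int = 500
    alpha: float = 0.5  # weakness; 1 disables the penalty randomization
    lam_min: float = 1e-3
    lam_max: float = 1e3
    n_lambda: int = 100
    subsample_fraction: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1_000

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.lam_min < self.lam_max):
            raise ValueError("need 0 < lam_min < lam_max")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")

    @property
    def lam_grid(self) -> np.ndarray:
        """Ascending logarithmic penalty grid."""
        return np.logspace(np.log10(self.lam_min), np.log10(self.lam_max), self.n_lambda)


class RandomizedLasso:
    """Stability-selection model for one response (e.g. HNAcc or LNAcc).

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
        Predictor matrix, typically CLR-transformed relative abundances.
    y : array-like, shape (n,)
        Response vector aligned with the rows of X.
    taxon_ids : sequence of str, optional
        Column names; taken from the DataFrame when omitted.
    config : StabilityConfig, optional
        Operating parameters; keyword overrides are also accepted.
    """

    def __init__(self, X, y, taxon_ids=None, config: StabilityConfig | None = None, **overrides):
        if isinstance(X, pd.DataFrame):
            if taxon_ids is None:
                taxon_ids = list(X.columns)
            X = X.to_numpy()
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in X or y")
        self.taxon_ids = list(taxon_ids) if taxon_ids is not None else [f"x{j}" for j in range(p)]
        cfg = config or StabilityConfig()
        if overrides:
            cfg = StabilityConfig(**{**cfg.__dict__, **overrides})
        self.config = cfg
        n_sub = int(np.floor(cfg.subsample_fraction * n))
        if n_sub < 2:
            raise ValueError(f"subsample size floor({cfg.subsample_fraction}*{n}) < 2")
        self._n_sub = n_sub

    def fit(self, seed: int | None = 0) -> "StabilityResults":
        """Run the B subsample fits; deterministic given ``seed``."""
        cfg = self.config
        n, p = self.X.shape
        rng = np.random.default_rng(seed)
        lams_asc = cfg.lam_grid
        lams_desc = lams_asc[::-1].copy()
        sel_counts = np.zeros((cfg.n_lambda, p), dtype=np.int64)
        for _ in range(cfg.B):
            idx = rng.choice(n, size=self._n_sub, replace=False)
            w = np.where(rng.random(p) < 0.5, cfg.alpha, 1.0)
            Z, yc, _, _, _ = standardize_train(self.X[idx], self.y[idx])
            ysd = yc.std()
            if ysd > 0:
                yc = yc / ysd  # unit-variance response keeps the fixed grid meaningful
            G = Z.T @ Z
            c = Z.T @ yc
            betas = lasso_path_gram(G, c, lams_desc, w, tol=cfg.tol, max_iter=cfg.max_iter)
            sel_counts += (betas[::-1] != 0)  # back to ascending-lambda order
        path = sel_counts / cfg.B
        return StabilityResults(
            model=self,
            path=pd.DataFrame(path, index=lams_asc, columns=self.taxon_ids),
            seed=seed,
        )


@dataclass
class StabilityResults:
    """Stability path and per-taxon RL scores from a fitted RandomizedLasso."""

    model: RandomizedLasso
    path: pd.DataFrame  # index: ascending lambda grid; columns: taxa
    seed: int | None = None
    _scores: pd.Series = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._scores = self.path.max(axis=0)
        self._scores.name = "rl_score"

    @property
    def scores(self) -> pd.Series:
        """RL score per taxon: max selection frequency over the penalty path."""
        return self._scores

    def ranking(self) -> pd.Series:
        """Scores ordered descending, ties broken by original column order."""
        order = np.argsort(-self._scores.to_numpy(), kind="stable")
        return self._scores.iloc[order]

    def select(self, threshold: float = 0.5) -> list[str]:
        return select_by_score(self._scores, threshold)

    def summary(self, top: int = 10) -> pd.DataFrame:
        """Top-ranked taxa with their RL scores and the penalty achieving them."""
        ranked = self.ranking().head(top)
        lam_at_max = self.path[ranked.index].idxmax(axis=0)
        out = pd.DataFrame(
            {"rl_score": ranked, "lambda_at_max": lam_at_max[ranked.index]}
        )
        out.index.name = "taxon_id"
        return out

    def plot_path(self, taxa=None, ax=None):
        """Stability path (selection frequency vs lambda) for chosen taxa."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cols = taxa if taxa is not None else self.ranking().head(8).index
        for t in cols:
            ax.semilogx(self.path.index, self.path[t], label=str(t))
        ax.set_xlabel(r"penalty $\lambda$")
        ax.set_ylabel("selection frequency")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize="x-small")
        return ax

    def to_csv(self, scores_path, path_path=None) -> None:
        df = self._scores.rename_axis("taxon_id").reset_index()
        df.to_csv(scores_path, index=False, float_format="%.10g", lineterminator="\n")
        if path_path is not None:
            long = self.path.rename_axis("lambda").reset_index().melt(
                id_vars="lambda", var_name="taxon_id", value_name="frequency"
            )
            long.to_csv(path_path, index=False, float_format="%.10g", lineterminator="\n")


def select_by_score(scores: pd.Series, threshold: float = 0.5) -> list[str]:
    """Taxa with score strictly above ``threshold``, descending score order.

    Ties are broken by original column order, making the ranking reproducible.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    arr = scores.to_numpy()
    order = np.argsort(-arr, kind="stable")
    return [scores.index[j] for j in order if arr[j] > threshold]
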