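"""All-relevant variable selection with shadow features (Boruta).

Each iteration appends a permuted "shadow" copy of every still-undecided
variable to the design, fits a Random-Forest regressor, and records a *hit*
for each original variable whose impurity importance exceeds the maximum
shadow importance.  Accumulated hit counts are tested against a Binomial(t,
0.5) null, two-sided, at a Bonferroni-corrected level: significantly-high
variables are confirmed (kept in the design, no longer tested),
significantly-low ones rejected (removed from the design), and whatever
remains when the iterations run out is labelled tentative.

Defaults follow the published setup: 300 iterations, forests with 200 trees,
p/3 candidate features per split, minimum of five samples per leaf, and
alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["BorutaConfig", "Boruta", "BorutaResults", "compare_selections"]

CONFIRMED = "confirmed"


def _fdr_reject(p_values: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    m = p_values.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p_values, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    passed = p_values[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        out[order[: k + 1]] = True
    return out
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass
class BorutaConfig:
    n_iterations: int = 300
    rf_trees: int = 200
    rf_max_features: float = 1 / 3  # fraction of p considered per split
    rf_min_leaf: int = 5
    alpha: float = 0.05  # level of the two-step (FDR + per-variable Bonferroni) test

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1 (no evidence otherwise)")
        if self.rf_trees < 1 or self.rf_min_leaf < 1:
            raise ValueError("rf_trees and rf_min_leaf must be positive")
        if not (0 < self.rf_max_features <= 1):
            raise ValueError("rf_max_features must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


class Boruta:
    """Boruta model for one response; ``fit(seed)`` returns :class:`BorutaResults`."""

    def __init__(self, X, y, taxon_ids=None, config: BorutaConfig | None = None, **overrides):
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
        if n < 10:
            raise ValueError("Boruta needs at least 10 samples")
        self.taxon_ids = list(taxon_ids) if taxon_ids is not None else [f"x{j}" for j in range(p)]
        cfg = config or BorutaConfig()
        if overrides:
            cfg = BorutaConfig(**{**cfg.__dict__, **overrides})
        self.config = cfg

    def fit(self, seed: int | None = 0) -> "BorutaResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        n, p = self.X.shape
        labels = np.array([TENTATIVE] * p, dtype=object)
        hits = np.zeros(p, dtype=np.int64)
        tested_iters = np.zeros(p, dtype=np.int64)
        in_design = np.ones(p, dtype=bool)   # confirmed stay, rejected leave
        undecided = np.ones(p, dtype=bool)
        history = []
        for t in range(1, cfg.n_iterations + 1):
            if not undecided.any():
                break
            design_cols = np.flatnonzero(in_design)
            Xd = self.X[:, design_cols]
            # shadows are re-permuted copies of *all* original columns: the
            # max-shadow reference must stay a maximum over the same number of
            # noise features in every iteration, otherwise the hit bar
            # collapses as variables are rejected and chance-correlated
            # survivors get confirmed
            shadow = self.X.copy()
            for k in range(p):
                shadow[:, k] = shadow[rng.permutation(n), k]
            Xfull = np.hstack([Xd, shadow])
            forest = RandomForestRegressor(
                n_estimators=cfg.rf_trees,
                max_features=max(1, int(round(cfg.rf_max_features * p))),
                min_samples_leaf=cfg.rf_min_leaf,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            forest.fit(Xfull, self.y)
            imp = forest.feature_importances_
            orig_imp = imp[: len(design_cols)]
            shadow_max = imp[len(design_cols):].max()
            for local_j, j in enumerate(design_cols):
                if undecided[j]:
                    tested_iters[j] += 1
                    if orig_imp[local_j] > shadow_max:
                        hits[j] += 1
            history.append(
                pd.DataFrame(
                    {
                        "iteration": t,
                        "taxon_id": [self.taxon_ids[j] for j in design_cols],
                        "importance": orig_imp,
                        "shadow_max": shadow_max,
                    }
                )
            )
            # two-step decision: Benjamini-Hochberg across the undecided
            # variables combined with a Bonferroni bound over the number of
            # times each variable has been tested.  The iteration-indexed
            # bound tightens as evidence accumulates, so only variables with
            # consistently extreme hit rates are ever decided — borderline
            # hit rates (chance-correlated taxa) stay tentative
            und = np.flatnonzero(undecided)
            p_hi = stats.binom.sf(hits[und] - 1, tested_iters[und], 0.5)
            p_lo = stats.binom.cdf(hits[und], tested_iters[und], 0.5)
            acc = _fdr_reject(p_hi, cfg.alpha) & (p_hi < cfg.alpha / tested_iters[und])
            rej = _fdr_reject(p_lo, cfg.alpha) & (p_lo < cfg.alpha / tested_iters[und])
            for j, a, r in zip(und, acc, rej):
                if a:
                    labels[j] = CONFIRMED
                    undecided[j] = False
                elif r:
                    labels[j] = REJECTED
                    undecided[j] = False
                    in_design[j] = False
        table = pd.DataFrame(
            {
                "label": labels,
                "hits": hits,
                "n_iter": tested_iters,
            },
            index=pd.Index(self.taxon_ids, name="taxon_id"),
        )
        return BorutaResults(
            table=table,
            importance_history=pd.concat(history, ignore_index=True) if history else pd.DataFrame(),
            seed=seed,
        )


@dataclass
class BorutaResults:
    table: pd.DataFrame  # index taxon_id; columns label, hits, n_iter
    importance_history: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    seed: int | None = None

    @property
    def confirmed(self) -> list[str]:
        return list(self.table.index[self.table["label"] == CONFIRMED])

    @property
    def rejected(self) -> list[str]:
        return list(self.table.index[self.table["label"] == REJECTED])

    @property
    def tentative(self) -> list[str]:
        return list(self.table.index[self.table["label"] == TENTATIVE])

    def summary(self) -> pd.DataFrame:
        counts = self.table["label"].value_counts()
        return counts.reindex([CONFIRMED, TENTATIVE, REJECTED], fill_value=0).to_frame("n_taxa")

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False, lineterminator="\n")


def compare_selections(
    rl_selected: list[str],
    boruta: BorutaResults | list[str],
    tau_significant: list[str],
    universe: list[str] | None = None,
) -> dict:
    """Three-way agreement between RL, Boruta-confirmed and tau-b-significant taxa.

    Returns set sizes, all pairwise/triple intersection counts and a
    per-taxon membership table over the shared universe.
    """
    b = set(boruta.confirmed) if isinstance(boruta, BorutaResults) else set(boruta)
    r = set(rl_selected)
    t = set(tau_significant)
    if universe is None:
        universe = sorted(r | b | t)
    membership = pd.DataFrame(
        {
            "rl": [u in r for u in universe],
            "boruta": [u in b for u in universe],
            "tau": [u in t for u in universe],
        },
        index=pd.Index(universe, name="taxon_id"),
    )
    return {
        "sizes": {"rl": len(r), "boruta": len(b), "tau": len(t)},
        "rl_and_boruta": len(r & b),
        "rl_and_tau": len(r & t),
        "boruta_and_tau": len(b & t),
        "all_three": len(r & b & t),
        "membership": membership,
    }
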