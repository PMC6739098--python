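"""Compositional preprocessing of taxon count tables.

The canonical order of operations is prevalence filtering at the OTU level,
rarefaction to an even depth, conversion to relative abundances, then the
centered log-ratio (CLR) transform with zero replacement delta = 1/p**2.
The pipeline orchestrator enforces this order; the functions here are
order-agnostic building blocks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TaxonTable

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionMatrix",
    "ClrMatrix",
    "filter_taxa",
    "rarefy",
    "aggregate_taxonomy",
    "to_relative",
    "clr_transform",
]


@dataclass
class CompositionMatrix:
    """Relative abundances: rows sum to one."""

    rel: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.rel.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(arr > 1 + 1e-12):
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.rel.index[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(f"row {bad!r} does not sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rel.columns)


@dataclass
class ClrMatrix:
    """CLR-transformed abundances; ``delta`` is the zero replacement used."""

    z: pd.DataFrame
    delta: float


def filter_taxa(table: TaxonTable, min_count: int = 5, min_fraction: float = 0.10) -> TaxonTable:
    """Keep taxa observed with >= ``min_count`` reads in >= ``min_fraction`` of samples.

    The prevalence requirement is ``ceil(min_fraction * n)`` samples.  The
    defaults implement the "at least five sequences in 10% of the samples"
    rule.  Survivor order is preserved.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    n = table.n_samples
    need = math.ceil(min_fraction * n)
    prevalent = (table.counts.to_numpy() >= min_count).sum(axis=0)
    keep = prevalent >= need
    if not keep.any():
        raise ValueError(
            f"no taxa pass min_count={min_count}, min_fraction={min_fraction}; "
            "lower the thresholds"
        )
    kept_cols = table.counts.columns[keep]
    tax = table.taxonomy.loc[kept_cols] if table.taxonomy is not None else None
    return TaxonTable(table.counts.loc[:, kept_cols], tax)


def rarefy(table: TaxonTable, depth: int, seed: int) -> TaxonTable:
    """Subsample each sample to ``depth`` reads uniformly without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    Deterministic given ``seed`` (one multivariate-hypergeometric draw per
    sample, in row order).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = counts.index[~keep].tolist()
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    rows = []
    for sid in counts.index[keep]:
        row = counts.loc[sid].to_numpy()
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    out = pd.DataFrame(np.asarray(rows, dtype=np.int64), index=counts.index[keep], columns=counts.columns)
    return TaxonTable(out, table.taxonomy)


def aggregate_taxonomy(table: TaxonTable, level: str) -> TaxonTable:
    """Sum counts over taxa sharing all taxonomy labels down to ``level``.

    Per-sample totals are conserved at every rank.  Aggregating at the finest
    rank (each taxon its own label) is the identity up to taxon naming.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy; cannot aggregate")
    ranks = list(table.taxonomy.columns)
    if level not in ranks:
        raise ValueError(f"unknown rank {level!r}; available: {ranks}")
    upto = ranks[: ranks.index(level) + 1]
    labels = table.taxonomy[upto].astype(str).agg(";".join, axis=1)
    # first-appearance order of aggregate labels
    uniq = labels[~labels.duplicated()].tolist()
    groups = {lab: labels.index[labels == lab] for lab in uniq}
    agg = pd.DataFrame(
        {lab: table.counts[cols].sum(axis=1) for lab, cols in groups.items()},
        index=table.counts.index,
    )
    tax_rows = pd.DataFrame(
        [table.taxonomy.loc[groups[lab][0], upto] for lab in uniq], index=uniq
    )
    return TaxonTable(agg, tax_rows)


def to_relative(table: TaxonTable) -> CompositionMatrix:
    """Divide each count by its sample's sequencing depth."""
    counts = table.counts.to_numpy(dtype=float)
    sums = counts.sum(axis=1)
    if np.any(sums <= 0):
        bad = table.counts.index[sums <= 0].tolist()
        raise ValueError(f"zero-sum sample(s): {bad}")
    rel = counts / sums[:, None]
    return CompositionMatrix(pd.DataFrame(rel, index=table.counts.index, columns=table.counts.columns))


def clr_transform(comp: CompositionMatrix | pd.DataFrame, delta: float | None = None) -> ClrMatrix:
    """Centered log-ratio transform with zero replacement.

    Zeros are replaced by ``delta`` (default ``1/p**2``) and the row is *not*
    renormalized afterwards; then ``z_ij = ln x_ij - mean_k ln x_ik``, so each
    row of ``z`` sums to zero by construction.  The transform is invariant to
    positive rescaling of a row.
    """
    rel = comp.rel if isinstance(comp, CompositionMatrix) else comp
    arr = rel.to_numpy(dtype=float)
    n, p = arr.shape
    if p < 2:
        raise ValueError("CLR requires at least 2 taxa")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("abundances must be finite and non-negative")
    if delta is None:
        delta = 1.0 / p**2
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.where(arr == 0, delta, arr)
    logx = np.log(x)
    z = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(z, index=rel.index, columns=rel.columns), delta)
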