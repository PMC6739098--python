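"""Gating, cell counting and the binned KDE fingerprint.

Events arrive on the instrument scale and are mapped to [0, 1]^2 by an
asinh transform (configurable cofactor, default 150) followed by a fixed
min-max rescale.  A polygon gate in the transformed plane separates cells
from background noise; a single fixed FL1 threshold then splits cells into
the low- and high-nucleic-acid populations (LNA/HNA), the same threshold for
every sample.  Per-replicate counts divided by the analysed volume give
cells/ml, averaged arithmetically over replicates (HNAcc, LNAcc).

The fingerprint is an exact Gaussian kernel density (bandwidth 0.01 on the
rescaled scale) evaluated at the centers of a fixed 128 x 128 grid and
normalized to unit mass per sample, so bin densities are comparable across
samples.  Per-bin Kendall tau-b against taxon relative abundances maps which
fingerprint subregions co-vary with which taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath

from .io import FcmSample
from .preprocess import CompositionMatrix
from .stats import kendall_tau_b_many

__all__ = [
    "GateConfig",
    "FunctionalCounts",
    "FingerprintGrid",
    "gate_counts",
    "fingerprint",
    "bin_correlations",
    "transform_events",
]

DEFAULT_NOISE_POLYGON = ((0.15, 0.02), (1.0, 0.02), (1.0, 1.0), (0.15, 1.0))


@dataclass
class GateConfig:
    """Fixed gates and the channel transform shared by every sample.

    ``noise_polygon`` lives in transformed (FL1, FL3) coordinates in
    [0, 1]^2; ``hna_threshold`` is a transformed-FL1 cutoff and must lie
    inside the polygon's FL1 span.  ``cofactor`` is the asinh cofactor;
    ``raw_min``/``raw_max`` bound the instrument scale for the rescale.
    """

    noise_polygon: tuple = DEFAULT_NOISE_POLYGON
    hna_threshold: float = 0.5
    cofactor: float = 150.0
    raw_min: float = 0.0
    raw_max: float = 1e6

    def __post_init__(self) -> None:
        poly = np.asarray(self.noise_polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise ValueError("noise_polygon needs >= 3 (FL1, FL3) vertices")
        fl1 = poly[:, 0]
        if not (fl1.min() <= self.hna_threshold <= fl1.max()):
            raise ValueError("hna_threshold must lie inside the noise gate's FL1 range")
        if self.cofactor <= 0 or self.raw_max <= self.raw_min:
            raise ValueError("invalid transform parameters")
        self._path = MplPath(poly)

    # -- channel transform ------------------------------------------------
    def transform(self, raw: np.ndarray) -> np.ndarray:
        lo = math.asinh(self.raw_min / self.cofactor)
        hi = math.asinh(self.raw_max / self.cofactor)
        u = (np.arcsinh(np.asarray(raw, float) / self.cofactor) - lo) / (hi - lo)
        return np.clip(u, 0.0, 1.0)

    def inverse_transform(self, u: np.ndarray) -> np.ndarray:
        lo = math.asinh(self.raw_min / self.cofactor)
        hi = math.asinh(self.raw_max / self.cofactor)
        return np.sinh(lo + np.asarray(u, float) * (hi - lo)) * self.cofactor

    def noise_gate_mask(self, uv: np.ndarray) -> np.ndarray:
        """Boolean mask of transformed events inside the cell (non-noise) gate."""
        return self._path.contains_points(uv)

    # -- (de)serialization ------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "noise_polygon": [list(map(float, v)) for v in np.asarray(self.noise_polygon)],
            "hna_threshold": float(self.hna_threshold),
            "cofactor": float(self.cofactor),
            "raw_min": float(self.raw_min),
            "raw_max": float(self.raw_max),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "GateConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["noise_polygon"] = tuple(tuple(v) for v in data["noise_polygon"])
        return cls(**data)


def transform_events(sample: FcmSample, gate: GateConfig) -> np.ndarray:
    """Events as transformed (FL1, FL3) in [0, 1]^2, noise NOT yet removed."""
    return gate.transform(sample.events[["FL1", "FL3"]].to_numpy())


@dataclass
class FunctionalCounts:
    """Replicate-averaged absolute cell concentrations for one sample."""

    sample_id: str
    hnacc: float
    lnacc: float
    n_replicates: int

    @property
    def totalcc(self) -> float:
        return self.hnacc + self.lnacc


def gate_counts(rep_samples: list[FcmSample], gate: GateConfig) -> FunctionalCounts:
    """Gate each replicate and average the cells/ml counts.

    Events inside the noise polygon are split at the fixed FL1 threshold
    (HNA strictly above, LNA at or below); counts are divided by the
    replicate's analysed volume and averaged arithmetically.  The result is
    invariant to event order and replicate order.
    """
    if not rep_samples:
        raise ValueError("need at least one replicate")
    sample_id = rep_samples[0].sample_id
    hna_per_ml = []
    lna_per_ml = []
    for rep in rep_samples:
        uv = transform_events(rep, gate)
        inside = gate.noise_gate_mask(uv)
        fl1 = uv[inside, 0]
        n_hna = int(np.sum(fl1 > gate.hna_threshold))
        n_lna = int(fl1.size - n_hna)
        hna_per_ml.append(n_hna / rep.volume_ml)
        lna_per_ml.append(n_lna / rep.volume_ml)
    return FunctionalCounts(
        sample_id=sample_id,
        hnacc=float(np.mean(hna_per_ml)),
        lnacc=float(np.mean(lna_per_ml)),
        n_replicates=len(rep_samples),
    )


@dataclass
class FingerprintGrid:
    """Normalized 128 x 128 cell-density image of one sample."""

    sample_id: str
    density: np.ndarray  # (grid, grid), sums to 1
    bandwidth: float

    @property
    def grid(self) -> int:
        return self.density.shape[0]

    def argmax_bin(self) -> tuple[int, int]:
        flat = int(np.argmax(self.density))
        return flat // self.density.shape[1], flat % self.density.shape[1]


def bin_centers(grid: int = 128) -> np.ndarray:
    return (np.arange(grid) + 0.5) / grid


def fingerprint(
    sample: FcmSample,
    gate: GateConfig,
    grid: int = 128,
    bandwidth: float = 0.01,
) -> FingerprintGrid:
    """Gaussian KDE of noise-gated events at the grid bin centers.

    The kernel is isotropic with SD ``bandwidth`` on the rescaled [0, 1]
    scale; the kernel factorizes over channels, so the density image is the
    product of two one-dimensional Gaussian design matrices (exact
    evaluation, no histogram approximation).  The image is normalized to sum
    to one.
    """
    uv = transform_events(sample, gate)
    uv = uv[gate.noise_gate_mask(uv)]
    if uv.shape[0] < 2:
        raise ValueError(f"sample {sample.sample_id}: KDE needs >= 2 gated events")
    centers = bin_centers(grid)
    # (grid, m) Gaussian factors per channel
    gx = np.exp(-0.5 * ((centers[:, None] - uv[None, :, 0]) / bandwidth) ** 2)
    gy = np.exp(-0.5 * ((centers[:, None] - uv[None, :, 1]) / bandwidth) ** 2)
    dens = gx @ gy.T  # sum over events of the product kernel
    total = dens.sum()
    if total <= 0:
        raise ValueError("degenerate KDE (all mass outside the grid)")
    return FingerprintGrid(sample.sample_id, dens / total, bandwidth)


@dataclass
class BinCorrelationMap:
    """Per-bin Kendall tau-b between fingerprint density and taxon abundance."""

    taxon_id: str
    tau: np.ndarray  # (grid, grid); NaN where bin density is constant
    p: np.ndarray

    def max_abs_bin(self) -> tuple[int, int]:
        a = np.abs(self.tau)
        a = np.where(np.isnan(a), -np.inf, a)
        flat = int(np.argmax(a))
        return flat // self.tau.shape[1], flat % self.tau.shape[1]

    def to_long(self) -> pd.DataFrame:
        g = self.tau.shape[0]
        rows, cols = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        return pd.DataFrame(
            {
                "taxon_id": self.taxon_id,
                "row": rows.ravel(),
                "col": cols.ravel(),
                "tau_b": self.tau.ravel(),
                "p": self.p.ravel(),
            }
        )


def bin_correlations(
    grids: dict[str, FingerprintGrid],
    comp: CompositionMatrix,
    taxa: list[str],
) -> dict[str, BinCorrelationMap]:
    """tau-b between each taxon's relative abundance and every bin's density.

    ``grids`` maps sample id to its fingerprint; samples are matched to the
    composition rows by id.  Bins whose density is constant across samples
    are flagged NaN (undefined), not zero.
    """
    ids = [sid for sid in comp.rel.index if sid in grids]
    if len(ids) < 3:
        raise ValueError("need >= 3 samples with both composition and fingerprint")
    missing = [t for t in taxa if t not in comp.rel.columns]
    if missing:
        raise ValueError(f"taxa not in composition: {missing}")
    g = next(iter(grids.values())).grid
    dens = np.stack([grids[sid].density.ravel() for sid in ids])  # (n, g*g)
    out = {}
    for taxon in taxa:
        x = comp.rel.loc[ids, taxon].to_numpy()
        taus, ps = kendall_tau_b_many(x, dens)
        out[taxon] = BinCorrelationMap(taxon, taus.reshape(g, g), ps.reshape(g, g))
    return out
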