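"""Synthetic communities, targets and cytometry clouds with known truth.

The generator emulates the statistical structure the analysis assumes:

* **Community** — per-taxon baseline log-abundances are Gaussian (log-normal
  abundances, realistic rank-abundance skew), shifted by site-by-year group
  effects and per-sample noise; the softmax gives each sample's true
  composition and counts are multinomial at the sequencing depth.
* **Targets** — a small planted driver set determines HNA/LNA cell
  concentrations linearly on the CLR scale of the *true* composition, plus
  Gaussian noise whose SD is calibrated so the out-of-group linear oracle
  reaches a requested pooled R² (0.6 by default).  The default identity
  link scales a standardized linear index into cells/ml around a large
  baseline; a log link (positive by construction, multiplicative noise) is
  also available.
* **Cytometry** — each sample gets three replicate event clouds from a 2-D
  Gaussian mixture: one broad LNA and one broad HNA base component on either
  side of the fixed FL1 threshold, a small background-noise component
  outside the cell gate, and one tight subcomponent per driver whose mixture
  weight is proportional to that driver's relative abundance.  Event numbers
  follow Poisson sampling at the analysed volume, so gated counts recover
  the generating concentrations up to Poisson noise.

Everything is deterministic from a single master seed, hierarchically split
per stage and sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fcm import GateConfig
from .io import FcmSample, SampleMetadata, TaxonTable, write_fcm_events, write_taxon_table
from .preprocess import clr_transform

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "simulate_community",
    "simulate_targets",
    "simulate_fcm",
    "simulate_dataset",
    "write_fixture",
]


@dataclass
class SimConfig:
    """Study-scale defaults: 60 samples in 10 site-by-year groups, 300 taxa,
    10 drivers per functional group, sequencing depth 5000."""

    n_samples: int = 60
    p_taxa: int = 300
    n_groups: int = 10
    depth: int = 9000
    n_drivers: int = 10
    effect_low: float = 0.3
    effect_high: float = 0.6
    overlap_fraction: float = 0.2  # drivers shared between the HNA and LNA sets
    target_r2: float | None = 0.6  # linear-oracle pooled R²; None -> use sigma
    sigma: float = 0.5
    link: str = "identity"  # additive cells/ml noise; "log" for multiplicative
    mixed_signs: bool = True
    base_sd: float = 1.5
    group_sd: float = 0.15
    eps_sd: float = 0.35
    driver_factor_sd: float = 0.4  # shared guild dynamics loading on drivers
    a0_hna: float = math.log(3e5)  # baseline log cells/ml (log link)
    a0_lna: float = math.log(2e5)
    a0_lin_hna: float = 4e5  # baseline cells/ml (identity link)
    a0_lin_lna: float = 3e5
    lin_scale: float = 8e4  # cells/ml per unit of the linear index (identity)
    floor_cc: float = 1e4  # positivity floor for the identity link
    volume_ml: float = 0.005
    n_replicates: int = 3
    noise_fraction: float = 0.05  # background events relative to cells
    blob_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 3:
            raise ValueError("n_groups must be >= 3")
        if self.p_taxa <= self.n_drivers:
            raise ValueError("p_taxa must exceed n_drivers")
        if self.n_samples < self.n_groups:
            raise ValueError("need at least one sample per group")
        if self.link not in ("log", "identity"):
            raise ValueError("link must be 'log' or 'identity'")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth against which recovery is scored."""

    drivers_hna: list[str]
    drivers_lna: list[str]
    coef_hna: dict[str, float]
    coef_lna: dict[str, float]
    sigma_hna: float
    sigma_lna: float
    link: str
    a0_hna: float
    a0_lna: float
    subregions: dict[str, dict]  # taxon -> {region, cx, cy, sd, radius}
    seed: int
    groups: np.ndarray = field(repr=False, default=None)  # per-sample block label
    true_composition: pd.DataFrame = field(repr=False, default=None)
    true_clr: pd.DataFrame = field(repr=False, default=None)

    @property
    def all_drivers(self) -> list[str]:
        return sorted(set(self.drivers_hna) | set(self.drivers_lna))


def simulate_community(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Multinomial counts over a latent log-normal community with group effects.

    Returns ``(TaxonTable, SampleMetadata, SyntheticTruth)``; the truth holds
    the true (pre-sampling) compositions, their CLR, the planted driver sets
    with coefficients, and the cytometry subregion assignments.  Noise SDs
    for the targets are filled in by :func:`simulate_targets`.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n, p, G = cfg.n_samples, cfg.p_taxa, cfg.n_groups
    taxa = [f"OTU{j + 1:04d}" for j in range(p)]
    samples = [f"S{i + 1:03d}" for i in range(n)]
    groups = np.array([i * G // n for i in range(n)])

    base = rng.normal(0.0, cfg.base_sd, size=p)
    gamma = rng.normal(0.0, cfg.group_sd, size=(G, p))
    eps = rng.normal(0.0, cfg.eps_sd, size=(n, p))

    # planted drivers: drawn from the dominant community members (echoing the
    # abundant bacterioplankton groups that track cytometric populations), so
    # their counts carry little multinomial noise and the prevalence filter
    # cannot silently remove them
    n_overlap = int(round(cfg.overlap_fraction * cfg.n_drivers))
    n_union = 2 * cfg.n_drivers - n_overlap
    order = np.argsort(-base, kind="stable")
    pool = order[: max(2 * n_union, 30)]
    chosen = rng.choice(pool, size=n_union, replace=False)
    hna_idx = list(chosen[: cfg.n_drivers])
    lna_idx = list(chosen[cfg.n_drivers - n_overlap :])
    signs = rng.choice([-1.0, 1.0], size=n_union) if cfg.mixed_signs else np.ones(n_union)
    mags = rng.uniform(cfg.effect_low, cfg.effect_high, size=n_union)
    coef_union = {int(j): float(s * m) for j, s, m in zip(chosen, signs, mags)}

    # drivers co-vary as guilds: one latent factor per functional group loads
    # on its drivers with the sign of their effect, so each driver is
    # individually informative while the response stays exactly linear in the
    # driver CLRs.  LNA-only drivers ride a separate factor and therefore stay
    # uninformative for the HNA response (and vice versa).
    factor_hna = rng.normal(0.0, 1.0, size=n)
    factor_lna = rng.normal(0.0, 1.0, size=n)
    lam = base[None, :] + gamma[groups] + eps
    sign_of = {int(j): float(s) for j, s in zip(chosen, signs)}
    for j in hna_idx:
        lam[:, j] += cfg.driver_factor_sd * sign_of[j] * factor_hna
    for j in lna_idx:
        if j not in hna_idx:
            lam[:, j] += cfg.driver_factor_sd * sign_of[j] * factor_lna
    expl = np.exp(lam - lam.max(axis=1, keepdims=True))
    comp = expl / expl.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(cfg.depth, comp[i]) for i in range(n)])

    table = TaxonTable(pd.DataFrame(counts, index=samples, columns=taxa))
    meta = SampleMetadata(
        pd.DataFrame(
            {"lake_system": "sim", "group_id": [f"g{g:02d}" for g in groups]},
            index=pd.Index(samples, name="sample_id"),
        )
    )

    subregions = _assign_subregions(cfg, rng, taxa, hna_idx, lna_idx)

    comp_df = pd.DataFrame(comp, index=samples, columns=taxa)
    truth = SyntheticTruth(
        drivers_hna=[taxa[j] for j in hna_idx],
        drivers_lna=[taxa[j] for j in lna_idx],
        coef_hna={taxa[j]: coef_union[j] for j in hna_idx},
        coef_lna={taxa[j]: coef_union[j] for j in lna_idx},
        sigma_hna=cfg.sigma,
        sigma_lna=cfg.sigma,
        link=cfg.link,
        a0_hna=cfg.a0_hna,
        a0_lna=cfg.a0_lna,
        subregions=subregions,
        seed=cfg.seed,
        groups=groups,
        true_composition=comp_df,
        true_clr=clr_transform(comp_df).z,
    )
    return table, meta, truth


def _assign_subregions(cfg, rng, taxa, hna_idx, lna_idx, threshold=0.5):
    """Place one tight mixture component per driver on a shuffled lattice,
    HNA drivers above the FL1 threshold, LNA-only drivers below."""
    out = {}
    lna_only = [j for j in lna_idx if j not in hna_idx]

    def lattice(x_lo, x_hi, y_lo, y_hi, m):
        k = max(2, math.ceil(math.sqrt(m)))
        xs = np.linspace(x_lo, x_hi, k)
        ys = np.linspace(y_lo, y_hi, k)
        pts = [(float(x), float(y)) for x in xs for y in ys]
        sel = rng.permutation(len(pts))[:m]
        return [pts[i] for i in sel]

    for j, (cx, cy) in zip(hna_idx, lattice(threshold + 0.08, 0.92, 0.15, 0.88, len(hna_idx))):
        out[taxa[j]] = {"region": "hna", "cx": cx, "cy": cy, "sd": cfg.blob_sd, "radius": 0.1}
    for j, (cx, cy) in zip(lna_only, lattice(0.20, threshold - 0.08, 0.10, 0.80, len(lna_only))):
        out[taxa[j]] = {"region": "lna", "cx": cx, "cy": cy, "sd": cfg.blob_sd, "radius": 0.1}
    return out


def _calibrate_sigma(f, make_y, eps_unit, Z_drivers, target_r2, groups):
    """Bisect the noise SD so the linear oracle attains ``target_r2``.

    The oracle is OLS of the response on the true driver CLR columns,
    evaluated as *pooled out-of-group* R² under leave-one-group-out over the
    blocking labels — the same score the pipeline is judged by.
    """
    uniq = np.unique(groups)
    A = np.column_stack([np.ones(len(f)), Z_drivers])

    def oracle_r2(sigma: float) -> float:
        y = make_y(f + sigma * eps_unit)
        preds = np.empty_like(y)
        for g in uniq:
            tr = groups != g
            coef, *_ = np.linalg.lstsq(A[tr], y[tr], rcond=None)
            preds[~tr] = A[~tr] @ coef
        sst = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum((y - preds) ** 2) / sst if sst > 0 else 0.0

    lo, hi = 0.0, 8.0
    if oracle_r2(lo) <= target_r2:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if oracle_r2(mid) > target_r2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_targets(
    truth: SyntheticTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
):
    """HNAcc and LNAcc as (log-)linear functions of the true driver CLR values.

    With the log link, ``log(HNAcc_i) = a0 + sum_j b_j z_ij + eps_i`` and the
    counts are strictly positive.  When ``cfg.target_r2`` is set, the noise
    SD is calibrated by bisection against the linear oracle (OLS of the
    response on the true driver CLR columns) and recorded in the truth.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    Z = truth.true_clr
    n = Z.shape[0]
    out = []
    for which in ("hna", "lna"):
        drivers = truth.drivers_hna if which == "hna" else truth.drivers_lna
        coef = truth.coef_hna if which == "hna" else truth.coef_lna
        if truth.link == "log":
            a0 = truth.a0_hna if which == "hna" else truth.a0_lna
            make_y = lambda eta, a0=a0: np.exp(a0 + eta)
        else:
            # unit-variance linear index scaled into cells/ml around a large
            # baseline: exactly linear in the driver CLRs, positive in practice
            # (the floor is a safety net ~5 SD out)
            a0 = cfg.a0_lin_hna if which == "hna" else cfg.a0_lin_lna

            def make_y(eta, a0=a0):
                s = np.std(eta)
                scaled = (eta - np.mean(eta)) / s if s > 0 else eta - np.mean(eta)
                return np.maximum(a0 + cfg.lin_scale * scaled, cfg.floor_cc)
        f = Z[drivers].to_numpy() @ np.array([coef[d] for d in drivers]) if drivers else np.zeros(n)
        eps_unit = rng.standard_normal(n)
        if cfg.target_r2 is not None and drivers:
            sigma = _calibrate_sigma(
                f, make_y, eps_unit, Z[drivers].to_numpy(), cfg.target_r2, truth.groups
            )
        else:
            sigma = cfg.sigma
        if which == "hna":
            truth.sigma_hna = float(sigma)
        else:
            truth.sigma_lna = float(sigma)
        out.append(pd.Series(make_y(f + sigma * eps_unit), index=Z.index, name=f"{which}cc"))
    return out[0], out[1]


def simulate_fcm(
    truth: SyntheticTruth,
    hnacc: pd.Series,
    lnacc: pd.Series,
    cfg: SimConfig,
    gate: GateConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[FcmSample]]:
    """Replicate event clouds whose gated counts match the simulated targets."""
    if gate is None:
        gate = GateConfig()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    thr = gate.hna_threshold
    comp = truth.true_composition
    hna_drivers = [t for t, s in truth.subregions.items() if s["region"] == "hna"]
    lna_drivers = [t for t, s in truth.subregions.items() if s["region"] == "lna"]
    mean_ab = comp.mean(axis=0)
    w0_h = 0.35 / max(len(hna_drivers), 1)
    w0_l = 0.35 / max(len(lna_drivers), 1)

    out: dict[str, list[FcmSample]] = {}
    for sid in comp.index:
        reps = []
        for r in range(cfg.n_replicates):
            n_h = rng.poisson(cfg.volume_ml * hnacc.loc[sid])
            n_l = rng.poisson(cfg.volume_ml * lnacc.loc[sid])
            n_noise = rng.poisson(cfg.noise_fraction * cfg.volume_ml * (hnacc.loc[sid] + lnacc.loc[sid]))
            pts = []
            pts.append(
                _side_events(rng, n_h, (0.72, 0.55), 0.10, hna_drivers, truth, comp, sid,
                             mean_ab, w0_h, fl1_lo=thr + 0.005, fl1_hi=0.995)
            )
            pts.append(
                _side_events(rng, n_l, (0.32, 0.30), 0.10, lna_drivers, truth, comp, sid,
                             mean_ab, w0_l, fl1_lo=0.16, fl1_hi=thr - 0.005)
            )
            if n_noise > 0:
                noise = rng.normal((0.05, 0.08), 0.03, size=(n_noise, 2))
                noise[:, 0] = np.clip(noise[:, 0], 0.0, 0.13)
                noise[:, 1] = np.clip(noise[:, 1], 0.0, 0.5)
                pts.append(noise)
            uv = np.vstack([q for q in pts if len(q)])
            raw = gate.inverse_transform(uv)
            reps.append(
                FcmSample(
                    sample_id=str(sid),
                    replicate_id=f"r{r + 1}",
                    events=pd.DataFrame(raw, columns=["FL1", "FL3"]),
                    volume_ml=cfg.volume_ml,
                )
            )
        out[str(sid)] = reps
    return out


def _side_events(rng, n_events, base_center, base_sd, drivers, truth, comp, sid,
                 mean_ab, w0, fl1_lo, fl1_hi):
    """Events for one side of the threshold: broad base + per-driver blobs."""
    if n_events <= 0:
        return np.empty((0, 2))
    w = np.array([w0 * comp.loc[sid, d] / mean_ab[d] for d in drivers]) if drivers else np.empty(0)
    total = w.sum()
    if total > 0.85:
        w = w * (0.85 / total)
    probs = np.concatenate([[1.0 - w.sum()], w])
    centers = [base_center] + [(truth.subregions[d]["cx"], truth.subregions[d]["cy"]) for d in drivers]
    sds = [base_sd] + [truth.subregions[d]["sd"] for d in drivers]
    comp_idx = rng.choice(len(centers), size=n_events, p=probs)
    pts = np.empty((n_events, 2))
    for k in range(len(centers)):
        mask = comp_idx == k
        m = int(mask.sum())
        if m:
            pts[mask] = rng.normal(centers[k], sds[k], size=(m, 2))
    pts[:, 0] = np.clip(pts[:, 0], fl1_lo, fl1_hi)
    pts[:, 1] = np.clip(pts[:, 1], 0.025, 0.995)
    return pts


@dataclass
class SimulatedDataset:
    config: SimConfig
    table: TaxonTable
    meta: SampleMetadata
    truth: SyntheticTruth
    hnacc: pd.Series
    lnacc: pd.Series
    fcm: dict[str, list[FcmSample]]
    gate: GateConfig


def simulate_dataset(cfg: SimConfig, with_fcm: bool = True) -> SimulatedDataset:
    """Run all three generators off one hierarchically split master seed."""
    ss = np.random.SeedSequence(cfg.seed)
    s_comm, s_targ, s_fcm = ss.spawn(3)
    table, meta, truth = simulate_community(cfg, np.random.default_rng(s_comm))
    hnacc, lnacc = simulate_targets(truth, cfg, np.random.default_rng(s_targ))
    gate = GateConfig()
    fcm = (
        simulate_fcm(truth, hnacc, lnacc, cfg, gate, np.random.default_rng(s_fcm))
        if with_fcm
        else {}
    )
    return SimulatedDataset(cfg, table, meta, truth, hnacc, lnacc, fcm, gate)


def write_fixture(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write the full fixture directory (counts, metadata, targets, events, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_taxon_table(ds.table, outdir / "counts.csv")
    ds.meta.frame.to_csv(outdir / "metadata.csv", index_label="sample_id", lineterminator="\n")
    pd.DataFrame({"hnacc": ds.hnacc, "lnacc": ds.lnacc}).to_csv(
        outdir / "targets.csv", index_label="sample_id", float_format="%.10g", lineterminator="\n"
    )
    ds.gate.to_yaml(outdir / "gate.yaml")
    events_dir = outdir / "events"
    events_dir.mkdir(exist_ok=True)
    for sid, reps in ds.fcm.items():
        for rep in reps:
            write_fcm_events(rep, events_dir / f"{sid}_{rep.replicate_id}.csv")
    truth = {
        "drivers_hna": ds.truth.drivers_hna,
        "drivers_lna": ds.truth.drivers_lna,
        "coef_hna": ds.truth.coef_hna,
        "coef_lna": ds.truth.coef_lna,
        "sigma_hna": ds.truth.sigma_hna,
        "sigma_lna": ds.truth.sigma_lna,
        "link": ds.truth.link,
        "subregions": ds.truth.subregions,
        "seed": ds.truth.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
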