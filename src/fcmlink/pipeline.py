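"""Stage orchestration: disk artifacts are the only inter-stage contract.

Each stage reads its inputs from the fixture paths or from artifacts written
by earlier stages into the output directory, and writes its own artifacts
with fixed floating-point formatting, so any two runs with identical config
and seed produce byte-identical result files and every stage can be rerun
in isolation.  Stage order follows the analysis: preprocess -> gate ->
stability -> elimination -> nested_cv -> boruta -> fingerprint -> assoc.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boruta import Boruta, BorutaConfig, compare_selections
from .evaluation import NestedGroupCV, RecursiveElimination
from .fcm import GateConfig, bin_correlations, fingerprint, gate_counts
from .io import read_fcm_events, read_metadata, read_targets, read_taxon_table
from .preprocess import clr_transform, filter_taxa, rarefy, to_relative
from .stability import RandomizedLasso, StabilityConfig, select_by_score
from .stats import bh_adjust, kendall_tau_b

logger = logging.getLogger(__name__)

STAGES = (
    "preprocess",
    "gate",
    "stability",
    "elimination",
    "nested_cv",
    "boruta",
    "fingerprint",
    "assoc",
)

_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    """Paths, per-stage blocks and the master seed (YAML-serializable)."""

    counts: str = "counts.csv"
    counts_format: str = "wide_csv"
    taxonomy: str | None = None
    metadata: str = "metadata.csv"
    targets: str | None = None
    events_dir: str = "events"
    gate: str | None = None
    outdir: str = "results"
    target: str = "hnacc"  # hnacc | lnacc | hna_fraction | productivity
    seed: int = 0
    filter: dict = field(default_factory=lambda: {"min_count": 5, "min_fraction": 0.10})
    rarefy: dict = field(default_factory=lambda: {"depth": None})
    clr: dict = field(default_factory=lambda: {"enabled": True})
    stability: dict = field(default_factory=lambda: {"B": 100, "alpha": 0.5})
    evaluation: dict = field(default_factory=lambda: {"sizes": "geometric", "eps": 1e-4, "n_lambda": 400})
    nested: dict = field(default_factory=lambda: {"sizes": "geometric"})
    boruta: dict = field(default_factory=lambda: {"n_iterations": 100})
    fingerprint: dict = field(default_factory=lambda: {"grid": 128, "bandwidth": 0.01, "top_taxa": 3})
    score_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        base = Path(path).parent
        for attr in ("counts", "taxonomy", "metadata", "targets", "events_dir", "gate", "outdir"):
            v = getattr(cfg, attr)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, attr, str(base / v))
        return cfg

    def canonical(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, default=str)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _gate_config(cfg: PipelineConfig) -> GateConfig:
    return GateConfig.from_yaml(cfg.gate) if cfg.gate else GateConfig()


def _load_clr(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "clr.csv", index_col=0)

def _load_rel(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "relative_abundance.csv", index_col=0)


def _load_counts_meta(cfg: PipelineConfig, out: Path):
    meta = read_metadata(cfg.metadata)
    X = _load_clr(out) if cfg.clr.get("enabled", True) else _load_rel(out)
    fc = pd.read_csv(out / "functional_counts.csv", index_col=0)
    if cfg.target == "hnacc":
        y = fc["hnacc"]
    elif cfg.target == "lnacc":
        y = fc["lnacc"]
    elif cfg.target == "hna_fraction":
        y = fc["hnacc"] / (fc["hnacc"] + fc["lnacc"])
    elif cfg.target == "productivity":
        if not cfg.targets:
            raise ValueError("target 'productivity' needs a targets CSV")
        y = read_targets(cfg.targets, "productivity")
    else:
        raise ValueError(f"unknown target {cfg.target!r}")
    ids = [s for s in X.index if s in y.index and s in meta.frame.index]
    if not ids:
        raise ValueError("no overlapping samples between predictors, target and metadata")
    return X.loc[ids], y.loc[ids], meta.frame.loc[ids, "group_id"].to_numpy()


# ---------------------------------------------------------------------------
# stages


def _stage_preprocess(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    table = read_taxon_table(cfg.counts, cfg.counts_format, taxonomy_path=cfg.taxonomy)
    table = filter_taxa(table, **cfg.filter)
    depth = cfg.rarefy.get("depth") or int(table.counts.sum(axis=1).min())
    table = rarefy(table, depth, seed=int(seeds["rarefy"]))
    comp = to_relative(table)
    clr = clr_transform(comp)
    table.counts.to_csv(out / "filtered_counts.csv", index_label="sample_id", lineterminator="\n")
    comp.rel.to_csv(out / "relative_abundance.csv", index_label="sample_id",
                    float_format=_FLOAT, lineterminator="\n")
    clr.z.to_csv(out / "clr.csv", index_label="sample_id", float_format=_FLOAT, lineterminator="\n")
    return ["filtered_counts.csv", "relative_abundance.csv", "clr.csv"]


def _stage_gate(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    gate = _gate_config(cfg)
    events_dir = Path(cfg.events_dir)
    files = sorted(events_dir.glob("*.csv")) if events_dir.is_dir() else []
    if not files:
        raise FileNotFoundError(f"no event CSVs found under {events_dir}")
    by_sample: dict[str, list] = {}
    for f in files:
        sid, _, rep = f.stem.rpartition("_")
        sample = read_fcm_events(f, "csv", sample_id=sid or f.stem, replicate_id=rep)
        by_sample.setdefault(sample.sample_id, []).append(sample)
    rows = []
    for sid in sorted(by_sample):
        counts = gate_counts(by_sample[sid], gate)
        rows.append(
            {"sample_id": sid, "hnacc": counts.hnacc, "lnacc": counts.lnacc,
             "totalcc": counts.totalcc, "n_replicates": counts.n_replicates}
        )
    pd.DataFrame(rows).set_index("sample_id").to_csv(
        out / "functional_counts.csv", float_format=_FLOAT, lineterminator="\n"
    )
    return ["functional_counts.csv"]


def _stage_stability(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    X, y, _ = _load_counts_meta(cfg, out)
    model = RandomizedLasso(X, y, config=StabilityConfig(**cfg.stability))
    res = model.fit(seed=int(seeds["stability"]))
    res.to_csv(out / "rl_scores.csv", out / "stability_path.csv")
    return ["rl_scores.csv", "stability_path.csv"]


def _stage_elimination(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    X, y, groups = _load_counts_meta(cfg, out)
    scores = pd.read_csv(out / "rl_scores.csv", index_col=0)["rl_score"].reindex(X.columns)
    sizes_cfg = cfg.evaluation.get("sizes", "geometric")
    kwargs = dict(eps=float(cfg.evaluation.get("eps", 1e-4)),
                  n_lambda=int(cfg.evaluation.get("n_lambda", 400)))
    if sizes_cfg == "full":
        elim = RecursiveElimination(X, y, groups, scores, step=int(cfg.evaluation.get("step", 1)), **kwargs)
    else:
        from .evaluation import geometric_sizes

        elim = RecursiveElimination(X, y, groups, scores, sizes=geometric_sizes(X.shape[1]), **kwargs)
    res = elim.fit()
    res.to_csv(out / "elimination_trace.csv")
    pd.DataFrame({"taxon_id": res.selected_taxa}).to_csv(
        out / "selected_taxa.csv", index=False, lineterminator="\n"
    )
    return ["elimination_trace.csv", "selected_taxa.csv"]


def _stage_nested_cv(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    X, y, groups = _load_counts_meta(cfg, out)
    model = NestedGroupCV(
        X, y, groups,
        stability_config=StabilityConfig(**cfg.stability),
        sizes=cfg.nested.get("sizes", "geometric"),
        eps=float(cfg.evaluation.get("eps", 1e-4)),
        n_lambda=int(cfg.evaluation.get("n_lambda", 400)),
    )
    res = model.fit(seed=int(seeds["nested"]))
    res.to_csv(out / "nested_predictions.csv")
    pd.DataFrame({"rncv2": [res.rncv2]}).to_csv(
        out / "nested_summary.csv", index=False, float_format=_FLOAT, lineterminator="\n"
    )
    return ["nested_predictions.csv", "nested_summary.csv"]


def _stage_boruta(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    X, y, _ = _load_counts_meta(cfg, out)
    res = Boruta(X, y, config=BorutaConfig(**cfg.boruta)).fit(seed=int(seeds["boruta"]))
    res.to_csv(out / "boruta_result.csv")
    return ["boruta_result.csv"]


def _stage_fingerprint(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    gate = _gate_config(cfg)
    fp_cfg = cfg.fingerprint
    events_dir = Path(cfg.events_dir)
    files = sorted(events_dir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no event CSVs found under {events_dir}")
    rel = _load_rel(out)
    grids = {}
    grid_dir = out / "fingerprints"
    grid_dir.mkdir(exist_ok=True)
    for f in files:
        sid, _, rep = f.stem.rpartition("_")
        if rep != "r1" or sid not in rel.index:
            continue  # fingerprint the first replicate of each sample
        sample = read_fcm_events(f, "csv", sample_id=sid, replicate_id=rep)
        fp = fingerprint(sample, gate, grid=int(fp_cfg.get("grid", 128)),
                         bandwidth=float(fp_cfg.get("bandwidth", 0.01)))
        grids[sid] = fp
        np.savetxt(grid_dir / f"{sid}.csv", fp.density, fmt="%.6g", delimiter=",")
    scores = pd.read_csv(out / "rl_scores.csv", index_col=0)["rl_score"]
    top = scores.sort_values(ascending=False, kind="stable").head(
        int(fp_cfg.get("top_taxa", 3))
    ).index.tolist()
    from .preprocess import CompositionMatrix

    sub = rel.loc[list(grids)]
    sub = sub.div(sub.sum(axis=1), axis=0)  # absorb CSV round-off before validation
    maps = bin_correlations(grids, CompositionMatrix(sub), top)
    long = pd.concat([m.to_long() for m in maps.values()], ignore_index=True)
    long.to_csv(out / "bin_correlations.csv", index=False, float_format="%.6g", lineterminator="\n")
    return ["bin_correlations.csv", "fingerprints/"]


def _stage_assoc(cfg: PipelineConfig, out: Path, seeds) -> list[str]:
    X, y, _ = _load_counts_meta(cfg, out)
    taus, ps = [], []
    for t in X.columns:
        tau, p = kendall_tau_b(X[t].to_numpy(), y.to_numpy())
        taus.append(tau)
        ps.append(p)
    adj = bh_adjust(ps)
    tab = pd.DataFrame({"taxon_id": X.columns, "tau_b": taus, "p": ps, "adjusted_p": adj})
    tab.to_csv(out / "tau_target.csv", index=False, float_format=_FLOAT, lineterminator="\n")
    scores = pd.read_csv(out / "rl_scores.csv", index_col=0)["rl_score"]
    rl_sel = select_by_score(scores, cfg.score_threshold)
    boruta_tab = pd.read_csv(out / "boruta_result.csv")
    boruta_sel = boruta_tab.loc[boruta_tab["label"] == "confirmed", "taxon_id"].tolist()
    tau_sel = tab.loc[tab["adjusted_p"] < 0.05, "taxon_id"].tolist()
    agr = compare_selections(rl_sel, boruta_sel, tau_sel, universe=list(X.columns))
    agr["membership"].reset_index().to_csv(out / "selection_membership.csv", index=False, lineterminator="\n")
    summary = {k: v for k, v in agr.items() if k != "membership"}
    (out / "selection_agreement.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return ["tau_target.csv", "selection_membership.csv", "selection_agreement.json"]


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "gate": _stage_gate,
    "stability": _stage_stability,
    "elimination": _stage_elimination,
    "nested_cv": _stage_nested_cv,
    "boruta": _stage_boruta,
    "fingerprint": _stage_fingerprint,
    "assoc": _stage_assoc,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (all eight by default) and write a manifest.

    A stage failure aborts the run with the failing stage named; artifacts
    from completed stages are retained on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(5)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("rarefy", "stability", "nested", "boruta", "extra"), children)
    }
    handler = logging.FileHandler(out / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fcmlink")
    root.addHandler(handler)
    manifest = {
        "package": "fcmlink",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "target": cfg.target,
        "stages": {},
    }
    manifest_path = out / "manifest.json"
    try:
        for name in wanted:
            logger.info("running stage %s", name)
            try:
                outputs = _STAGE_FUNCS[name](cfg, out, seeds)
            except Exception as exc:  # noqa: BLE001 - stage name must surface
                raise StageError(name, exc) from exc
            manifest["stages"][name] = outputs
            manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest
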