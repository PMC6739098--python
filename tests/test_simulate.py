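"""The synthetic-data generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from fcmlink.evaluation import pooled_r2
from fcmlink.fcm import gate_counts
from fcmlink.simulate import (
    SimConfig,
    simulate_community,
    simulate_dataset,
    simulate_targets,
    write_fixture,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_groups=2)
    with pytest.raises(ValueError):
        SimConfig(p_taxa=5, n_drivers=5)
    with pytest.raises(ValueError):
        SimConfig(link="probit")


def test_rows_sum_to_depth_and_determinism():
    cfg = SimConfig(n_samples=12, p_taxa=30, n_groups=3, depth=1000, n_drivers=3, seed=1)
    t1, m1, tr1 = simulate_community(cfg)
    t2, _, _ = simulate_community(cfg)
    assert (t1.counts.sum(axis=1) == 1000).all()
    pd.testing.assert_frame_equal(t1.counts, t2.counts)
    assert set(tr1.drivers_hna) <= set(t1.taxon_ids)
    assert len(tr1.drivers_hna) == 3


def test_driver_overlap_fraction():
    cfg = SimConfig(n_samples=12, p_taxa=50, n_groups=3, n_drivers=10,
                    overlap_fraction=0.2, seed=0)
    _, _, truth = simulate_community(cfg)
    shared = set(truth.drivers_hna) & set(truth.drivers_lna)
    assert len(shared) == 2
    assert len(truth.drivers_hna) == len(truth.drivers_lna) == 10


def test_mean_composition_tracks_truth():
    """Observed mean shares match the mean true composition (multinomial LLN)."""
    cfg = SimConfig(n_samples=200, p_taxa=25, n_groups=4, depth=2000, n_drivers=3, seed=3)
    table, _, truth = simulate_community(cfg)
    obs = table.counts.to_numpy() / 2000
    true = truth.true_composition.to_numpy()
    diff = obs.mean(axis=0) - true.mean(axis=0)
    # per-taxon SE combines multinomial noise and composition variability
    se = np.sqrt(true.var(axis=0) / 200 + true.mean(axis=0) / (2000 * 200))
    assert (np.abs(diff) <= 3 * np.maximum(se, 1e-4)).mean() > 0.9


def test_noiseless_single_driver_is_affine():
    cfg = SimConfig(
        n_samples=15, p_taxa=20, n_groups=3, n_drivers=1, overlap_fraction=0.0,
        target_r2=None, sigma=0.0, seed=5,
    )
    _, _, truth = simulate_community(cfg)
    hnacc, _ = simulate_targets(truth, cfg)
    z = truth.true_clr[truth.drivers_hna[0]].to_numpy()
    # identity link, sigma 0: response is an exact affine function of the
    # driver's CLR value
    fit = np.polyfit(z, hnacc.to_numpy(), 1)
    resid = hnacc.to_numpy() - np.polyval(fit, z)
    assert np.abs(resid).max() < 1e-6 * np.abs(hnacc).max()


def test_log_link_positive_and_affine_in_log():
    cfg = SimConfig(
        n_samples=15, p_taxa=20, n_groups=3, n_drivers=1, overlap_fraction=0.0,
        target_r2=None, sigma=0.0, link="log", seed=5,
    )
    _, _, truth = simulate_community(cfg)
    hnacc, lnacc = simulate_targets(truth, cfg)
    assert (hnacc > 0).all() and (lnacc > 0).all()
    z = truth.true_clr[truth.drivers_hna[0]].to_numpy()
    b = truth.coef_hna[truth.drivers_hna[0]]
    pred = truth.a0_hna + b * z
    np.testing.assert_allclose(np.log(hnacc.to_numpy()), pred, atol=1e-10)


def test_sigma_calibration_hits_oracle_r2():
    cfg = SimConfig(n_samples=60, p_taxa=80, n_groups=10, n_drivers=5, target_r2=0.6, seed=2)
    _, _, truth = simulate_community(cfg)
    hnacc, _ = simulate_targets(truth, cfg)
    # recompute the pooled leave-one-group-out oracle at the calibrated sigma
    Z = truth.true_clr[truth.drivers_hna].to_numpy()
    y = hnacc.to_numpy()
    groups = truth.groups
    A = np.column_stack([np.ones(len(y)), Z])
    preds = np.empty_like(y)
    for g in np.unique(groups):
        tr = groups != g
        coef, *_ = np.linalg.lstsq(A[tr], y[tr], rcond=None)
        preds[~tr] = A[~tr] @ coef
    assert pooled_r2(y, preds) == pytest.approx(0.6, abs=0.02)
    assert truth.sigma_hna > 0


def test_fcm_generative_consistency(fcm_dataset):
    """Gated counts recover the generating concentrations within Poisson noise."""
    ds = fcm_dataset
    zscores = []
    for sid in ds.table.sample_ids:
        fc = gate_counts(ds.fcm[sid], ds.gate)
        true = ds.hnacc[sid]
        sd = np.sqrt(true / (ds.config.n_replicates * ds.config.volume_ml))
        zscores.append((fc.hnacc - true) / sd)
    assert np.abs(zscores).max() <= 4.0
    assert np.abs(np.mean(zscores)) <= 1.0


def test_zero_driver_weight_two_component_cloud():
    cfg = SimConfig(
        n_samples=6, p_taxa=20, n_groups=3, n_drivers=1, overlap_fraction=0.0,
        seed=9, driver_factor_sd=0.0,
    )
    ds = simulate_dataset(cfg)
    # strip the driver subregions: clouds regenerate with base components only
    ds.truth.subregions = {}
    from fcmlink.simulate import simulate_fcm

    fcm = simulate_fcm(ds.truth, ds.hnacc, ds.lnacc, cfg, ds.gate,
                       np.random.default_rng(0))
    sid = ds.table.sample_ids[0]
    uv = ds.gate.transform(fcm[sid][0].events.to_numpy())
    # all cell events concentrate near the two base centers (within 4 SD)
    cells = uv[ds.gate.noise_gate_mask(uv)]
    d_hna = np.hypot(cells[:, 0] - 0.72, cells[:, 1] - 0.55)
    d_lna = np.hypot(cells[:, 0] - 0.32, cells[:, 1] - 0.30)
    assert (np.minimum(d_hna, d_lna) < 0.45).all()


def test_targets_positive_across_seeds():
    for seed in range(5):
        cfg = SimConfig(n_samples=20, p_taxa=30, n_groups=4, n_drivers=3, seed=seed)
        ds = simulate_dataset(cfg, with_fcm=False)
        assert (ds.hnacc > 0).all() and (ds.lnacc > 0).all()


def test_write_fixture_layout(tmp_path):
    cfg = SimConfig(n_samples=6, p_taxa=15, n_groups=3, n_drivers=2, seed=4)
    ds = simulate_dataset(cfg)
    write_fixture(ds, tmp_path)
    assert (tmp_path / "counts.csv").exists()
    assert (tmp_path / "metadata.csv").exists()
    assert (tmp_path / "targets.csv").exists()
    assert (tmp_path / "truth.json").exists()
    assert (tmp_path / "gate.yaml").exists()
    events = list((tmp_path / "events").glob("*.csv"))
    assert len(events) == 6 * cfg.n_replicates
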