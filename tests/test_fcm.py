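"""Gating, cell counting, KDE fingerprints and per-bin correlations."""

import numpy as np
import pandas as pd
import pytest

from fcmlink.fcm import (
    GateConfig,
    bin_correlations,
    fingerprint,
    gate_counts,
    transform_events,
)
from fcmlink.io import FcmSample
from fcmlink.preprocess import CompositionMatrix
from fcmlink.stats import kendall_tau_b


def _sample(uv, gate, sample_id="s", rep="r1", volume_ml=0.001):
    raw = gate.inverse_transform(np.asarray(uv, dtype=float))
    return FcmSample(sample_id, rep, pd.DataFrame(raw, columns=["FL1", "FL3"]), volume_ml)


@pytest.fixture(scope="module")
def gate():
    return GateConfig()


class TestGateConfig:
    def test_transform_round_trip(self, gate):
        u = np.array([[0.1, 0.2], [0.9, 0.5]])
        raw = gate.inverse_transform(u)
        np.testing.assert_allclose(gate.transform(raw), u, atol=1e-10)

    def test_threshold_must_lie_in_gate(self):
        with pytest.raises(ValueError, match="threshold"):
            GateConfig(hna_threshold=0.05)

    def test_yaml_round_trip(self, tmp_path, gate):
        gate.to_yaml(tmp_path / "g.yaml")
        back = GateConfig.from_yaml(tmp_path / "g.yaml")
        assert back.hna_threshold == gate.hna_threshold
        assert back.cofactor == gate.cofactor
        np.testing.assert_allclose(back.noise_polygon, gate.noise_polygon)


class TestGateCounts:
    def test_direct_count_all_hna(self, gate):
        uv = np.full((10, 2), 0.8)  # all above threshold, inside gate
        fc = gate_counts([_sample(uv, gate)], gate)
        assert fc.hnacc == pytest.approx(10_000.0)
        assert fc.lnacc == 0.0
        assert fc.totalcc == pytest.approx(10_000.0)

    def test_replicate_mean(self, gate):
        reps = []
        for k, n_ev in enumerate((1, 2, 3)):
            uv = np.full((n_ev, 2), 0.8)
            reps.append(_sample(uv, gate, rep=f"r{k}", volume_ml=0.01))
        fc = gate_counts(reps, gate)
        assert fc.hnacc == pytest.approx((100 + 200 + 300) / 3)
        assert fc.n_replicates == 3

    def test_threshold_sweep_boundary(self, gate, rng):
        uv = np.column_stack([rng.uniform(0.3, 0.9, 200), rng.uniform(0.2, 0.8, 200)])
        s = _sample(uv, gate)
        low = GateConfig(hna_threshold=0.2)
        fc = gate_counts([s], low)
        assert fc.lnacc == 0.0 and fc.hnacc == fc.totalcc

    def test_event_and_replicate_order_invariance(self, gate, rng):
        uv = np.column_stack([rng.uniform(0.2, 0.95, 300), rng.uniform(0.1, 0.9, 300)])
        s1 = _sample(uv, gate, rep="r1")
        s2 = _sample(uv[::-1], gate, rep="r2")
        a = gate_counts([s1, s2], gate)
        b = gate_counts([s2, s1], gate)
        assert (a.hnacc, a.lnacc) == (b.hnacc, b.lnacc)

    def test_conservation_hna_plus_lna(self, gate, rng):
        uv = rng.uniform(0.0, 1.0, size=(500, 2))
        s = _sample(uv, gate)
        inside = gate.noise_gate_mask(transform_events(s, gate))
        fc = gate_counts([s], gate)
        assert fc.hnacc + fc.lnacc == pytest.approx(inside.sum() / s.volume_ml)


class TestFingerprint:
    def test_tight_cluster_at_center(self, gate, rng):
        uv = 0.5 + 0.002 * rng.standard_normal((200, 2))
        fp = fingerprint(_sample(uv, gate), gate)
        r, c = fp.argmax_bin()
        assert abs(r - 63.5) <= 1.5 and abs(c - 63.5) <= 1.5

    def test_grid_normalized(self, gate, rng):
        uv = np.column_stack([rng.uniform(0.2, 0.9, 400), rng.uniform(0.1, 0.9, 400)])
        fp = fingerprint(_sample(uv, gate), gate)
        assert fp.density.shape == (128, 128)
        assert fp.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert (fp.density >= 0).all()

    def test_mirror_symmetry(self, gate, rng):
        pts = np.column_stack([rng.uniform(0.55, 0.75, 300), rng.uniform(0.3, 0.7, 300)])
        mirrored = pts.copy()
        mirrored[:, 0] = 1.25 - mirrored[:, 0]  # reflect FL1 about 0.625
        uv = np.vstack([pts, mirrored])
        fp = fingerprint(_sample(uv, gate), gate)
        sym = fp.density[::-1, :]  # FL1 runs along rows; 0.625*128 = 80 = 128-48
        # reflection about bin boundary 80 maps row r -> 159-r; compare windows
        a = fp.density[48:80, :]
        b = fp.density[80:112, :][::-1]
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_too_few_events(self, gate):
        with pytest.raises(ValueError, match="2 gated events"):
            fingerprint(_sample([[0.5, 0.5]], gate), gate)


class TestBinCorrelations:
    def _grids_tracking_abundance(self, gate, abund):
        grids = {}
        for i, a in enumerate(abund):
            # cluster mass at (0.75, 0.55) grows with abundance; base at (0.3, 0.3)
            n_blob = int(200 * a * 10)
            rng = np.random.default_rng(i)
            blob = np.column_stack(
                [rng.normal(0.75, 0.01, n_blob), rng.normal(0.55, 0.01, n_blob)]
            )
            base = np.column_stack(
                [rng.normal(0.3, 0.02, 400), rng.normal(0.3, 0.02, 400)]
            )
            grids[f"s{i}"] = fingerprint(_sample(np.vstack([blob, base]), gate, f"s{i}"), gate)
        return grids

    def _comp(self, abund):
        rel = pd.DataFrame(
            {"drv": abund, "other": 1 - np.asarray(abund)},
            index=[f"s{i}" for i in range(len(abund))],
        )
        return CompositionMatrix(rel)

    def test_monotone_abundance_gives_tau_one_at_blob(self, gate):
        abund = [0.02, 0.05, 0.08, 0.11, 0.14]
        maps = bin_correlations(
            self._grids_tracking_abundance(gate, abund), self._comp(abund), ["drv"]
        )
        tau = maps["drv"].tau
        blob = tau[int(0.75 * 128), int(0.55 * 128)]
        base = tau[int(0.30 * 128), int(0.30 * 128)]
        # blob density rises perfectly with abundance; per-sample grid
        # normalization makes the static base region fall in lockstep
        assert blob == pytest.approx(1.0)
        assert base == pytest.approx(-1.0)
        r, c = maps["drv"].max_abs_bin()
        assert abs(tau[r, c]) == pytest.approx(1.0)

    def test_constant_bins_flagged_nan(self, gate):
        abund = [0.02, 0.05, 0.08]
        maps = bin_correlations(
            self._grids_tracking_abundance(gate, abund), self._comp(abund), ["drv"]
        )
        # far corner bins receive no density variation -> undefined
        assert np.isnan(maps["drv"].tau).any()

    def test_matches_scalar_tau_oracle(self, gate, fcm_dataset):
        ds = fcm_dataset
        ids = ds.table.sample_ids[:5]
        grids = {s: fingerprint(ds.fcm[s][0], ds.gate) for s in ids}
        comp = CompositionMatrix(ds.truth.true_composition.loc[ids])
        taxon = ds.truth.drivers_hna[0]
        maps = bin_correlations(grids, comp, [taxon])
        x = comp.rel[taxon].to_numpy()
        dens = np.stack([grids[s].density for s in ids])
        for (r, c) in [(20, 30), (64, 64), (100, 90)]:
            ref_tau, _ = kendall_tau_b(x, dens[:, r, c])
            got = maps[taxon].tau[r, c]
            if np.isnan(ref_tau):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(ref_tau, abs=1e-12)

    def test_needs_three_samples(self, gate):
        abund = [0.1, 0.2]
        with pytest.raises(ValueError, match="3 samples"):
            bin_correlations(
                self._grids_tracking_abundance(gate, abund), self._comp(abund), ["drv"]
            )
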