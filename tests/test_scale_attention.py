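"""Distance gates, attention normalization, encoder symmetries."""

import math

import numpy as np
import pytest

from molscale.molgraph import MolecularGraph, pairwise_distances
from molscale.scale_attention import (EncoderConfig, ScaleSpec,
                                      attention_weights, default_scales,
                                      encoder_forward, export_attention_tsv,
                                      gate, init_params, load_checkpoint,
                                      save_checkpoint, specialization_score)
from molscale.synthetic import SyntheticSpec, make_corpus, make_synthetic

from conftest import random_rigid_motion


def small_config(in_dim, seed=0, **kw):
    defaults = dict(in_dim=in_dim, hidden=32, layers=2, heads=8,
                    head_split=(3, 3, 2), proj_dim=16, seed=seed)
    defaults.update(kw)
    return EncoderConfig(**defaults)


class TestGate:
    def test_sigmoid_half_at_mu(self):
        s = ScaleSpec(2)
        assert gate(s.mu, s, "sigmoid").item() == pytest.approx(0.5)

    def test_sigmoid_closed_form(self):
        s = ScaleSpec(1, beta=1.0)
        got = gate(s.mu + 1.0, s, "sigmoid").item()
        assert got == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-9)
        assert got == pytest.approx(0.731059, abs=1e-6)

    def test_bandpass_limits(self):
        s = ScaleSpec(2, beta=50.0)
        assert gate(0.1, s, "bandpass").item() < 1e-6
        assert gate(30.0, s, "bandpass").item() < 1e-6
        assert gate(3.5, s, "bandpass").item() > 1 - 1e-6

    def test_sigmoid_monotone(self):
        s = ScaleSpec(1, beta=2.0)
        d = np.linspace(0, 12, 200)
        v = gate(d, s, "sigmoid").data
        assert np.all(np.diff(v) > 0)

    def test_bandpass_unimodal(self):
        s = ScaleSpec(2, beta=4.0)
        d = np.linspace(0, 12, 400)
        v = gate(d, s, "bandpass").data
        peak = v.argmax()
        assert np.all(np.diff(v[:peak + 1]) >= -1e-12)
        assert np.all(np.diff(v[peak:]) <= 1e-12)

    def test_gate_bounded(self):
        s = ScaleSpec(3)
        d = np.linspace(0, 40, 100)
        for form in ("sigmoid", "bandpass"):
            v = gate(d, s, form).data
            assert np.all((v >= 0) & (v <= 1))


class TestAttentionWeights:
    def test_single_neighbor_gets_all(self):
        h = np.eye(2, 6)
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        rng = np.random.default_rng(0)
        a = attention_weights(h, coords, ScaleSpec(1), rng.normal(size=(6, 4)),
                              rng.normal(size=(6, 4)))
        # neighborhood includes self; each row sums to one
        np.testing.assert_allclose(a.data.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_neighbors_split_evenly(self):
        # center atom with two identical-feature neighbors at equal distance
        h = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 1.0, 0]])
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [-1.5, 0, 0]])
        rng = np.random.default_rng(1)
        a = attention_weights(h, coords, ScaleSpec(1), rng.normal(size=(3, 4)),
                              rng.normal(size=(3, 4))).data
        assert a[0, 1] == pytest.approx(a[0, 2], abs=1e-12)

    def test_matches_manual_softmax(self):
        """Brute-force evaluation of the gated-logit softmax, atom by atom."""
        rng = np.random.default_rng(2)
        h = rng.normal(size=(3, 5))
        coords = rng.normal(size=(3, 3)) * 2.0
        WQ, WK = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        s = ScaleSpec(2, beta=3.0)
        got = attention_weights(h, coords, s, WQ, WK, form="sigmoid").data

        d = pairwise_distances(coords)
        expect = np.zeros((3, 3))
        for i in range(3):
            logits = []
            for j in range(3):
                g = 1 / (1 + math.exp(-s.beta * (d[i, j] - s.mu)))
                logits.append((h[i] @ WQ) @ (h[j] @ WK) / math.sqrt(4) * g)
            e = np.exp(np.array(logits) - max(logits))
            expect[i] = e / e.sum()
        np.testing.assert_allclose(got, expect, atol=1e-10)


class TestEncoder:
    def test_rows_stochastic_every_layer_and_scale(self):
        corpus = make_corpus(5, seed=2)
        cfg = small_config(corpus[0].atom_features.shape[1])
        params = init_params(cfg)
        for g in corpus:
            emb = encoder_forward(g, params, cfg, collect_attention=True)
            assert emb.attention
            for (layer, k), alpha in emb.attention.items():
                np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_se3_invariance(self):
        rng = np.random.default_rng(3)
        g = make_synthetic(SyntheticSpec("decorated_scaffold", 10, seed=4))
        cfg = small_config(g.atom_features.shape[1])
        params = init_params(cfg)
        base = encoder_forward(g, params, cfg)
        for _ in range(5):
            Q, t = random_rigid_motion(rng)
            moved = g.copy_with_coords(g.coords @ Q.T + t)
            emb = encoder_forward(moved, params, cfg)
            assert np.abs(emb.node_embeddings - base.node_embeddings).max() < 1e-5

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        g = make_synthetic(SyntheticSpec("alkane_chain", 8, seed=5))
        cfg = small_config(g.atom_features.shape[1])
        params = init_params(cfg)
        base = encoder_forward(g, params, cfg)
        perm = rng.permutation(g.atom_count)
        inv = np.argsort(perm)
        gp = MolecularGraph(g.atom_features[perm], g.coords[perm],
                            [(int(inv[i]), int(inv[j]), o) for i, j, o in g.bonds],
                            [g.symbols[i] for i in perm], "perm")
        emb = encoder_forward(gp, params, cfg)
        assert np.abs(emb.node_embeddings - base.node_embeddings[perm]).max() < 1e-5
        for k in (1, 2, 3):
            assert np.abs(emb.scale_embeddings[k] - base.scale_embeddings[k]).max() < 1e-5

    def test_two_atom_manual_forward(self):
        """Single layer, single-head-sized config against a hand computation."""
        feats = np.array([[1.0, 0.0], [0.0, 1.0]])
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        g = MolecularGraph(feats, coords, [(0, 1, 1)], ["C", "C"])
        cfg = EncoderConfig(in_dim=2, hidden=2, layers=1, heads=1,
                            head_split=(1, 0, 0), proj_dim=2, gate_form="sigmoid",
                            seed=0)
        params = init_params(cfg)
        # overwrite with identity-like projections
        for name in ("embed_W", "l0_h0_WQ", "l0_h0_WK", "l0_h0_WV", "l0_WO"):
            params[name].data = np.eye(2)
        params["embed_b"].data[:] = 0
        emb = encoder_forward(g, params, cfg)

        h0 = feats @ np.eye(2)
        beta, mu = 4.0, 1.5
        d = np.array([[0, 1.5], [1.5, 0]])
        gmat = 1 / (1 + np.exp(-beta * (d - mu)))
        logits = (h0 @ h0.T) / math.sqrt(2) * gmat
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        alpha = e / e.sum(axis=1, keepdims=True)
        x = h0 + alpha @ h0
        mean = x.mean(axis=1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=1, keepdims=True)
        expect = (x - mean) / np.sqrt(var + 1e-5)
        np.testing.assert_allclose(emb.node_embeddings, expect, atol=1e-10)

    def test_empty_molecule_rejected(self):
        cfg = small_config(4)
        params = init_params(cfg)
        g = MolecularGraph(np.zeros((0, 4)), np.zeros((0, 3)), [], [])
        with pytest.raises(ValueError, match="empty"):
            encoder_forward(g, params, cfg)

    def test_coordinate_gradients_finite(self):
        """Finite-difference sensitivity of z_k to coordinates stays finite."""
        g = make_synthetic(SyntheticSpec("alkane_chain", 6, seed=6))
        cfg = small_config(g.atom_features.shape[1])
        params = init_params(cfg)
        base = encoder_forward(g, params, cfg)
        eps = 1e-5
        for trial in range(3):
            coords = np.array(g.coords)
            coords[trial % g.atom_count, trial % 3] += eps
            emb = encoder_forward(g.copy_with_coords(coords), params, cfg)
            for k in (1, 2, 3):
                grad = (emb.scale_embeddings[k] - base.scale_embeddings[k]) / eps
                assert np.all(np.isfinite(grad))


class TestSpecialization:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.samples = [rng.uniform(1, 2, 400), rng.uniform(2, 5, 400),
                        rng.uniform(5, 12, 400)]

    def test_bandpass_specializes_all_scales(self):
        scales = [ScaleSpec(k, beta=25.0) for k in (1, 2, 3)]
        centers = [np.full(100, 1.5), np.full(100, 3.5), np.full(100, 7.0)]
        gaps = specialization_score(scales, centers, form="bandpass")
        assert all(v > 0 for v in gaps.values())

    def test_identical_samples_zero_gap(self):
        scales = default_scales()
        same = [self.samples[0]] * 3
        gaps = specialization_score(scales, same, form="bandpass")
        assert all(abs(v) < 1e-12 for v in gaps.values())

    def test_monotone_sigmoid_fails_middle_scale(self):
        # a monotone gate responds more to 10 Å than to its own 3.5 Å band
        scales = default_scales()
        samples = [np.full(100, 1.5), np.full(100, 3.5), np.full(100, 10.0)]
        gaps = specialization_score(scales, samples, form="sigmoid")
        assert gaps[2] < 0

    def test_empty_sample_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            specialization_score(default_scales(), [np.array([]), [1.0], [2.0]])


class TestCheckpoint:
    def test_roundtrip_bit_identical_embeddings(self, tmp_path):
        g = make_synthetic(SyntheticSpec("alkane_chain", 7, seed=8))
        cfg = small_config(g.atom_features.shape[1], seed=1)
        params = init_params(cfg)
        before = encoder_forward(g, params, cfg)
        p = tmp_path / "ck.npz"
        save_checkpoint(p, params, cfg, extra={"note": "test"})
        params2, cfg2, extra = load_checkpoint(p)
        assert extra["note"] == "test"
        after = encoder_forward(g, params2, cfg2)
        np.testing.assert_array_equal(after.node_embeddings, before.node_embeddings)

    def test_attention_export(self, tmp_path):
        g = make_synthetic(SyntheticSpec("alkane_chain", 5, seed=9))
        cfg = small_config(g.atom_features.shape[1])
        params = init_params(cfg)
        out = export_attention_tsv(tmp_path / "attn.tsv", g, params, cfg)
        lines = open(out).read().splitlines()
        assert lines[0] == "i\tj\tscale\talpha"
        rows = [ln.split("\t") for ln in lines[1:]]
        scales = {int(r[2]) for r in rows}
        assert scales == {1, 2, 3}
        # per (i, scale) the exported weights sum to ~1
        from collections import defaultdict
        sums = defaultdict(float)
        for i, j, k, a in rows:
            sums[(i, k)] += float(a)
        assert all(abs(v - 1) < 1e-4 for v in sums.values())
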