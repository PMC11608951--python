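"""Vector quantization, VQ losses and stage-1 training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemfinger.fingerprints import default_profiles, generate_hplc
from chemfinger.vq import (TRACE_COLUMNS, Codebook, Stage1Config,
                           codebook_loss, quantize, reconstruction_loss,
                           train_stage1)

RNG = np.random.default_rng(13)


def random_codebook(K=16, d=4, seed=0):
    return Codebook("LF", np.random.default_rng(seed).normal(size=(K, d)))


class TestQuantize:
    def test_exact_codeword_maps_to_its_index_with_zero_error(self):
        cb = random_codebook()
        grid, q = quantize(cb.vectors[7][None, :], cb)
        assert grid.indices[0] == 7
        np.testing.assert_array_equal(q[0], cb.vectors[7])

    def test_matches_brute_force_nearest_neighbour(self):
        cb = random_codebook(K=16, d=6, seed=1)
        Z = RNG.normal(size=(100, 6))
        grid, q = quantize(Z, cb)
        brute = np.array([np.argmin([np.sum((z - c) ** 2) for c in cb.vectors])
                          for z in Z])
        np.testing.assert_array_equal(grid.indices, brute)
        np.testing.assert_allclose(q, cb.vectors[brute])

    def test_tie_breaks_to_lowest_index(self):
        vecs = np.full((8, 2), 100.0)
        vecs[2] = [11.0, 0.0]
        vecs[5] = [9.0, 0.0]
        cb = Codebook("LF", vecs)
        # latent equidistant from entries 2 and 5, far from all others
        grid, _ = quantize(np.array([[10.0, 0.5]]), cb)
        assert grid.indices[0] == 2

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((3, 5)), random_codebook(d=4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_idempotence(self, seed):
        cb = random_codebook(K=12, d=3, seed=2)
        z = np.random.default_rng(seed).normal(size=(10, 3))
        grid1, q1 = quantize(z, cb)
        grid2, q2 = quantize(q1, cb)
        np.testing.assert_array_equal(grid1.indices, grid2.indices)
        np.testing.assert_array_equal(q1, q2)


class TestLosses:
    def test_codebook_loss_zero_when_quantization_exact(self):
        e = RNG.normal(size=(4, 3))
        assert codebook_loss(e, e, e.copy(), e.copy(), beta=0.25) == 0.0

    def test_codebook_loss_scalar_hand_case(self):
        # one branch, e=1, q=0: ||e-q||^2 + beta ||e-q||^2 = 1 + 0.25
        val = codebook_loss(np.array([1.0]), np.array([0.0]),
                            np.array([0.0]), np.array([0.0]), beta=0.25)
        assert val == pytest.approx(1.25)

    def test_codebook_loss_value_identity(self):
        # evaluated value equals (1+beta) * sum of branch quantization errors
        e1, q1 = RNG.normal(size=(5, 2)), RNG.normal(size=(5, 2))
        e2, q2 = RNG.normal(size=(3, 2)), RNG.normal(size=(3, 2))
        beta = 0.4
        expect = (1 + beta) * (np.sum((e1 - q1) ** 2) + np.sum((e2 - q2) ** 2))
        assert codebook_loss(e1, e2, q1, q2, beta) == pytest.approx(expect)

    def test_negative_beta_rejected(self):
        z = np.zeros(2)
        with pytest.raises(ValueError):
            codebook_loss(z, z, z, z, beta=-0.1)

    def test_reconstruction_loss_perfect_and_unit_offset(self):
        x = RNG.normal(size=6)
        u = RNG.normal(size=4) + 1j * RNG.normal(size=4)
        assert reconstruction_loss(x, x, x, x, u, u, u, u) == 0.0
        e = np.zeros(6)
        e[2] = 1.0  # unit vector on one time-domain branch
        assert reconstruction_loss(x, x + e, x, x, u, u, u, u) == pytest.approx(1.0)

    def test_reconstruction_loss_term_by_term_oracle(self):
        parts = [RNG.normal(size=5) for _ in range(4)]
        specs = [RNG.normal(size=3) + 1j * RNG.normal(size=3) for _ in range(4)]
        hats = [p + RNG.normal(size=p.shape) * 0.3 for p in parts]
        shats = [s + (RNG.normal(size=3) + 1j * RNG.normal(size=3)) * 0.2
                 for s in specs]
        expect = sum(np.sum(np.abs(a - b) ** 2) for a, b in
                     [(parts[0], hats[0]), (parts[1], hats[1]),
                      (specs[0], shats[0]), (specs[1], shats[1])])
        got = reconstruction_loss(parts[0], hats[0], parts[1], hats[1],
                                  specs[0], shats[0], specs[1], shats[1])
        assert got == pytest.approx(expect, rel=1e-12)


@pytest.fixture(scope="module")
def desk_run():
    profiles = default_profiles()
    data = []
    for k, g in enumerate("HML"):
        data += generate_hplc(profiles[g], 20, seed=50 + k, length=512)
    return train_stage1(data, Stage1Config(iterations=300, seed=1))


class TestStage1Training:
    def test_reconstruction_improves_over_training(self, desk_run):
        tr = desk_run.loss_trace
        assert tr["Recons_loss"].iloc[-1] < tr["Recons_loss"].iloc[0]

    def test_trace_has_report_columns_and_additive_loss(self, desk_run):
        tr = desk_run.loss_trace
        assert TRACE_COLUMNS == ["Loss", "Recons_loss", "Recons_loss.LF",
                                 "Recons_loss.HF"]
        assert all(c in tr.columns for c in TRACE_COLUMNS)
        np.testing.assert_allclose(
            tr["Loss"], tr["Codebook_loss"] + tr["Recons_loss"], atol=1e-9)
        np.testing.assert_allclose(
            tr["Recons_loss"], tr["Recons_loss.LF"] + tr["Recons_loss.HF"],
            atol=1e-9)

    def test_round_trip_preserves_shape_and_finiteness(self, desk_run):
        m = desk_run.model
        X = RNG.normal(size=(3, 512))
        out = m.decode_tokens(m.encode_tokens(X))
        assert out.shape == X.shape
        assert np.all(np.isfinite(out))

    def test_training_is_deterministic_for_fixed_seed(self):
        data = generate_hplc(default_profiles()["M"], 6, seed=0, length=128)
        a = train_stage1(data, Stage1Config(iterations=20, seed=9))
        b = train_stage1(data, Stage1Config(iterations=20, seed=9))
        assert a.loss_trace.equals(b.loss_trace)
        assert a.state_hash() == b.state_hash()

    def test_frozen_codebook_with_zero_beta_trains_reconstruction_only(self):
        data = generate_hplc(default_profiles()["L"], 6, seed=2, length=128)
        cfg = Stage1Config(iterations=25, seed=3, beta=0.0,
                           freeze_codebook=True)
        res = train_stage1(data, cfg)
        model = res.model
        # codebook excluded from trainable parameters entirely
        ids = {id(p) for p in model.parameters()}
        for b in ("LF", "HF"):
            assert id(model.codebooks[b].param) not in ids
        assert (res.loss_trace["Recons_loss"].iloc[-1]
                < res.loss_trace["Recons_loss"].iloc[0])

    def test_too_few_samples_raise(self):
        from chemfinger.vq import TrainingError
        data = generate_hplc(default_profiles()["H"], 1, seed=0, length=128)
        with pytest.raises(TrainingError):
            train_stage1(data, Stage1Config(iterations=5))
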