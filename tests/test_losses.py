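"""Focal and NT-Xent losses against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from bundleseg.losses import (
    ContrastiveParams,
    FocalParams,
    contrastive_loss,
    contrastive_loss_grad,
    focal_loss,
    focal_loss_grad,
)


def focal_oracle(p, y, alpha, gamma, eps=1e-7):
    """Direct elementwise evaluation of the focal-loss definition."""
    total = 0.0
    p = np.clip(p, eps, 1 - eps)
    for pi, yi in zip(np.ravel(p), np.ravel(y)):
        pt = pi if yi == 1 else 1 - pi
        at = alpha if yi == 1 else 1 - alpha
        total += -at * (1 - pt) ** gamma * np.log(pt)
    return total / np.size(p)


def ntxent_oracle(features, tau):
    """Double loop over all 2N x 2N cosine similarities (interleaved pairs)."""
    f = np.asarray(features, dtype=float)
    n2 = f.shape[0]

    def sim(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    losses = []
    for i in range(n2):
        j = i + 1 if i % 2 == 0 else i - 1
        denom = sum(np.exp(sim(f[i], f[k]) / tau) for k in range(n2) if k != i)
        losses.append(-np.log(np.exp(sim(f[i], f[j]) / tau) / denom))
    return float(np.mean(losses))


class TestFocal:
    def test_perfect_prediction_is_zero(self):
        assert focal_loss(np.array([1.0]), np.array([1]), FocalParams()) < 1e-5
        assert focal_loss(np.array([0.0]), np.array([0]), FocalParams()) < 1e-5

    def test_printed_example(self):
        # y=1, p=0.5, alpha=0.25, gamma=2 -> 0.25 * 0.25 * (-log 0.5)
        expected = 0.25 * 0.25 * -np.log(0.5)
        got = focal_loss(np.array([0.5]), np.array([1]), FocalParams(0.25, 2.0))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_gamma_zero_reduces_to_weighted_cross_entropy(self, rng):
        p = rng.uniform(0.01, 0.99, 200)
        y = rng.integers(0, 2, 200)
        fl = focal_loss(p, y, FocalParams(alpha=0.5, gamma=0.0))
        bce = -np.mean(np.where(y == 1, np.log(p), np.log(1 - p)))
        assert fl == pytest.approx(0.5 * bce, rel=1e-10)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            p = rng.uniform(0.0, 1.0, n)
            y = rng.integers(0, 2, n)
            alpha = float(rng.uniform(0, 1))
            gamma = float(rng.uniform(0, 4))
            got = focal_loss(p, y, FocalParams(alpha, gamma))
            assert got == pytest.approx(focal_oracle(p, y, alpha, gamma), abs=1e-8)

    def test_nonnegative_and_decreasing_in_pt(self, rng):
        params = FocalParams()
        ps = np.linspace(0.01, 0.99, 50)
        losses = [focal_loss(np.array([p]), np.array([1]), params) for p in ps]
        assert all(l >= 0 for l in losses)
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros(3), np.zeros(4), FocalParams())

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.05, 0.95, 40)
        y = rng.integers(0, 2, 40)
        params = FocalParams()
        g = focal_loss_grad(p, y, params)
        eps = 1e-6
        for i in range(0, 40, 7):
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (focal_loss(pp, y, params) - focal_loss(pm, y, params)) / (2 * eps)
            assert g[i] == pytest.approx(num, abs=1e-6)


class TestContrastive:
    def test_matches_oracle_identical_orthogonal_pairs(self):
        e1, e2 = np.eye(4)[0], np.eye(4)[1]
        feats = np.stack([e1, e1, e2, e2])
        got = contrastive_loss(feats, ContrastiveParams(tau=0.5))
        assert got == pytest.approx(ntxent_oracle(feats, 0.5), abs=1e-10)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n_pairs = int(rng.integers(2, 8))
            d = int(rng.integers(2, 10))
            f = rng.normal(size=(2 * n_pairs, d))
            tau = float(rng.uniform(0.1, 2.0))
            got = contrastive_loss(f, ContrastiveParams(tau))
            assert got == pytest.approx(ntxent_oracle(f, tau), abs=1e-8)

    def test_scale_invariance_of_single_vector(self, rng):
        f = rng.normal(size=(6, 5))
        base = contrastive_loss(f, ContrastiveParams())
        f2 = f.copy()
        f2[3] *= 3.0
        assert contrastive_loss(f2, ContrastiveParams()) == pytest.approx(base, abs=1e-10)

    def test_global_rotation_invariance(self, rng):
        f = rng.normal(size=(8, 5))
        q = ortho_group.rvs(5, random_state=7)
        base = contrastive_loss(f, ContrastiveParams())
        assert contrastive_loss(f @ q, ContrastiveParams()) == pytest.approx(base, abs=1e-8)

    def test_odd_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            contrastive_loss(rng.normal(size=(5, 3)), ContrastiveParams())

    def test_gradient_matches_finite_differences(self, rng):
        f = rng.normal(size=(6, 4))
        params = ContrastiveParams(tau=0.7)
        g = contrastive_loss_grad(f, params)
        eps = 1e-6
        for i in range(6):
            for j in range(4):
                fp, fm = f.copy(), f.copy()
                fp[i, j] += eps
                fm[i, j] -= eps
                num = (contrastive_loss(fp, params) - contrastive_loss(fm, params)) / (
                    2 * eps
                )
                assert g[i, j] == pytest.approx(num, abs=1e-7)
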