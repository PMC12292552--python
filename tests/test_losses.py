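"""Contrastive-loss correctness against naive double-loop oracles."""

import math

import numpy as np
import pytest

from supconvoice.autodiff import Tensor
from supconvoice.losses import (SupConConfig, combined_objective,
                                hard_negative_adjust, supcon_loss)

from conftest import unit_rows


def supcon_oracle(z: np.ndarray, labels: np.ndarray, tau: float,
                  hard_scale: float = 1.0, hard_k: int = 0) -> float:
    """Naive double-loop evaluation: no vectorisation, no stabilisation.

    Hard scaling multiplies the denominator exponentials of the hard_k
    most-similar negatives per anchor (ties broken toward lowest index).
    """
    n = z.shape[0]
    total = 0.0
    for i in range(n):
        positives = [p for p in range(n) if p != i and labels[p] == labels[i]]
        if not positives:
            continue
        others = [a for a in range(n) if a != i]
        negatives = [a for a in others if labels[a] != labels[i]]
        scaled = set()
        if hard_scale != 1.0 and hard_k > 0 and negatives:
            sims = sorted(negatives, key=lambda a: (-float(z[i] @ z[a]), a))
            scaled = set(sims[:hard_k])
        denom = 0.0
        for a in others:
            term = math.exp(float(z[i] @ z[a]) / tau)
            if a in scaled:
                term *= hard_scale
            denom += term
        inner = 0.0
        for p in positives:
            inner += math.log(math.exp(float(z[i] @ z[p]) / tau) / denom)
        total += -inner / len(positives)
    return total


def test_two_same_class_samples_give_exact_zero():
    rng = np.random.default_rng(0)
    z = unit_rows(rng, 2, 8)
    loss = supcon_loss(z, np.array([1, 1]), SupConConfig(hard_negatives=False))
    assert loss.item() == 0.0


def test_large_temperature_limit_is_n_log_n_minus_1():
    rng = np.random.default_rng(1)
    z = unit_rows(rng, 4, 4)
    labels = np.array([0, 0, 1, 1])
    cfg = SupConConfig(temperature=1e6, hard_negatives=False)
    assert abs(supcon_loss(z, labels, cfg).item() - 4 * math.log(3)) < 1e-3


def test_matches_double_loop_oracle_on_random_batches():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        p = int(rng.integers(2, 5))
        z = unit_rows(rng, n, p)
        labels = rng.integers(0, 2, size=n)
        tau = float(rng.uniform(0.05, 2.0))
        ours = supcon_loss(z, labels, SupConConfig(temperature=tau, hard_negatives=False))
        assert abs(ours.item() - supcon_oracle(z, labels, tau)) < 1e-6


def test_hard_scaling_matches_explicit_topk_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        z = unit_rows(rng, n, int(rng.integers(2, 5)))
        labels = rng.integers(0, 2, size=n)
        k = int(rng.integers(1, 3))
        cfg = SupConConfig(temperature=0.07, hard_scale=1.5, hard_k=k)
        ours = hard_negative_adjust(z, labels, cfg)
        oracle = supcon_oracle(z, labels, 0.07, hard_scale=1.5, hard_k=k)
        assert abs(ours.item() - oracle) < 1e-6


def test_hard_scale_one_reproduces_plain_loss_bitwise():
    rng = np.random.default_rng(3)
    z = unit_rows(rng, 6, 4)
    labels = np.array([0, 1, 0, 1, 0, 1])
    plain = supcon_loss(z, labels, SupConConfig(hard_negatives=False))
    scaled = hard_negative_adjust(z, labels, SupConConfig(hard_scale=1.0))
    assert plain.item() == scaled.item()


def test_hard_scaling_strictly_increases_loss_with_any_negative():
    rng = np.random.default_rng(4)
    for _ in range(50):
        n = int(rng.integers(3, 9))
        labels = rng.integers(0, 2, size=n)
        if len(set(labels.tolist())) < 2:
            labels[0] = 1 - labels[0]
        z = unit_rows(rng, n, 3)
        plain = supcon_loss(z, labels, SupConConfig(hard_negatives=False)).item()
        scaled = hard_negative_adjust(z, labels, SupConConfig(hard_scale=1.5)).item()
        assert scaled > plain


def test_permutation_equivariance():
    rng = np.random.default_rng(5)
    z = unit_rows(rng, 8, 4)
    labels = rng.integers(0, 2, size=8)
    perm = rng.permutation(8)
    cfg = SupConConfig()
    a = supcon_loss(z, labels, cfg).item()
    b = supcon_loss(z[perm], labels[perm], cfg).item()
    assert abs(a - b) < 1e-9


def test_temperature_limit_approach_is_monotone():
    rng = np.random.default_rng(6)
    z = unit_rows(rng, 6, 4)
    labels = np.array([0, 0, 0, 1, 1, 1])
    limit = 6 * math.log(5)
    gaps = [abs(supcon_loss(z, labels, SupConConfig(temperature=t, hard_negatives=False)).item() - limit)
            for t in (10.0, 100.0, 1e6)]
    assert gaps[0] > gaps[1] > gaps[2]


def test_low_temperature_near_duplicates_stay_finite():
    rng = np.random.default_rng(8)
    base = unit_rows(rng, 1, 4)[0]
    z = np.vstack([base + rng.normal(0, 1e-9, 4) for _ in range(6)])
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    labels = np.array([0, 1, 0, 1, 0, 1])
    loss = supcon_loss(z, labels, SupConConfig(temperature=0.01))
    assert np.isfinite(loss.item())


def test_anchor_without_positives_is_skipped():
    rng = np.random.default_rng(9)
    z = unit_rows(rng, 3, 4)
    labels = np.array([0, 1, 1])  # anchor 0 has no positives
    ours = supcon_loss(z, labels, SupConConfig(hard_negatives=False)).item()
    assert abs(ours - supcon_oracle(z, labels, 0.07)) < 1e-9


def test_rejects_tiny_batches_and_unnormalised_rows():
    with pytest.raises(ValueError):
        supcon_loss(np.ones((1, 4)), np.array([0]))
    bad = np.ones((3, 4))  # norm 2, not 1
    with pytest.raises(ValueError):
        supcon_loss(bad, np.array([0, 1, 0]))


def test_gradient_step_decreases_loss_on_clustered_batch():
    """One gradient step along -grad reduces the loss (20 random seeds)."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        centres = np.array([[1.0, 0, 0, 0], [-1.0, 0, 0, 0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        raw = np.vstack([centres[l] + rng.normal(0, 0.5, 4) for l in labels])
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        z = Tensor(raw, requires_grad=True)
        cfg = SupConConfig(hard_negatives=False)
        loss = supcon_loss(z, labels, cfg)
        loss.backward()
        stepped = raw - 0.01 * z.grad
        stepped /= np.linalg.norm(stepped, axis=1, keepdims=True)
        assert supcon_loss(stepped, labels, cfg).item() < loss.item()


class TestCombinedObjective:
    def test_total_is_sum_of_components(self):
        rng = np.random.default_rng(10)
        z = unit_rows(rng, 6, 4)
        labels = np.array([0, 1, 0, 1, 0, 1])
        logits = rng.standard_normal((6, 2))
        total, sup, ce = combined_objective(logits, z, labels)
        assert abs(total.item() - (sup.item() + ce.item())) < 1e-9

    def test_zero_contrastive_batch_leaves_pure_cross_entropy(self):
        rng = np.random.default_rng(11)
        z = unit_rows(rng, 2, 4)
        labels = np.array([1, 1])
        logits = rng.standard_normal((2, 2))
        total, sup, ce = combined_objective(logits, z, labels)
        assert sup.item() == 0.0
        assert total.item() == ce.item()

    def test_uniform_logits_give_log_two_per_sample(self):
        z = unit_rows(np.random.default_rng(12), 4, 4)
        labels = np.array([0, 0, 1, 1])
        logits = np.zeros((4, 2))
        _, _, ce = combined_objective(logits, z, labels)
        assert abs(ce.item() - math.log(2)) < 1e-12

    def test_mismatched_batch_sizes_error(self):
        z = unit_rows(np.random.default_rng(13), 4, 4)
        with pytest.raises(ValueError):
            combined_objective(np.zeros((3, 2)), z, np.array([0, 1, 0, 1]))
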