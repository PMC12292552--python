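"""Multi-positive supervised contrastive loss with hard-negative scaling.

For a batch of unit-norm projections ``z`` with class labels, the loss of
anchor ``i`` averages, over its positives ``p`` (same label, excluding
``i``), the log-ratio of ``exp(sim(z_i, z_p)/τ)`` to the sum of
``exp(sim(z_i, z_a)/τ)`` over *all* other batch members ``a`` (positives
included in the denominator).  ``sim`` is the dot product of unit vectors
(cosine similarity) and ``τ`` sharpens the distribution (default 0.07).
Anchor terms are summed over the batch; anchors with no positives are
skipped, following the published multi-positive convention.

Hard pair scaling multiplies the denominator terms of each anchor's most
similar negatives (top-``hard_k`` by cosine similarity, ties broken toward
the lowest index) by a factor ≥ 1 (default 1.5), which strictly increases
the loss whenever a negative exists and reduces to the plain loss at
factor 1.

The log-sum-exp is evaluated with max subtraction, so the loss stays finite
even at very low temperatures with near-duplicate rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import cross_entropy

__all__ = ["SupConConfig", "supcon_loss", "hard_negative_adjust", "combined_objective"]

_NORM_TOL = 1e-3


@dataclass
class SupConConfig:
    temperature: float = 0.07
    hard_scale: float = 1.5
    hard_k: int = 1
    hard_negatives: bool = True  # apply hard pair scaling

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.hard_scale < 1.0:
            raise ValueError("hard_scale must be >= 1")
        if self.hard_k < 0:
            raise ValueError("hard_k must be >= 0")


def _validate(z: Tensor, labels: np.ndarray) -> None:
    n = z.shape[0]
    if n < 2:
        raise ValueError(f"contrastive loss needs a batch of >= 2, got {n}")
    if labels.shape != (n,):
        raise ValueError("labels must be one id per batch row")
    norms = np.linalg.norm(z.data, axis=1)
    if np.any(np.abs(norms - 1.0) > _NORM_TOL):
        raise ValueError("projection rows must be unit-norm")


def _hard_scale_matrix(sims: np.ndarray, pos_mask: np.ndarray, not_self: np.ndarray,
                       config: SupConConfig) -> np.ndarray:
    """Additive log-scale matrix: log(hard_scale) at each anchor's hardest negatives."""
    n = sims.shape[0]
    log_scale = np.zeros((n, n))
    if not config.hard_negatives or config.hard_scale == 1.0 or config.hard_k == 0:
        return log_scale
    neg_mask = not_self & ~pos_mask
    for i in range(n):
        negs = np.flatnonzero(neg_mask[i])
        if negs.size == 0:
            continue  # anchor without negatives: plain term
        order = negs[np.argsort(-sims[i, negs], kind="stable")]  # ties → lowest index
        log_scale[i, order[: config.hard_k]] = np.log(config.hard_scale)
    return log_scale


def supcon_loss(z, labels, config: SupConConfig | None = None) -> Tensor:
    """Batch supervised contrastive loss (Tensor in → differentiable Tensor out).

    ``z``: (N, p) unit-norm projections (ndarray or Tensor); ``labels``:
    length-N integer class ids.  Hard-negative scaling is applied according
    to ``config``; pass ``hard_negatives=False`` for the plain loss.
    """
    config = config or SupConConfig()
    z = as_tensor(z)
    labels = np.asarray(labels)
    _validate(z, labels)
    n = z.shape[0]

    not_self = ~np.eye(n, dtype=bool)
    pos_mask = (labels[:, None] == labels[None, :]) & not_self
    n_pos = pos_mask.sum(axis=1)

    sims = z.data @ z.data.T  # detached copy for hard-negative mining
    log_scale = _hard_scale_matrix(sims, pos_mask, not_self, config)

    s = (z @ z.swapaxes(-1, -2)) * (1.0 / config.temperature)
    shifted_logits_np = s.data + log_scale
    row_max = np.where(not_self, shifted_logits_np, -np.inf).max(axis=1, keepdims=True)
    exp_terms = ((s + log_scale) - row_max).exp() * not_self.astype(float)
    log_denom = exp_terms.sum(axis=1, keepdims=True).log() + row_max
    log_prob = s - log_denom  # numerator terms are unscaled similarities

    weights = np.where(n_pos[:, None] > 0, pos_mask / np.maximum(n_pos, 1)[:, None], 0.0)
    return -(log_prob * weights).sum()


def hard_negative_adjust(z, labels, config: SupConConfig | None = None) -> Tensor:
    """The loss with hard pair scaling forced on (factor ``config.hard_scale``)."""
    config = config or SupConConfig()
    forced = SupConConfig(temperature=config.temperature, hard_scale=config.hard_scale,
                          hard_k=config.hard_k, hard_negatives=True)
    return supcon_loss(z, labels, forced)


def combined_objective(logits, projection, labels, config: SupConConfig | None = None
                       ) -> tuple[Tensor, Tensor, Tensor]:
    """Joint training objective: contrastive + cross-entropy with unit weights.

    Returns ``(total, contrastive_component, cross_entropy_component)``.  The
    cross-entropy is the mean softmax negative log-likelihood; in the
    gradient-blocked architecture its logits come from the detached pathway,
    so only the heads feel it.
    """
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    if logits.shape[0] != labels.shape[0]:
        raise ValueError("logits and labels batch sizes differ")
    if projection is not None and as_tensor(projection).shape[0] != labels.shape[0]:
        raise ValueError("projection and labels batch sizes differ")
    sup = supcon_loss(projection, labels, config)
    ce = cross_entropy(logits, labels)
    return sup + ce, sup, ce
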