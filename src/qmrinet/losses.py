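"""Bias/variance-controlled training losses for regression estimators.

The family generalizes the mean squared error in three steps:

1. weight each parameter (``wmse``) so quantities with different units and
   scales can be summed — the canonical choice is the inverse CRB,
   ``W_i = diag(b_i)^{-1}``, which renders the loss dimensionless and
   de-emphasizes inherently hard-to-estimate points;
2. average over ``Nr`` noise realizations of the same measurement
   (``wmse_multi_noise``), which decomposes exactly into a weighted trace of
   the (uncorrected) sample covariance plus the weighted squared sample bias
   (:func:`bias_variance_decomposition`);
3. re-weight the two terms: the *bias-constrained* loss (``wbce``) scales the
   bias term by ``(lambda_tilde + 1)``, while the *variance-constrained bias*
   loss (``wvcb``) penalizes the CRB-normalized squared bias plus a hinge on
   the CRB-normalized variance exceeding ``delta`` — so an efficient
   estimator (zero bias, variance at the bound) achieves zero loss with
   ``delta = 1``.

Identities locked by tests: ``wvcb`` reduces to plain MSE for ``b = 1`` and
``Nr = 1``; for ``delta = 0`` and ``lambda = 1/(lambda_tilde + 1)`` it equals
``lambda * wbce`` (the overall factor ``lambda`` is deliberate — we match the
per-parameter form literally).

All losses operate on numpy arrays shaped ``(Ns, Nr, Np)`` for the estimates
and ``(Ns, Np)`` for truths/weights; :func:`wvcb_loss_grad` supplies the
analytic gradient with respect to the estimates for the numpy trainer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "EstimateBlock",
    "mse_loss",
    "wmse_loss",
    "wmse_multi_noise",
    "bias_variance_decomposition",
    "wbce_loss",
    "wvcb_loss",
    "wvcb_loss_grad",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss variant and hyperparameters.

    ``lam`` is the variance-penalty weight of the WVCB loss, ``delta`` the
    variance tolerance in CRB units (1 penalizes variance above the CRB;
    1.01 compensates the sample-variance noise at Nr=200), ``lambda_tilde``
    the bias re-weighting of the WBCE loss.
    """

    variant: str = "wvcb"
    lam: float = 1.0
    delta: float = 1.0
    lambda_tilde: float = 0.0
    weighting: str = "crb_inverse"

    def __post_init__(self) -> None:
        if self.variant not in {"mse", "wmse", "wmse_multi", "wbce", "wvcb"}:
            raise ValueError(f"unknown loss variant {self.variant!r}")
        if self.lam < 0 or self.delta < 0 or self.lambda_tilde < 0:
            raise ValueError("lam, delta and lambda_tilde must be non-negative")
        if self.weighting not in {"identity", "crb_inverse", "custom"}:
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class EstimateBlock:
    """Estimates over noise realizations with ground truth.

    ``x_hat``: (Ns, Nr, Np); ``x_true``: (Ns, Np).  ``mu_hat`` is the sample
    mean over the realization axis.
    """

    x_hat: np.ndarray
    x_true: np.ndarray

    def __post_init__(self) -> None:
        x_hat = np.asarray(self.x_hat, dtype=float)
        if x_hat.ndim == 2:  # (Ns, Np) -> Nr = 1
            x_hat = x_hat[:, None, :]
        object.__setattr__(self, "x_hat", x_hat)
        object.__setattr__(self, "x_true", np.asarray(self.x_true, dtype=float))
        if self.x_hat.shape[::2] != self.x_true.shape:
            raise ValueError(
                f"shape mismatch: x_hat {self.x_hat.shape} vs x_true {self.x_true.shape}"
            )

    @property
    def mu_hat(self) -> np.ndarray:
        return self.x_hat.mean(axis=1)

    @property
    def sample_var(self) -> np.ndarray:
        """Uncorrected (divide-by-Nr) per-parameter sample variance, (Ns, Np)."""
        return ((self.x_hat - self.mu_hat[:, None, :]) ** 2).mean(axis=1)


def _diag_weights(weights, block: EstimateBlock) -> np.ndarray:
    """Broadcast scalar / (Np,) / (Ns, Np) diagonal weights to (Ns, Np)."""
    ns, _, np_ = block.x_hat.shape
    w = np.asarray(weights, dtype=float)
    w = np.broadcast_to(w, (ns, np_))
    if np.any(w < 0):
        raise ValueError("diagonal weights must be non-negative")
    return w


def mse_loss(block: EstimateBlock) -> float:
    """Plain MSE over samples and parameters (realizations count as samples)."""
    err = block.x_hat - block.x_true[:, None, :]
    return float((err**2).mean())


def wmse_loss(block: EstimateBlock, weights) -> float:
    """Weighted MSE with diagonal (per-sample, per-parameter) weights.

    With identity weights this is exactly :func:`mse_loss`.  Normalization is
    by Ns*Np (and Nr if realizations are present), keeping the CRB-weighted
    loss dimensionless per term.
    """
    w = _diag_weights(weights, block)
    err = block.x_hat - block.x_true[:, None, :]
    return float((w[:, None, :] * err**2).mean())


def wmse_multi_noise(block: EstimateBlock, weights) -> float:
    """Weighted MSE averaged over the Nr noise realizations of each sample."""
    return wmse_loss(block, weights)


def bias_variance_decomposition(block: EstimateBlock, weights) -> tuple[float, float]:
    """Split the multi-realization weighted MSE into (trace, bias) terms.

    ``trace`` is the weighted trace of the uncorrected sample covariance and
    ``bias`` the weighted squared sample bias; their sum equals
    :func:`wmse_multi_noise` identically (tested to 1e-10 relative).
    """
    w = _diag_weights(weights, block)
    trace = float((w * block.sample_var).mean())
    bias = float((w * (block.mu_hat - block.x_true) ** 2).mean())
    return trace, bias


def wbce_loss(block: EstimateBlock, weights, lambda_tilde: float) -> float:
    """Bias-constrained weighted loss: trace + (lambda_tilde + 1) * bias."""
    if lambda_tilde < 0:
        raise ValueError("lambda_tilde must be non-negative")
    trace, bias = bias_variance_decomposition(block, weights)
    return trace + (lambda_tilde + 1.0) * bias


def wvcb_loss(block: EstimateBlock, b, lam: float, delta: float) -> float:
    """Variance-constrained bias loss with CRB weighting.

    ``(1/(Ns*Np)) * sum_ik [ (mu_ik - x_ik)^2 / b_ik
    + lam * max(0, var_ik / b_ik - delta) ]`` with the uncorrected sample
    variance over the Nr realizations.  ``delta = 1`` penalizes only variance
    exceeding the CRB; ``lam -> inf`` approaches a hard variance constraint.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("CRB weights b must be positive")
    if lam < 0 or delta < 0:
        raise ValueError("lam and delta must be non-negative")
    binv = _diag_weights(1.0 / b, block)
    bias_sq = binv * (block.mu_hat - block.x_true) ** 2
    hinge = np.maximum(0.0, binv * block.sample_var - delta)
    return float((bias_sq + lam * hinge).mean())


def wvcb_loss_grad(block: EstimateBlock, b, lam: float, delta: float) -> np.ndarray:
    """Analytic d(wvcb)/d(x_hat), shape (Ns, Nr, Np).

    The variance hinge uses the subgradient 0 at the kink.  Gradients flow
    through both the sample mean and the variance term (no stop-gradient).
    """
    b = np.asarray(b, dtype=float)
    binv = _diag_weights(1.0 / b, block)
    ns, nr, np_ = block.x_hat.shape
    mu = block.mu_hat
    scale = 1.0 / (ns * np_)
    g_bias = 2.0 * binv * (mu - block.x_true) / nr  # (Ns, Np), same for all j
    active = (binv * block.sample_var - delta) > 0
    g_var = lam * binv * active * (2.0 / nr)  # (Ns, Np)
    grad = scale * (g_bias[:, None, :] + g_var[:, None, :] * (block.x_hat - mu[:, None, :]))
    return grad
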