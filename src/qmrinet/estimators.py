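"""Parameter estimators: the DRONE-style network and the two references.

The network is a fully connected multilayer perceptron taking the real and
imaginary parts of the ``r`` subspace coefficients (``2r`` real inputs),
with ReLU activations, affine batch normalization after each hidden layer,
and outputs constrained by ReLUs capped at the maximum values expected in
vivo (5 s for both T1 and T2).  With the published FISP configuration
(20 -> 300 -> 300 -> 2) this network has 98,402 trainable parameters.

Because this package targets CPU-only environments without a deep-learning
framework, the forward pass, backpropagation (including through batch
normalization and the hinged WVCB loss) and the ADAM optimizer are
implemented directly in numpy.  Training follows the two-stage protocol:
a stage-0 network trained with ``lambda = 0, Nr = 1`` to convergence
initializes both the Bias-Reduced branch (``Nr = 200, lambda = 1, delta = 1``)
and the MSE-CRB branch (``Nr = 1, lambda = 1, delta = 0``, large batch).

Reference estimators: dictionary matching (discretized maximum likelihood by
maximum normalized correlation) and variable-projection Levenberg-Marquardt
non-linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .datagen import make_training_batch
from .losses import EstimateBlock, wvcb_loss, wvcb_loss_grad

__all__ = [
    "NetworkSpec",
    "MLP",
    "StageConfig",
    "TrainingProtocol",
    "TrainingData",
    "build_network",
    "train",
    "train_stage",
    "predict",
    "dictionary_match",
    "nlls_fit",
]


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; parameter count is a pure function of this."""

    input_dim: int = 20
    hidden_widths: tuple[int, ...] = (300, 300)
    output_dim: int = 2
    output_caps: tuple[float, ...] = (5.0, 5.0)
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be >= 1")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be >= 1")
        if len(self.output_caps) != self.output_dim:
            raise ValueError("need one output cap per output")

    @property
    def n_parameters(self) -> int:
        """Trainable parameters: weights, biases, batch-norm scale/shift."""
        dims = (self.input_dim, *self.hidden_widths, self.output_dim)
        n = sum(din * dout + dout for din, dout in zip(dims[:-1], dims[1:]))
        if self.batch_norm:
            n += sum(2 * w for w in self.hidden_widths)
        return n


class MLP:
    """Fully connected ReLU network with affine batch norm, in numpy.

    Batch statistics are used in training mode and exponentially averaged
    into running statistics, which are frozen at inference — so inference is
    deterministic and batch-size independent.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = (spec.input_dim, *spec.hidden_widths, spec.output_dim)
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / din), (din, dout))
            for din, dout in zip(dims[:-1], dims[1:])
        ]
        self.biases = [np.zeros(d) for d in dims[1:]]
        # start the capped output ReLUs inside their active range
        self.biases[-1] = np.minimum(0.5, np.asarray(spec.output_caps) / 2.0)
        self.gamma = [np.ones(w) for w in spec.hidden_widths] if spec.batch_norm else []
        self.beta = [np.zeros(w) for w in spec.hidden_widths] if spec.batch_norm else []
        self.run_mean = [np.zeros(w) for w in spec.hidden_widths]
        self.run_var = [np.ones(w) for w in spec.hidden_widths]
        self._cache = None

    # -- parameter flattening (for the optimizer) ---------------------------
    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, *self.gamma, *self.beta]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (n, input_dim) features to (n, output_dim) capped estimates."""
        spec = self.spec
        caches = []
        h = np.asarray(x, dtype=float)
        n_hidden = len(spec.hidden_widths)
        for layer in range(n_hidden):
            z = h @ self.weights[layer] + self.biases[layer]
            if spec.batch_norm:
                if training:
                    mean = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.run_mean[layer] = (
                        (1 - self.BN_MOMENTUM) * self.run_mean[layer] + self.BN_MOMENTUM * mean
                    )
                    self.run_var[layer] = (
                        (1 - self.BN_MOMENTUM) * self.run_var[layer] + self.BN_MOMENTUM * var
                    )
                else:
                    mean, var = self.run_mean[layer], self.run_var[layer]
                inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
                z_hat = (z - mean) * inv_std
                a_in = self.gamma[layer] * z_hat + self.beta[layer]
            else:
                z_hat, inv_std, a_in = None, None, z
            a = np.maximum(a_in, 0.0)
            caches.append((h, z_hat, inv_std, a_in, a))
            h = a
        z_out = h @ self.weights[-1] + self.biases[-1]
        caps = np.asarray(spec.output_caps)
        out = np.clip(z_out, 0.0, caps)
        if training:
            self._cache = (caches, z_out, out)
        return out

    # -- backward -----------------------------------------------------------
    def backward(self, grad_out: np.ndarray) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. parameters, same order as
        :meth:`parameters`.  Requires a preceding training-mode forward."""
        if self._cache is None:
            raise RuntimeError("backward requires a training-mode forward pass")
        caches, z_out, _ = self._cache
        spec = self.spec
        caps = np.asarray(spec.output_caps)
        n = z_out.shape[0]

        g_w = [None] * len(self.weights)
        g_b = [None] * len(self.biases)
        g_gamma = [None] * len(self.gamma)
        g_beta = [None] * len(self.beta)

        # capped output ReLU: zero gradient outside (0, cap)
        dz = grad_out * ((z_out > 0) & (z_out < caps))
        h_last = caches[-1][4]
        g_w[-1] = h_last.T @ dz
        g_b[-1] = dz.sum(axis=0)
        dh = dz @ self.weights[-1].T

        for layer in range(len(spec.hidden_widths) - 1, -1, -1):
            h_in, z_hat, inv_std, a_in, _ = caches[layer]
            da_in = dh * (a_in > 0)
            if spec.batch_norm:
                g_gamma[layer] = (da_in * z_hat).sum(axis=0)
                g_beta[layer] = da_in.sum(axis=0)
                dz_hat = da_in * self.gamma[layer]
                # batch-statistics backprop
                dz = (
                    dz_hat
                    - dz_hat.mean(axis=0)
                    - z_hat * (dz_hat * z_hat).mean(axis=0)
                ) * inv_std
            else:
                dz = da_in
            g_w[layer] = h_in.T @ dz
            g_b[layer] = dz.sum(axis=0)
            if layer > 0:
                dh = dz @ self.weights[layer].T
        del n
        return [*g_w, *g_b, *g_gamma, *g_beta]

    def copy(self) -> "MLP":
        other = MLP(self.spec, seed=0)
        other.weights = [w.copy() for w in self.weights]
        other.biases = [b.copy() for b in self.biases]
        other.gamma = [g.copy() for g in self.gamma]
        other.beta = [b.copy() for b in self.beta]
        other.run_mean = [m.copy() for m in self.run_mean]
        other.run_var = [v.copy() for v in self.run_var]
        return other


def build_network(spec: NetworkSpec, seed: int = 0) -> tuple[MLP, int]:
    """Instantiate the network; returns it with its trainable-parameter count."""
    net = MLP(spec, seed=seed)
    count = net.n_parameters()
    assert count == spec.n_parameters  # two independent counts must agree
    return net, count


class Adam:
    """Standard ADAM with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# --------------------------------------------------------------------------
# training protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageConfig:
    """One training stage of the WVCB loss."""

    nr: int = 1
    lam: float = 0.0
    delta: float = 1.0
    epochs: int = 500
    batch_size: int = 256
    early_stop: bool = False
    early_stop_rel: float = 1e-3
    early_stop_patience: int = 20


@dataclass(frozen=True)
class TrainingProtocol:
    """Two-stage protocol: stage-0 init, then the two published branches.

    Published values: stage-0 ``lambda=0, Nr=1`` to convergence; Bias-Reduced
    ``Nr=200, lambda=1, delta=1``, 500 epochs, batch 256; MSE-CRB ``Nr=1,
    lambda=1, delta=0``, 500 epochs, batch 51200.  Desk-scale runs shrink
    ``Nr``, the epoch counts and batch sizes but keep the structure.
    """

    stage0: StageConfig = field(default_factory=lambda: StageConfig(
        nr=1, lam=0.0, delta=0.0, epochs=1000, batch_size=256, early_stop=True))
    bias_reduced: StageConfig = field(default_factory=lambda: StageConfig(
        nr=200, lam=1.0, delta=1.0, epochs=500, batch_size=256))
    mse_crb: StageConfig = field(default_factory=lambda: StageConfig(
        nr=1, lam=1.0, delta=0.0, epochs=500, batch_size=51200))
    learning_rate: float = 1e-4
    snr_range: tuple[float, float] = (10.0, 50.0)


@dataclass(frozen=True)
class TrainingData:
    """Noiseless compressed dictionary with truths and reference CRBs.

    ``y0``: (N, r) complex coefficients at unit m0; ``x_true``: (N, Np) in
    seconds; ``crb_ref``: (N, Np) CRBs at ``sigma_ref = 1``.
    """

    y0: np.ndarray
    x_true: np.ndarray
    crb_ref: np.ndarray
    sigma_ref: float = 1.0


def features(y: np.ndarray) -> np.ndarray:
    """Real/imaginary split of complex coefficients: (..., r) -> (..., 2r)."""
    y = np.asarray(y, dtype=complex)
    return np.concatenate([y.real, y.imag], axis=-1)


def predict(net: MLP, y: np.ndarray) -> np.ndarray:
    """Parameter estimates for compressed measurements, inference mode."""
    y = np.atleast_2d(np.asarray(y, dtype=complex))
    if y.shape[-1] * 2 != net.spec.input_dim:
        raise ValueError(f"expected {net.spec.input_dim // 2} coefficients, got {y.shape[-1]}")
    return net.forward(features(y), training=False)


def train_stage(
    net: MLP,
    data: TrainingData,
    stage: StageConfig,
    snr_range: tuple[float, float],
    rng: np.random.Generator,
    lr: float = 1e-4,
    val_indices: np.ndarray | None = None,
    train_indices: np.ndarray | None = None,
) -> list[float]:
    """Run one stage; returns the per-epoch training loss history.

    Each epoch draws a fresh SNR per sample (shared by that sample's ``nr``
    realizations), regenerates the noise, and sweeps shuffled minibatches of
    samples.  Early stopping (stage-0 "to convergence") halts when the
    validation loss improves by less than ``early_stop_rel`` over
    ``early_stop_patience`` epochs.
    """
    idx_all = np.arange(data.y0.shape[0]) if train_indices is None else np.asarray(train_indices)
    opt = Adam(net.parameters(), lr=lr)
    history: list[float] = []
    best_val, since_best = np.inf, 0

    for _epoch in range(stage.epochs):
        order = rng.permutation(idx_all)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, order.size, stage.batch_size):
            sel = order[lo: lo + stage.batch_size]
            batch = make_training_batch(
                data.y0, data.x_true, data.crb_ref, stage.nr, snr_range, rng,
                indices=sel, sigma_ref=data.sigma_ref,
            )
            ns, nr, r = batch.y_noisy.shape
            x_in = features(batch.y_noisy.reshape(ns * nr, r))
            pred = net.forward(x_in, training=True)
            block = EstimateBlock(pred.reshape(ns, nr, -1), batch.x_true)
            loss = wvcb_loss(block, batch.b, stage.lam, stage.delta)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (loss={loss}) at epoch {_epoch}")
            g_block = wvcb_loss_grad(block, batch.b, stage.lam, stage.delta)
            grads = net.backward(g_block.reshape(ns * nr, -1))
            opt.step(net.parameters(), grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))

        if stage.early_stop and val_indices is not None and val_indices.size:
            vb = make_training_batch(
                data.y0, data.x_true, data.crb_ref, stage.nr, snr_range,
                np.random.default_rng(12345), indices=val_indices, sigma_ref=data.sigma_ref,
            )
            ns, nr, r = vb.y_noisy.shape
            pred = predict(net, vb.y_noisy.reshape(ns * nr, r)).reshape(ns, nr, -1)
            val = wvcb_loss(EstimateBlock(pred, vb.x_true), vb.b, stage.lam, stage.delta)
            if val < best_val * (1.0 - stage.early_stop_rel):
                best_val, since_best = val, 0
            else:
                since_best += 1
                if since_best >= stage.early_stop_patience:
                    break
    return history


def train(
    net: MLP,
    data: TrainingData,
    protocol: TrainingProtocol,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> dict:
    """Two-stage training; returns stage-0 net, both branch nets and histories.

    Both branches start from the *identical* stage-0 weights.  The master
    seed drives every random choice (shuffles, SNRs, noise) so identical
    seeds give identical histories.
    """
    rng = np.random.default_rng(seed)
    n = data.y0.shape[0]
    n_val = max(1, int(round(val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    h0 = train_stage(
        net, data, protocol.stage0, protocol.snr_range, rng, lr=protocol.learning_rate,
        val_indices=val_idx, train_indices=train_idx,
    )
    stage0_net = net.copy()

    net_br = stage0_net.copy()
    rng_br = np.random.default_rng(seed + 1)
    h_br = train_stage(
        net_br, data, protocol.bias_reduced, protocol.snr_range, rng_br,
        lr=protocol.learning_rate, train_indices=train_idx,
    )

    net_mse = stage0_net.copy()
    rng_mse = np.random.default_rng(seed + 2)
    h_mse = train_stage(
        net_mse, data, protocol.mse_crb, protocol.snr_range, rng_mse,
        lr=protocol.learning_rate, train_indices=train_idx,
    )

    return {
        "stage0": stage0_net,
        "bias_reduced": net_br,
        "mse_crb": net_mse,
        "history": {"stage0": h0, "bias_reduced": h_br, "mse_crb": h_mse},
        "val_indices": val_idx,
        "train_indices": train_idx,
    }


# --------------------------------------------------------------------------
# reference estimators
# --------------------------------------------------------------------------

def dictionary_match(
    y: np.ndarray, dictionary_compressed: np.ndarray, params: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-correlation (discretized maximum likelihood) matching.

    ``y``: (r,) or (n, r) measurements; ``dictionary_compressed``: (N, r)
    noiseless atoms; ``params``: (N, Np) grid parameters.  Returns the
    matched parameters (n, Np) and the complex scale estimates
    ``m0 = <d, y> / ||d||^2``.  Ties break to the lowest atom index (argmax).
    """
    d = np.asarray(dictionary_compressed, dtype=complex)
    if d.size == 0:
        raise ValueError("empty dictionary")
    y = np.atleast_2d(np.asarray(y, dtype=complex))
    norms = np.linalg.norm(d, axis=1)
    corr = y @ d.conj().T  # (n, N): corr[n, i] = <d_i, y_n>
    idx = np.argmax(np.abs(corr) / norms[None, :], axis=1)
    m0 = corr[np.arange(y.shape[0]), idx] / norms[idx] ** 2
    return np.asarray(params)[idx], m0


def nlls_fit(
    y: np.ndarray,
    model,
    init: tuple[float, float],
    bounds: tuple | None = None,
    xtol: float = 1e-12,
) -> dict:
    """Variable-projection Levenberg-Marquardt fit of (T1, T2, complex M0).

    ``model(t1, t2)`` must return the unit-m0 compressed signal.  For each
    candidate (T1, T2) the complex scale is solved in closed form,
    ``m0* = <g, y> / ||g||^2``, and the real/imaginary parts of the residual
    ``y - m0* g`` are minimized over (T1, T2) with Levenberg-Marquardt
    (bounded problems fall back to the trust-region reflective solver).
    """
    y = np.asarray(y, dtype=complex)

    def proj_residual(theta):
        g = np.asarray(model(theta[0], theta[1]), dtype=complex)
        m0 = np.vdot(g, y) / np.vdot(g, g).real
        r = y - m0 * g
        return np.concatenate([r.real, r.imag])

    if bounds is None:
        res = scipy.optimize.least_squares(
            proj_residual, np.asarray(init, dtype=float), method="lm", xtol=xtol
        )
    else:
        res = scipy.optimize.least_squares(
            proj_residual, np.asarray(init, dtype=float), bounds=bounds, method="trf", xtol=xtol
        )
    t1, t2 = res.x
    g = np.asarray(model(t1, t2), dtype=complex)
    m0 = np.vdot(g, y) / np.vdot(g, g).real
    return {
        "t1": float(t1),
        "t2": float(t2),
        "m0": complex(m0),
        "cost": float(res.cost),
        "converged": bool(res.success),
        "n_evaluations": int(res.nfev),
    }
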