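"""Synthetic training/test data for the FISP T1/T2 estimation problem.

All data in this package are synthesized; nothing is downloaded.  The default
parameter grids reproduce the published FISP dictionary ranges (min:step:max,
in ms) for three tissue blocks — grey/white matter, fat, and CSF — with a
cartesian product of T1 and T2 within each block:

==========  =====================  ====================
block       T1 range (ms)          T2 range (ms)
==========  =====================  ====================
gm_wm       500 : 2   : 1500       10   : 0.38 : 200
fat         250 : 2.4 : 550        60   : 0.65 : 140
csf         3000: 16  : 5000       1500 : 8.1  : 2500
==========  =====================  ====================

Training batches carry ``Nr`` independent noise realizations of each sample
at a per-sample noise level drawn via SNR ~ Uniform(10, 50) (the published
interval; uniform is our least-informative reading of the open interval),
with the stored reference CRBs rescaled to the realized sigma via
``b(sigma) = sigma^2 * b(sigma=1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crb import compressed_crb
from .sequence import IsochromatEnsemble, SequenceConfig, simulate_fisp_batch, signal_jacobian, TissueParams

__all__ = [
    "ParamGrid",
    "TrainingBatch",
    "reference_fisp_grid",
    "desk_scale_grid",
    "expand_grid",
    "build_dictionary",
    "dictionary_crbs",
    "add_noise",
    "make_training_batch",
    "train_test_split",
]

# (t1_min, t1_step, t1_max, t2_min, t2_step, t2_max) in ms, per tissue block
_REFERENCE_BLOCKS = {
    "gm_wm": (500.0, 2.0, 1500.0, 10.0, 0.38, 200.0),
    "fat": (250.0, 2.4, 550.0, 60.0, 0.65, 140.0),
    "csf": (3000.0, 16.0, 5000.0, 1500.0, 8.1, 2500.0),
}


@dataclass(frozen=True)
class ParamGrid:
    """Blocks of (t1_range, t2_range, label); ranges are (min, step, max) in ms."""

    blocks: tuple = ()

    def __post_init__(self) -> None:
        for t1r, t2r, label in self.blocks:
            for lo, step, hi in (t1r, t2r):
                if step <= 0:
                    raise ValueError(f"non-positive step in block {label!r}")
                if lo > hi:
                    raise ValueError(f"min > max in block {label!r}")


def reference_fisp_grid() -> ParamGrid:
    """The published three-block FISP grid (282,249 atoms as printed)."""
    return ParamGrid(
        blocks=tuple(
            ((b[0], b[1], b[2]), (b[3], b[4], b[5]), label) for label, b in _REFERENCE_BLOCKS.items()
        )
    )


def desk_scale_grid(t1_step_ms: float = 25.0, t2_step_ms: float = 5.0) -> ParamGrid:
    """Coarsened grey/white-matter block for CPU-scale experiments.

    Same T1/T2 extents as the published grey/white-matter block, coarser
    steps (default 41 x 39 = 1599 atoms).
    """
    return ParamGrid(
        blocks=(((500.0, t1_step_ms, 1500.0), (10.0, t2_step_ms, 200.0), "gm_wm"),)
    )


def _axis(lo: float, step: float, hi: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def expand_grid(grid: ParamGrid) -> pd.DataFrame:
    """Cartesian product within each block; block-major, then T1-major order.

    Returns a DataFrame with columns ``t1``, ``t2`` (seconds) and ``block``.
    """
    frames = []
    for t1r, t2r, label in grid.blocks:
        t1 = _axis(*t1r) * 1e-3
        t2 = _axis(*t2r) * 1e-3
        if t1.size == 0 or t2.size == 0:
            raise ValueError(f"empty block {label!r}")
        tt1, tt2 = np.meshgrid(t1, t2, indexing="ij")
        frames.append(
            pd.DataFrame({"t1": tt1.ravel(), "t2": tt2.ravel(), "block": label})
        )
    if not frames:
        raise ValueError("grid has no blocks")
    return pd.concat(frames, ignore_index=True)


def build_dictionary(
    params: pd.DataFrame,
    seq: SequenceConfig,
    ensemble: IsochromatEnsemble,
    chunk: int = 2048,
    long_t2_ensemble: IsochromatEnsemble | None = None,
    long_t2_threshold: float = 1.0,
) -> np.ndarray:
    """Simulate one unit-``m0`` fingerprint per parameter row; returns (T, N).

    Rows are simulated in vectorized chunks; a failure is re-raised with the
    offending row range named.  ``long_t2_ensemble`` optionally substitutes a
    denser isochromat sampling for rows with T2 above ``long_t2_threshold``
    seconds (CSF-like tissues, where slowly decaying high dephasing orders
    need finer intravoxel sampling).
    """
    t1 = params["t1"].to_numpy(dtype=float)
    t2 = params["t2"].to_numpy(dtype=float)
    out = np.empty((seq.n_excitations, len(params)), dtype=complex)

    def simulate_rows(rows: np.ndarray, ens: IsochromatEnsemble) -> None:
        for lo in range(0, rows.size, chunk):
            sel = rows[lo: lo + chunk]
            try:
                out[:, sel] = simulate_fisp_batch(t1[sel], t2[sel], seq, ens).T
            except FloatingPointError as exc:  # pragma: no cover - defensive
                raise FloatingPointError(
                    f"simulation failed in rows {sel[0]}..{sel[-1]}: {exc}"
                ) from exc

    if long_t2_ensemble is None:
        simulate_rows(np.arange(len(params)), ensemble)
    else:
        dense = t2 > long_t2_threshold
        simulate_rows(np.flatnonzero(~dense), ensemble)
        if dense.any():
            simulate_rows(np.flatnonzero(dense), long_t2_ensemble)
    return out


def dictionary_crbs(
    params: pd.DataFrame,
    seq: SequenceConfig,
    ensemble: IsochromatEnsemble,
    basis,
    sigma_ref: float = 1.0,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Compressed-domain CRBs of (T1, T2) per atom at reference sigma; (N, 2).

    Jacobians are built from whole-dictionary perturbation passes (T1 +- h,
    T2 +- h) so the finite differencing is vectorized over atoms; the complex
    scale is handled analytically and enters the Fisher matrix as the two
    nuisance parameters (Re M0, Im M0).
    """
    t1 = params["t1"].to_numpy(dtype=float)
    t2 = params["t2"].to_numpy(dtype=float)
    base = build_dictionary(params, seq, ensemble)

    def pass_for(t1v, t2v):
        p = pd.DataFrame({"t1": t1v, "t2": t2v})
        return build_dictionary(p, seq, ensemble)

    h1 = rel_step * t1
    h2 = rel_step * t2
    d_t1 = (pass_for(t1 + h1, t2) - pass_for(t1 - h1, t2)) / (2.0 * h1)
    d_t2 = (pass_for(t1, t2 + h2) - pass_for(t1, t2 - h2)) / (2.0 * h2)

    out = np.empty((len(params), 2))
    mask = np.array([True, True, False, False])
    for i in range(len(params)):
        jac = np.stack([d_t1[:, i], d_t2[:, i], base[:, i], 1j * base[:, i]], axis=1)
        out[i] = compressed_crb(jac, basis, sigma_ref, estimated_mask=mask).b
    return out


def add_noise(y: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add white complex Gaussian noise, per-channel std ``sigma`` (0 = identity)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    y = np.asarray(y, dtype=complex)
    if sigma == 0:
        return y.copy()
    noise = rng.normal(0.0, sigma, y.shape) + 1j * rng.normal(0.0, sigma, y.shape)
    return y + noise


@dataclass(frozen=True)
class TrainingBatch:
    """Noisy compressed measurements with ground truth and realized CRBs.

    ``y_noisy``: (Ns, Nr, r) complex; ``x_true``: (Ns, Np); ``b``: (Ns, Np)
    CRBs at the realization's sigma; ``sigma``: (Ns,) per-sample noise std
    (shared across that sample's Nr realizations); ``seed``: bookkeeping.
    """

    y_noisy: np.ndarray
    x_true: np.ndarray
    b: np.ndarray
    sigma: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.y_noisy.ndim != 3:
            raise ValueError("y_noisy must be (Ns, Nr, r)")
        if np.any(self.b <= 0):
            raise ValueError("CRBs must be positive")

    @property
    def n_samples(self) -> int:
        return self.y_noisy.shape[0]

    @property
    def n_realizations(self) -> int:
        return self.y_noisy.shape[1]


def make_training_batch(
    compressed_dict: np.ndarray,
    x_true: np.ndarray,
    crb_ref: np.ndarray,
    nr: int,
    snr_range: tuple[float, float],
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
    sigma_ref: float = 1.0,
    m0_scale: float = 1.0,
    max_elements: int = 200_000_000,
) -> TrainingBatch:
    """Assemble an (Ns, Nr, r) noisy batch with per-sample random SNR.

    ``compressed_dict`` is (N, r) noiseless coefficients with unit m0;
    ``crb_ref`` the (N, Np) CRBs at ``sigma_ref``.  For each selected sample
    an SNR is drawn uniformly from ``snr_range``, sigma = m0_scale/SNR, and
    ``nr`` independent noisy copies are emitted; stored CRBs are rescaled by
    (sigma/sigma_ref)^2.
    """
    if nr < 1:
        raise ValueError("nr must be >= 1")
    lo, hi = snr_range
    if lo <= 0 or hi <= 0 or lo > hi:
        raise ValueError("snr_range must be positive with lo <= hi")
    if indices is None:
        indices = np.arange(compressed_dict.shape[0])
    ns = len(indices)
    r = compressed_dict.shape[1]
    if ns * nr * r > max_elements:
        raise MemoryError(
            f"batch of {ns}x{nr}x{r} exceeds the element budget {max_elements}; "
            "use a smaller batch or fewer realizations"
        )
    snr = rng.uniform(lo, hi, ns)
    sigma = m0_scale / snr
    y0 = compressed_dict[indices]  # (Ns, r)
    # draw noise at unit sigma then scale per sample (keeps one RNG stream)
    y = y0[:, None, :] + (
        rng.normal(0.0, 1.0, (ns, nr, r)) + 1j * rng.normal(0.0, 1.0, (ns, nr, r))
    ) * sigma[:, None, None]
    b = crb_ref[indices] * (sigma[:, None] / sigma_ref) ** 2
    return TrainingBatch(y_noisy=y, x_true=np.asarray(x_true)[indices], b=b, sigma=sigma)


def train_test_split(
    n: int, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random by-sample split; returns (train_idx, test_idx)."""
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])
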