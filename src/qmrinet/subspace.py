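"""Temporal subspace compression of fingerprint dictionaries.

The dictionary (time x atoms, complex) is factored with an SVD and the first
``r`` left singular vectors form the orthonormal temporal basis U.  Measured
fingerprints are represented by their coefficients ``y = U^H s`` — the same
low-rank representation a subspace reconstruction produces — and these
coefficients are what the network estimates parameters from.  Orthonormality
means white complex Gaussian noise on the signal stays white with the same
per-channel sigma in coefficient space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["SubspaceBasis", "build_basis", "compress", "reconstruction_error"]


@dataclass(frozen=True)
class SubspaceBasis:
    u: np.ndarray  # (T, r), orthonormal columns
    singular_values: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "u", np.asarray(self.u, dtype=complex))
        object.__setattr__(self, "singular_values", np.asarray(self.singular_values, dtype=float))
        gram = self.u.conj().T @ self.u
        if not np.allclose(gram, np.eye(self.rank), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")


def build_basis(dictionary_matrix: np.ndarray, rank: int) -> SubspaceBasis:
    """First ``rank`` left singular vectors of the (noiseless) dictionary.

    The per-column unit-phase ambiguity of the SVD is fixed by rotating each
    column so its largest-magnitude entry is real and positive, making stored
    bases reproducible across runs and platforms.
    """
    d = np.asarray(dictionary_matrix, dtype=complex)
    if d.size == 0:
        raise ValueError("empty dictionary")
    if not 1 <= rank <= min(d.shape):
        raise ValueError(f"rank must be in [1, {min(d.shape)}], got {rank}")
    u, s, _ = scipy.linalg.svd(d, full_matrices=False)
    u = u[:, :rank].copy()
    for k in range(rank):
        i = int(np.argmax(np.abs(u[:, k])))
        phase = u[i, k] / abs(u[i, k])
        u[:, k] *= np.conj(phase)
    return SubspaceBasis(u=u, singular_values=s, rank=rank)


def compress(signal: np.ndarray, basis: SubspaceBasis) -> np.ndarray:
    """Coefficients ``y = U^H s``; accepts a vector or a (T, N) matrix."""
    s = np.asarray(signal, dtype=complex)
    if s.shape[0] != basis.u.shape[0]:
        raise ValueError(f"signal length {s.shape[0]} != basis length {basis.u.shape[0]}")
    return basis.u.conj().T @ s


def reconstruction_error(dictionary_matrix: np.ndarray, basis: SubspaceBasis) -> np.ndarray:
    """Per-atom relative projection residual ``||U U^H s - s|| / ||s||``."""
    d = np.asarray(dictionary_matrix, dtype=complex)
    norms = np.linalg.norm(d, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm atom in dictionary")
    resid = d - basis.u @ (basis.u.conj().T @ d)
    return np.linalg.norm(resid, axis=0) / norms
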