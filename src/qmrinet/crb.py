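"""Fisher information and Cramér-Rao bounds for complex-valued signal models.

Noise convention (used consistently across the whole package): the measurement
is corrupted by additive white complex Gaussian noise whose real and imaginary
parts are each i.i.d. ``N(0, sigma^2)`` per channel, and ``SNR = |M0| / sigma``.
For real parameters ``theta`` of a complex model ``s(theta)`` this gives the
Fisher information ``I = Re(J^H J) / sigma^2`` with ``J`` the complex Jacobian.
The CRB of parameter ``k`` is the ``k``-th diagonal element of ``I^{-1}``,
with jointly identifiable nuisance parameters (the complex scale M0,
parameterized as Re/Im) included in the inversion and masked out of the
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseModel", "CRBTable", "fisher_information", "crb", "compressed_crb"]


@dataclass(frozen=True)
class NoiseModel:
    """White complex Gaussian noise: per-channel std ``sigma``, ``snr = |m0|/sigma``."""

    sigma: float
    m0_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def snr(self) -> float:
        return self.m0_scale / self.sigma

    @classmethod
    def from_snr(cls, snr: float, m0_scale: float = 1.0) -> "NoiseModel":
        return cls(sigma=m0_scale / snr, m0_scale=m0_scale)


@dataclass(frozen=True)
class CRBTable:
    """Per-parameter CRBs with the Fisher matrix they came from.

    ``b`` holds the bounds for the *estimated* parameters only (in squared
    parameter units); ``fisher`` is the full matrix including nuisance
    parameters; ``estimated_mask`` records which rows were reported.
    """

    b: np.ndarray
    fisher: np.ndarray
    estimated_mask: np.ndarray
    parameter_order: tuple[str, ...] = ("t1", "t2", "re_m0", "im_m0")
    sigma: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        object.__setattr__(self, "fisher", np.asarray(self.fisher, dtype=float))
        object.__setattr__(self, "estimated_mask", np.asarray(self.estimated_mask, dtype=bool))

    def rescaled(self, sigma: float) -> np.ndarray:
        """CRBs at a different noise level: ``b(sigma) = (sigma/sigma_ref)^2 b``."""
        return self.b * (sigma / self.sigma) ** 2


def fisher_information(jacobian: np.ndarray, sigma: float) -> np.ndarray:
    """``I = Re(J^H J) / sigma^2`` for per-channel noise std ``sigma``.

    Symmetric positive semi-definite by construction; scales as ``1/sigma^2``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    j = np.asarray(jacobian, dtype=complex)
    if not np.isfinite(j).all():
        raise ValueError("jacobian contains non-finite entries")
    info = (j.conj().T @ j).real / sigma**2
    return 0.5 * (info + info.T)


def crb(
    fisher: np.ndarray,
    estimated_mask: np.ndarray | None = None,
    parameter_order: tuple[str, ...] = ("t1", "t2", "re_m0", "im_m0"),
    sigma: float = 1.0,
    rcond: float = 1e-12,
) -> CRBTable:
    """Cramér-Rao bounds ``b_k = [I^{-1}]_kk`` for the estimated parameters.

    Nuisance parameters participate in the inversion and are masked out of
    ``b``.  A singular Fisher matrix raises with the null-space direction
    named, since it means some parameter combination is unidentifiable from
    the measurement.
    """
    fisher = np.asarray(fisher, dtype=float)
    n = fisher.shape[0]
    if estimated_mask is None:
        estimated_mask = np.ones(n, dtype=bool)
    estimated_mask = np.asarray(estimated_mask, dtype=bool)

    w, v = np.linalg.eigh(fisher)
    tol = rcond * max(abs(w).max(), 1.0)
    if w.min() < tol:
        null_dir = v[:, int(np.argmin(w))]
        labels = ", ".join(
            f"{c:+.3f}*{name}" for c, name in zip(null_dir, parameter_order[:n]) if abs(c) > 1e-3
        )
        raise np.linalg.LinAlgError(
            f"Fisher matrix is singular: unidentifiable direction [{labels}]"
        )
    inv = v @ np.diag(1.0 / w) @ v.T
    b = np.diag(inv)[estimated_mask]
    return CRBTable(
        b=b, fisher=fisher, estimated_mask=estimated_mask,
        parameter_order=parameter_order, sigma=sigma,
    )


def compressed_crb(
    jacobian: np.ndarray,
    basis,
    sigma: float,
    estimated_mask: np.ndarray | None = None,
    parameter_order: tuple[str, ...] = ("t1", "t2", "re_m0", "im_m0"),
) -> CRBTable:
    """CRB for measurements compressed onto an orthonormal temporal basis.

    Because the basis is orthonormal, white noise on the full signal maps to
    white noise with the same per-channel ``sigma`` on the coefficients, so
    the Fisher matrix is simply recomputed from ``U^H J``.  Equals the
    full-signal CRB when all Jacobian columns lie in span(U); otherwise each
    bound can only grow (data-processing inequality).
    """
    u = basis.u if hasattr(basis, "u") else np.asarray(basis)
    j_c = u.conj().T @ np.asarray(jacobian, dtype=complex)
    fisher = fisher_information(j_c, sigma)
    return crb(fisher, estimated_mask, parameter_order, sigma=sigma)
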