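"""Inversion-recovery MRF-FISP signal simulation.

Two simulators of the same gradient-spoiled fingerprinting experiment:

* an isochromat-ensemble Bloch simulator (:func:`simulate_fisp_isochromat`)
  that models intravoxel spoiler dephasing and the small-flip-angle slice
  profile explicitly, matching how FISP dictionaries are usually computed;
* an extended-phase-graph (EPG) recursion (:func:`simulate_fisp_epg`) for the
  ideal-spoiling, no-slice-profile regime, kept as an independent cross-check.

Conventions
-----------
Time is in seconds everywhere inside the library (milliseconds appear only at
CLI/config boundaries).  The transverse signal is ``Mx + i*My``; RF pulses
rotate the magnetization about an axis in the transverse plane at angle
``rf_phase`` (constant phase, FISP convention), with a positive flip tipping
equilibrium +z magnetization toward +y for ``rf_phase = 0``.  The recorded
fingerprint is the complex isochromat average of the transverse magnetization
at the echo time of every excitation, scaled by the complex proton density
``m0``; the signal is therefore exactly linear in ``m0``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence as _Seq

import numpy as np

__all__ = [
    "SequenceConfig",
    "TissueParams",
    "IsochromatEnsemble",
    "Fingerprint",
    "make_flip_schedule",
    "slice_profile",
    "simulate_fisp_isochromat",
    "simulate_fisp_epg",
    "signal_jacobian",
    "default_sequence",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceConfig:
    """FISP pulse-sequence timing, flip-angle train, and spoiling.

    Parameters
    ----------
    tr, te, ti
        Repetition time, echo time and inversion time in seconds.  ``ti`` is
        the delay between the (instantaneous) adiabatic inversion and the
        first excitation.
    flip_schedule
        Flip angle per excitation in radians, length ``T``.
    rf_phase
        Constant RF phase in radians (FISP: no quadratic RF spoiling).
    spoil_phase_per_tr
        Intravoxel dephasing in radians accrued across the slice-profile FWHM
        per TR (default 14.6*pi).
    pulse_duration, time_bandwidth
        Sinc excitation pulse parameters used only to derive the slice
        profile (the pulse itself is treated as instantaneous).
    inversion_efficiency
        Fraction of longitudinal magnetization inverted, in [0, 1].
    n_cycles
        Number of repetitions of the flip train (>=1).  Successive cycles
        continue from the running magnetization without a new inversion.
    """

    tr: float = 10e-3
    te: float = 5e-3
    ti: float = 20e-3
    flip_schedule: np.ndarray = field(
        default_factory=lambda: make_flip_schedule({"kind": "sinusoidal", "length": 400})
    )
    rf_phase: float = 0.0
    spoil_phase_per_tr: float = 14.6 * np.pi
    pulse_duration: float = 1e-3
    time_bandwidth: float = 4.0
    inversion_efficiency: float = 1.0
    n_cycles: int = 1

    def __post_init__(self) -> None:
        flips = np.atleast_1d(np.asarray(self.flip_schedule, dtype=float))
        object.__setattr__(self, "flip_schedule", flips)
        if not (self.tr > self.te > 0):
            raise ValueError(f"require tr > te > 0, got tr={self.tr}, te={self.te}")
        if self.ti <= 0:
            raise ValueError("ti must be positive")
        if flips.size < 1:
            raise ValueError("flip_schedule must contain at least one excitation")
        if np.any(flips < 0) or np.any(flips > np.pi):
            raise ValueError("flip angles must lie in [0, pi]")
        if not 0.0 <= self.inversion_efficiency <= 1.0:
            raise ValueError("inversion_efficiency must lie in [0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def n_excitations(self) -> int:
        return int(self.flip_schedule.size) * self.n_cycles


@dataclass(frozen=True)
class TissueParams:
    """Single-compartment tissue parameters: T1, T2 (seconds), complex M0, B1+."""

    t1: float
    t2: float
    m0: complex = 1.0 + 0.0j
    b1: float = 1.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")
        if self.t2 > self.t1:
            warnings.warn(
                f"T2={self.t2}s exceeds T1={self.t1}s; physically implausible",
                stacklevel=2,
            )

    def replace(self, **kw) -> "TissueParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class IsochromatEnsemble:
    """Intravoxel spin packets sampling the slice profile and the spoiler.

    ``positions`` are slice coordinates in units of the slice FWHM (the two
    FWHM points sit at +-0.5).  ``flip_scale`` scales every nominal flip angle
    per isochromat; ``phase_per_tr`` is the spoiler phase each isochromat
    accrues per TR, linear in position so that the span across the FWHM
    equals the sequence's ``spoil_phase_per_tr``.
    """

    positions: np.ndarray
    flip_scale: np.ndarray
    phase_per_tr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("positions", "flip_scale", "phase_per_tr"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (self.positions.size == self.flip_scale.size == self.phase_per_tr.size):
            raise ValueError("ensemble arrays must have equal length")
        if self.positions.size < 1:
            raise ValueError("ensemble must contain at least one isochromat")

    @property
    def n_iso(self) -> int:
        return int(self.positions.size)

    @classmethod
    def uniform_dephasing(cls, n_iso: int, phase_span: float = 2 * np.pi) -> "IsochromatEnsemble":
        """Uniformly dephased spins with unit flip scale (ideal-spoiling limit).

        Phases ``phase_span * k / n_iso`` reproduce EPG exactly once
        ``n_iso`` exceeds the number of populated dephasing orders.
        """
        k = np.arange(n_iso)
        return cls(
            positions=k / max(n_iso, 1),
            flip_scale=np.ones(n_iso),
            phase_per_tr=phase_span * k / n_iso,
        )


@dataclass(frozen=True)
class Fingerprint:
    """Complex signal time-series with its generating parameters."""

    signal: np.ndarray
    params: TissueParams
    seq_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=complex))


# --------------------------------------------------------------------------
# flip schedules
# --------------------------------------------------------------------------

def make_flip_schedule(descriptor: dict | _Seq[float]) -> np.ndarray:
    """Build a flip-angle train (radians) from an explicit list or a generator.

    Descriptors (dict):

    * ``{"kind": "explicit", "angles": [...]}`` — angles in radians.
    * ``{"kind": "constant", "length": T, "angle": a}``.
    * ``{"kind": "sinusoidal", "length": T, "max_angle": a, "n_lobes": L}`` —
      smooth sinusoidal lobes ``a * |sin(pi * L * t / T)|``, a documented
      stand-in for the (unpublished) MRF-FISP schedule; default max angle
      ~70 deg, 2 lobes.

    A bare sequence of floats is treated as an explicit list.  Deterministic
    for a fixed descriptor.
    """
    if not isinstance(descriptor, dict):
        descriptor = {"kind": "explicit", "angles": list(descriptor)}
    kind = descriptor.get("kind", "explicit")
    if kind == "explicit":
        angles = np.asarray(descriptor["angles"], dtype=float)
    elif kind == "constant":
        t = int(descriptor["length"])
        angles = np.full(t, float(descriptor.get("angle", np.deg2rad(35.0))))
    elif kind == "sinusoidal":
        t = int(descriptor["length"])
        max_angle = float(descriptor.get("max_angle", np.deg2rad(70.0)))
        n_lobes = int(descriptor.get("n_lobes", 2))
        idx = np.arange(t, dtype=float)
        angles = max_angle * np.abs(np.sin(np.pi * n_lobes * (idx + 0.5) / t))
    else:
        raise ValueError(f"unknown flip-schedule kind {kind!r}")
    if angles.size == 0:
        raise ValueError("empty flip schedule")
    if np.any(angles < 0) or np.any(angles > np.pi):
        raise ValueError("flip angles must lie in [0, pi]")
    return angles


# --------------------------------------------------------------------------
# slice profile
# --------------------------------------------------------------------------

def _sinc_envelope(time_bandwidth: float, n: int = 1024) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-apodized sinc RF envelope on normalized support [-1/2, 1/2]."""
    x = np.linspace(-0.5, 0.5, n)
    env = np.sinc(time_bandwidth * x) * np.hamming(n)
    return x, env


def slice_profile(
    time_bandwidth: float = 4.0,
    pulse_duration: float = 1e-3,
    n_fwhm: int = 600,
    n_total: int = 1324,
    tail_span: float = 2.0,
    spoil_phase_per_tr: float = 14.6 * np.pi,
) -> IsochromatEnsemble:
    """Isochromat ensemble sampling the small-flip-angle slice profile.

    The excitation profile across the slice is the Fourier transform of the
    apodized sinc envelope (small-flip-angle approximation), magnitude
    normalized to 1 at slice center.  ``n_fwhm`` isochromats are placed
    uniformly between the two FWHM points (where the profile is 0.5 by
    definition); the remaining ``n_total - n_fwhm`` sample the tails out to
    ``tail_span`` FWHMs on each side.  Spoiler phase per TR is linear in
    position with exactly ``spoil_phase_per_tr`` span across the FWHM.
    """
    if pulse_duration <= 0 or time_bandwidth <= 0:
        raise ValueError("pulse_duration and time_bandwidth must be positive")
    if not (n_total >= n_fwhm >= 1):
        raise ValueError("require n_total >= n_fwhm >= 1")
    if tail_span < 1:
        raise ValueError("tail_span must be >= 1 FWHM")

    if n_total == 1:
        return IsochromatEnsemble(
            positions=np.zeros(1), flip_scale=np.ones(1), phase_per_tr=np.zeros(1)
        )

    # dense numerical FT of the envelope; symmetric envelope -> real profile
    x, env = _sinc_envelope(time_bandwidth)
    u = np.linspace(-2.0 * time_bandwidth, 2.0 * time_bandwidth, 4096)
    profile = (env[None, :] * np.exp(-2j * np.pi * u[:, None] * x[None, :])).sum(axis=1).real
    profile = np.abs(profile)
    profile /= profile.max()

    # locate the FWHM points by interpolation on either side of the peak
    peak = int(np.argmax(profile))
    left = np.interp(0.5, profile[: peak + 1], u[: peak + 1])
    right = np.interp(0.5, profile[peak:][::-1], u[peak:][::-1])
    fwhm = right - left
    center = 0.5 * (right + left)

    # positions in FWHM units, FWHM points at +-0.5
    pos_fwhm = np.linspace(-0.5, 0.5, n_fwhm)
    n_tail = n_total - n_fwhm
    n_left = n_tail // 2
    n_right = n_tail - n_left
    pos_left = np.linspace(-0.5 - tail_span, -0.5, n_left, endpoint=False) if n_left else np.empty(0)
    pos_right = (
        np.linspace(0.5 + tail_span, 0.5, n_right, endpoint=False)[::-1] if n_right else np.empty(0)
    )
    positions = np.concatenate([pos_left, pos_fwhm, pos_right])

    flip_scale = np.interp(center + positions * fwhm, u, profile, left=0.0, right=0.0)
    phase_per_tr = spoil_phase_per_tr * positions
    return IsochromatEnsemble(positions=positions, flip_scale=flip_scale, phase_per_tr=phase_per_tr)


# --------------------------------------------------------------------------
# isochromat Bloch simulation
# --------------------------------------------------------------------------

def _relax(mx, my, mz, e1, e2):
    return mx * e2, my * e2, 1.0 + (mz - 1.0) * e1


def simulate_fisp_batch(
    t1: np.ndarray,
    t2: np.ndarray,
    seq: SequenceConfig,
    ensemble: IsochromatEnsemble,
    b1: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Vectorized isochromat simulation for many tissues at once.

    Returns the complex signal array of shape ``(n_tissues, T)`` for unit
    ``m0``; multiply by ``m0`` for scaled fingerprints.
    """
    t1 = np.atleast_1d(np.asarray(t1, dtype=float))[:, None]
    t2 = np.atleast_1d(np.asarray(t2, dtype=float))[:, None]
    n_tis = t1.shape[0]
    n_iso = ensemble.n_iso
    flips = np.tile(seq.flip_schedule, seq.n_cycles)
    n_t = flips.size

    b1 = np.broadcast_to(np.asarray(b1, dtype=float), (n_tis,))[:, None]
    uniform_b1 = np.allclose(b1, b1.flat[0])

    e1_te = np.exp(-seq.te / t1)
    e2_te = np.exp(-seq.te / t2)
    e1_rr = np.exp(-(seq.tr - seq.te) / t1)
    e2_rr = np.exp(-(seq.tr - seq.te) / t2)
    e1_ti = np.exp(-seq.ti / t1)

    cph, sph = np.cos(ensemble.phase_per_tr), np.sin(ensemble.phase_per_tr)
    cr, sr = np.cos(seq.rf_phase), np.sin(seq.rf_phase)

    # per-(excitation, isochromat) rotation angles; shared across tissues
    # when B1+ is uniform so the trig is hoisted out of the TR loop
    if uniform_b1:
        ang = flips[:, None] * ensemble.flip_scale[None, :] * b1.flat[0]  # (T, iso)
        cos_a, sin_a = np.cos(ang), np.sin(ang)

    mx = np.zeros((n_tis, n_iso))
    my = np.zeros((n_tis, n_iso))
    mz = np.ones((n_tis, n_iso))

    # inversion + TI recovery
    mz *= -seq.inversion_efficiency
    mx, my, mz = _relax(mx, my, mz, e1_ti, 0.0)

    signal = np.empty((n_tis, n_t), dtype=complex)
    for t in range(n_t):
        if uniform_b1:
            ca, sa = cos_a[t], sin_a[t]  # (iso,)
        else:
            ang = flips[t] * ensemble.flip_scale[None, :] * b1
            ca, sa = np.cos(ang), np.sin(ang)
        # rotate about the transverse axis at rf_phase: R_z(phi) R_x(a) R_z(-phi),
        # with R_x(a): y -> y cos a + z sin a (tips +z toward +y)
        if seq.rf_phase != 0.0:
            mxp = cr * mx + sr * my
            myp = -sr * mx + cr * my
        else:
            mxp, myp = mx, my
        my2 = myp * ca + mz * sa
        mz = -myp * sa + mz * ca
        if seq.rf_phase != 0.0:
            mx = cr * mxp - sr * my2
            my = sr * mxp + cr * my2
        else:
            mx, my = mxp, my2
        # TE relaxation, then readout
        mx, my, mz = _relax(mx, my, mz, e1_te, e2_te)
        signal[:, t] = (mx + 1j * my).mean(axis=1)
        # rest of TR + spoiler dephasing (z-rotation commutes with relaxation)
        mx, my, mz = _relax(mx, my, mz, e1_rr, e2_rr)
        mx, my = mx * cph - my * sph, mx * sph + my * cph
        if t % 64 == 0 and not np.isfinite(mz).all():
            raise FloatingPointError(f"NaN in magnetization state at excitation {t}")
    if not np.isfinite(signal).all():
        raise FloatingPointError("NaN in simulated signal")
    return signal


def simulate_fisp_isochromat(
    tissue: TissueParams, seq: SequenceConfig, ensemble: IsochromatEnsemble
) -> Fingerprint:
    """Single-tissue isochromat-ensemble FISP fingerprint (slice profile + spoiler)."""
    sig = simulate_fisp_batch(tissue.t1, tissue.t2, seq, ensemble, b1=tissue.b1)[0]
    return Fingerprint(signal=tissue.m0 * sig, params=tissue)


# --------------------------------------------------------------------------
# EPG simulation (ideal spoiling, no slice profile)
# --------------------------------------------------------------------------

def simulate_fisp_epg(
    tissue: TissueParams, seq: SequenceConfig, max_order: int | None = None
) -> Fingerprint:
    """Extended-phase-graph FISP fingerprint under ideal unbalanced spoiling.

    One unit of gradient dephasing per TR; the signal is read from the F0
    configuration at TE.  Equivalent to averaging uniformly dephased
    isochromats once the dephasing-order ladder is resolved; used as the
    cross-check oracle for the isochromat simulator.
    """
    flips = np.tile(seq.flip_schedule, seq.n_cycles) * tissue.b1
    n_t = flips.size
    k_max = n_t if max_order is None else min(max_order, n_t)

    # transverse configurations F_k for k in [-k_max, k_max] (offset storage)
    f = np.zeros(2 * k_max + 1, dtype=complex)
    z = np.zeros(k_max + 1, dtype=complex)
    z[0] = 1.0

    e1_te, e2_te = np.exp(-seq.te / tissue.t1), np.exp(-seq.te / tissue.t2)
    e1_rr = np.exp(-(seq.tr - seq.te) / tissue.t1)
    e2_rr = np.exp(-(seq.tr - seq.te) / tissue.t2)

    def relax(e1, e2):
        nonlocal f, z
        f = f * e2
        z = z * e1
        z[0] += 1.0 - e1

    # inversion + TI
    z[0] *= -seq.inversion_efficiency
    relax(np.exp(-seq.ti / tissue.t1), 0.0)

    phi = seq.rf_phase
    ks = np.arange(k_max + 1)
    signal = np.empty(n_t, dtype=complex)
    for t in range(n_t):
        a = flips[t]
        c2, s2 = np.cos(a / 2.0) ** 2, np.sin(a / 2.0) ** 2
        sa, ca = np.sin(a), np.cos(a)
        # RF mixing of (F+_k, F-_k, Z_k); conventions chosen so a pulse about
        # rf_phase=0 tips +z toward +y, matching the isochromat simulator
        fp = f[k_max + ks]
        fm = np.conj(f[k_max - ks])
        zk = z[ks].copy()
        fp_new = c2 * fp + s2 * np.exp(2j * phi) * fm + 1j * np.exp(1j * phi) * sa * zk
        fm_new = s2 * np.exp(-2j * phi) * fp + c2 * fm - 1j * np.exp(-1j * phi) * sa * zk
        z_new = 0.5j * sa * (np.exp(-1j * phi) * fp - np.exp(1j * phi) * fm) + ca * zk
        f[k_max + ks] = fp_new
        f[k_max - ks] = np.conj(fm_new)
        f[k_max] = fp_new[0]  # k=0 consistency
        z[ks] = z_new
        # TE relaxation and readout of F0
        relax(e1_te, e2_te)
        signal[t] = f[k_max]
        # rest of TR, then one unit of gradient dephasing: F_k -> F_{k+1}
        relax(e1_rr, e2_rr)
        f[1:] = f[:-1]
        f[0] = 0.0
    if not np.isfinite(signal).all():
        raise FloatingPointError("NaN in EPG signal")
    return Fingerprint(signal=tissue.m0 * signal, params=tissue)


# --------------------------------------------------------------------------
# signal Jacobian
# --------------------------------------------------------------------------

def signal_jacobian(
    tissue: TissueParams,
    seq: SequenceConfig,
    ensemble: IsochromatEnsemble,
    params_to_differentiate: _Seq[str] = ("t1", "t2", "re_m0", "im_m0"),
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Complex signal Jacobian, columns in the order requested.

    T1/T2 derivatives use central finite differences with relative step
    ``rel_step``; the M0 derivatives are analytic by linearity of the signal
    in the complex scale (``d s / d Re(m0) = s / m0`` and
    ``d s / d Im(m0) = i s / m0``).
    """
    if rel_step <= 0 or rel_step < 1e-12:
        raise ValueError("rel_step underflow")
    base = simulate_fisp_batch(tissue.t1, tissue.t2, seq, ensemble, b1=tissue.b1)[0]
    cols = []
    for name in params_to_differentiate:
        if name in ("t1", "t2"):
            val = getattr(tissue, name)
            h = rel_step * val
            lo, hi = val - h, val + h
            if lo <= 0:
                raise ValueError(f"{name} too close to domain boundary for step {h}")
            t1s = [hi if name == "t1" else tissue.t1, lo if name == "t1" else tissue.t1]
            t2s = [hi if name == "t2" else tissue.t2, lo if name == "t2" else tissue.t2]
            sig = simulate_fisp_batch(np.array(t1s), np.array(t2s), seq, ensemble, b1=tissue.b1)
            cols.append(tissue.m0 * (sig[0] - sig[1]) / (2.0 * h))
        elif name == "re_m0":
            cols.append(base.copy())
        elif name == "im_m0":
            cols.append(1j * base)
        else:
            raise ValueError(f"unknown parameter {name!r}")
    return np.stack(cols, axis=1)


def default_sequence(n_excitations: int = 400, **kw) -> SequenceConfig:
    """The default FISP sequence: TR=10ms, TE=5ms, TI=20ms, sinusoidal train."""
    return SequenceConfig(
        flip_schedule=make_flip_schedule({"kind": "sinusoidal", "length": n_excitations}), **kw
    )
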