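"""Three-compartment diffusion-relaxation forward signal model.

The signal at diffusion weighting ``b`` (s/mm^2) and echo time ``TE`` (ms) is

    S(b, TE) = S0 * ( f * exp(-b*d_star - TE*r2fb)
                      + (1 - f) * exp(-b*d) * ( v * exp(-TE*r2mb)
                                                + (1 - v) * exp(-TE*r2t) ) )

with rapid-perfusing (fetal blood) volume fraction ``f``, tissue diffusivity
``d`` (mm^2/s), pseudo-diffusivity ``d_star`` (mm^2/s), fetal-blood transverse
relaxation rate ``r2fb = 1/T2fb`` (1/ms) and slow-perfusing (maternal blood)
volume fraction ``v``. Maternal-blood and tissue relaxation rates are fixed
literature constants. Note that the tissue compartment carries the same
``exp(-b*d)`` attenuation as the maternal-blood compartment, consistent with
the linearized form (see :mod:`decidemri.linear_fit`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "ModelConstants",
    "DecideParams",
    "Fo2Calibration",
    "decide_signal",
    "lambda_from_physio",
    "physio_from_lambda",
    "fo2_from_t2fb",
    "t2fb_from_fo2",
]

PARAM_NAMES = ("f", "d", "d_star", "t2fb", "v")


@dataclass(frozen=True)
class ModelConstants:
    """Fixed model constants (all overridable).

    r2mb, r2t : maternal-blood and tissue relaxation rates, 1/ms.
    d_star_fixed, t2fb_fixed : literature pseudo-diffusivity (mm^2/s) and
        fetal-blood T2 (ms) used by the linearized fit, where d* and r2fb
        must be assumed known.
    """

    r2mb: float = 1.0 / 240.0
    r2t: float = 1.0 / 46.0
    d_star_fixed: float = 0.073
    t2fb_fixed: float = 144.89

    @property
    def r2fb_fixed(self) -> float:
        return 1.0 / self.t2fb_fixed


@dataclass
class DecideParams:
    """The five model parameters plus S0, scalar or as broadcastable maps."""

    s0: float | np.ndarray = 1.0
    f: float | np.ndarray = 0.2
    d: float | np.ndarray = 0.0015
    d_star: float | np.ndarray = 0.04
    t2fb: float | np.ndarray = 160.0
    v: float | np.ndarray = 0.3

    @property
    def r2fb(self) -> float | np.ndarray:
        return 1.0 / np.asarray(self.t2fb)

    def validate(self) -> None:
        for name, lo_ok in (("s0", np.all(np.asarray(self.s0) > 0)),
                            ("d", np.all(np.asarray(self.d) > 0)),
                            ("d_star", np.all(np.asarray(self.d_star) > 0)),
                            ("t2fb", np.all(np.asarray(self.t2fb) > 0))):
            if not lo_ok:
                raise ValueError(f"{name} must be > 0")
        for name in ("f", "v"):
            val = np.asarray(getattr(self, name))
            if np.any(val <= 0) or np.any(val >= 1):
                raise ValueError(f"{name} must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        """Stack (f, d, d_star, t2fb, v) along a trailing axis."""
        return np.stack(
            [np.asarray(getattr(self, k), dtype=float) for k in PARAM_NAMES], axis=-1
        )

    def copy(self) -> "DecideParams":
        return replace(self)


def decide_signal(
    params: DecideParams,
    constants: ModelConstants,
    protocol: AcquisitionProtocol,
) -> np.ndarray:
    """Evaluate the forward model for every protocol entry.

    Parameter fields may be scalars or arrays of a common shape ``shape``;
    the result has shape ``shape + (protocol.n,)`` with entry ``i``
    corresponding to ``protocol.entries[i]``.
    """
    b = protocol.b
    te = protocol.te
    s0 = np.asarray(params.s0, dtype=float)[..., None]
    f = np.asarray(params.f, dtype=float)[..., None]
    d = np.asarray(params.d, dtype=float)[..., None]
    d_star = np.asarray(params.d_star, dtype=float)[..., None]
    r2fb = 1.0 / np.asarray(params.t2fb, dtype=float)[..., None]
    v = np.asarray(params.v, dtype=float)[..., None]

    fast = f * np.exp(-b * d_star - te * r2fb)
    tissue_mix = v * np.exp(-te * constants.r2mb) + (1.0 - v) * np.exp(-te * constants.r2t)
    slow = (1.0 - f) * np.exp(-b * d) * tissue_mix
    return s0 * (fast + slow)


def lambda_from_physio(
    s0: float | np.ndarray, f: float | np.ndarray, v: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map (S0, f, v) to the nonnegative linear amplitudes (lam1, lam2, lam3).

    lam1 = S0*f, lam2 = S0*(1-f)*v, lam3 = S0*(1-f)*(1-v); their sum is S0.
    """
    s0 = np.asarray(s0, dtype=float)
    f = np.asarray(f, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("s0 must be > 0")
    if np.any((f < 0) | (f > 1)) or np.any((v < 0) | (v > 1)):
        raise ValueError("f and v must lie in [0, 1]")
    return s0 * f, s0 * (1.0 - f) * v, s0 * (1.0 - f) * (1.0 - v)


def physio_from_lambda(
    lam1: float | np.ndarray, lam2: float | np.ndarray, lam3: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert :func:`lambda_from_physio`: returns (s0, f, v).

    S0 = lam1 + lam2 + lam3 (the value consistent with the amplitude
    definitions), f = lam1/S0, v = lam2/(lam2 + lam3).
    """
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    lam3 = np.asarray(lam3, dtype=float)
    s0 = lam1 + lam2 + lam3
    if np.any(s0 <= 0):
        raise ValueError("lam1 + lam2 + lam3 must be > 0")
    denom = lam2 + lam3
    if np.any(denom <= 0):
        raise ValueError("lam2 + lam3 must be > 0 (degenerate voxel)")
    return s0, lam1 / s0, lam2 / denom


@dataclass(frozen=True)
class Fo2Calibration:
    """Quadratic blood relaxometry calibration 1/T2 = a + k*(1 - FO2)^2.

    The defaults place fully oxygenated blood at T2 = 240 ms (a = 1/240 1/ms)
    with a deoxygenation coefficient k = 0.025 1/ms, a 1.5 T spin-echo-scale
    curve; both constants must be reviewed against the relaxometry literature
    for the field strength and sequence in use before physiological claims
    are made.
    """

    a: float = 1.0 / 240.0
    k: float = 0.025


def fo2_from_t2fb(
    t2fb: float | np.ndarray, calibration: Fo2Calibration | None = None
) -> np.ndarray:
    """Convert fetal-blood T2 (ms) to fractional oxygen saturation in [0, 1].

    Monotone increasing in t2fb; values whose relaxation rate falls outside
    the calibration's representable range are clipped with a warning.
    """
    cal = calibration or Fo2Calibration()
    t2fb = np.asarray(t2fb, dtype=float)
    if np.any(t2fb <= 0):
        raise ValueError("t2fb must be > 0")
    excess = (1.0 / t2fb - cal.a) / cal.k
    if np.any(excess < 0) or np.any(excess > 1):
        warnings.warn(
            "t2fb outside calibration range; fractional saturation clipped",
            stacklevel=2,
        )
    fo2 = 1.0 - np.sqrt(np.clip(excess, 0.0, None))
    return np.clip(fo2, 0.0, 1.0)


def t2fb_from_fo2(
    fo2: float | np.ndarray, calibration: Fo2Calibration | None = None
) -> np.ndarray:
    """Inverse of :func:`fo2_from_t2fb` on the calibration's valid range."""
    cal = calibration or Fo2Calibration()
    fo2 = np.asarray(fo2, dtype=float)
    return 1.0 / (cal.a + cal.k * (1.0 - fo2) ** 2)
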