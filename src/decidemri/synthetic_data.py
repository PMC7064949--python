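"""Placenta-like phantoms: smooth parameter fields, noisy series, motion.

Everything is seeded and bit-reproducible, so the full pipeline is testable
without clinical data. Parameter ranges default to plausible placental values
(roughly mean +- SD of published unregistered-data estimates, clipped to the
fit bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .model import DecideParams, ModelConstants, decide_signal
from .protocol import AcquisitionProtocol
from .registration import DisplacementField, bspline_basis_matrix, warp_volume
from .series import SignalSeries

__all__ = ["PhantomSpec", "make_phantom", "simulate_series", "simulate_motion"]

#: default per-parameter (low, high) value ranges for the phantom fields
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "s0": (0.8, 1.2),
    "f": (0.10, 0.34),
    "d": (0.0012, 0.0018),
    "d_star": (0.021, 0.056),
    "t2fb": (155.0, 207.0),
    "v": (0.255, 0.357),
}

#: surrounding-tissue ranges used by the "tissue" background mode; distinctly
#: different from the ROI so the organ boundary is sharp, as in real anatomy
BACKGROUND_RANGES: dict[str, tuple[float, float]] = {
    "s0": (0.45, 0.65),
    "f": (0.02, 0.08),
    "d": (0.0008, 0.0012),
    "d_star": (0.010, 0.020),
    "t2fb": (60.0, 90.0),
    "v": (0.10, 0.20),
}


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (32, 32, 16)
    spacing: tuple[float, float, float] = (2.5, 2.5, 3.0)
    ellipsoid_radii: tuple[float, float, float] | None = None  # voxels; default 0.38*shape
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))
    smoothness: float = 4.0  # Gaussian SD (voxels) of the random fields
    background: str = "zero"  # "zero": fields vanish outside the ROI;
    # "full": the ROI fields extend smoothly over the whole grid;
    # "tissue": outside voxels get separate tissue-like fields (sharp organ
    # boundary). In both non-zero modes the ROI mask only delimits analysis.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        for name, (lo, hi) in self.ranges.items():
            if not lo <= hi:
                raise ValueError(f"range for {name} must satisfy low <= high")


def _ellipsoid_mask(
    shape: tuple[int, int, int], radii: tuple[float, float, float]
) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grid, center, radii))
    return r2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[DecideParams, np.ndarray]:
    """Smooth seeded random parameter maps inside an ellipsoidal mask.

    Each parameter is smoothed white noise rescaled to span the declared
    range (with infinite smoothness the field collapses to the midpoint).
    Background voxels are zero.
    """
    rng = np.random.default_rng(spec.seed)
    radii = spec.ellipsoid_radii or tuple(0.38 * n for n in spec.shape)
    mask = _ellipsoid_mask(spec.shape, radii)

    def _smooth_field(lo: float, hi: float) -> np.ndarray:
        noise = rng.standard_normal(spec.shape)
        if np.isfinite(spec.smoothness) and spec.smoothness > 0:
            noise = gaussian_filter(noise, spec.smoothness)
        span = noise.max() - noise.min()
        if not np.isfinite(spec.smoothness) or span == 0 or lo == hi:
            return np.full(spec.shape, 0.5 * (lo + hi))
        return lo + (hi - lo) * (noise - noise.min()) / span

    maps: dict[str, np.ndarray] = {}
    for name in ("s0", "f", "d", "d_star", "t2fb", "v"):
        fieldmap = _smooth_field(*spec.ranges[name])
        if spec.background == "zero":
            fieldmap = np.where(mask, fieldmap, 0.0)
        elif spec.background == "tissue":
            fieldmap = np.where(mask, fieldmap, _smooth_field(*BACKGROUND_RANGES[name]))
        elif spec.background != "full":
            raise ValueError(f"unknown background mode: {spec.background!r}")
        maps[name] = fieldmap
    return DecideParams(**maps), mask


def simulate_series(
    params: DecideParams,
    mask: np.ndarray,
    protocol: AcquisitionProtocol,
    constants: ModelConstants,
    *,
    snr: float = np.inf,
    noise_model: str = "gaussian",
    seed: int = 0,
    spacing: tuple[float, float, float] = (2.5, 2.5, 3.0),
) -> SignalSeries:
    """Forward-model series with seeded noise of SD = mean-S0-over-mask / SNR.

    ``noise_model`` is ``"gaussian"`` (matching the fitting likelihood) or
    ``"rician"`` (magnitude data: |signal + complex Gaussian|, so background
    magnitudes are Rayleigh-distributed with the same sigma).
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape

    clean = np.zeros(shape + (protocol.n,), dtype=float)
    masked = DecideParams(
        **{
            k: np.broadcast_to(np.asarray(getattr(params, k), float), shape)[mask]
            for k in ("s0", "f", "d", "d_star", "t2fb", "v")
        }
    )
    clean[mask] = decide_signal(masked, constants, protocol)

    if np.isinf(snr):
        return SignalSeries(clean, spacing=spacing)

    rng = np.random.default_rng(seed)
    sigma = float(np.mean(np.broadcast_to(np.asarray(params.s0, float), shape)[mask])) / snr
    if noise_model == "gaussian":
        noisy = clean + sigma * rng.standard_normal(clean.shape)
    elif noise_model == "rician":
        real = clean + sigma * rng.standard_normal(clean.shape)
        imag = sigma * rng.standard_normal(clean.shape)
        noisy = np.hypot(real, imag)
    else:
        raise ValueError(f"unknown noise model: {noise_model!r}")
    return SignalSeries(noisy, spacing=spacing)


def _random_smooth_field(
    shape: tuple[int, int, int],
    control_spacing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random cubic-B-spline displacement (voxels), unscaled, shape (..., 3)."""
    bx = bspline_basis_matrix(shape[0], control_spacing)
    by = bspline_basis_matrix(shape[1], control_spacing)
    bz = bspline_basis_matrix(shape[2], control_spacing)
    coef = rng.standard_normal((bx.shape[1], by.shape[1], bz.shape[1], 3))
    out = np.tensordot(bx, coef, axes=(1, 0))
    out = np.tensordot(by, out, axes=(1, 1)).transpose(1, 0, 2, 3)
    out = np.tensordot(bz, out, axes=(1, 2)).transpose(1, 2, 0, 3)
    return out


def simulate_motion(
    series: SignalSeries,
    mask: np.ndarray,
    *,
    mean_disp: tuple[float, float, float] = (2.11, 2.54, 1.56),
    control_spacing: float = 8.0,
    temporal_corr: float = 0.0,
    seed: int = 0,
) -> tuple[SignalSeries, list[DisplacementField]]:
    """Deform every volume by a smooth random field of known average magnitude.

    Each volume gets an independent (optionally AR(1)-correlated, to mimic
    breathing) B-spline displacement field whose mask-average absolute
    component is scaled exactly to ``mean_disp`` per axis, in millimetres.
    Returns the deformed series and the ground-truth fields.
    """
    mean_disp = tuple(float(x) for x in mean_disp)
    if any(x < 0 for x in mean_disp):
        raise ValueError("mean_disp must be >= 0 per axis")
    if not 0 <= temporal_corr < 1:
        raise ValueError("temporal_corr must lie in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)

    fields: list[DisplacementField] = []
    deformed = np.empty_like(series.data)
    raw_prev: np.ndarray | None = None
    for i in range(series.n_volumes):
        raw = _random_smooth_field(series.spatial_shape, control_spacing, rng)
        if temporal_corr and raw_prev is not None:
            raw = temporal_corr * raw_prev + np.sqrt(1 - temporal_corr**2) * raw
        raw_prev = raw
        u = np.zeros_like(raw)
        for ax in range(3):
            target = mean_disp[ax]
            if target == 0:
                continue
            mean_abs = float(np.mean(np.abs(raw[mask][:, ax])))
            if mean_abs > 0:
                u[..., ax] = raw[..., ax] * (target / mean_abs)
        field = DisplacementField(u, spacing=series.spacing)
        fields.append(field)
        if all(x == 0 for x in mean_disp):
            deformed[..., i] = series.volume(i)
        else:
            deformed[..., i] = warp_volume(series.volume(i), field)
    return series.with_data(deformed), fields
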