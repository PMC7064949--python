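"""Fast linearized model fitting used to synthesize registration targets.

With d* and the fetal-blood relaxation rate held at literature values the
model becomes linear in the three amplitudes

    S = lam1 * exp(-b*d_star - TE*r2fb)
      + lam2 * exp(-b*d - TE*r2mb)
      + lam3 * exp(-b*d - TE*r2t)

which is solved per voxel by (nonnegative) linear least squares. The tissue
diffusivity d still enters the design matrix nonlinearly, so it is handled by
a 1-D variable-projection grid search: solve the linear problem on a small
log-spaced grid of candidate d values and keep the minimum-residual solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .model import DecideParams, ModelConstants, physio_from_lambda, decide_signal
from .protocol import AcquisitionProtocol
from .series import SignalSeries

__all__ = [
    "DesignMatrix",
    "default_d_grid",
    "build_design_matrix",
    "lls_fit_voxel",
    "lls_fit_volume",
    "synthesize_targets",
    "LinearFitResult",
]


def default_d_grid(n: int = 15, lo: float = 0.0005, hi: float = 0.004) -> np.ndarray:
    """Log-spaced candidate tissue diffusivities for the grid search (mm^2/s)."""
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class DesignMatrix:
    """n x 3 matrix of exponential basis terms and the constants it was built with."""

    a: np.ndarray
    d: float
    constants: ModelConstants

    def __post_init__(self) -> None:
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise ValueError("design matrix must be n x 3")


def build_design_matrix(
    protocol: AcquisitionProtocol, d: float, constants: ModelConstants
) -> DesignMatrix:
    """Exponential basis columns for the linearized model at tissue diffusivity d."""
    if d <= 0:
        raise ValueError("d must be > 0")
    b = protocol.b
    te = protocol.te
    a = np.column_stack(
        [
            np.exp(-b * constants.d_star_fixed - te * constants.r2fb_fixed),
            np.exp(-b * d - te * constants.r2mb),
            np.exp(-b * d - te * constants.r2t),
        ]
    )
    return DesignMatrix(a=a, d=float(d), constants=constants)


def lls_fit_voxel(
    signal: np.ndarray, design: DesignMatrix, *, nonneg: bool = True
) -> tuple[np.ndarray, float]:
    """Solve min ||S - A*lam|| for one voxel.

    Returns (lam, residual_norm). With ``nonneg`` (default) the amplitudes are
    constrained to lam >= 0; otherwise a plain least-squares solve is clipped
    at zero. Rank-deficient designs yield lam = 0 with the full signal norm as
    residual.
    """
    signal = np.asarray(signal, dtype=float)
    a = design.a
    if signal.shape != (a.shape[0],):
        raise ValueError("signal length must match design rows")
    if np.linalg.matrix_rank(a) < 3:
        return np.zeros(3), float(np.linalg.norm(signal))
    if nonneg:
        lam, res = nnls(a, signal)
        return lam, float(res)
    lam, *_ = np.linalg.lstsq(a, signal, rcond=None)
    lam = np.clip(lam, 0.0, None)
    return lam, float(np.linalg.norm(signal - a @ lam))


@dataclass
class LinearFitResult:
    """Voxelwise maps from the linearized fit (zero outside the mask)."""

    s0: np.ndarray
    f: np.ndarray
    v: np.ndarray
    d: np.ndarray
    residual: np.ndarray
    degenerate: np.ndarray  # voxels where lam2+lam3 = 0 and v was set to 0.5

    def as_params(self, constants: ModelConstants) -> DecideParams:
        """Parameter maps with d* and T2fb at the fixed linearization values."""
        return DecideParams(
            s0=self.s0,
            f=self.f,
            d=self.d,
            d_star=np.full_like(self.d, constants.d_star_fixed),
            t2fb=np.full_like(self.d, constants.t2fb_fixed),
            v=self.v,
        )


def _batched_lstsq(a: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """Unconstrained least squares for many voxels at once: (M, 3) solutions."""
    pinv = np.linalg.pinv(a)
    return signals @ pinv.T


def lls_fit_volume(
    series: SignalSeries,
    mask: np.ndarray,
    constants: ModelConstants,
    protocol: AcquisitionProtocol,
    d_grid: np.ndarray | None = None,
    *,
    nonneg: bool = True,
) -> LinearFitResult:
    """Variable-projection linearized fit of every mask voxel.

    For each candidate d the linear system is solved for all voxels in a
    single batched unconstrained solve; voxels with negative amplitudes are
    re-solved with the nonnegative solver (unless ``nonneg`` is off, in which
    case they are clipped). Per voxel the candidate minimizing the residual
    norm is kept.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValueError("mask shape must match the series spatial grid")
    if not mask.any():
        raise ValueError("mask is empty")
    if d_grid is None:
        d_grid = default_d_grid()
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.size == 0:
        raise ValueError("d_grid must be nonempty")

    signals = series.data[mask]  # (M, n)
    m = signals.shape[0]
    best_res = np.full(m, np.inf)
    best_lam = np.zeros((m, 3))
    best_d = np.full(m, d_grid[0])

    for d in d_grid:
        design = build_design_matrix(protocol, d, constants)
        lam = _batched_lstsq(design.a, signals)
        neg = np.any(lam < 0, axis=1)
        if neg.any():
            if nonneg:
                for idx in np.flatnonzero(neg):
                    lam[idx], _ = nnls(design.a, signals[idx])
            else:
                lam = np.clip(lam, 0.0, None)
        res = np.linalg.norm(signals - lam @ design.a.T, axis=1)
        better = res < best_res
        best_res[better] = res[better]
        best_lam[better] = lam[better]
        best_d[better] = d

    lam_sum = best_lam.sum(axis=1)
    slow_sum = best_lam[:, 1] + best_lam[:, 2]
    degen = (lam_sum <= 0) | (slow_sum <= 0)

    s0 = np.where(lam_sum > 0, lam_sum, 0.0)
    f = np.divide(best_lam[:, 0], lam_sum, out=np.zeros(m), where=lam_sum > 0)
    v = np.divide(best_lam[:, 1], slow_sum, out=np.full(m, 0.5), where=slow_sum > 0)

    def _to_map(values: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape, dtype=float)
        out[mask] = values
        return out

    return LinearFitResult(
        s0=_to_map(s0),
        f=_to_map(f),
        v=_to_map(v),
        d=_to_map(best_d),
        residual=_to_map(best_res),
        degenerate=_to_map(degen.astype(float)).astype(bool),
    )


def synthesize_targets(
    fit: LinearFitResult | DecideParams,
    mask: np.ndarray,
    constants: ModelConstants,
    protocol: AcquisitionProtocol,
    *,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
    background: str = "zero",
    reference: SignalSeries | None = None,
) -> SignalSeries:
    """Noise-free model series evaluated voxelwise from fitted parameter maps.

    Volume i of the result is the forward model at protocol entry i. Outside
    the mask, voxels are zero (``background="zero"``) or copied from
    ``reference`` (``background="reference"``).
    """
    mask = np.asarray(mask, dtype=bool)
    params = fit.as_params(constants) if isinstance(fit, LinearFitResult) else fit

    def _masked(value: float | np.ndarray) -> np.ndarray:
        return np.broadcast_to(np.asarray(value, dtype=float), mask.shape)[mask]

    masked = DecideParams(
        s0=_masked(params.s0),
        f=_masked(params.f),
        d=_masked(params.d),
        d_star=_masked(params.d_star),
        t2fb=_masked(params.t2fb),
        v=_masked(params.v),
    )
    data = np.zeros(mask.shape + (protocol.n,), dtype=float)
    data[mask] = decide_signal(masked, constants, protocol)
    if background == "reference":
        if reference is None:
            raise ValueError("background='reference' requires a reference series")
        data[~mask] = reference.data[~mask]
    elif background != "zero":
        raise ValueError(f"unknown background mode: {background!r}")
    return SignalSeries(data, spacing=spacing, affine=affine)
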