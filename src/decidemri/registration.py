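"""Pairwise deformable registration behind a pluggable backend contract.

The default backend is a multi-resolution cubic B-spline free-form
deformation (FFD): a dense displacement field is parameterized by a coarse
control-point lattice, optimized with L-BFGS against a sum-of-squared-
differences metric plus a bending-energy penalty on the lattice. SSD is
appropriate here because in model-driven registration the moving volume and
its synthetic target share the same intensity scale by construction.

Displacement fields map moving -> target space in pull-back form: the warped
image samples the moving image at x + u(x). Fields are stored in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .series import SignalSeries

__all__ = [
    "DisplacementField",
    "RegistrationConfig",
    "register_pair",
    "warp_volume",
    "compose_fields",
    "bspline_basis_matrix",
    "BSplineFFDBackend",
    "REGISTRATION_BACKENDS",
]


@dataclass
class DisplacementField:
    """Dense per-voxel displacement, millimetres, shape (nx, ny, nz, 3)."""

    u: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]  # type: ignore[return-value]

    def in_voxels(self) -> np.ndarray:
        return self.u / np.asarray(self.spacing)

    @classmethod
    def zero(
        cls, shape: tuple[int, int, int], spacing: tuple[float, float, float] = (1, 1, 1)
    ) -> "DisplacementField":
        return cls(np.zeros((*shape, 3)), spacing=spacing)

    @classmethod
    def from_voxels(
        cls, u_vox: np.ndarray, spacing: tuple[float, float, float]
    ) -> "DisplacementField":
        return cls(u_vox * np.asarray(spacing), spacing=spacing)


@dataclass
class RegistrationConfig:
    """Settings for the FFD backend.

    control_spacings : B-spline lattice spacings in voxels, coarse to fine;
        each :func:`register_pair` call runs this schedule in order.
    """

    control_spacings: tuple[float, ...] = (10.0, 5.0, 2.5)
    similarity: str = "ssd"
    reg_weight: float = 0.01
    max_iter: int = 60

    def __post_init__(self) -> None:
        if len(self.control_spacings) == 0 or any(s <= 0 for s in self.control_spacings):
            raise ValueError("control_spacings must be positive")
        if self.similarity != "ssd":
            raise ValueError("only the 'ssd' similarity is implemented")


# cubic B-spline blending weights on t in [0, 1)
def _bspline_weights(t: np.ndarray) -> np.ndarray:
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


def bspline_basis_matrix(n: int, spacing: float) -> np.ndarray:
    """Dense (n, K) cubic B-spline basis: rows sum to 1 (partition of unity)."""
    x = np.arange(n, dtype=float)
    s = x / spacing
    i0 = np.floor(s).astype(int)
    w = _bspline_weights(s - i0)  # (n, 4)
    k_max = int(np.floor((n - 1) / spacing)) + 4
    basis = np.zeros((n, k_max))
    for m in range(4):
        basis[np.arange(n), i0 + m] = w[:, m]
    return basis


def _upsample(coef: np.ndarray, bx, by, bz) -> np.ndarray:
    """Lattice coefficients (Kx, Ky, Kz, 3) -> dense field (nx, ny, nz, 3)."""
    out = np.tensordot(bx, coef, axes=(1, 0))
    out = np.tensordot(by, out, axes=(1, 1)).transpose(1, 0, 2, 3)
    out = np.tensordot(bz, out, axes=(1, 2)).transpose(1, 2, 0, 3)
    return out


def _downsample_adjoint(vox: np.ndarray, bx, by, bz) -> np.ndarray:
    """Adjoint of :func:`_upsample` applied to a dense (nx, ny, nz, 3) array."""
    out = np.tensordot(bx.T, vox, axes=(1, 0))
    out = np.tensordot(by.T, out, axes=(1, 1)).transpose(1, 0, 2, 3)
    out = np.tensordot(bz.T, out, axes=(1, 2)).transpose(1, 2, 0, 3)
    return out


def _bending(coef: np.ndarray) -> tuple[float, np.ndarray]:
    """Squared second differences of the lattice along each axis + gradient."""
    energy = 0.0
    grad = np.zeros_like(coef)
    for ax in range(3):
        d2 = np.diff(coef, n=2, axis=ax)
        energy += float(np.sum(d2 * d2))
        # adjoint of the second-difference operator
        pad = [(0, 0)] * coef.ndim
        pad[ax] = (2, 2)
        d2p = np.pad(d2, pad)
        sl = [slice(None)] * coef.ndim
        out = np.zeros_like(coef)
        for offset, w in ((0, 1.0), (1, -2.0), (2, 1.0)):
            sl[ax] = slice(2 - offset, 2 - offset + coef.shape[ax])
            out += w * d2p[tuple(sl)]
        grad += 2.0 * out
    return energy, grad


def warp_volume(
    volume: np.ndarray,
    field: DisplacementField,
    *,
    order: int = 3,
) -> np.ndarray:
    """Resample ``volume`` at x + u(x); edge values extend beyond the grid."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != field.spatial_shape:
        raise ValueError("volume and field grids must match")
    u_vox = field.in_voxels()
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in volume.shape], indexing="ij")
    coords = [grid[c] + u_vox[..., c] for c in range(3)]
    return map_coordinates(volume, coords, order=order, mode="nearest")


class BSplineFFDBackend:
    """Multi-resolution FFD registration with SSD + bending energy."""

    def __init__(self, config: RegistrationConfig | None = None) -> None:
        self.config = config or RegistrationConfig()

    def register(
        self,
        moving: np.ndarray,
        target: np.ndarray,
        spacing: tuple[float, float, float],
        *,
        control_spacings: tuple[float, ...] | None = None,
    ) -> DisplacementField:
        from scipy.optimize import minimize

        moving = np.asarray(moving, dtype=float)
        target = np.asarray(target, dtype=float)
        shape = moving.shape
        grid = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        grads = np.gradient(moving)
        scale = float(np.mean(target**2)) + 1e-30
        n_vox = moving.size

        u_total = np.zeros((*shape, 3))
        spacings = control_spacings or self.config.control_spacings
        for sp in spacings:
            bx = bspline_basis_matrix(shape[0], sp)
            by = bspline_basis_matrix(shape[1], sp)
            bz = bspline_basis_matrix(shape[2], sp)
            k_shape = (bx.shape[1], by.shape[1], bz.shape[1], 3)
            n_ctrl = int(np.prod(k_shape))

            def objective(flat: np.ndarray) -> tuple[float, np.ndarray]:
                coef = flat.reshape(k_shape)
                u = u_total + _upsample(coef, bx, by, bz)
                coords = [grid[c] + u[..., c] for c in range(3)]
                warped = map_coordinates(moving, coords, order=1, mode="nearest")
                r = warped - target
                ssd = float(np.sum(r * r)) / (n_vox * scale)
                dvox = np.stack(
                    [map_coordinates(g, coords, order=1, mode="nearest") for g in grads],
                    axis=-1,
                )
                dssd = 2.0 * r[..., None] * dvox / (n_vox * scale)
                grad = _downsample_adjoint(dssd, bx, by, bz)
                bend, bend_grad = _bending(coef)
                w = self.config.reg_weight / n_ctrl
                return ssd + w * bend, (grad + w * bend_grad).ravel()

            res = minimize(
                objective,
                np.zeros(n_ctrl),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.config.max_iter, "ftol": 1e-10, "gtol": 1e-8},
            )
            u_total = u_total + _upsample(res.x.reshape(k_shape), bx, by, bz)

        return DisplacementField.from_voxels(u_total, spacing)


REGISTRATION_BACKENDS: dict[str, type] = {"ffd": BSplineFFDBackend}


def register_pair(
    moving: np.ndarray,
    target: np.ndarray,
    config: RegistrationConfig | None = None,
    *,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    backend: str = "ffd",
    control_spacings: tuple[float, ...] | None = None,
) -> tuple[DisplacementField, np.ndarray]:
    """Register ``moving`` to ``target``; returns (field, warped moving).

    Contract: the warped volume's SSD against the target never exceeds the
    unwarped moving volume's. If the backend fails to improve, the identity
    field is returned with a warning.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError("moving and target must share one grid")
    config = config or RegistrationConfig()
    try:
        backend_cls = REGISTRATION_BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown registration backend: {backend!r}") from None

    try:
        field = backend_cls(config).register(
            moving, target, spacing, control_spacings=control_spacings
        )
        warped = warp_volume(moving, field)
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"registration backend failed ({exc}); returning identity field")
        field = DisplacementField.zero(moving.shape, spacing)
        return field, moving.copy()

    before = float(np.sum((moving - target) ** 2))
    after = float(np.sum((warped - target) ** 2))
    if after > before:
        warnings.warn("registration did not improve similarity; returning identity field")
        field = DisplacementField.zero(moving.shape, spacing)
        return field, moving.copy()
    return field, warped


def compose_fields(
    old: DisplacementField, new: DisplacementField
) -> DisplacementField:
    """Compose so that warping by the result equals warping by ``old`` then ``new``.

    In pull-back form: if W1 = orig(x + u_old(x)) and W2 = W1(x + u_new(x)),
    then W2 = orig(x + u_new(x) + u_old(x + u_new(x))).
    """
    if old.spatial_shape != new.spatial_shape:
        raise ValueError("fields must share one grid")
    new_vox = new.in_voxels()
    grid = np.meshgrid(
        *[np.arange(n, dtype=float) for n in old.spatial_shape], indexing="ij"
    )
    coords = [grid[c] + new_vox[..., c] for c in range(3)]
    moved_old = np.stack(
        [map_coordinates(old.u[..., c], coords, order=1, mode="nearest") for c in range(3)],
        axis=-1,
    )
    return DisplacementField(new.u + moved_old, spacing=old.spacing)
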