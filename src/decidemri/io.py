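"""NIfTI / CSV / JSON input-output.

All volumes travel as NIfTI-1; maps are written float32 with the source
affine preserved and a JSON sidecar recording units and provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .protocol import AcquisitionProtocol
from .series import SignalSeries

__all__ = [
    "read_series",
    "read_mask",
    "write_series",
    "write_maps",
    "write_field",
    "write_json",
]

log = logging.getLogger("decidemri")

#: units written to the parameter-map sidecar
_UNITS = {
    "s0": "arbitrary",
    "f": "fraction",
    "d": "mm^2/s",
    "d_star": "mm^2/s",
    "t2fb": "ms",
    "v": "fraction",
    "fo2": "fraction",
    "residual": "signal",
}


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_series(
    path: str | Path, protocol_path: str | Path
) -> tuple[SignalSeries, AcquisitionProtocol]:
    """Load a 4D NIfTI series and its protocol table, validating the pairing."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D series, got {data.ndim}D in {path}")
    protocol = AcquisitionProtocol.from_csv(protocol_path)
    if data.shape[3] != protocol.n:
        raise ValueError(
            f"series has {data.shape[3]} volumes but protocol lists {protocol.n} entries"
        )
    log.info("loaded series %s with shape %s", path, data.shape)
    return (
        SignalSeries(data, spacing=_spacing_from(img), affine=np.asarray(img.affine)),
        protocol,
    )


def read_mask(path: str | Path, series: SignalSeries | None = None) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asanyarray(img.dataobj) > 0
    if mask.ndim != 3:
        raise ValueError(f"expected 3D mask, got {mask.ndim}D in {path}")
    if series is not None and mask.shape != series.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match series grid {series.spatial_shape}"
        )
    return mask


def write_series(series: SignalSeries, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(series.data.astype(np.float32), series.affine), str(path))


def write_field(u_mm: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Store a displacement field (mm) as a 4D vector NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(u_mm, dtype=np.float32), affine), str(path))


def write_maps(
    maps: Mapping[str, np.ndarray],
    out_dir: str | Path,
    *,
    affine: np.ndarray | None = None,
    provenance: Mapping | None = None,
    prefix: str = "",
) -> list[Path]:
    """Write one float32 NIfTI per parameter map plus a JSON sidecar.

    All maps must share a grid; the source affine is preserved bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shapes = {np.asarray(v).shape for v in maps.values()}
    if len(shapes) > 1:
        raise ValueError(f"maps must share a grid, got shapes {shapes}")
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    written: list[Path] = []
    for name, arr in maps.items():
        path = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))
        written.append(path)

    sidecar = {
        "maps": {name: {"units": _UNITS.get(name, "unknown")} for name in maps},
        "provenance": dict(provenance or {}),
    }
    sidecar_path = out_dir / f"{prefix}maps.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=_json_default))
    written.append(sidecar_path)
    return written


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def provenance_record(config: Mapping | None = None, seed: int | None = None) -> dict:
    """Provenance block embedded in every CLI output (required to reproduce
    stochastic results)."""
    from . import __version__

    cfg = dict(config or {})
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=_json_default).encode()
    ).hexdigest()[:12]
    return {"version": __version__, "seed": seed, "config": cfg, "config_hash": cfg_hash}
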