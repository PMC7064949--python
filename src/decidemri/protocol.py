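"""Acquisition protocols: ordered (b-value, echo-time) pairs indexing a 4D series.

Units are fixed package-wide: b in s/mm^2, TE in ms. The protocol order is the
order of volumes along the 4th axis of every signal series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionProtocol",
    "build_protocol",
    "DEFAULT_B_VALUES",
    "DEFAULT_ECHO_TIMES",
]

#: The seven diffusion weightings of the default placental protocol (s/mm^2).
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 400.0, 600.0)

#: The ten echo times of the default placental protocol (ms).
DEFAULT_ECHO_TIMES = (81.0, 90.0, 96.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0)

#: TE used for the pure-diffusion arm of the default protocol (ms).
_DIFFUSION_TE = 96.0

#: The two shells sampled jointly in b and TE, and their echo times.
_JOINT_B = (50.0, 200.0)
_JOINT_TE = (81.0, 96.0, 120.0, 150.0, 180.0, 210.0, 240.0)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Ordered list of (b, TE) measurement settings.

    Parameters
    ----------
    b : array of diffusion weightings, s/mm^2, all >= 0.
    te : array of echo times, ms, all > 0.
    """

    b: np.ndarray
    te: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        te = np.atleast_1d(np.asarray(self.te, dtype=float))
        if b.size == 0:
            raise ValueError("protocol must contain at least one entry")
        if b.shape != te.shape or b.ndim != 1:
            raise ValueError("b and te must be 1-D arrays of equal length")
        if np.any(b < 0):
            raise ValueError("all b-values must be >= 0")
        if np.any(te <= 0):
            raise ValueError("all echo times must be > 0")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "te", te)

    @property
    def n(self) -> int:
        """Number of measurements (volumes in the 4D series)."""
        return int(self.b.size)

    @property
    def entries(self) -> list[tuple[float, float]]:
        return list(zip(self.b.tolist(), self.te.tolist()))

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[float, float]]) -> "AcquisitionProtocol":
        entries = list(entries)
        if not entries:
            raise ValueError("protocol must contain at least one entry")
        b, te = zip(*entries)
        return cls(np.asarray(b, dtype=float), np.asarray(te, dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AcquisitionProtocol":
        """Read a protocol table with columns ``index,b_s_per_mm2,te_ms``."""
        df = pd.read_csv(path)
        required = {"index", "b_s_per_mm2", "te_ms"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"protocol CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        df = df.sort_values("index")
        return cls(df["b_s_per_mm2"].to_numpy(float), df["te_ms"].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "index": np.arange(self.n),
                "b_s_per_mm2": self.b,
                "te_ms": self.te,
            }
        ).to_csv(path, index=False)

    def __len__(self) -> int:
        return self.n


def _default_entries() -> list[tuple[float, float]]:
    entries: list[tuple[float, float]] = []
    # relaxometry arm: all echo times at b = 0
    entries += [(0.0, te) for te in DEFAULT_ECHO_TIMES]
    # diffusion arm: all b-values at TE = 96 ms
    entries += [(b, _DIFFUSION_TE) for b in DEFAULT_B_VALUES]
    # joint arm: two intermediate shells across seven echo times
    entries += [(b, te) for b in _JOINT_B for te in _JOINT_TE]
    return entries


def build_protocol(
    spec: str | Sequence[tuple[float, float]] = "decide_default",
    *,
    dedup: bool = False,
    repeats: Sequence[tuple[float, float]] | None = None,
) -> AcquisitionProtocol:
    """Build an acquisition protocol from a preset name or an explicit list.

    Parameters
    ----------
    spec : ``"decide_default"`` or an explicit list of (b, te) tuples.
    dedup : drop duplicate (b, te) pairs (the default preset's three arms
        overlap at (0, 96), (50, 96) and (200, 96); deduplication yields 28
        unique settings, otherwise 31). Repeated settings are genuine
        acquisitions, so the default keeps them.
    repeats : extra (b, te) pairs appended after the preset, e.g. to declare
        the repeated volumes of a longer clinical series.

    Returns
    -------
    AcquisitionProtocol with deterministic ordering (b-major, then TE, for the
    deduplicated preset; acquisition-arm order otherwise).
    """
    if isinstance(spec, str):
        if spec != "decide_default":
            raise ValueError(f"unknown protocol preset: {spec!r}")
        entries = _default_entries()
        if dedup:
            unique = sorted(set(entries))
            entries = unique
    else:
        entries = list(spec)
        if not entries:
            raise ValueError("explicit protocol list must be nonempty")
        if dedup:
            entries = sorted(set(entries))
    if repeats:
        entries = entries + list(repeats)
    return AcquisitionProtocol.from_entries(entries)
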