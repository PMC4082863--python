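"""Core volume data model, index conventions, and boundary padding.

A :class:`Volume` is a thin validated wrapper around a 3D NumPy array of real
intensities.  Conventions used throughout the package:

* axes are ``(x, y, z)``; the **third** axis (``z``) is the slice axis along
  which large volumes are split into chunks;
* indexing is 0-based and slab ranges are half-open ``[z0, z1)``;
* filtering pads the volume by ``search_radius + sim_radius`` so that every
  similarity box is always full-sized (reflect padding by default — mirrored
  without repeating the edge sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidPadError, InvalidRangeError

__all__ = ["Volume", "PadSpec", "pad_volume", "crop_volume", "stack_volumes"]

_ALLOWED_DTYPES = (np.float32, np.float64)

#: np.pad mode name per supported boundary mode
_PAD_MODES = {"reflect": "reflect", "edge": "edge", "zero": "constant"}


@dataclass(frozen=True, eq=False)
class Volume:
    """A 3D scalar intensity grid.

    Parameters
    ----------
    data
        3D array of finite real intensities, float32 or float64.  Integer
        input is converted to float64; NaN/Inf raise ``ValueError``.
    """

    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={arr.ndim}")
        if min(arr.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got shape {arr.shape}")
        if arr.dtype not in _ALLOWED_DTYPES:
            arr = arr.astype(np.float64)
        if not np.isfinite(arr).all():
            raise ValueError("volume intensities must be finite (no NaN/Inf)")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype

    def astype(self, dtype) -> "Volume":
        return Volume(self.data.astype(dtype))

    def allclose(self, other: "Volume", rtol: float = 1e-10, atol: float = 0.0) -> bool:
        return self.shape == other.shape and np.allclose(
            self.data, other.data, rtol=rtol, atol=atol
        )


@dataclass(frozen=True)
class PadSpec:
    """Boundary padding: ``mode`` in {reflect, edge, zero}, per-axis margins.

    For filtering with search radius ``M`` and similarity radius ``d`` the
    margin must be at least ``M + d`` on every axis so each voxel's search box
    and every member's similarity box stay inside the padded grid.
    """

    mode: str = "reflect"
    margin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.mode not in _PAD_MODES:
            raise InvalidPadError(
                f"pad mode must be one of {sorted(_PAD_MODES)}, got {self.mode!r}"
            )
        m = tuple(int(v) for v in self.margin)
        if len(m) != 3 or any(v < 0 for v in m):
            raise InvalidPadError(f"margins must be 3 nonnegative ints, got {self.margin}")
        object.__setattr__(self, "margin", m)

    @classmethod
    def for_filter(cls, search_radius: int, sim_radius: int, mode: str = "reflect") -> "PadSpec":
        m = int(search_radius) + int(sim_radius)
        return cls(mode=mode, margin=(m, m, m))


def pad_volume(vol: Volume, spec: PadSpec) -> Volume:
    """Pad a volume on all sides according to ``spec``.

    Reflect mode mirrors without repeating the edge sample, e.g. the row
    ``[1, 2, 3]`` with margin 1 becomes ``[2, 1, 2, 3, 2]``.  Reflecting an
    axis of extent 1 is impossible and raises :class:`InvalidPadError`.
    """
    m = spec.margin
    if all(v == 0 for v in m):
        return Volume(vol.data.copy())
    if spec.mode == "reflect":
        for ax in range(3):
            if m[ax] > 0 and vol.shape[ax] < 2:
                raise InvalidPadError(
                    f"reflect padding needs extent >= 2 on axis {ax}, "
                    f"got extent {vol.shape[ax]}"
                )
    widths = tuple((v, v) for v in m)
    if spec.mode == "zero":
        padded = np.pad(vol.data, widths, mode="constant", constant_values=0)
    else:
        padded = np.pad(vol.data, widths, mode=_PAD_MODES[spec.mode])
    return Volume(padded)


def crop_volume(vol: Volume, z0: int, z1: int) -> Volume:
    """Extract the half-open slab ``[z0, z1)`` along the z (third) axis."""
    L3 = vol.shape[2]
    if not (0 <= z0 < z1 <= L3):
        raise InvalidRangeError(
            f"slab [{z0}, {z1}) is empty or outside [0, {L3})"
        )
    return Volume(vol.data[:, :, z0:z1].copy())


def stack_volumes(slabs: list[Volume]) -> Volume:
    """Concatenate slabs along z (inverse of cropping a partition)."""
    if not slabs:
        raise InvalidRangeError("cannot stack an empty list of slabs")
    return Volume(np.concatenate([s.data for s in slabs], axis=2))
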