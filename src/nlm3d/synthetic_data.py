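"""Synthetic MRI-like phantoms and calibrated noise.

Every generated noisy volume is paired with its clean source, so error to
ground truth is always computable without downloading reference data.  The
default "brain-like" preset is a set of nested ellipsoids with three tissue
intensities on a 0-255 scale over a 64 x 64 x 48 grid — a piecewise-constant
stand-in for a T1 brain volume, with flat regions large enough for flatness
and residual statistics.

Noise models:

* ``gaussian`` — additive white Gaussian noise of standard deviation sigma;
* ``rician`` — the magnitude-MRI model ``sqrt((clean + e1)^2 + e2^2)`` with
  e1, e2 independent N(0, sigma^2); on zero signal this is a Rayleigh
  distribution with mean ``sigma * sqrt(pi / 2)``.

All randomness flows through ``numpy.random.default_rng(seed)`` (the PCG64
generator), so outputs are platform-stable and bit-reproducible per seed.
Noise is applied in float64 and never clipped to a display range, which
would bias residual statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidNoiseError, InvalidSpecError
from .volumes import Volume

__all__ = [
    "Primitive",
    "PhantomSpec",
    "NoiseModel",
    "render_phantom",
    "add_noise",
    "random_volume",
    "brain_phantom_spec",
]


@dataclass(frozen=True)
class Primitive:
    """One piecewise-constant primitive: axis-aligned ellipsoid or cuboid.

    ``half_extents`` are the ellipsoid semi-axes or the cuboid half edge
    lengths; a voxel belongs to the primitive if its integer center does.
    """

    kind: str  # "ellipsoid" | "cuboid"
    center: tuple[float, float, float]
    half_extents: tuple[float, float, float]
    intensity: float

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "cuboid"):
            raise InvalidSpecError(f"unknown primitive kind {self.kind!r}")
        if min(self.half_extents) <= 0:
            raise InvalidSpecError(f"half extents must be positive, got {self.half_extents}")


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise-constant phantom: background plus ordered primitives
    (later primitives overwrite earlier ones)."""

    shape: tuple[int, int, int]
    primitives: tuple[Primitive, ...] = ()
    background: float = 0.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise InvalidSpecError(f"shape must be 3 positive ints, got {self.shape}")


def render_phantom(spec: PhantomSpec) -> Volume:
    """Render the phantom deterministically (voxel-center membership)."""
    shape = spec.shape
    out = np.full(shape, float(spec.background), dtype=np.float64)
    ix, iy, iz = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    for p in spec.primitives:
        dx = ix - p.center[0]
        dy = iy - p.center[1]
        dz = iz - p.center[2]
        hx, hy, hz = p.half_extents
        if p.kind == "ellipsoid":
            mask = (dx / hx) ** 2 + (dy / hy) ** 2 + (dz / hz) ** 2 <= 1.0
        else:
            mask = (np.abs(dx) <= hx) & (np.abs(dy) <= hy) & (np.abs(dz) <= hz)
        out[mask] = float(p.intensity)
    return Volume(out)


def brain_phantom_spec(shape: tuple[int, int, int] = (64, 64, 48)) -> PhantomSpec:
    """Default brain-like preset: nested ellipsoids, 3 tissue intensities.

    Intensities sit on a 0-255 scale: 60 (CSF-like rim), 120 (grey-like
    shell), 200 (white-like core), over a zero background.
    """
    cx, cy, cz = (s / 2.0 - 0.5 for s in shape)
    sx, sy, sz = (s / 2.0 for s in shape)
    return PhantomSpec(
        shape=shape,
        primitives=(
            Primitive("ellipsoid", (cx, cy, cz), (0.92 * sx, 0.92 * sy, 0.92 * sz), 60.0),
            Primitive("ellipsoid", (cx, cy, cz), (0.75 * sx, 0.75 * sy, 0.75 * sz), 120.0),
            Primitive("ellipsoid", (cx, cy, cz), (0.45 * sx, 0.45 * sy, 0.45 * sz), 200.0),
        ),
        background=0.0,
    )


@dataclass(frozen=True)
class NoiseModel:
    kind: str  # "gaussian" | "rician"
    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "rician"):
            raise InvalidNoiseError(f"noise kind must be gaussian or rician, got {self.kind!r}")
        if self.sigma <= 0:
            raise InvalidNoiseError(f"sigma must be positive, got {self.sigma}")


def add_noise(vol: Volume, model: NoiseModel) -> Volume:
    """Corrupt a clean volume; deterministic given the model's seed."""
    rng = np.random.default_rng(model.seed)
    clean = vol.data.astype(np.float64, copy=False)
    if model.kind == "gaussian":
        noisy = clean + rng.normal(0.0, model.sigma, size=clean.shape)
    else:
        e1 = rng.normal(0.0, model.sigma, size=clean.shape)
        e2 = rng.normal(0.0, model.sigma, size=clean.shape)
        noisy = np.sqrt((clean + e1) ** 2 + e2**2)
    return Volume(noisy)


def random_volume(shape: tuple[int, int, int], seed: int) -> Volume:
    """I.i.d. standard-normal volume (the classic synthetic benchmark input)."""
    if len(shape) != 3 or min(shape) < 1:
        raise InvalidSpecError(f"shape must be 3 positive ints, got {shape}")
    rng = np.random.default_rng(seed)
    return Volume(rng.standard_normal(shape))
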