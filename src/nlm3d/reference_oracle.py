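"""Literal reference implementations used as ground truth.

Two deliberately transparent filters live here:

* :func:`nlm_naive` — the serial nested-loop binary-cutoff NLM: three loops
  over voxels, three over search offsets, three over patch offsets, with no
  vectorisation or reordering.  It is the oracle against which the optimised
  filter in :mod:`nlm3d.nlm_core` is verified.  The loop nest is compiled
  with numba so the oracle stays usable on realistic test sizes; the code it
  compiles is the plain nested iteration, unchanged.

* :func:`nlm_gaussian` — the classic discrete NLM whose patch distance is
  weighted by a Gaussian kernel of width ``a``:

      d_a^2(x_i, x_j) = sum_k |X(x_i + dk) - X(x_j + dk)|^2 * G(dk),
      G(dk) = exp(-||dk||^2 / (2 a^2)) / ((2 pi)^{3/2} * a),

  with the (formally infinite) offset sum truncated to a finite cube.  This
  form documents the lineage of the binary-cutoff filter; it is pure Python,
  test-suite and documentation use only, and makes no performance claims.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import ceil, exp, pi

import numpy as np
from numba import njit

from .errors import InvalidStrengthError
from .nlm_core import NLMParams, _check_box
from .volumes import PadSpec, Volume, pad_volume

__all__ = [
    "GaussianKernelParams",
    "nlm_naive",
    "gaussian_patch_sqdist",
    "nlm_gaussian",
]


@dataclass(frozen=True)
class GaussianKernelParams:
    """Parameters of the classic Gaussian patch kernel.

    ``a`` is the Gaussian similarity radius, ``h`` the filter strength; the
    kernel normalisation uses the 3D exponent in ``(2 pi)^{3/2}``.
    """

    a: float
    h: float
    kernel_dim_exponent: int = 3

    def __post_init__(self) -> None:
        if self.a <= 0 or self.h <= 0:
            raise InvalidStrengthError(f"a and h must be positive (a={self.a}, h={self.h})")


@njit(cache=False)
def _naive_loops(P, L1, L2, L3, sr, dr, h2, include_self):  # pragma: no cover - jitted
    pad = sr + dr
    out = np.empty((L1, L2, L3), dtype=np.float64)
    for i1 in range(L1):
        for i2 in range(L2):
            for i3 in range(L3):
                num = 0.0
                den = 0.0
                for dx in range(-sr, sr + 1):
                    for dy in range(-sr, sr + 1):
                        for dz in range(-sr, sr + 1):
                            if (not include_self) and dx == 0 and dy == 0 and dz == 0:
                                continue
                            d = 0.0
                            for t1 in range(-dr, dr + 1):
                                for t2 in range(-dr, dr + 1):
                                    for t3 in range(-dr, dr + 1):
                                        a = P[pad + i1 + t1, pad + i2 + t2, pad + i3 + t3]
                                        b = P[
                                            pad + i1 + dx + t1,
                                            pad + i2 + dy + t2,
                                            pad + i3 + dz + t3,
                                        ]
                                        d += (a - b) * (a - b)
                            w = np.exp(-d / h2)
                            num += w * P[pad + i1 + dx, pad + i2 + dy, pad + i3 + dz]
                            den += w
                out[i1, i2, i3] = num / den
    return out


def nlm_naive(vol: Volume, params: NLMParams, pad_mode: str = "reflect") -> Volume:
    """Binary-cutoff NLM by explicit nested iteration (the ground truth).

    Same contract as :func:`nlm3d.nlm_core.denoise_volume`; the computation
    is the literal nine-deep loop nest over voxels, search offsets and patch
    offsets, accumulating in float64.
    """
    padded = pad_volume(
        vol, PadSpec.for_filter(params.search_radius, params.sim_radius, pad_mode)
    )
    P = padded.data.astype(np.float64, copy=False)
    L1, L2, L3 = vol.shape
    out = _naive_loops(
        P,
        L1,
        L2,
        L3,
        params.search_radius,
        params.sim_radius,
        params.h_squared,
        params.include_self,
    )
    return Volume(out.astype(vol.dtype, copy=False))


def _gauss_kernel_value(dk: tuple[int, int, int], a: float) -> float:
    n2 = dk[0] * dk[0] + dk[1] * dk[1] + dk[2] * dk[2]
    return exp(-n2 / (2.0 * a * a)) / ((2.0 * pi) ** 1.5 * a)


def gaussian_patch_sqdist(
    padded: Volume,
    center_i: tuple[int, int, int],
    center_j: tuple[int, int, int],
    kparams: GaussianKernelParams,
    patch_truncation_radius: int,
) -> float:
    """Gaussian-kernel patch distance, truncated to a finite offset cube."""
    if patch_truncation_radius < 1:
        raise InvalidStrengthError("truncation radius must be >= 1")
    _check_box(padded, center_i, patch_truncation_radius)
    _check_box(padded, center_j, patch_truncation_radius)
    P = padded.data
    r = patch_truncation_radius
    total = 0.0
    for dk in itertools.product(range(-r, r + 1), repeat=3):
        xi = float(P[center_i[0] + dk[0], center_i[1] + dk[1], center_i[2] + dk[2]])
        xj = float(P[center_j[0] + dk[0], center_j[1] + dk[1], center_j[2] + dk[2]])
        total += (xi - xj) ** 2 * _gauss_kernel_value(dk, kparams.a)
    return total


def nlm_gaussian(
    vol: Volume,
    search_edge: int,
    kparams: GaussianKernelParams,
    patch_truncation_radius: int | None = None,
    pad_mode: str = "reflect",
) -> Volume:
    """Classic discrete NLM with the Gaussian patch kernel.

    ``patch_truncation_radius`` bounds the offset sum; by default ``2 a``
    rounded up (the kernel mass beyond two standard deviations is
    negligible).  Flat volumes are fixed points and outputs are convex
    combinations of search-box intensities, as for the binary-cutoff filter.
    """
    if search_edge < 1 or search_edge % 2 == 0:
        raise InvalidStrengthError(f"search_edge must be odd positive, got {search_edge}")
    if patch_truncation_radius is None:
        patch_truncation_radius = max(1, ceil(2.0 * kparams.a))
    sr = (search_edge - 1) // 2
    padded = pad_volume(vol, PadSpec.for_filter(sr, patch_truncation_radius, pad_mode))
    P = padded.data
    pad = sr + patch_truncation_radius
    h2 = kparams.h**2
    L1, L2, L3 = vol.shape
    out = np.empty((L1, L2, L3), dtype=np.float64)
    for i1 in range(L1):
        for i2 in range(L2):
            for i3 in range(L3):
                ci = (pad + i1, pad + i2, pad + i3)
                num = 0.0
                den = 0.0
                for dj in itertools.product(range(-sr, sr + 1), repeat=3):
                    cj = (ci[0] + dj[0], ci[1] + dj[1], ci[2] + dj[2])
                    d2 = gaussian_patch_sqdist(
                        padded, ci, cj, kparams, patch_truncation_radius
                    )
                    w = exp(-d2 / h2)
                    num += w * float(P[cj])
                    den += w
                out[i1, i2, i3] = num / den
    return Volume(out.astype(vol.dtype, copy=False))
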