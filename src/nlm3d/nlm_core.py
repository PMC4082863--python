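"""The fully 3D Nonlocal Means filter.

Each voxel i is restored as a weighted mean over the voxels j of a cubic
*search box* V_i centred on i:

    Y_i = sum_{j in V_i} w(i, j) X_j / sum_{j in V_i} w(i, j)
    w(i, j) = exp( -|| B_j - B_i ||_2^2 / h^2 )

where B_j is the cubic *similarity box* (patch) around j, and the patch
distance is the raw, unnormalised sum of squared intensity differences over
aligned patch offsets — the classical Gaussian patch kernel is replaced by a
hard binary cut-off at the patch boundary.  The filter strength h can be
given directly, or derived from the noise level sigma and a dimensionless
tuning constant beta (of order 1) as

    h^2 = 2 * beta * sigma^2 * |V_i|,

with |V_i| = search_edge**3 the search-box cardinality.  Note that this rule
scales h with the search-box size, so enlarging the search window also
strengthens the smoothing.

Numerical conventions (shared with the chunked and parallel execution paths
so that all of them agree to near machine precision):

* all accumulation is in float64 regardless of storage dtype;
* search-box terms are accumulated in fixed lexicographic offset order;
* patch sums are separable sliding sums (axis 0, then 1, then 2), whose value
  at an interior position is independent of the surrounding array extent —
  this makes chunked and unchunked runs bit-identical on chunk cores.

Boundaries are handled by reflect padding of thickness
``search_radius + sim_radius`` (configurable to edge/zero replication), so
every patch distance is a sum over the same patch cardinality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .errors import BoxOutOfBoundsError, InvalidParamsError, InvalidStrengthError
from .volumes import PadSpec, Volume, pad_volume

__all__ = [
    "NLMParams",
    "compute_h_squared",
    "patch_sqdist",
    "denoise_voxel",
    "denoise_volume",
]


def compute_h_squared(beta: float, sigma: float, search_cardinality: int) -> float:
    """Filter strength rule ``h^2 = 2 * beta * sigma^2 * |V_i|``.

    ``beta`` is a dimensionless constant of order 1, ``sigma`` the noise
    standard deviation, and ``search_cardinality`` the number of voxels in
    the search box (``search_edge**3``).
    """
    if beta <= 0 or sigma <= 0:
        raise InvalidStrengthError(
            f"beta and sigma must be positive (got beta={beta}, sigma={sigma}); "
            "h^2 = 0 makes the exponential weights ill-defined"
        )
    if search_cardinality < 1:
        raise InvalidStrengthError(f"search cardinality must be >= 1, got {search_cardinality}")
    return 2.0 * beta * sigma**2 * search_cardinality


@dataclass(frozen=True)
class NLMParams:
    """Filter parameters.

    Windows are specified by their odd **edge** length (a window "11^3" has
    ``search_edge = 11``); the corresponding radius is ``(edge - 1) // 2``.
    Exactly one of ``h`` or the pair ``(beta, sigma)`` must be given.
    ``include_self`` keeps the j = i term (self weight exp(0) = 1), which
    guarantees a nonzero denominator.
    """

    search_edge: int
    sim_edge: int
    h: float | None = None
    beta: float | None = None
    sigma: float | None = None
    include_self: bool = True

    def __post_init__(self) -> None:
        se, pe = self.search_edge, self.sim_edge
        if se < 1 or pe < 1 or se % 2 == 0 or pe % 2 == 0 or se < pe:
            raise InvalidParamsError(
                f"window edges must be odd, positive, search >= sim; "
                f"got search_edge={se}, sim_edge={pe}"
            )
        if self.h is not None:
            if self.beta is not None or self.sigma is not None:
                raise InvalidParamsError("give either h or (beta, sigma), not both")
            if self.h <= 0:
                raise InvalidStrengthError(f"h must be positive, got {self.h}")
        else:
            if self.beta is None or self.sigma is None:
                raise InvalidParamsError("either h or both beta and sigma are required")
            # validates beta/sigma positivity
            compute_h_squared(self.beta, self.sigma, se**3)

    @property
    def search_radius(self) -> int:
        return (self.search_edge - 1) // 2

    @property
    def sim_radius(self) -> int:
        return (self.sim_edge - 1) // 2

    @property
    def search_cardinality(self) -> int:
        return self.search_edge**3

    @property
    def sim_cardinality(self) -> int:
        return self.sim_edge**3

    @property
    def h_squared(self) -> float:
        if self.h is not None:
            return float(self.h) ** 2
        return compute_h_squared(self.beta, self.sigma, self.search_cardinality)

    @property
    def pad_margin(self) -> int:
        return self.search_radius + self.sim_radius


def _check_box(padded: Volume, center: tuple[int, int, int], radius: int) -> None:
    for ax in range(3):
        if center[ax] - radius < 0 or center[ax] + radius >= padded.shape[ax]:
            raise BoxOutOfBoundsError(
                f"box of radius {radius} at {center} exceeds padded shape {padded.shape}"
            )


def patch_sqdist(
    padded: Volume,
    center_i: tuple[int, int, int],
    center_j: tuple[int, int, int],
    sim_radius: int,
) -> float:
    """Raw squared L2 distance between the two similarity boxes.

    Sums ``(X[i + t] - X[j + t])**2`` over the ``(2*sim_radius + 1)**3``
    aligned offsets t; no normalisation by patch size.  Symmetric in its two
    centers and zero iff the patches are identical.
    """
    _check_box(padded, center_i, sim_radius)
    _check_box(padded, center_j, sim_radius)
    P = padded.data.astype(np.float64, copy=False)
    r = sim_radius
    a = P[
        center_i[0] - r : center_i[0] + r + 1,
        center_i[1] - r : center_i[1] + r + 1,
        center_i[2] - r : center_i[2] + r + 1,
    ]
    b = P[
        center_j[0] - r : center_j[0] + r + 1,
        center_j[1] - r : center_j[1] + r + 1,
        center_j[2] - r : center_j[2] + r + 1,
    ]
    d = (a - b) ** 2
    # separable summation order matches the volume path (axis 0, 1, then 2)
    return float(d.sum(axis=0).sum(axis=0).sum(axis=0))


def denoise_voxel(
    padded: Volume, center: tuple[int, int, int], params: NLMParams
) -> float:
    """Restore a single voxel of a padded volume.

    ``center`` indexes the padded grid; its search box and every member's
    similarity box must lie inside it.  Terms are accumulated in
    lexicographic search-offset order in float64.
    """
    sr = params.search_radius
    _check_box(padded, center, sr + params.sim_radius)
    h2 = params.h_squared
    num = 0.0
    den = 0.0
    P = padded.data
    for dx, dy, dz in itertools.product(range(-sr, sr + 1), repeat=3):
        if not params.include_self and dx == 0 and dy == 0 and dz == 0:
            continue
        j = (center[0] + dx, center[1] + dy, center[2] + dz)
        w = float(np.exp(-patch_sqdist(padded, center, j, params.sim_radius) / h2))
        num += w * float(P[j])
        den += w
    return num / den


def _box_sum(arr: np.ndarray, edge: int) -> np.ndarray:
    """Centred sliding-cube sum of ``arr`` (separable, axis 0 -> 1 -> 2).

    The value at any position at least ``(edge-1)//2`` from every border is
    an exact direct sum over the cube and does not depend on the array
    extent, which makes chunked evaluation bit-identical to unchunked.
    """
    if edge == 1:
        return arr
    kernel = np.ones(edge, dtype=np.float64)
    out = arr
    for ax in range(3):
        out = correlate1d(out, kernel, axis=ax, mode="constant", cval=0.0)
    return out


def _denoise_padded_block(
    P: np.ndarray,
    out_shape: tuple[int, int, int],
    origin: tuple[int, int, int],
    params: NLMParams,
) -> np.ndarray:
    """Filter the block of ``out_shape`` voxels whose first voxel sits at
    padded index ``origin`` (vectorised over the whole block).

    For each search offset delta (lexicographic order) the per-voxel patch
    distance is the sliding-cube sum of the squared shifted difference
    ``(P[q] - P[q + delta])**2``; the weighted intensities are then
    accumulated in float64.
    """
    sr, dr = params.search_radius, params.sim_radius
    pad = sr + dr
    h2 = params.h_squared
    o = origin
    n1, n2, n3 = out_shape

    # region over which squared differences feed the sliding patch sums
    d_lo = (o[0] - dr, o[1] - dr, o[2] - dr)
    base = P[
        d_lo[0] : d_lo[0] + n1 + 2 * dr,
        d_lo[1] : d_lo[1] + n2 + 2 * dr,
        d_lo[2] : d_lo[2] + n3 + 2 * dr,
    ]
    num = np.zeros(out_shape, dtype=np.float64)
    den = np.zeros(out_shape, dtype=np.float64)
    for dx, dy, dz in itertools.product(range(-sr, sr + 1), repeat=3):
        if not params.include_self and dx == 0 and dy == 0 and dz == 0:
            continue
        shifted = P[
            d_lo[0] + dx : d_lo[0] + dx + n1 + 2 * dr,
            d_lo[1] + dy : d_lo[1] + dy + n2 + 2 * dr,
            d_lo[2] + dz : d_lo[2] + dz + n3 + 2 * dr,
        ]
        sq = (base - shifted) ** 2
        dist = _box_sum(sq, params.sim_edge)
        if dr:
            dist = dist[dr : dr + n1, dr : dr + n2, dr : dr + n3]
        w = np.exp(dist * (-1.0 / h2))
        xj = P[
            o[0] + dx : o[0] + dx + n1,
            o[1] + dy : o[1] + dy + n2,
            o[2] + dz : o[2] + dz + n3,
        ]
        num += w * xj
        den += w
    return num / den


def denoise_volume(
    vol: Volume,
    params: NLMParams,
    traversal: str = "voxel",
    pad_mode: str = "reflect",
) -> Volume:
    """Apply the 3D NLM filter to a whole volume.

    ``traversal`` selects the work mapping: ``"voxel"`` flattens the full
    voxel grid into one vectorised sweep (full unrolling), ``"column"``
    iterates (x, y) columns, each sweeping its z extent (partial unrolling).
    Both traversals perform identical per-voxel arithmetic and return
    bit-identical results; they exist so the execution layer can reproduce
    and verify both mappings.

    The output has the input's shape and dtype; internal arithmetic is
    float64.  Constant volumes are fixed points and every output voxel is a
    convex combination of its (padded) search-box intensities.
    """
    if traversal not in ("voxel", "column"):
        raise InvalidParamsError(f"traversal must be 'voxel' or 'column', got {traversal!r}")
    pad = params.pad_margin
    padded = pad_volume(vol, PadSpec.for_filter(params.search_radius, params.sim_radius, pad_mode))
    P = padded.data.astype(np.float64, copy=False)
    L1, L2, L3 = vol.shape
    if traversal == "voxel":
        out = _denoise_padded_block(P, (L1, L2, L3), (pad, pad, pad), params)
    else:
        out = np.empty((L1, L2, L3), dtype=np.float64)
        for x in range(L1):
            for y in range(L2):
                col = _denoise_padded_block(P, (1, 1, L3), (x + pad, y + pad, pad), params)
                out[x, y, :] = col[0, 0, :]
    return Volume(out.astype(vol.dtype, copy=False))
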