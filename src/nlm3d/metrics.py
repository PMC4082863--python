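"""Quantitative volume comparison and residual statistics.

Two uses drive this module: (i) consistency checking between execution paths
(chunked vs unsplit, column vs voxel traversal, different worker counts),
operationalised as the maximum absolute voxel difference relative to the
reference dynamic range — agreement at 1e-6 of the signal range is the
"machine precision in single-precision arithmetic" bar; and (ii) denoising
quality: MSE/PSNR against a known clean volume, and the whiteness of the
residual (a good denoiser turns white noise into white noise, so the lag-1
autocorrelation of the residual along each axis should stay near zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateResidualError, IncompatibleVolumesError
from .volumes import Volume

__all__ = ["ResidualStats", "compare_volumes", "residual_whiteness"]


@dataclass(frozen=True)
class ResidualStats:
    """Voxel-by-voxel comparison summary.

    ``relative_max_diff`` divides the max absolute difference by the
    reference volume's dynamic range (max - min of the first argument);
    ``psnr_db`` is None when the volumes are identical (MSE = 0).
    ``lag1_autocorr`` is None when the difference field is constant.
    """

    mse: float
    psnr_db: float | None
    max_abs_diff: float
    relative_max_diff: float
    lag1_autocorr: tuple[float, float, float] | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "mse": self.mse,
                "psnr_db": self.psnr_db,
                "max_abs_diff": self.max_abs_diff,
                "relative_max_diff": self.relative_max_diff,
                "lag1_autocorr": list(self.lag1_autocorr) if self.lag1_autocorr else None,
            },
            indent=2,
        )


def compare_volumes(a: Volume, b: Volume, peak: float) -> ResidualStats:
    """Compare two volumes voxel by voxel.

    ``mse = mean((a - b)^2)``; ``psnr_db = 10 log10(peak^2 / mse)`` for the
    stated peak; ``max_abs_diff = max |a - b|``.  ``a`` is the reference for
    the dynamic range used by ``relative_max_diff``.
    """
    if a.shape != b.shape:
        raise IncompatibleVolumesError(f"shapes differ: {a.shape} vs {b.shape}")
    if peak <= 0:
        raise IncompatibleVolumesError(f"peak must be positive, got {peak}")
    da = a.data.astype(np.float64, copy=False)
    db = b.data.astype(np.float64, copy=False)
    diff = da - db
    mse = float(np.mean(diff**2))
    max_abs = float(np.max(np.abs(diff)))
    dyn = float(da.max() - da.min())
    if max_abs == 0.0:
        rel = 0.0
    elif dyn == 0.0:
        rel = float("inf")
    else:
        rel = max_abs / dyn
    psnr = 10.0 * np.log10(peak**2 / mse) if mse > 0 else None
    try:
        lag1 = residual_whiteness(Volume(diff)) if min(a.shape) >= 2 else None
    except DegenerateResidualError:
        lag1 = None
    return ResidualStats(
        mse=mse,
        psnr_db=float(psnr) if psnr is not None else None,
        max_abs_diff=max_abs,
        relative_max_diff=rel,
        lag1_autocorr=lag1,
    )


def residual_whiteness(residual: Volume) -> tuple[float, float, float]:
    """Lag-1 autocorrelation of the residual along each axis.

    Pearson correlation between the field and its one-voxel shift, computed
    on the overlapping region after mean removal.  White residuals give
    values near zero; smooth structure in the residual shows up as strong
    positive correlation along that axis.
    """
    r = residual.data.astype(np.float64, copy=False)
    if min(r.shape) < 2:
        raise DegenerateResidualError("need >= 2 voxels per axis for a lag-1 shift")
    if np.ptp(r) == 0.0:
        raise DegenerateResidualError("residual is constant; autocorrelation undefined")
    out = []
    for ax in range(3):
        lead = np.take(r, range(0, r.shape[ax] - 1), axis=ax).ravel()
        lag = np.take(r, range(1, r.shape[ax]), axis=ax).ravel()
        if np.ptp(lead) == 0.0 or np.ptp(lag) == 0.0:
            raise DegenerateResidualError(f"residual constant along axis {ax} overlap")
        out.append(float(np.corrcoef(lead, lag)[0, 1]))
    return (out[0], out[1], out[2])
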