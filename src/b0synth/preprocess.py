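"""Intensity normalization, working-grid resampling and sampling masks.

The synthesis network consumes volumes on a fixed low-resolution working
grid (2.5 mm isotropic by default) with intensities mapped to [-1, 1]:

* T1 images are assumed already on the 0-150 convention that standard
  T1 intensity normalization produces; the fixed map ``v -> v/75 - 1``
  (clipped) takes them to [-1, 1].
* b0 images are scaled by the 99th percentile of the *distorted* b0 —
  min/max scaling is unstable under signal pileup, while the 99th
  percentile reliably lands on CSF, the brightest tissue. The same
  percentile value is applied to the paired undistorted b0 so the two
  share one intensity scale.

Resampling transforms are recorded so results can be mapped back to
subject space, and validity masks mark voxels where resampling was
possible; their intersection is the sampling mask used by the training
loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter, laplace

from .core_io import Volume3D

__all__ = [
    "NormalizationParams",
    "GridTransform",
    "match_gain",
    "normalize_t1",
    "denormalize_t1",
    "normalize_b0_pair",
    "normalize_b0",
    "denormalize_b0",
    "default_working_grid",
    "to_working_grid",
    "from_working_grid",
    "make_sampling_mask",
    "smoothness_energy",
    "smooth_to_match",
]

T1_LOW = 0.0
T1_HIGH = 150.0


@dataclass(frozen=True)
class NormalizationParams:
    """Intensity maps applied before synthesis (and inverted after).

    ``b0_p99`` is the 99th-percentile intensity of the distorted b0, in
    image units; it maps to +1 under the b0 normalization.
    """

    t1_low: float = T1_LOW
    t1_high: float = T1_HIGH
    b0_p99: float = 1.0

    def __post_init__(self) -> None:
        if not self.t1_high > self.t1_low:
            raise ValueError("t1_high must exceed t1_low")
        if not self.b0_p99 > 0:
            raise ValueError("b0_p99 must be positive")


@dataclass
class GridTransform:
    """Resampling record: subject grid <-> working grid.

    ``forward`` maps working-grid indices to subject-grid indices (the
    matrix handed to the resampler); ``inverse`` is its exact inverse.
    ``validity`` flags working-grid voxels whose source position lies
    inside the subject field of view.
    """

    src_shape: tuple[int, int, int]
    src_affine: np.ndarray
    dst_shape: tuple[int, int, int]
    dst_affine: np.ndarray
    validity: np.ndarray

    @property
    def forward(self) -> np.ndarray:
        return np.linalg.inv(self.src_affine) @ self.dst_affine

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.dst_affine) @ self.src_affine


def match_gain(b0_u: Volume3D, b0_d: Volume3D, mask: Volume3D) -> Volume3D:
    """Rescale ``b0_u`` so its masked median matches ``b0_d``'s.

    Needed when truth and distorted b0 come from separate acquisitions
    with different receiver gain; a pure global scale, analogous to
    topup's ``-scale`` option.
    """
    m = mask.data > 0
    if not m.any():
        raise ValueError("gain-matching mask is empty")
    med_u = float(np.median(b0_u.data[m]))
    med_d = float(np.median(b0_d.data[m]))
    if med_u <= 0 or med_d <= 0:
        raise ValueError(
            f"degenerate image: masked medians must be positive "
            f"(undistorted {med_u:g}, distorted {med_d:g})"
        )
    return b0_u.like(b0_u.data * (med_d / med_u))


def normalize_t1(t1: Volume3D) -> Volume3D:
    """Map T1 intensities 0..150 to [-1, 1]; values above 150 clip to +1."""
    scale = (T1_HIGH - T1_LOW) / 2.0
    out = (t1.data - T1_LOW) / scale - 1.0
    return t1.like(np.clip(out, -1.0, 1.0))


def denormalize_t1(t1n: Volume3D) -> Volume3D:
    """Inverse of :func:`normalize_t1` for in-range values."""
    scale = (T1_HIGH - T1_LOW) / 2.0
    return t1n.like((t1n.data + 1.0) * scale + T1_LOW)


def _b0_p99(b0_d: Volume3D, validity: np.ndarray | None) -> float:
    data = b0_d.data if validity is None else b0_d.data[validity > 0]
    p99 = float(np.percentile(data, 99.0))
    if p99 <= 0:
        raise ValueError("99th percentile of distorted b0 is not positive")
    return p99


def normalize_b0(vol: Volume3D, params: NormalizationParams) -> Volume3D:
    """Map 0..p99 to [-1, +1]; no upper clipping (pileup may exceed +1)."""
    return vol.like(2.0 * vol.data / params.b0_p99 - 1.0)


def denormalize_b0(vol: Volume3D, params: NormalizationParams) -> Volume3D:
    """Inverse of :func:`normalize_b0` (exact; the map is affine)."""
    return vol.like((vol.data + 1.0) * params.b0_p99 / 2.0)


def normalize_b0_pair(
    b0_d: Volume3D,
    b0_u: Volume3D | None = None,
    validity: np.ndarray | None = None,
) -> tuple[Volume3D, Volume3D | None, NormalizationParams]:
    """Scale distorted (and optionally undistorted) b0 by the distorted p99.

    The percentile is computed on the distorted b0 (within the validity
    mask when given, else over the whole volume) and the same value is
    applied to both volumes so they share one intensity scale.
    """
    params = NormalizationParams(b0_p99=_b0_p99(b0_d, validity))
    out_d = normalize_b0(b0_d, params)
    out_u = normalize_b0(b0_u, params) if b0_u is not None else None
    return out_d, out_u, params


def default_working_grid(
    vol: Volume3D, voxel_mm: float = 2.5, multiple_of: int = 8
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Working-grid geometry covering the volume's field of view.

    Returns ``(shape, affine)`` for an axis-aligned isotropic grid centered
    on the source FOV, with each dim rounded up to a multiple of
    ``multiple_of`` so pooling by the network is exact.
    """
    fov = np.asarray(vol.shape) * np.asarray(vol.voxel_size)
    shape = tuple(
        int(np.ceil(f / voxel_mm / multiple_of) * multiple_of) for f in fov
    )
    src_center = vol.affine @ np.array(
        [(vol.shape[0] - 1) / 2, (vol.shape[1] - 1) / 2, (vol.shape[2] - 1) / 2, 1.0]
    )
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = src_center[:3] - voxel_mm * (np.asarray(shape) - 1) / 2.0
    return shape, aff


def to_working_grid(
    vol: Volume3D,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    fill: float = 0.0,
) -> tuple[Volume3D, GridTransform]:
    """Resample onto the working grid with linear interpolation.

    The recorded transform makes the operation invertible (up to
    interpolation error) and its validity mask marks working-grid voxels
    whose source location lies inside the subject field of view.
    """
    target_affine = np.asarray(target_affine, dtype=np.float64)
    M = np.linalg.inv(vol.affine) @ target_affine
    if abs(np.linalg.det(M[:3, :3])) < 1e-12:
        raise ValueError("degenerate grid mapping")
    out = affine_transform(
        vol.data.astype(np.float64),
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=target_shape,
        order=1,
        mode="constant",
        cval=fill,
    )
    ii, jj, kk = np.meshgrid(
        *[np.arange(s) for s in target_shape], indexing="ij"
    )
    src = (
        M[:3, :3] @ np.stack([ii.ravel(), jj.ravel(), kk.ravel()])
        + M[:3, 3:4]
    )
    lim = np.asarray(vol.shape, dtype=float) - 1.0
    valid = np.all((src >= -1e-9) & (src <= lim[:, None] + 1e-9), axis=0)
    validity = valid.reshape(target_shape).astype(np.float32)
    if not validity.any():
        raise ValueError("no overlap between source volume and working grid")
    voxel = tuple(float(np.linalg.norm(target_affine[:3, a])) for a in range(3))
    tfm = GridTransform(
        src_shape=vol.shape,
        src_affine=vol.affine.copy(),
        dst_shape=tuple(target_shape),
        dst_affine=target_affine.copy(),
        validity=validity,
    )
    return Volume3D(out, voxel, target_affine.copy()), tfm


def from_working_grid(vol: Volume3D, tfm: GridTransform, fill: float = 0.0) -> Volume3D:
    """Resample a working-grid volume back to subject space (linear interp)."""
    M = tfm.inverse
    out = affine_transform(
        vol.data.astype(np.float64),
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=tfm.src_shape,
        order=1,
        mode="constant",
        cval=fill,
    )
    voxel = tuple(float(np.linalg.norm(tfm.src_affine[:3, a])) for a in range(3))
    return Volume3D(out, voxel, tfm.src_affine.copy())


def make_sampling_mask(*validity_masks: np.ndarray) -> np.ndarray:
    """Intersection of per-volume validity masks (the training-loss mask)."""
    if not validity_masks:
        raise ValueError("need at least one validity mask")
    out = np.ones_like(np.asarray(validity_masks[0], dtype=np.float32))
    for m in validity_masks:
        out = out * (np.asarray(m) > 0)
    if not out.any():
        raise ValueError("sampling-mask intersection is empty")
    return out.astype(np.float32)


def smoothness_energy(data: np.ndarray) -> float:
    """Mean squared voxel-difference Laplacian energy (lower = smoother)."""
    return float(np.mean(laplace(np.asarray(data, dtype=np.float64)) ** 2))


def smooth_to_match(
    b0_d: Volume3D, reference: Volume3D, sigma_max: float = 1.5
) -> tuple[Volume3D, float]:
    """Gaussian-smooth ``b0_d`` to match the reference's smoothness.

    The synthesized reference inherits interpolation smoothing from the
    working-grid round trip; matching the distorted b0's smoothness to it
    removes that systematic difference before field estimation. The kernel
    width is found by monotone bisection on the Laplacian-energy statistic
    over sigma in [0, ``sigma_max``] voxels; sigma = 0 is returned when the
    input is already at least as smooth as the reference.
    """
    if b0_d.shape != reference.shape:
        raise ValueError("volumes must share a grid")
    target = smoothness_energy(reference.data)
    if smoothness_energy(b0_d.data) <= target:
        return b0_d.copy(), 0.0

    def stat(sigma: float) -> float:
        if sigma <= 0:
            return smoothness_energy(b0_d.data)
        return smoothness_energy(gaussian_filter(b0_d.data.astype(np.float64), sigma))

    lo, hi = 0.0, float(sigma_max)
    if stat(hi) > target:
        sigma = hi  # even max smoothing stays rougher than the reference
    else:
        for _ in range(40):
            mid = (lo + hi) / 2.0
            if stat(mid) > target:
                lo = mid
            else:
                hi = mid
        sigma = (lo + hi) / 2.0
    out = gaussian_filter(b0_d.data.astype(np.float64), sigma)
    return b0_d.like(out), float(sigma)
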