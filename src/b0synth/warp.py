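"""1D warping primitives along the phase-encoding axis.

Susceptibility distortion in single-shot EPI displaces signal along the PE
axis only, so both the forward (distorting) and inverse (correcting) maps
are families of 1D warps applied line by line.

Two adjoint discretizations are provided:

* :func:`pushforward` — mass-preserving linear *splatting*: each source
  voxel's intensity is distributed to the two grid neighbours of its
  displaced position. Per-line intensity sums are conserved exactly (to
  float rounding) and signal pileup emerges naturally where the shift
  gradient compresses voxels. This is the simulator's forward model.
* :func:`pullback` — linear *interpolation* at the displaced position with
  optional Jacobian intensity modulation. This is the correction model.

Using adjoint discretizations for simulation and correction gives an
independent consistency check between the two pipeline halves.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pushforward", "pullback", "shift_gradient"]


def _lines_first(arr: np.ndarray, axis: int) -> np.ndarray:
    """View with the warp axis last, flattened to (n_lines, line_len)."""
    moved = np.moveaxis(arr, axis, -1)
    return moved.reshape(-1, moved.shape[-1]), moved.shape


def pushforward(data: np.ndarray, shift: np.ndarray, axis: int) -> np.ndarray:
    """Splat ``data`` along ``axis`` by per-voxel ``shift`` (voxel units).

    Each source voxel at index ``i`` sends its intensity to position
    ``i + shift[i]``, split linearly between the two neighbouring grid
    points. Positions are clamped to the line ends so no mass is lost.

    Raises if any ``|shift|`` exceeds the line extent (unphysical).
    """
    data = np.asarray(data)
    shift = np.asarray(shift)
    if data.shape != shift.shape:
        raise ValueError("data and shift must share a grid")
    n = data.shape[axis]
    if np.max(np.abs(shift)) > n:
        raise ValueError(
            f"shift magnitude {np.max(np.abs(shift)):.2f} exceeds line extent {n}"
        )
    flat, moved_shape = _lines_first(data.astype(np.float64), axis)
    sflat, _ = _lines_first(shift.astype(np.float64), axis)
    m, n = flat.shape
    idx = np.arange(n)[None, :]
    pos = np.clip(idx + sflat, 0.0, n - 1.0)
    k0 = np.minimum(np.floor(pos), n - 2).astype(np.intp)
    f = pos - k0
    row = (np.arange(m)[:, None] * n)
    lo = (row + k0).ravel()
    hi = lo + 1
    v = flat.ravel()
    w1 = f.ravel()
    out = np.bincount(lo, weights=v * (1.0 - w1), minlength=m * n)
    out += np.bincount(hi, weights=v * w1, minlength=m * n)
    out = out.reshape(m, n).reshape(moved_shape)
    return np.moveaxis(out, -1, axis).astype(data.dtype, copy=False)


def shift_gradient(shift: np.ndarray, axis: int) -> np.ndarray:
    """Central-difference derivative of the shift along the warp axis."""
    return np.gradient(np.asarray(shift, dtype=np.float64), axis=axis)


def pullback(
    data: np.ndarray,
    shift: np.ndarray,
    axis: int,
    jacobian: bool = False,
    jacobian_floor: float = 0.05,
) -> np.ndarray:
    """Sample ``data`` at ``i + shift[i]`` along ``axis`` (linear interp).

    With ``jacobian=True`` the result is multiplied by ``1 + d(shift)/di``
    (clamped below at ``jacobian_floor``), the intensity modulation that
    undoes signal pileup when inverting a susceptibility warp.
    """
    data = np.asarray(data)
    shift = np.asarray(shift)
    if data.shape != shift.shape:
        raise ValueError("data and shift must share a grid")
    flat, moved_shape = _lines_first(data.astype(np.float64), axis)
    sflat, _ = _lines_first(shift.astype(np.float64), axis)
    m, n = flat.shape
    idx = np.arange(n)[None, :]
    pos = np.clip(idx + sflat, 0.0, n - 1.0)
    k0 = np.minimum(np.floor(pos), n - 2).astype(np.intp)
    f = pos - k0
    rows = np.arange(m)[:, None]
    out = flat[rows, k0] * (1.0 - f) + flat[rows, k0 + 1] * f
    out = out.reshape(moved_shape)
    out = np.moveaxis(out, -1, axis)
    if jacobian:
        jac = 1.0 + shift_gradient(shift, axis)
        out = out * np.maximum(jac, jacobian_floor)
    return out.astype(data.dtype, copy=False)
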