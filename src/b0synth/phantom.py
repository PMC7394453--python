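"""Synthetic head phantoms and the EPI susceptibility-distortion forward model.

The simulator produces co-registered T1w / b0 pairs with realistic contrast
orderings (T1: white > gray > CSF; b0: CSF brightest), a smooth off-resonance
field with localized hotspots near anterior-inferior tissue boundaries (where
air-tissue susceptibility gradients concentrate in real heads), and
single-blip or opposite-blip distorted b0 volumes with genuine signal pileup.

Displacement follows the standard EPI relation: a voxel at off-resonance
``f`` Hz is displaced along the phase-encoding axis by
``polarity * f * readout_time`` voxels, where ``readout_time`` is the total
readout in seconds. ``readout_time = 0`` is the undistorted (infinite
phase-encode bandwidth) limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import PhaseEncodingSpec, Volume3D
from .warp import pushforward

__all__ = [
    "PhantomParams",
    "SusceptibilityField",
    "DisplacementField",
    "SubjectSample",
    "make_phantom",
    "make_field",
    "field_to_displacement",
    "apply_distortion",
    "simulate_subject",
    "simulate_cohort",
]

#: tissue order used for all per-tissue parameter tuples
TISSUES = ("csf", "gray", "white", "skull")


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the synthetic head and its off-resonance field.

    Intensity means are in arbitrary image units; the T1 defaults live on
    the 0-150 convention produced by standard T1 intensity normalization,
    and the b0 defaults put CSF brightest so the 99th-percentile scaling
    convention captures CSF.
    """

    grid: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 2.5
    #: per-tissue (csf, gray, white, skull) mean intensities
    t1_means: tuple[float, float, float, float] = (30.0, 90.0, 120.0, 40.0)
    b0_means: tuple[float, float, float, float] = (900.0, 400.0, 380.0, 100.0)
    noise_sd_t1: float = 2.0
    noise_sd_b0: float = 15.0
    #: SD of post-distortion acquisition noise added to each blip; the
    #: default 0 keeps distorted blips exact pushforwards of the truth so
    #: per-line mass conservation holds exactly.
    post_noise_sd: float = 0.0
    field_amplitude_hz: float = 50.0
    field_smoothness_vox: float = 6.0
    n_hotspots: int = 2
    hotspot_spread_vox: float = 3.0
    #: readout (s) at which the smooth field component is kept invertible
    nominal_readout_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(g) < 16 for g in self.grid):
            raise ValueError(f"phantom grid must be >= 16 per axis, got {self.grid}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if any(m < 0 for m in self.t1_means + self.b0_means):
            raise ValueError("tissue intensity means must be >= 0")
        if min(self.noise_sd_t1, self.noise_sd_b0, self.post_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.field_amplitude_hz < 0:
            raise ValueError("field amplitude must be >= 0")
        if self.field_smoothness_vox < 1:
            raise ValueError("field smoothness must be >= 1 voxel")
        if self.n_hotspots < 0:
            raise ValueError("hotspot count must be >= 0")


@dataclass
class SusceptibilityField:
    """Off-resonance field in Hz on the subject grid; zero outside the head."""

    field: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float32)
        if not np.all(np.isfinite(self.field)):
            raise ValueError("susceptibility field contains non-finite values")


@dataclass
class DisplacementField:
    """Per-voxel shift in voxel units along one phase-encoding axis."""

    shift: np.ndarray
    pe: PhaseEncodingSpec

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=np.float32)
        if not np.all(np.isfinite(self.shift)):
            raise ValueError("displacement field contains non-finite values")


@dataclass
class SubjectSample:
    """One simulated session: T1, truth b0, distorted blip(s), mask, truth field."""

    subject_id: str
    t1: Volume3D
    b0_u: Volume3D
    b0_d_blips: list[tuple[Volume3D, PhaseEncodingSpec]]
    mask: Volume3D
    truth_field: SusceptibilityField | None = None
    labels: np.ndarray | None = None  # tissue labels, simulation only

    def __post_init__(self) -> None:
        if not 1 <= len(self.b0_d_blips) <= 2:
            raise ValueError("a sample carries one or two distorted blips")
        shape = self.t1.shape
        for vol in (self.b0_u, self.mask):
            if vol.shape != shape:
                raise ValueError("all volumes in a sample must share a grid")
        for vol, _pe in self.b0_d_blips:
            if vol.shape != shape:
                raise ValueError("all volumes in a sample must share a grid")
        if len(self.b0_d_blips) == 2:
            pe1, pe2 = (pe for _v, pe in self.b0_d_blips)
            if (pe1.axis, pe1.readout_time) != (pe2.axis, pe2.readout_time) or (
                pe1.polarity != -pe2.polarity
            ):
                raise ValueError("two-blip specs must differ only in polarity sign")
        if not np.any(self.mask.data > 0):
            raise ValueError("sample mask is empty")

    @property
    def n_blips(self) -> int:
        return len(self.b0_d_blips)


def _ras_affine(grid: Sequence[int], voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(grid, dtype=float) - 1) / 2.0
    return aff


def _tissue_labels(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Label volume: 0 background, 1 csf, 2 gray, 3 white, 4 skull."""
    nx, ny, nz = params.grid
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    c = (np.array(params.grid) - 1) / 2.0
    semi = np.array([0.72 * nx, 0.85 * ny, 0.78 * nz]) / 2.0
    rho = np.sqrt(
        ((x - c[0]) / semi[0]) ** 2
        + ((y - c[1]) / semi[1]) ** 2
        + ((z - c[2]) / semi[2]) ** 2
    )
    # cortical-like perturbation of the shell radii
    bump = gaussian_filter(rng.standard_normal(params.grid), 2.0)
    bump *= 0.05 / max(bump.std(), 1e-12)
    rho_p = rho + bump
    labels = np.zeros(params.grid, dtype=np.uint8)
    labels[rho_p < 1.0] = 4  # skull / scalp shell
    labels[rho_p < 0.88] = 1  # outer CSF shell
    labels[rho_p < 0.72] = 2  # gray shell
    labels[rho_p < 0.52] = 3  # white core
    # ventricle-like central CSF pocket
    vent = (
        ((x - c[0]) / (0.10 * nx)) ** 2
        + ((y - c[1]) / (0.16 * ny)) ** 2
        + ((z - c[2] - 0.04 * nz) / (0.10 * nz)) ** 2
    )
    labels[(vent < 1.0) & (labels == 3)] = 1
    return labels


def _paint(labels: np.ndarray, means: Sequence[float]) -> np.ndarray:
    out = np.zeros(labels.shape, dtype=np.float32)
    for lab, mean in zip((1, 2, 3, 4), means):
        out[labels == lab] = mean
    return out


def make_phantom(
    params: PhantomParams,
) -> tuple[Volume3D, Volume3D, Volume3D, np.ndarray]:
    """Build a co-registered (T1, undistorted b0, head mask) triple.

    Returns ``(t1, b0_u, mask, labels)``; the label volume (0 background,
    1 CSF, 2 gray, 3 white, 4 skull) is exposed for evaluation only.
    Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    labels = _tissue_labels(params, rng)
    t1 = _paint(labels, params.t1_means)
    b0 = _paint(labels, params.b0_means)
    if params.noise_sd_t1 > 0:
        t1 = t1 + rng.normal(0.0, params.noise_sd_t1, size=t1.shape)
    if params.noise_sd_b0 > 0:
        b0 = b0 + rng.normal(0.0, params.noise_sd_b0, size=b0.shape)
    t1 = np.clip(t1, 0.0, None)
    b0 = np.clip(b0, 0.0, None)
    aff = _ras_affine(params.grid, params.voxel_size_mm)
    vs = (params.voxel_size_mm,) * 3
    mask = (labels > 0).astype(np.float32)
    return (
        Volume3D(t1, vs, aff),
        Volume3D(b0, vs, aff),
        Volume3D(mask, vs, aff),
        labels,
    )


def make_field(
    params: PhantomParams, mask: Volume3D, rng: np.random.Generator | None = None
) -> SusceptibilityField:
    """Smooth random off-resonance field (Hz) with localized hotspots.

    The smooth component is correlated Gaussian noise at the configured
    correlation length, globally scaled so the induced warp at the nominal
    readout stays invertible (``1 + d(shift)/di >= 0.05`` along every
    axis). Hotspots — high-amplitude Gaussian bumps placed near the
    anterior-inferior mask boundary, emulating air-tissue interfaces at the
    sinuses and ear canals — may violate that bound, producing genuine
    pileup. The final field is clipped to +/- the configured amplitude and
    zeroed outside the mask. Deterministic under seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    amp = params.field_amplitude_hz
    shape = mask.data.shape
    if amp == 0:
        return SusceptibilityField(np.zeros(shape, dtype=np.float32))
    base = gaussian_filter(
        rng.standard_normal(shape), params.field_smoothness_vox
    )
    base *= (amp / 2.5) / max(base.std(), 1e-12)
    # keep the smooth component invertible at the nominal readout
    shift = base * params.nominal_readout_s
    worst = min(np.gradient(shift, axis=ax).min() for ax in range(3))
    if worst < -0.95:
        base *= 0.95 / abs(worst)
    m = mask.data > 0
    fld = base
    if params.n_hotspots > 0 and m.any():
        # anterior (+y) inferior (-z) boundary voxels of the mask
        idx = np.argwhere(m)
        score = idx[:, 1] / shape[1] - idx[:, 2] / shape[2]
        cand = idx[score >= np.quantile(score, 0.92)]
        centers = cand[rng.integers(0, len(cand), size=params.n_hotspots)]
        gx, gy, gz = np.meshgrid(
            np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
            indexing="ij",
        )
        s = params.hotspot_spread_vox
        for cx, cy, cz in centers:
            r2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
            fld = fld + rng.choice([-1.5, 1.5]) * amp * np.exp(-r2 / (2 * s**2))
    fld = np.clip(fld, -amp, amp)
    # taper continuously to zero at the mask edge (real fields are smooth;
    # a hard cutoff would put an unphysical step at the head boundary)
    interior = gaussian_filter(m.astype(np.float64), 2.0)
    taper = np.where(m, np.clip(2.0 * interior - 1.0, 0.0, 1.0), 0.0)
    fld = fld * taper
    return SusceptibilityField(fld.astype(np.float32))


def field_to_displacement(
    field: SusceptibilityField, pe: PhaseEncodingSpec
) -> DisplacementField:
    """Voxel shift along the PE axis: ``polarity * field_Hz * readout_s``."""
    shift = pe.polarity * field.field * pe.readout_time
    return DisplacementField(shift, pe)


def apply_distortion(vol: Volume3D, dfield: DisplacementField) -> Volume3D:
    """Mass-preserving forward distortion of a volume (splatting pushforward)."""
    if vol.shape != dfield.shift.shape:
        raise ValueError("volume and displacement field must share a grid")
    out = pushforward(vol.data, dfield.shift, dfield.pe.axis)
    return vol.like(out)


def simulate_subject(
    params: PhantomParams,
    pe_axis: int = 1,
    readout: float = 0.05,
    n_blips: int = 1,
    subject_id: str | None = None,
) -> SubjectSample:
    """Simulate one session: phantom, field, and distorted blip(s).

    ``n_blips=2`` produces opposite-polarity distortions of the same truth
    volume (a blip-up/blip-down pair); their displacement fields are exact
    negations by construction.
    """
    if n_blips not in (1, 2):
        raise ValueError("n_blips must be 1 or 2")
    t1, b0_u, mask, labels = make_phantom(params)
    rng = np.random.default_rng(params.seed + 1)
    fld = make_field(params, mask, rng)
    blips = []
    pols = (1,) if n_blips == 1 else (1, -1)
    for pol in pols:
        pe = PhaseEncodingSpec(pe_axis, pol, readout)
        d = field_to_displacement(fld, pe)
        b0_d = apply_distortion(b0_u, d)
        if params.post_noise_sd > 0:
            b0_d = b0_d.like(
                np.clip(
                    b0_d.data
                    + rng.normal(0.0, params.post_noise_sd, size=b0_d.shape),
                    0.0,
                    None,
                )
            )
        blips.append((b0_d, pe))
    return SubjectSample(
        subject_id=subject_id or f"sub-{params.seed:05d}",
        t1=t1,
        b0_u=b0_u,
        b0_d_blips=blips,
        mask=mask,
        truth_field=fld,
        labels=labels,
    )


def simulate_cohort(
    n_subjects: int,
    params: PhantomParams,
    pe_axis: int = 1,
    readout: float = 0.05,
    blips: str | int = "mixed",
    master_seed: int = 0,
) -> list[SubjectSample]:
    """Simulate a cohort with per-subject seeds and mild parameter spread.

    ``blips`` is 1, 2, or ``"mixed"`` (alternating single- and dual-blip
    sessions, emulating a corpus that mixes single-PE and reverse-PE
    acquisitions). Field amplitude and noise vary mildly across subjects;
    everything is deterministic under ``master_seed``.
    """
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s) for s in ss.generate_state(n_subjects) >> 1]
    spread = np.random.default_rng(ss.spawn(1)[0])
    cohort = []
    for i, seed in enumerate(child_seeds):
        amp = params.field_amplitude_hz * float(spread.uniform(0.7, 1.3))
        nb0 = params.noise_sd_b0 * float(spread.uniform(0.7, 1.3))
        p = replace(params, seed=seed, field_amplitude_hz=amp, noise_sd_b0=nb0)
        nb = {1: 1, 2: 2}.get(blips, 2 if i % 2 else 1)
        cohort.append(
            simulate_subject(
                p, pe_axis=pe_axis, readout=readout, n_blips=nb,
                subject_id=f"sub-{i:03d}",
            )
        )
    return cohort
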