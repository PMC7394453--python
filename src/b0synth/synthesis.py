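"""Training and inference for the b0 synthesizer.

The loss mirrors a Siamese design keyed on how many opposite-polarity
blips a session has:

* single blip: masked MSE of the synthesized b0 against the undistorted
  truth;
* two blips: both distorted b0s pass through the same network; the two
  truth MSEs are averaged (a bias term) and the masked MSE *between* the
  two syntheses is added (a variance term) — outputs from opposite
  distortions of the same anatomy should agree.

Training runs k-fold cross-validation partitioned by subject, Adam
(lr 1e-4, betas 0.9/0.999, weight decay 1e-5) for a fixed number of
epochs; after each epoch the masked validation MSE is recorded and the
weights from the minimum-validation epoch are kept, giving k networks
whose voxelwise ensemble average is the final synthesizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import PhaseEncodingSpec, Volume3D
from .phantom import SubjectSample
from .preprocess import (
    GridTransform,
    NormalizationParams,
    denormalize_b0,
    from_working_grid,
    make_sampling_mask,
    normalize_b0,
    normalize_b0_pair,
    normalize_t1,
    to_working_grid,
)
from .unet import UNet3D, UNetConfig

__all__ = [
    "TrainConfig",
    "LossReport",
    "FoldEnsemble",
    "PreparedSample",
    "prepare_sample",
    "compute_loss",
    "loss_and_grads",
    "split_folds",
    "train_fold",
    "train_ensemble",
    "ensemble_predict",
    "synthesize_b0",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-5
    folds: int = 5
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive (decay >= 0)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class LossReport:
    """Decomposition of the training objective for one sample."""

    truth_losses: tuple[float, ...]
    diff_loss: float | None
    total: float

    def __post_init__(self) -> None:
        if any(l < 0 for l in self.truth_losses) or (
            self.diff_loss is not None and self.diff_loss < 0
        ):
            raise ValueError("loss components must be >= 0")


def _masked_mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    m = mask > 0
    return float(np.mean((a[m] - b[m]) ** 2))


def compute_loss(
    outputs: list[np.ndarray], truth: np.ndarray, mask: np.ndarray
) -> LossReport:
    """Masked synthesis loss for one or two blips.

    One output: ``total = MSE(out, truth)``. Two outputs:
    ``total = (MSE1 + MSE2)/2 + MSE(out1, out2)``, all over mask voxels.
    """
    if len(outputs) not in (1, 2):
        raise ValueError("expected one or two synthesized outputs")
    if not np.any(mask > 0):
        raise ValueError("loss mask is empty")
    truths = tuple(_masked_mse(o, truth, mask) for o in outputs)
    if len(outputs) == 1:
        return LossReport(truths, None, truths[0])
    diff = _masked_mse(outputs[0], outputs[1], mask)
    return LossReport(truths, diff, (truths[0] + truths[1]) / 2.0 + diff)


def loss_and_grads(
    outputs: list[np.ndarray], truth: np.ndarray, mask: np.ndarray
) -> tuple[LossReport, list[np.ndarray]]:
    """Loss report plus d(total)/d(output_i) for backpropagation."""
    report = compute_loss(outputs, truth, mask)
    m = (mask > 0).astype(np.float32)
    n = float(m.sum())
    if len(outputs) == 1:
        g = 2.0 * m * (outputs[0] - truth) / n
        return report, [g.astype(np.float32)]
    o1, o2 = outputs
    g1 = m * ((o1 - truth) + 2.0 * (o1 - o2)) / n
    g2 = m * ((o2 - truth) - 2.0 * (o1 - o2)) / n
    return report, [g1.astype(np.float32), g2.astype(np.float32)]


# ---------------------------------------------------------------------------
# Sample preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparedSample:
    """A session resampled to the working grid and normalized for the net."""

    subject_id: str
    inputs: list[np.ndarray]  # per blip: (2, X, Y, Z) = [T1_norm, b0_d_norm]
    truth: np.ndarray  # normalized undistorted b0
    mask: np.ndarray  # sampling (loss) mask on the working grid
    pes: list[PhaseEncodingSpec]
    norm: NormalizationParams
    tfm: GridTransform


def prepare_sample(
    sample: SubjectSample,
    target_shape: tuple[int, int, int] | None = None,
    target_affine: np.ndarray | None = None,
) -> PreparedSample:
    """Resample a session onto the working grid and normalize intensities.

    The b0 scale (99th percentile) is computed on the first distorted blip
    and shared by every b0 in the session so they stay on one intensity
    scale. The sampling mask is the intersection of all per-volume
    resampling validity masks.
    """
    if target_shape is None or target_affine is None:
        target_shape = sample.t1.shape
        target_affine = sample.t1.affine
    t1_w, tfm = to_working_grid(sample.t1, target_shape, target_affine)
    validities = [tfm.validity]
    blips_w = []
    for vol, pe in sample.b0_d_blips:
        v_w, v_tfm = to_working_grid(vol, target_shape, target_affine)
        blips_w.append((v_w, pe))
        validities.append(v_tfm.validity)
    b0u_w, u_tfm = to_working_grid(sample.b0_u, target_shape, target_affine)
    validities.append(u_tfm.validity)
    mask = make_sampling_mask(*validities)

    t1n = normalize_t1(t1_w)
    d0n, un, norm = normalize_b0_pair(blips_w[0][0], b0u_w, validity=mask)
    inputs = [np.stack([t1n.data, d0n.data])]
    pes = [blips_w[0][1]]
    for vol, pe in blips_w[1:]:
        inputs.append(np.stack([t1n.data, normalize_b0(vol, norm).data]))
        pes.append(pe)
    return PreparedSample(
        subject_id=sample.subject_id,
        inputs=inputs,
        truth=un.data,
        mask=mask,
        pes=pes,
        norm=norm,
        tfm=tfm,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def split_folds(
    subject_ids: list[str], k: int = 5, seed: int = 0, n_test: int = 0
) -> tuple[list[str], list[list[str]]]:
    """Withhold a test set, then partition the rest into k subject folds.

    Partitioning is always by subject (never by session or volume), folds
    are disjoint and covering with sizes differing by at most one, and the
    assignment is deterministic under ``seed``.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test, learn = order[:n_test], order[n_test:]
    if len(learn) < k:
        raise ValueError(f"need at least {k} learning subjects, have {len(learn)}")
    folds: list[list[str]] = [learn[i::k] for i in range(k)]
    return test, folds


@dataclass
class FoldCurves:
    train_loss: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_mse))


def _validation_mse(net: UNet3D, samples: list[PreparedSample]) -> float:
    """Masked truth MSE averaged over blips then over validation samples."""
    vals = []
    for s in samples:
        blip_mses = [
            _masked_mse(net.forward(x)[0], s.truth, s.mask) for x in s.inputs
        ]
        vals.append(float(np.mean(blip_mses)))
    return float(np.mean(vals))


def train_fold(
    samples: dict[str, PreparedSample],
    train_ids: list[str],
    val_ids: list[str],
    unet_cfg: UNetConfig,
    cfg: TrainConfig,
    seed: int | None = None,
) -> tuple[UNet3D, FoldCurves]:
    """Train one fold and return the minimum-validation-epoch weights.

    Runs Adam with the configured schedule, records the training loss and
    masked validation MSE after every epoch, and restores the weights from
    the epoch with the lowest validation MSE. Dual-blip samples
    backpropagate both the truth and difference terms (the first blip is
    re-run forward so each backward pass sees its own activations).
    Deterministic under the seed. Raises on non-finite loss.
    """
    if set(train_ids) & set(val_ids):
        raise ValueError("train and validation subjects overlap")
    if not train_ids or not val_ids:
        raise ValueError("train and validation sets must be non-empty")
    from .nn import Adam

    seed = cfg.seed if seed is None else seed
    net = UNet3D(unet_cfg, seed=seed)
    opt = Adam(
        net.param_refs(),
        lr=cfg.learning_rate,
        betas=cfg.adam_betas,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(seed + 1)
    curves = FoldCurves()
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        order = [train_ids[i] for i in rng.permutation(len(train_ids))]
        epoch_losses = []
        for sid in order:
            s = samples[sid]
            net.zero_grad()
            outs = [net.forward(x)[0] for x in s.inputs]
            report, grads = loss_and_grads(outs, s.truth, s.mask)
            if not np.isfinite(report.total):
                raise FloatingPointError(
                    f"training diverged on {sid} at epoch {epoch}: "
                    f"loss={report.total}"
                )
            # backprop the last forward's term, then re-run earlier blips so
            # each backward uses its own cached activations
            net.backward(grads[-1][None])
            for x, g in zip(s.inputs[:-1], grads[:-1]):
                net.forward(x)
                net.backward(g[None])
            opt.step()
            epoch_losses.append(report.total)
        curves.train_loss.append(float(np.mean(epoch_losses)))
        vmse = _validation_mse(net, [samples[v] for v in val_ids])
        curves.val_mse.append(vmse)
        if vmse < best[0]:
            best = (vmse, net.state_dict())
    net.load_state_dict(best[1])
    return net, curves


@dataclass
class FoldEnsemble:
    """The k networks kept from k-fold cross-validation, plus their curves."""

    models: list[UNet3D]
    curves: list[FoldCurves]
    unet_cfg: UNetConfig

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs at least one model")

    @property
    def selected_epochs(self) -> list[int]:
        return [c.best_epoch for c in self.curves]


def train_ensemble(
    samples: dict[str, PreparedSample],
    folds: list[list[str]],
    unet_cfg: UNetConfig,
    cfg: TrainConfig,
) -> FoldEnsemble:
    """k-fold training: fold i validates on fold i, trains on the rest."""
    models, curves = [], []
    for i, val_ids in enumerate(folds):
        train_ids = [sid for j, f in enumerate(folds) if j != i for sid in f]
        net, c = train_fold(
            samples, train_ids, val_ids, unet_cfg, cfg, seed=cfg.seed + i
        )
        models.append(net)
        curves.append(c)
    return FoldEnsemble(models, curves, unet_cfg)


def ensemble_predict(ensemble: FoldEnsemble, x: np.ndarray) -> np.ndarray:
    """Voxelwise mean of the fold members' outputs (normalized units)."""
    outs = [net.forward(x)[0] for net in ensemble.models]
    return np.mean(outs, axis=0).astype(np.float32)


def synthesize_b0(
    ensemble: FoldEnsemble,
    t1_norm: Volume3D,
    b0_d_norm: Volume3D,
    norm: NormalizationParams,
    tfm: GridTransform | None = None,
) -> Volume3D:
    """Synthesize the undistorted b0 and map it back to image units.

    Averages the fold members' outputs, undoes the b0 normalization with
    the stored parameters, and (when a grid transform is given) resamples
    from the working grid back to subject space.
    """
    x = np.stack([t1_norm.data, b0_d_norm.data])
    out = ensemble_predict(ensemble, x)
    vol = denormalize_b0(t1_norm.like(out), norm)
    if tfm is not None:
        vol = from_working_grid(vol, tfm)
    return vol
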