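"""Pre-training, fine-tuning, direct baselines, ensembling and uncertainty.

Model families follow the study design the package reproduces:

* ``pre``     — trained on pooled samples from all source-domain subjects
                (j minutes of acquisition per subject).
* ``pre+TL``  — a pre-trained model fine-tuned on i minutes of samples from
                one new target subject, same hyper-parameters.
* ``direct``  — trained from scratch on the target subject only (baseline).

An ensemble holds N independently initialized pre-trained-then-fine-tuned
members; its prediction is the voxelwise mean of the denormalized member
predictions and its uncertainty map the voxelwise coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from liver4d.core_io import NormParams, TrainingSample, minutes_to_pairs, zscore_normalize
from liver4d.network import ArchConfig, ModelHandle, TrainConfig, build_unet, train
from liver4d.phantom import SyntheticSubject, sample_training_pairs


# ---------------------------------------------------------------------------
# sample budgeting
# ---------------------------------------------------------------------------

def subject_norm(subject: SyntheticSubject, samples: Sequence[TrainingSample]) -> NormParams:
    """Per-subject pooled statistics over dynamic frames and the static volume."""
    imgs = [s.navigator for s in samples] + [s.label for s in samples]
    imgs.append(subject.static.voxels)
    _, params = zscore_normalize(imgs, subject.subject_id)
    return params


def budget_samples(
    subject: SyntheticSubject,
    minutes: float,
    seed: int = 0,
    val_fraction: float = 0.5,
) -> tuple[list[TrainingSample], list[TrainingSample], NormParams]:
    """Acquire a minutes-budget of pairs and split train/validation.

    Pairs are taken contiguously from the sequence start (the budget-limited
    acquisition order); the first half of the acquisition is training data and
    the second half validation data.
    """
    n = minutes_to_pairs(minutes)
    samples = sample_training_pairs(subject, n, seed=seed)
    n_train = max(1, int(round(len(samples) * (1 - val_fraction))))
    if n_train == len(samples):
        n_train = len(samples) - 1
    norm = subject_norm(subject, samples)
    return list(samples[:n_train]), list(samples[n_train:]), norm


# ---------------------------------------------------------------------------
# training entry points
# ---------------------------------------------------------------------------

def pretrain(
    source_subjects: Sequence[SyntheticSubject],
    j_minutes: float,
    n_models: int = 1,
    seeds: Sequence[int] | None = None,
    cfg: TrainConfig | None = None,
    arch: ArchConfig | None = None,
) -> list[ModelHandle]:
    """Train N independently initialized models on pooled source samples.

    Each source subject contributes ``minutes_to_pairs(j_minutes)`` pairs,
    each z-scored with that subject's own statistics before pooling. The
    pooled pool is split per-subject into first-half train / second-half
    validation.
    """
    if not source_subjects:
        raise ValueError("need at least one source subject")
    cfg = cfg or TrainConfig()
    arch = arch or ArchConfig()
    seeds = list(seeds) if seeds is not None else list(range(n_models))
    if len(seeds) != n_models:
        raise ValueError("need one seed per ensemble member")

    train_pool: list[TrainingSample] = []
    val_pool: list[TrainingSample] = []
    for k, subj in enumerate(source_subjects):
        tr, va, norm = budget_samples(subj, j_minutes, seed=1000 + k)
        # normalize per subject here; pooled training then uses identity stats
        train_pool += [_prenormalized(s, norm) for s in tr]
        val_pool += [_prenormalized(s, norm) for s in va]

    identity = NormParams(mean=0.0, std=1.0, subject_id="pooled")
    models = []
    for seed in seeds:
        model = build_unet(arch, seed=seed)
        model.norm = identity
        run_cfg = _reseeded(cfg, seed)
        model, _ = train(model, train_pool, val_pool, run_cfg, identity)
        model.provenance = {
            "family": "pre",
            "source_minutes": j_minutes,
            "target_minutes": None,
            "seed": seed,
        }
        models.append(model)
    return models


def _prenormalized(s: TrainingSample, norm: NormParams) -> TrainingSample:
    z = lambda a: (np.asarray(a, dtype=np.float64) - norm.mean) / norm.std  # noqa: E731
    return TrainingSample(
        navigator=z(s.navigator), static_at_nav=z(s.static_at_nav),
        static_at_target=z(s.static_at_target), label=z(s.label),
        target_position=s.target_position, subject_id=s.subject_id,
    )


def _reseeded(cfg: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def finetune(
    base: ModelHandle,
    target_subject: SyntheticSubject,
    i_minutes: float,
    cfg: TrainConfig | None = None,
    seed: int | None = None,
    data_seed: int | None = None,
) -> ModelHandle:
    """Continue optimizing a pre-trained model on one target subject.

    Uses the same training recipe as pre-training; the target subject's own
    pooled normalization replaces the source statistics. ``seed`` drives the
    member-specific training stochasticity (shuffling, dropout, augmentation)
    while ``data_seed`` fixes the acquired sample set, so ensemble members
    can share one acquisition and differ only in initialization and training
    randomness. The base model is not modified.
    """
    cfg = cfg or TrainConfig()
    h, w, _ = base.arch.in_shape
    if (target_subject.grid[2], target_subject.grid[1]) != (h, w):
        raise ValueError(
            f"architecture mismatch: model expects {h}x{w} slices but subject "
            f"{target_subject.subject_id} produces "
            f"{target_subject.grid[2]}x{target_subject.grid[1]}"
        )
    seed = seed if seed is not None else int(base.provenance.get("seed", 0))
    data_seed = data_seed if data_seed is not None else seed
    tr, va, norm = budget_samples(target_subject, i_minutes, seed=data_seed + 7)
    model = base.clone()
    model.norm = norm
    if cfg.epochs == 0:
        model.provenance = {**base.provenance, "family": "pre+TL",
                            "target_minutes": i_minutes}
        return model
    model, _ = train(model, tr, va, _reseeded(cfg, seed), norm)
    model.provenance = {
        "family": "pre+TL",
        "source_minutes": base.provenance.get("source_minutes"),
        "target_minutes": i_minutes,
        "seed": seed,
    }
    return model


def train_direct(
    target_subject: SyntheticSubject,
    i_minutes: float,
    cfg: TrainConfig | None = None,
    arch: ArchConfig | None = None,
    seed: int = 0,
) -> ModelHandle:
    """Train from random initialization on the target subject only."""
    cfg = cfg or TrainConfig()
    arch = arch or ArchConfig()
    tr, va, norm = budget_samples(target_subject, i_minutes, seed=seed + 7)
    model = build_unet(arch, seed=seed)
    model.norm = norm
    model, _ = train(model, tr, va, _reseeded(cfg, seed), norm)
    model.provenance = {
        "family": "direct",
        "source_minutes": None,
        "target_minutes": i_minutes,
        "seed": seed,
    }
    return model


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """N fine-tuned members sharing one architecture and target subject."""

    members: list[ModelHandle]
    target_subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        archs = {
            (m.arch.in_shape, m.arch.base_filters, m.arch.levels) for m in self.members
        }
        if len(archs) != 1:
            raise ValueError("all ensemble members must share one architecture")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class UncertaintyMap:
    """Voxelwise coefficient of variation across ensemble members."""

    values: np.ndarray
    mean_prediction: np.ndarray
    guarded: np.ndarray  # voxels where |mean| fell below epsilon (CoV set to 0)


def ensemble_predict(
    ensemble: Ensemble, stacks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average the denormalized member predictions voxelwise.

    Returns ``(mean_prediction, member_predictions)`` with member predictions
    stacked on axis 0 and already denormalized (so the uncertainty map can be
    computed on the denormalized intensity scale).
    """
    preds = []
    for m in ensemble.members:
        if m.norm is None:
            raise ValueError("ensemble members must carry normalization parameters")
        preds.append(m.predict(stacks) * m.norm.std + m.norm.mean)
    member_preds = np.stack(preds)
    return member_preds.mean(axis=0), member_preds


def uncertainty_map(
    member_predictions: np.ndarray,
    epsilon_rel: float = 1e-6,
    sample_std: bool = False,
) -> UncertaintyMap:
    """Voxelwise CoV = std / mean over members (population std by default).

    Voxels whose |mean| is below ``epsilon_rel`` times the intensity range are
    flagged and their CoV set to 0 rather than left undefined.
    """
    member_predictions = np.asarray(member_predictions, dtype=np.float64)
    if member_predictions.shape[0] < 2:
        raise ValueError("CoV undefined for a single member")
    mean = member_predictions.mean(axis=0)
    std = member_predictions.std(axis=0, ddof=1 if sample_std else 0)
    rng_ = float(member_predictions.max() - member_predictions.min())
    eps = epsilon_rel * (rng_ if rng_ > 0 else 1.0)
    guarded = np.abs(mean) < eps
    cov = np.zeros_like(mean)
    np.divide(std, np.abs(mean), out=cov, where=~guarded)
    return UncertaintyMap(values=cov, mean_prediction=mean, guarded=guarded)
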