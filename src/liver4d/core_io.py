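"""Domain types, NIfTI I/O, intensity normalization and acquisition-budget math.

Conventions used throughout the package:

* 3D volumes are indexed ``voxels[lr, ap, si]`` (left-right, anterior-posterior,
  superior-inferior) with isotropic spacing in mm (default 1.8).
* A sagittal slice at LR index ``i`` is the 2D image ``voxels[i].T`` with axes
  (SI, AP), which is also the shape of every dynamic frame.
* Acquisition timing: one 2D slice takes 166 ms, navigators and data slices
  alternate, hence 360 slices (180 navigator/data pairs) per minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

#: One acquired 2D slice every 166 ms.
SLICE_INTERVAL_S = 0.166
#: Budget conversions count 360 acquired slices (180 pairs) per minute.
SLICES_PER_MINUTE = 360


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar image with isotropic-by-default voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.8, 1.8, 1.8)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"Volume requires a rank-3 voxel array, got rank {self.voxels.ndim}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("Volume voxels must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def sagittal_slice(self, lr_index: int) -> np.ndarray:
        """2D (SI, AP) slice at a fixed LR position."""
        if not 0 <= lr_index < self.voxels.shape[0]:
            raise ValueError(
                f"LR index {lr_index} outside volume extent {self.voxels.shape[0]}"
            )
        return self.voxels[lr_index].T.copy()


@dataclass
class SliceSequence:
    """An interleaved navigator/data 2D+t sequence.

    ``roles`` tags every frame as ``"navigator"`` or ``"data"``; navigator
    frames all sit at the fixed ``navigator_position`` LR index while data
    frames sweep the liver.
    """

    frames: list[np.ndarray]
    timestamps_s: np.ndarray
    roles: list[str]
    slice_positions: list[int]
    navigator_position: int

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
        n = len(self.frames)
        if not (len(self.roles) == len(self.slice_positions) == self.timestamps_s.size == n):
            raise ValueError("frames, roles, slice_positions and timestamps must align")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for i, role in enumerate(self.roles):
            if role not in ("navigator", "data"):
                raise ValueError(f"unknown frame role {role!r}")
            expected = "navigator" if i % 2 == 0 else "data"
            if role != expected:
                raise ValueError("roles must interleave navigator,data,navigator,...")
            if role == "navigator" and self.slice_positions[i] != self.navigator_position:
                raise ValueError("navigator frames must share navigator_position")

    def pairs(self) -> list[tuple[np.ndarray, np.ndarray, int, float]]:
        """(navigator, data, data_position, navigator_time) tuples."""
        out = []
        for i in range(0, len(self.frames) - 1, 2):
            out.append(
                (self.frames[i], self.frames[i + 1], self.slice_positions[i + 1],
                 float(self.timestamps_s[i]))
            )
        return out


@dataclass
class TrainingSample:
    """One supervised unit: navigator + two static conditioning slices + label."""

    navigator: np.ndarray
    static_at_nav: np.ndarray
    static_at_target: np.ndarray
    label: np.ndarray
    target_position: int
    subject_id: str

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(a).shape
            for a in (self.navigator, self.static_at_nav, self.static_at_target, self.label)
        }
        if len(shapes) != 1:
            raise ValueError(f"all four images must share one shape, got {shapes}")


@dataclass
class NormParams:
    """Per-subject pooled intensity statistics for z-score (de)normalization."""

    mean: float
    std: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError(f"NormParams.std must be > 0, got {self.std}")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def zscore_normalize(
    images: np.ndarray | Sequence[np.ndarray], subject_id: str = ""
) -> tuple[np.ndarray | list[np.ndarray], NormParams]:
    """Whiten image intensities pooled over all of a subject's images.

    Returns the normalized image(s) (zero pooled mean, unit pooled std) and the
    original statistics so the mapping can be reversed after prediction.
    """
    single = isinstance(images, np.ndarray)
    arrs = [np.asarray(images, dtype=np.float64)] if single else [
        np.asarray(a, dtype=np.float64) for a in images
    ]
    if not arrs:
        raise ValueError("need at least one image")
    pooled = np.concatenate([a.ravel() for a in arrs])
    if pooled.size == 0 or not np.all(np.isfinite(pooled)):
        raise ValueError("images must contain finite voxels")
    mean = float(pooled.mean())
    std = float(pooled.std())
    if std == 0.0:
        raise ValueError("degenerate intensity distribution: all voxels equal")
    params = NormParams(mean=mean, std=std, subject_id=subject_id)
    out = [(a - mean) / std for a in arrs]
    return (out[0] if single else out), params


def denormalize(
    normalized: np.ndarray | Sequence[np.ndarray], params: NormParams
) -> np.ndarray | list[np.ndarray]:
    """Invert :func:`zscore_normalize` (``x * std + mean``)."""
    if params is None:
        raise ValueError("NormParams required to denormalize")
    if not params.std > 0:
        raise ValueError("NormParams.std must be > 0")
    if isinstance(normalized, np.ndarray):
        return np.asarray(normalized, dtype=np.float64) * params.std + params.mean
    return [np.asarray(a, dtype=np.float64) * params.std + params.mean for a in normalized]


# ---------------------------------------------------------------------------
# acquisition-budget conversion
# ---------------------------------------------------------------------------

def minutes_to_pairs(minutes: float) -> int:
    """Convert an acquisition budget in minutes to navigator/data pairs.

    A "sample" is one acquired 2D slice; a training pair consumes two slices
    (navigator + data) at 166 ms each, giving 180 pairs per minute.
    """
    if not minutes > 0:
        raise ValueError(f"minutes must be positive, got {minutes}")
    return int(round(minutes * SLICES_PER_MINUTE / 2))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_volume(vol: Volume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected a rank-3 NIfTI volume, got rank {data.ndim} from {path}"
        )
    zooms = img.header.get_zooms()[:3]
    return Volume(voxels=np.asarray(data, dtype=np.float64), spacing=tuple(zooms))


def write_sequence(seq: SliceSequence, path: str | Path, spacing: float = 1.8) -> Path:
    """Store a 2D+t sequence as 4D NIfTI plus a role/position sidecar JSON."""
    path = Path(path)
    stack = np.stack([np.asarray(f, dtype=np.float32) for f in seq.frames], axis=-1)
    stack = stack[:, :, None, :]  # (SI, AP, 1, T)
    img = nib.Nifti1Image(stack, _affine((spacing, spacing, spacing)))
    nib.save(img, str(path))
    sidecar = {
        "roles": seq.roles,
        "slice_positions": [int(p) for p in seq.slice_positions],
        "timestamps_s": [float(t) for t in seq.timestamps_s],
        "navigator_position": int(seq.navigator_position),
    }
    sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii.gz/.nii
    sidecar_path = Path(str(sidecar_path) + ".json")
    sidecar_path.write_text(json.dumps(sidecar))
    return path


def read_sequence(path: str | Path) -> SliceSequence:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a rank-4 NIfTI sequence, got rank {data.ndim}")
    sidecar_path = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    meta = json.loads(sidecar_path.read_text())
    frames = [np.asarray(data[:, :, 0, t], dtype=np.float64) for t in range(data.shape[3])]
    return SliceSequence(
        frames=frames,
        timestamps_s=np.asarray(meta["timestamps_s"]),
        roles=list(meta["roles"]),
        slice_positions=list(meta["slice_positions"]),
        navigator_position=int(meta["navigator_position"]),
    )


def load_subject_dir(path: str | Path):
    """Load one subject directory written by the simulator CLI.

    Expects ``static.nii.gz``, ``liver_mask.nii.gz`` and any number of
    ``sequence_*.nii.gz`` with sidecar JSON. Returns ``(static, mask,
    samples, norm)`` where samples pair each navigator with its data slice
    and the static conditioning slices, and norm holds the subject's pooled
    intensity statistics (dynamic frames plus static volume).
    """
    path = Path(path)
    static = read_volume(path / "static.nii.gz")
    mask = read_volume(path / "liver_mask.nii.gz").voxels > 0.5
    samples: list[TrainingSample] = []
    dynamics: list[np.ndarray] = []
    for seq_path in sorted(path.glob("sequence_*.nii.gz")):
        seq = read_sequence(seq_path)
        nav_static = static.voxels[seq.navigator_position].T
        for navigator, label, pos, _t in seq.pairs():
            samples.append(
                TrainingSample(
                    navigator=navigator,
                    static_at_nav=nav_static.copy(),
                    static_at_target=static.voxels[pos].T.copy(),
                    label=label,
                    target_position=pos,
                    subject_id=path.name,
                )
            )
            dynamics += [navigator, label]
    if not samples:
        raise ValueError(f"no sequences found under {path}")
    _, norm = zscore_normalize(dynamics + [static.voxels], path.name)
    return static, mask, samples, norm
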