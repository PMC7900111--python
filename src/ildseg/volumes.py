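"""Study containers, NIfTI IO, intensity normalization and 2.5D slab extraction.

A :class:`MultisequenceStudy` holds one subject's S co-registered 3D
volumes plus a binary lesion ground truth and a brain mask, all on one
grid.  Slices are axial along the third array axis; the network consumes
:class:`SlabStack` inputs — k contiguous slices of every sequence stacked
channel-wise (S·k channels, e.g. 4 sequences × 5 slices = 20 channels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .ild import AvailabilityPattern

__all__ = [
    "MultisequenceStudy",
    "SlabStack",
    "ZeroVarianceError",
    "read_study",
    "write_study",
    "normalize_study",
    "extract_slab",
    "write_manifest",
    "read_manifest",
    "load_study_from_manifest_row",
]


class ZeroVarianceError(ValueError):
    """An available sequence has (numerically) zero variance inside the brain mask."""


@dataclass
class MultisequenceStudy:
    """One subject: S co-registered volumes + lesion ground truth + brain mask.

    ``volumes`` has shape (S, X, Y, Z); masks have shape (X, Y, Z).  Every
    ground-truth voxel must lie inside the brain mask.
    """

    volumes: np.ndarray
    sequence_names: tuple[str, ...]
    voxel_spacing: tuple[float, float, float]
    ground_truth: np.ndarray
    brain_mask: np.ndarray
    availability: AvailabilityPattern | None = None
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=np.float32)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must have shape (S, X, Y, Z)")
        self.ground_truth = np.asarray(self.ground_truth).astype(bool)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        self.sequence_names = tuple(self.sequence_names)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.sequence_names) != self.volumes.shape[0]:
            raise ValueError("one name per sequence required")
        if self.ground_truth.shape != self.grid_shape or self.brain_mask.shape != self.grid_shape:
            raise ValueError("masks must share the volume grid shape")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.ground_truth & ~self.brain_mask):
            raise ValueError("ground truth extends outside the brain mask")
        if self.availability is not None and self.availability.n_sequences != self.n_sequences:
            raise ValueError("availability pattern length must equal S")

    @property
    def n_sequences(self) -> int:
        return self.volumes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    @property
    def n_slices(self) -> int:
        return self.volumes.shape[3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def pattern(self) -> AvailabilityPattern:
        if self.availability is not None:
            return self.availability
        return AvailabilityPattern.all_available(self.n_sequences)


@dataclass
class SlabStack:
    """2.5D network input: k slices of each of S sequences, channel-first.

    ``values`` has shape (C, H, W) with C = S·k; channels [s·k, (s+1)·k)
    hold sequence s's k contiguous slices in ascending slice order, so the
    center channel of each block is the slice being predicted.
    """

    values: np.ndarray
    center_index: int
    pattern: AvailabilityPattern
    slab_half_width: int = 2

    @property
    def slab_width(self) -> int:
        return 2 * self.slab_half_width + 1

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_sequences(self) -> int:
        return self.n_channels // self.slab_width


def extract_slab(study: MultisequenceStudy, z: int, slab_half_width: int = 2) -> SlabStack:
    """Build the S·k-channel stack centered at axial slice ``z``.

    Out-of-range slices at the volume boundary are edge-replicated rather
    than zero-filled, so boundary slabs do not mimic sequence dropout.
    """
    depth = study.n_slices
    if not 0 <= z < depth:
        raise IndexError(f"slice {z} out of range [0, {depth})")
    k = 2 * slab_half_width + 1
    idx = np.clip(np.arange(z - slab_half_width, z + slab_half_width + 1), 0, depth - 1)
    # (S, X, Y, k) -> (S, k, X, Y) -> (S*k, X, Y)
    block = np.moveaxis(study.volumes[:, :, :, idx], 3, 1)
    values = np.ascontiguousarray(block).reshape(
        study.n_sequences * k, *study.grid_shape[:2]
    )
    return SlabStack(
        values=values,
        center_index=z,
        pattern=study.pattern(),
        slab_half_width=slab_half_width,
    )


def normalize_study(study: MultisequenceStudy) -> MultisequenceStudy:
    """Z-score each available sequence over brain-mask voxels.

    Unavailable (or identically zero) sequences are left untouched so
    their zeros coincide with the masked-mean background level of the
    normalized data.  Idempotent: normalizing twice is the identity.
    """
    if not study.brain_mask.any():
        raise ValueError("brain mask is empty")
    avail = study.pattern().available
    volumes = study.volumes.copy()
    for s in range(study.n_sequences):
        vol = volumes[s]
        if not avail[s] or not np.any(vol):
            continue
        inside = vol[study.brain_mask].astype(np.float64)
        mean, sd = inside.mean(), inside.std()
        if sd < 1e-8 * max(1.0, abs(mean)):
            raise ZeroVarianceError(
                f"sequence {study.sequence_names[s]!r} has zero variance in the brain mask"
            )
        volumes[s] = ((vol - mean) / sd).astype(np.float32)
    return replace(study, volumes=volumes)


# ---------------------------------------------------------------------------
# NIfTI IO


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_study(study: MultisequenceStudy, out_dir: str | Path, sidecar: dict | None = None) -> dict:
    """Write one NIfTI per sequence plus ground_truth / brain_mask and a JSON sidecar.

    Returns a dict of written paths keyed by sequence name (plus
    ``ground_truth`` and ``brain_mask``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_spacing)
    paths: dict[str, str] = {}
    for s, name in enumerate(study.sequence_names):
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(study.volumes[s].astype(np.float32), aff), p)
        paths[name] = str(p)
    for key, arr in (("ground_truth", study.ground_truth), ("brain_mask", study.brain_mask)):
        p = out / f"{key}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.uint8), aff), p)
        paths[key] = str(p)
    meta = {
        "subject_id": study.subject_id,
        "sequence_names": list(study.sequence_names),
        "voxel_spacing": list(study.voxel_spacing),
        "availability": study.pattern().to_string(),
    }
    if sidecar:
        meta.update(sidecar)
    (out / "study.json").write_text(json.dumps(meta, indent=2))
    return paths


def read_study(
    sequence_paths: Sequence[str | Path | None],
    gt_path: str | Path,
    mask_path: str | Path,
    sequence_names: Sequence[str] | None = None,
    availability: AvailabilityPattern | None = None,
    spacing_tol: float = 1e-3,
    subject_id: str = "subject",
) -> MultisequenceStudy:
    """Load a study from per-sequence NIfTI files.

    Sequences declared unavailable (pattern bit 0, or a ``None`` path) are
    not read; their volumes are zero-filled.  A missing file for an
    *available* sequence is an error.  All files must agree on grid shape
    and voxel spacing within ``spacing_tol`` — co-registration itself is
    assumed to have happened upstream.
    """
    n_seq = len(sequence_paths)
    if availability is None:
        availability = AvailabilityPattern(
            available=tuple(p is not None for p in sequence_paths)
        )
    if availability.n_sequences != n_seq:
        raise ValueError("availability pattern length must match the number of sequences")

    ref_shape: tuple[int, ...] | None = None
    ref_spacing: np.ndarray | None = None

    def load(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
        nonlocal ref_shape, ref_spacing
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        spacing = np.asarray(nib.affines.voxel_sizes(img.affine))
        if ref_shape is None:
            ref_shape, ref_spacing = arr.shape, spacing
        else:
            if arr.shape != ref_shape:
                raise ValueError(f"{path}: shape {arr.shape} != {ref_shape}")
            if np.any(np.abs(spacing - ref_spacing) > spacing_tol):
                raise ValueError(f"{path}: voxel spacing {spacing} != {ref_spacing}")
        return np.asarray(arr), spacing

    loaded: dict[int, np.ndarray] = {}
    for s in range(n_seq):
        if not availability.available[s]:
            continue
        path = sequence_paths[s]
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"available sequence {s} has no file: {path}")
        loaded[s], _ = load(path)
    gt, _ = load(gt_path)
    mask, _ = load(mask_path)

    assert ref_shape is not None and ref_spacing is not None
    volumes = np.zeros((n_seq, *ref_shape), dtype=np.float32)
    for s, arr in loaded.items():
        volumes[s] = arr.astype(np.float32)
    if sequence_names is None:
        sequence_names = tuple(f"seq{s}" for s in range(n_seq))
    return MultisequenceStudy(
        volumes=volumes,
        sequence_names=tuple(sequence_names),
        voxel_spacing=tuple(float(x) for x in ref_spacing),
        ground_truth=gt,
        brain_mask=mask,
        availability=availability,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Manifests


def write_manifest(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write a CSV manifest: one row per subject with file paths and availability."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"availability": str})
    required = {"subject", "ground_truth", "brain_mask"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    return df


def load_study_from_manifest_row(
    row: pd.Series, availability: AvailabilityPattern | None = None
) -> MultisequenceStudy:
    """Load one subject from a manifest row (columns ``path_<seqname>``)."""
    seq_cols = [c for c in row.index if c.startswith("path_")]
    names = tuple(c[len("path_") :] for c in seq_cols)
    paths = [row[c] if isinstance(row[c], str) and row[c] else None for c in seq_cols]
    if availability is None and "availability" in row.index and isinstance(row["availability"], str):
        availability = AvailabilityPattern.from_string(row["availability"])
    return read_study(
        paths,
        row["ground_truth"],
        row["brain_mask"],
        sequence_names=names,
        availability=availability,
        subject_id=str(row["subject"]),
    )
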