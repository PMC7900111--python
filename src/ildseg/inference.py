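"""Whole-volume prediction under a declared availability pattern."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .ild import AvailabilityPattern, apply_input_dropout
from .network import SegmentationModel
from .volumes import MultisequenceStudy, extract_slab, normalize_study

__all__ = ["ProbabilityMap", "predict_volume", "binarize", "write_probability_map"]


@dataclass
class ProbabilityMap:
    """Voxel-wise lesion probability in [0, 1], on the study grid."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]
    pattern: AvailabilityPattern
    model_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("probability map must be 3D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def predict_volume(
    model: SegmentationModel,
    study: MultisequenceStudy,
    pattern: AvailabilityPattern | None = None,
    batch_size: int = 8,
) -> ProbabilityMap:
    """Predict every axial slice and assemble the 3D probability map.

    Each slice's slab is zero-filled and 1/(1-p)-upweighted according to
    the declared pattern — the same operation used in training — so a
    sequence can be "missing" either physically (zeroed volume, pattern
    recorded on the study) or by declaration here; both give identical
    maps.  Deterministic given the model and inputs.
    """
    if pattern is None:
        pattern = study.pattern()
    if pattern.n_sequences != study.n_sequences:
        raise ValueError("pattern length must match the study's sequence count")
    k_total = model.config.in_channels
    if k_total % study.n_sequences != 0:
        raise ValueError(
            f"model expects {k_total} channels; not a multiple of S={study.n_sequences}"
        )
    k = k_total // study.n_sequences
    half = (k - 1) // 2

    normalized = normalize_study(study)
    depth = study.n_slices
    out = np.zeros(study.grid_shape, dtype=np.float32)
    for start in range(0, depth, batch_size):
        zs = range(start, min(start + batch_size, depth))
        slabs = []
        for z in zs:
            slab = extract_slab(normalized, z, slab_half_width=half)
            slabs.append(apply_input_dropout(slab, pattern).values)
        probs = model.predict_proba(np.stack(slabs))[:, 0]
        for i, z in enumerate(zs):
            out[:, :, z] = probs[i]
    return ProbabilityMap(
        values=out,
        voxel_spacing=study.voxel_spacing,
        pattern=pattern,
        model_id=model.model_id,
    )


def binarize(prob_map: ProbabilityMap | np.ndarray, threshold: float) -> np.ndarray:
    """Voxel included iff probability >= threshold (closed lower bound)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = prob_map.values if isinstance(prob_map, ProbabilityMap) else np.asarray(prob_map)
    return values >= threshold


def write_probability_map(prob_map: ProbabilityMap, path: str | Path) -> None:
    aff = np.diag([*prob_map.voxel_spacing, 1.0])
    nib.save(nib.Nifti1Image(prob_map.values.astype(np.float32), aff), str(path))
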