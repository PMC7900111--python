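"""Synthetic multisequence brain phantoms with known lesion masks.

Each phantom emulates the features of a contrast-enhanced metastasis
study that the downstream pipeline actually exercises: S co-registered
contrasts over a smooth two-tissue background inside an ellipsoidal
brain mask, a handful of ellipsoidal enhancing lesions spanning the
size filter's range, curvilinear vessel-like bright confounders that
are visible on only some sequences (mimicking the difference between
vessel-suppressed fast-spin-echo contrasts and gradient-echo contrasts,
the classic source of false positives), and additive Gaussian noise.
Everything is driven by a single seed and is bit-reproducible.

The default contrast design (sequence -> lesion contrast / vessel
contrast):

======== =================== ======= =======
index    role                lesion  vessel
======== =================== ======= =======
0        post-Gd T1 FSE      1.2     0.0
1        post-Gd T1 GRE      0.9     1.0
2        FLAIR (FSE)         0.5     0.0
3        pre-Gd T1 GRE       0.1     0.8
======== =================== ======= =======

Sequence 0 is the cleanest, strongest lesion contrast — and the one a
"site missing a sequence" scenario drops, so a model that leans on it
exclusively has a learnable reason to fail, while the vessel-free FLAIR
and the vessel-confounded post-Gd GRE remain informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .ild import AvailabilityPattern
from .volumes import MultisequenceStudy, write_study, write_manifest

__all__ = [
    "PhantomConfig",
    "PlacementError",
    "generate_phantom",
    "degrade_study",
    "generate_cohort",
    "DEFAULT_SEQUENCE_NAMES",
]

DEFAULT_SEQUENCE_NAMES = ("t1c_fse", "t1c_gre", "flair", "t1_pre")


class PlacementError(RuntimeError):
    """Lesions could not be placed inside the brain mask after bounded retries."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic study.

    Contrasts are signal offsets relative to the background tissue, in the
    same arbitrary units as the tissue levels (gray 0.45 / white 0.65);
    radii and spacing are in mm.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_sequences: int = 4
    lesion_count_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (2.5, 6.0)
    lesion_contrast: tuple[float, ...] = (1.2, 0.9, 0.5, 0.1)
    vessel_count: int = 3
    vessel_contrast: tuple[float, ...] = (0.0, 1.0, 0.0, 0.8)
    noise_sd: float = 0.15
    seed: int = 0
    sequence_names: tuple[str, ...] = DEFAULT_SEQUENCE_NAMES

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.lesion_count_range[0] < 1 or self.lesion_count_range[1] < self.lesion_count_range[0]:
            raise ValueError("lesion_count_range lower bound must be >= 1")
        if self.lesion_radius_range[0] <= 0 or self.lesion_radius_range[1] < self.lesion_radius_range[0]:
            raise ValueError("lesion_radius_range must be a positive interval")
        if self.vessel_count < 0 or self.noise_sd < 0:
            raise ValueError("vessel_count and noise_sd must be nonnegative")
        for name, vec in (("lesion_contrast", self.lesion_contrast),
                          ("vessel_contrast", self.vessel_contrast)):
            if len(vec) != self.n_sequences:
                raise ValueError(f"{name} must have one entry per sequence")
        if len(self.sequence_names) != self.n_sequences:
            raise ValueError("sequence_names must have one entry per sequence")


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned ellipsoid inscribed in the grid (semi-axes 0.46·extent)."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    semi = [max(0.46 * n, 1.0) for n in shape]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return q <= 1.0


def _background(shape, rng: np.random.Generator) -> np.ndarray:
    """Two smooth tissue classes: low-pass noise thresholded at its median."""
    field3 = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    tissue = np.where(field3 > np.median(field3), 0.65, 0.45)
    return gaussian_filter(tissue, sigma=0.5)


def _rasterize_ellipsoid(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return q <= 1.0


def _place_lesions(cfg: PhantomConfig, mask: np.ndarray, rng: np.random.Generator,
                   max_retries: int = 100) -> np.ndarray:
    n = int(rng.integers(cfg.lesion_count_range[0], cfg.lesion_count_range[1] + 1))
    extent = [g * s for g, s in zip(cfg.grid_shape, cfg.voxel_spacing)]
    lesions = np.zeros(cfg.grid_shape, dtype=bool)
    lo, hi = cfg.lesion_radius_range
    for _ in range(n):
        for attempt in range(max_retries):
            radii = rng.uniform(lo, hi, size=3)
            if any(2 * r > e for r, e in zip(radii, extent)):
                continue  # cannot fit along some axis; counts as a failed attempt
            center = rng.uniform([r for r in radii], [e - r for e, r in zip(extent, radii)])
            les = _rasterize_ellipsoid(cfg.grid_shape, cfg.voxel_spacing, center, radii)
            if les.any() and not np.any(les & ~mask):
                lesions |= les
                break
        else:
            raise PlacementError(
                f"could not place a lesion of radius in [{lo}, {hi}] mm inside the "
                f"brain mask after {max_retries} attempts; grid too small?"
            )
    return lesions


def _trace_vessels(cfg: PhantomConfig, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Curvilinear tubes: persistent random walks stamped with ~1 mm balls."""
    vessels = np.zeros(cfg.grid_shape, dtype=bool)
    shape = np.asarray(cfg.grid_shape, dtype=float)
    spacing = np.asarray(cfg.voxel_spacing)
    n_steps = int(2 * max(cfg.grid_shape))
    # ~1.5 mm-radius stamp around each walk position
    offs = np.argwhere(np.ones((3, 3, 3))) - 1
    ball_offsets = offs[np.linalg.norm(offs * spacing, axis=1) <= 1.5]
    inside = np.argwhere(mask)
    for _ in range(cfg.vessel_count):
        pos = inside[rng.integers(len(inside))].astype(float)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        for _ in range(n_steps):
            direction += 0.35 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
            ijk = np.round(pos).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= shape) or not mask[tuple(ijk)]:
                break
            stamp = ijk + ball_offsets
            sel = stamp[np.all((stamp >= 0) & (stamp < shape), axis=1)]
            vessels[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return vessels & mask


def generate_phantom(config: PhantomConfig) -> MultisequenceStudy:
    """Generate one study: background + lesions + vessels + noise, fully seeded.

    The ground truth is exactly the union of the lesion ellipsoids;
    vessels never contribute to it (their voxels are carved out of the
    vessel indicator wherever a lesion already is).
    """
    rng = np.random.default_rng(config.seed)
    mask = _brain_mask(config.grid_shape)
    background = _background(config.grid_shape, rng)
    lesions = _place_lesions(config, mask, rng)
    vessels = _trace_vessels(config, mask, rng) & ~lesions

    volumes = np.zeros((config.n_sequences, *config.grid_shape), dtype=np.float32)
    for s in range(config.n_sequences):
        vol = background.copy()
        vol += config.lesion_contrast[s] * lesions
        vol += config.vessel_contrast[s] * vessels
        if config.noise_sd > 0:
            vol = vol + config.noise_sd * rng.standard_normal(config.grid_shape)
        volumes[s] = np.where(mask, vol, 0.0)

    return MultisequenceStudy(
        volumes=volumes,
        sequence_names=config.sequence_names,
        voxel_spacing=config.voxel_spacing,
        ground_truth=lesions,
        brain_mask=mask,
        subject_id=f"phantom-{config.seed}",
    )


def degrade_study(study: MultisequenceStudy, pattern: AvailabilityPattern) -> MultisequenceStudy:
    """Simulate a site missing sequences: zero their volumes, record the pattern."""
    if pattern.n_sequences != study.n_sequences:
        raise ValueError("pattern length must equal the study's sequence count")
    volumes = study.volumes.copy()
    for s in pattern.dropped_indices:
        volumes[s] = 0.0
    return MultisequenceStudy(
        volumes=volumes,
        sequence_names=study.sequence_names,
        voxel_spacing=study.voxel_spacing,
        ground_truth=study.ground_truth,
        brain_mask=study.brain_mask,
        availability=pattern,
        subject_id=study.subject_id,
    )


def generate_cohort(
    config: PhantomConfig,
    n_subjects: int,
    out_dir: str | Path,
    manifest_name: str = "manifest.csv",
):
    """Write ``n_subjects`` phantoms (per-subject derived seeds) plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(n_subjects) % (2**31)
    rows = []
    for i in range(n_subjects):
        sub_cfg = PhantomConfig(**{**config.__dict__, "seed": int(seeds[i])})
        study = generate_phantom(sub_cfg)
        study.subject_id = f"sub-{i:03d}"
        paths = write_study(study, out / study.subject_id,
                            sidecar={"phantom_seed": int(seeds[i])})
        row = {"subject": study.subject_id}
        for name in config.sequence_names:
            row[f"path_{name}"] = paths[name]
        row["ground_truth"] = paths["ground_truth"]
        row["brain_mask"] = paths["brain_mask"]
        row["availability"] = "1" * config.n_sequences
        rows.append(row)
    return write_manifest(rows, out / manifest_name)
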