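"""Synthetic resting-state cohorts with planted networks and a group effect.

The generator emulates the structure that seed-based connectivity analysis
assumes: each subject's 4-D BOLD volume is a linear mixture of a small number
of spatially smooth networks whose in-network voxels covary over time,

    bold(v, t) = sum_k  c_k * a_k(v) * s_k(t)  +  sigma * eps(v, t),

where ``a_k`` is a smooth, unit-norm spatial loading map, ``s_k`` an AR(1)
temporal course, ``c_k`` a per-subject coupling strength and ``eps`` white
Gaussian observation noise.  One shared network contains every seed sphere;
each seed additionally sits inside its own satellite network, so different
seeds produce overlapping but distinct connectivity maps.  A group contrast is
planted by shifting the coupling of selected components in group 2 by
``effect_size * noise_sigma``, split across components according to
``effect_weights``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .connectivity import SeedSpec

GROUP1 = "group1"
GROUP2 = "group2"

#: Default seed hubs on the reduced grid, expressed as fractions of the grid
#: shape (anterior midline, posterior midline, left and right parietal --
#: the MPFC / PCC / LLP / RLP arrangement of the default mode network).
_SEED_FRACTIONS = {
    "MPFC": (0.50, 0.78, 0.55),
    "PCC": (0.50, 0.34, 0.60),
    "LLP": (0.24, 0.46, 0.50),
    "RLP": (0.76, 0.46, 0.50),
}


@dataclass
class SubjectScan:
    """One subject's 4-D BOLD volume plus mask and group label."""

    subject_id: str
    bold: np.ndarray  # (x, y, z, t)
    mask: np.ndarray  # (x, y, z) boolean
    group: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def t_len(self) -> int:
        return self.bold.shape[-1]

    def __post_init__(self) -> None:
        if self.bold.ndim != 4:
            raise ValueError("bold must be 4-D (x, y, z, t)")
        if self.mask.shape != self.bold.shape[:3]:
            raise ValueError(
                f"mask grid {self.mask.shape} != bold grid {self.bold.shape[:3]}"
            )
        if not np.any(self.mask):
            raise ValueError("mask has no nonzero voxel")


@dataclass
class GroundTruth:
    """The generative state behind a synthetic cohort.

    ``spatial_components`` holds the k_true unit-norm loading vectors over
    in-mask voxels (rows), with ``voxel_index`` giving the (3, V) in-mask
    coordinates they refer to.  ``subject_couplings`` is (n_subjects, k_true);
    ``temporal_courses`` is (n_subjects, k_true, t_len).
    """

    spatial_components: np.ndarray
    temporal_courses: np.ndarray
    subject_couplings: np.ndarray
    group_effect: float
    noise_sigma: float
    voxel_index: np.ndarray
    effect_weights: dict[int, float]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the target study design: 18 subjects per group and 130
    retained time points, on a reduced 20x24x20 grid (the full 91x109x91
    grid remains available through this same field).
    """

    n_per_group: int = 18
    grid: tuple[int, int, int] = (20, 24, 20)
    t_len: int = 130
    k_true: int = 5
    seeds: list[SeedSpec] | None = None
    effect_size: float = 1.0
    noise_sigma: float = 1.0
    coupling_mean: float = 4.0
    coupling_sd: float = 0.8
    ar_coef: float = 0.3
    smooth_sigma: float = 1.2
    seed_radius: float = 2.0
    effect_weights: dict[int, float] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.t_len < 2:
            raise ValueError("t_len must be >= 2")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if len(self.grid) != 3 or any(g < 4 for g in self.grid):
            raise ValueError(f"grid {self.grid} too small (need >= 4 per axis)")

    def resolved_seeds(self) -> list[SeedSpec]:
        if self.seeds is not None:
            return list(self.seeds)
        return default_seeds(self.grid, radius=self.seed_radius)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        if self.seeds is not None:
            d["seeds"] = [dataclasses.asdict(s) for s in self.seeds]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["grid"] = tuple(d["grid"])
        if d.get("seeds") is not None:
            d["seeds"] = [SeedSpec(**s) for s in d["seeds"]]
        if d.get("effect_weights") is not None:
            d["effect_weights"] = {int(k): float(v) for k, v in d["effect_weights"].items()}
        return cls(**d)


def default_seeds(grid: tuple[int, int, int], radius: float = 2.0) -> list[SeedSpec]:
    """Four DMN-hub seed spheres scaled to the given grid (voxel space)."""
    out = []
    for name, frac in _SEED_FRACTIONS.items():
        center = tuple(float(round(f * (g - 1))) for f, g in zip(frac, grid))
        out.append(SeedSpec(name=name, center=center, radius=radius, space="voxel"))
    return out


def _ellipsoid_mask(grid: tuple[int, int, int]) -> np.ndarray:
    """Brain-like ellipsoid occupying most of the grid."""
    axes = [np.arange(g) for g in grid]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    c = [(g - 1) / 2.0 for g in grid]
    semi = [max(g / 2.0 - 0.5, 1.0) for g in grid]
    r2 = (
        ((xx - c[0]) / semi[0]) ** 2
        + ((yy - c[1]) / semi[1]) ** 2
        + ((zz - c[2]) / semi[2]) ** 2
    )
    return r2 <= 1.0


def _sphere(grid: tuple[int, int, int], center, radius: float) -> np.ndarray:
    axes = [np.arange(g) for g in grid]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return d2 <= radius**2


def _check_seed_geometry(cfg: CohortConfig, seeds: list[SeedSpec], mask: np.ndarray) -> None:
    occupied = np.zeros(cfg.grid, dtype=bool)
    for s in seeds:
        sph = _sphere(cfg.grid, s.center, max(s.radius, 0.0)) & mask
        if not sph.any():
            raise ValueError(f"grid {cfg.grid} too small: seed {s.name!r} lies outside the mask")
        if (sph & occupied).any():
            raise ValueError(
                f"grid {cfg.grid} too small to contain all seed spheres disjointly "
                f"(seed {s.name!r} overlaps another seed)"
            )
        occupied |= sph


def _spatial_components(
    cfg: CohortConfig, seeds: list[SeedSpec], mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Build k_true smooth unit-norm loading maps over in-mask voxels.

    Component 0 is the shared network: the union of spheres around every seed.
    Components 1..n_seeds are seed-specific satellites centred on each seed.
    Any further components are background blobs at random in-mask locations.
    """
    grid = cfg.grid
    n_seeds = len(seeds)
    supports = []
    shared = np.zeros(grid, dtype=bool)
    for s in seeds:
        shared |= _sphere(grid, s.center, s.radius + 1.5)
    supports.append(shared)
    for s in seeds[: max(cfg.k_true - 1, 0)]:
        supports.append(_sphere(grid, s.center, s.radius + 2.5))
    in_mask = np.argwhere(mask)
    while len(supports) < cfg.k_true:
        c = in_mask[rng.integers(len(in_mask))]
        supports.append(_sphere(grid, c, cfg.seed_radius + 2.0))
    supports = supports[: cfg.k_true]

    comps = []
    for sup in supports:
        vol = gaussian_filter(sup.astype(float), sigma=cfg.smooth_sigma)
        vec = vol[mask]
        nrm = np.linalg.norm(vec)
        if nrm == 0:
            raise ValueError("a planted component has no support inside the mask")
        comps.append(vec / nrm)
    return np.asarray(comps)


def _ar1(rng: np.random.Generator, n: int, t: int, phi: float) -> np.ndarray:
    """n AR(1) series of length t with unit marginal variance."""
    eps = rng.standard_normal((n, t))
    out = np.empty((n, t))
    out[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - phi**2)
    for i in range(1, t):
        out[:, i] = phi * out[:, i - 1] + scale * eps[:, i]
    return out


def generate_cohort(config: CohortConfig) -> tuple[list[SubjectScan], GroundTruth]:
    """Generate ``2 * n_per_group`` scans plus the ground truth behind them.

    Fully deterministic given ``config`` (including ``rng_seed``).  Group 2
    subjects have the couplings of the effect-carrying components shifted by
    ``effect_size * noise_sigma`` (split according to ``effect_weights``,
    default: all on the shared component 0).
    """
    rng = np.random.default_rng(config.rng_seed)
    seeds = config.resolved_seeds()
    mask = _ellipsoid_mask(config.grid)
    _check_seed_geometry(config, seeds, mask)

    comps = _spatial_components(config, seeds, mask, rng)
    voxel_index = np.asarray(np.nonzero(mask))
    k, v = comps.shape

    weights = config.effect_weights if config.effect_weights is not None else {0: 1.0}
    for idx in weights:
        if not 0 <= idx < k:
            raise ValueError(f"effect_weights component {idx} out of range [0, {k})")
    group_effect = config.effect_size * config.noise_sigma

    n = config.n_per_group
    scans: list[SubjectScan] = []
    couplings = np.empty((2 * n, k))
    courses = np.empty((2 * n, k, config.t_len))
    for i in range(2 * n):
        group = GROUP1 if i < n else GROUP2
        c = config.coupling_mean + config.coupling_sd * rng.standard_normal(k)
        if group == GROUP2:
            for idx, w in weights.items():
                c[idx] += group_effect * w
        s = _ar1(rng, k, config.t_len, config.ar_coef)
        signal = (c[:, None] * comps).T @ s  # (V, T)
        bold = np.zeros(config.grid + (config.t_len,), dtype=np.float32)
        bold[mask] = signal
        if config.noise_sigma > 0:
            bold += (
                config.noise_sigma
                * rng.standard_normal(bold.shape).astype(np.float32)
            )
        couplings[i] = c
        courses[i] = s
        scans.append(
            SubjectScan(
                subject_id=f"sub-{i + 1:03d}",
                bold=bold,
                mask=mask.copy(),
                group=group,
            )
        )

    truth = GroundTruth(
        spatial_components=comps,
        temporal_courses=courses,
        subject_couplings=couplings,
        group_effect=group_effect,
        noise_sigma=config.noise_sigma,
        voxel_index=voxel_index,
        effect_weights=dict(weights),
    )
    return scans, truth


def write_cohort(scans: list[SubjectScan], directory: str | os.PathLike) -> pd.DataFrame:
    """Write one NIfTI per subject plus the shared mask; return the manifest.

    The manifest has columns ``subject_id,group,path`` and is also saved as
    ``manifest.csv`` in the directory.  Arrays round-trip bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        path = directory / f"{scan.subject_id}_bold.nii"
        try:
            nib.save(nib.Nifti1Image(scan.bold, scan.affine), path)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed to write {path}: {exc}") from exc
        rows.append({"subject_id": scan.subject_id, "group": scan.group, "path": str(path)})
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "path"])
    if scans:
        mask_path = directory / "mask.nii"
        nib.save(
            nib.Nifti1Image(scans[0].mask.astype(np.uint8), scans[0].affine), mask_path
        )
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_cohort(manifest_path: str | os.PathLike) -> list[SubjectScan]:
    """Load scans from a ``write_cohort`` manifest (mask.nii beside it)."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    mask_img = nib.load(directory / "mask.nii")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    scans = []
    for row in manifest.itertuples():
        img = nib.load(row.path)
        bold = np.asarray(img.dataobj)
        scans.append(
            SubjectScan(
                subject_id=row.subject_id,
                bold=bold,
                mask=mask,
                group=row.group,
                affine=np.asarray(img.affine),
            )
        )
    return scans
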