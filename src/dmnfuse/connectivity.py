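"""Seed-to-voxel functional connectivity maps.

For each subject and seed region the mean BOLD time series over the seed
sphere is correlated (Pearson) with every in-mask voxel time series and the
correlations are Fisher-z transformed, ``z = atanh(r)``, with ``|r|`` clipped
at ``1 - 1e-7`` so self-correlation stays finite.  This is the uniform-weight,
single-condition special case of the weighted GLM connectivity measure used
by resting-state toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import nibabel as nib
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import SubjectScan

R_CLIP = 1.0 - 1e-7

#: Literature-standard MNI (mm) coordinates of the four DMN hubs, for use on
#: real, MNI-normalized data.  Sphere radius 10 mm.  These are a documented
#: package default, not values prescribed by any particular dataset.
MNI_DMN_SEEDS_MM = {
    "MPFC": (0.0, 52.0, -6.0),
    "PCC": (0.0, -53.0, 26.0),
    "LLP": (-48.0, -62.0, 36.0),
    "RLP": (48.0, -62.0, 36.0),
}


@dataclass
class SeedSpec:
    """A named spherical seed region.

    ``space`` flags whether ``center``/``radius`` are voxel indices (0-based)
    or millimetres interpreted through the scan's NIfTI affine.  Radius 0
    denotes a single-voxel seed.
    """

    name: str
    center: tuple[float, float, float]
    radius: float
    space: str = "voxel"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"seed {self.name!r}: radius must be >= 0")
        if self.space not in ("voxel", "mm"):
            raise ValueError(f"seed {self.name!r}: space must be 'voxel' or 'mm'")
        self.center = tuple(float(c) for c in self.center)


def mni_default_seeds(radius: float = 10.0) -> list[SeedSpec]:
    """The four canonical DMN hub seeds in MNI mm space."""
    return [SeedSpec(n, c, radius, space="mm") for n, c in MNI_DMN_SEEDS_MM.items()]


@dataclass
class ConnectivityMap:
    """Fisher-z connectivity of one (subject, seed) pair over mask voxels."""

    subject_id: str
    seed_name: str
    values: np.ndarray  # (V,)
    voxel_index: np.ndarray  # (3, V) in-mask voxel coordinates


@dataclass
class MapTable:
    """Connectivity maps for a cohort, on one shared voxel ordering.

    ``data`` is (n_subjects, n_seeds, V); rows follow ``subjects`` and the
    seed axis follows ``seed_names``.
    """

    subjects: list[str]
    groups: list[str]
    seed_names: list[str]
    voxel_index: np.ndarray
    data: np.ndarray

    def get(self, subject_id: str, seed_name: str) -> ConnectivityMap:
        try:
            i = self.subjects.index(subject_id)
        except ValueError:
            raise KeyError(f"no maps for subject {subject_id!r}") from None
        try:
            j = self.seed_names.index(seed_name)
        except ValueError:
            raise KeyError(
                f"no map for subject {subject_id!r}, seed {seed_name!r}"
            ) from None
        return ConnectivityMap(subject_id, seed_name, self.data[i, j], self.voxel_index)

    def __len__(self) -> int:
        return self.data.shape[0] * self.data.shape[1]


def _seed_voxels(scan: "SubjectScan", seed: SeedSpec) -> np.ndarray:
    """(3, n) coordinates of in-mask voxels inside the seed sphere."""
    coords = np.asarray(np.nonzero(scan.mask), dtype=float)  # (3, V)
    if seed.space == "mm":
        homo = np.vstack([coords, np.ones(coords.shape[1])])
        coords_ref = (scan.affine @ homo)[:3]
        center = np.asarray(seed.center)
    else:
        coords_ref = coords
        center = np.asarray(seed.center)
    d2 = ((coords_ref - center[:, None]) ** 2).sum(axis=0)
    inside = d2 <= seed.radius**2 + 1e-12
    if not inside.any():
        raise ValueError(f"seed {seed.name!r} does not intersect the mask")
    return np.asarray(np.nonzero(scan.mask))[:, inside]


def extract_seed_timeseries(scan: "SubjectScan", seed: SeedSpec) -> np.ndarray:
    """Unweighted mean time series over the in-mask voxels of the seed sphere."""
    vox = _seed_voxels(scan, seed)
    series = scan.bold[vox[0], vox[1], vox[2], :]
    return series.mean(axis=0)


def _fisher_z_correlation(seed_ts: np.ndarray, voxel_ts: np.ndarray) -> np.ndarray:
    """Clipped Fisher-z Pearson correlation of seed_ts against each row."""
    t = seed_ts.shape[0]
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed time series has zero variance; cannot correlate")
    v = voxel_ts - voxel_ts.mean(axis=1, keepdims=True)
    v_norm = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v @ s) / (v_norm * s_norm)
    r[~np.isfinite(r)] = 0.0  # zero-variance voxels carry no association
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def seed_to_voxel_map(scan: "SubjectScan", seed: SeedSpec) -> ConnectivityMap:
    """Fisher-z map of the seed's mean series against every in-mask voxel."""
    if scan.t_len < 3:
        raise ValueError("need at least 3 time points to correlate")
    seed_ts = extract_seed_timeseries(scan, seed)
    voxel_index = np.asarray(np.nonzero(scan.mask))
    voxel_ts = scan.bold[scan.mask].astype(float)  # (V, T)
    z = _fisher_z_correlation(seed_ts.astype(float), voxel_ts)
    return ConnectivityMap(scan.subject_id, seed.name, z, voxel_index)


class SeedConnectivity(BaseEstimator, TransformerMixin):
    """Transformer turning subject scans into a cohort map table.

    ``fit`` fixes the shared mask and voxel ordering from the first scan;
    ``transform`` computes one Fisher-z map per (subject, seed) pair and
    checks every scan against the fitted mask.
    """

    def __init__(self, seeds: Sequence[SeedSpec] = ()):
        self.seeds = seeds

    def fit(self, scans: Sequence["SubjectScan"], y=None) -> "SeedConnectivity":
        if not scans:
            raise ValueError("need at least one scan")
        if not self.seeds:
            raise ValueError("need at least one seed")
        self.mask_ = scans[0].mask.copy()
        self.voxel_index_ = np.asarray(np.nonzero(self.mask_))
        return self

    def transform(self, scans: Sequence["SubjectScan"]) -> MapTable:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mask_")
        v = self.voxel_index_.shape[1]
        data = np.empty((len(scans), len(self.seeds), v))
        subjects, groups = [], []
        for i, scan in enumerate(scans):
            if scan.mask.shape != self.mask_.shape or not np.array_equal(
                scan.mask, self.mask_
            ):
                raise ValueError(
                    f"subject {scan.subject_id!r}: mask differs from the cohort mask"
                )
            subjects.append(scan.subject_id)
            groups.append(scan.group)
            for j, seed in enumerate(self.seeds):
                data[i, j] = seed_to_voxel_map(scan, seed).values
        return MapTable(
            subjects=subjects,
            groups=groups,
            seed_names=[s.name for s in self.seeds],
            voxel_index=self.voxel_index_.copy(),
            data=data,
        )


def map_cohort(scans: Sequence["SubjectScan"], seeds: Sequence[SeedSpec]) -> MapTable:
    """One Fisher-z map per (subject, seed), all on one shared voxel index."""
    return SeedConnectivity(seeds=seeds).fit(scans).transform(scans)


def map_to_nifti(cmap: ConnectivityMap, grid: tuple[int, int, int], affine=None):
    """Scatter a connectivity vector back into the 3-D grid (0 outside mask)."""
    vol = np.zeros(grid, dtype=np.float32)
    vol[tuple(cmap.voxel_index)] = cmap.values
    return nib.Nifti1Image(vol, np.eye(4) if affine is None else affine)
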