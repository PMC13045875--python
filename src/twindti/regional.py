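"""Tensor scalar maps and atlas-based regional extraction from TBSS skeletons.

Scalar metrics are computed voxelwise from the three ordered tensor
eigenvalues (L1 >= L2 >= L3, mm^2/s):

    AD = L1
    MD = (L1 + L2 + L3) / 3
    RD = (L2 + L3) / 2
    FA = sqrt(3/2) * sqrt(sum_i (L_i - MD)^2) / sqrt(sum_i L_i^2)

Regional extraction averages each skeletonised 4D map over the voxels of
each atlas label, excluding exactly-zero voxels (TBSS writes literal zeros
outside the skeleton projection).  Bilateral regions are kept separate per
hemisphere; regions with no qualifying voxel for a subject yield a missing
value rather than an imputed one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AtlasLabelVolume",
    "tensor_metrics_from_eigenvalues",
    "extract_regional_means",
    "apply_region_exclusions",
    "load_skeleton_maps",
]


@dataclass
class AtlasLabelVolume:
    """Integer label volume plus region names and an exclusion set."""

    labels: np.ndarray  # 3D int array, 0 = background
    label_names: dict[int, str]
    exclusion_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.label_names)
        if unnamed:
            raise ValueError(f"labels without names in volume: {sorted(unnamed)}")
        unknown = set(self.exclusion_set) - set(self.label_names.values())
        if unknown:
            raise ValueError(f"exclusion_set names not in atlas: {sorted(unknown)}")

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        label_names: dict[int, str],
        exclusion_set=frozenset(),
    ) -> "AtlasLabelVolume":
        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        return cls(labels=labels, label_names=label_names, exclusion_set=frozenset(exclusion_set))


def tensor_metrics_from_eigenvalues(
    L1: np.ndarray, L2: np.ndarray, L3: np.ndarray
) -> dict[str, np.ndarray]:
    """FA/MD/AD/RD maps from ordered eigenvalue maps.

    Small negative eigenvalues (numerical noise from tensor fitting) are
    clamped to zero with a warning.  All-zero voxels get FA = 0 by
    convention.
    """
    L1, L2, L3 = (np.asarray(x, dtype=np.float64) for x in (L1, L2, L3))
    if not (L1.shape == L2.shape == L3.shape):
        raise ValueError("eigenvalue maps must share a shape")
    stacked = np.stack([L1, L2, L3])
    if np.any(stacked < 0):
        warnings.warn(
            "negative eigenvalues clamped to 0 before metric computation",
            RuntimeWarning,
            stacklevel=2,
        )
        log.warning("clamped %d negative eigenvalue voxels", int((stacked < 0).sum()))
        stacked = np.clip(stacked, 0.0, None)
        L1, L2, L3 = stacked
    nonzero = stacked.any(axis=0)
    if np.any((stacked[0] < stacked[1]) & nonzero) or np.any(
        (stacked[1] < stacked[2]) & nonzero
    ):
        raise ValueError("eigenvalue ordering L1 >= L2 >= L3 violated")

    MD = (L1 + L2 + L3) / 3.0
    AD = L1.copy()
    RD = (L2 + L3) / 2.0
    num = np.sqrt((L1 - MD) ** 2 + (L2 - MD) ** 2 + (L3 - MD) ** 2)
    den = np.sqrt(L1**2 + L2**2 + L3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        FA = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    FA = np.clip(FA, 0.0, 1.0)
    return {"FA": FA, "MD": MD, "AD": AD, "RD": RD}


def load_skeleton_maps(paths: dict[str, str | Path]) -> tuple[dict[str, np.ndarray], None]:
    """Load per-metric 4D skeletonised NIfTI maps (x, y, z, subject)."""
    maps = {m: np.asarray(nib.load(str(p)).dataobj, dtype=np.float64) for m, p in paths.items()}
    shapes = {m: a.shape for m, a in maps.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"skeleton maps disagree on shape: {shapes}")
    return maps, None


def extract_regional_means(
    maps: dict[str, np.ndarray],
    atlas: AtlasLabelVolume,
    subjects: list[str],
) -> pd.DataFrame:
    """Per-subject regional means of each metric over non-zero labelled voxels.

    Returns a long table (subject_id, region, metric, value); a cell with no
    qualifying voxels is NaN and logged.  Regions in ``atlas.exclusion_set``
    are dropped from the output.
    """
    rows = []
    spatial = atlas.labels.shape
    for metric, vol4 in maps.items():
        vol4 = np.asarray(vol4, dtype=np.float64)
        if vol4.ndim != 4 or vol4.shape[:3] != spatial:
            raise ValueError(
                f"{metric}: map shape {vol4.shape} incompatible with atlas {spatial}"
            )
        if vol4.shape[3] != len(subjects):
            raise ValueError(
                f"{metric}: {vol4.shape[3]} volumes for {len(subjects)} subjects"
            )
        flat = vol4.reshape(-1, vol4.shape[3])
        lab_flat = atlas.labels.ravel()
        for label, region in sorted(atlas.label_names.items()):
            if region in atlas.exclusion_set:
                continue
            vox = flat[lab_flat == label]  # (n_vox, n_subj)
            inside = vox != 0.0  # literal zero = outside skeleton
            counts = inside.sum(axis=0)
            with np.errstate(invalid="ignore"):
                means = np.where(
                    counts > 0, (vox * inside).sum(axis=0) / np.maximum(counts, 1), np.nan
                )
            for subj, m, c in zip(subjects, means, counts):
                if c == 0:
                    log.warning("no skeleton voxels for %s / %s / %s", subj, region, metric)
                rows.append((subj, region, metric, m if c > 0 else np.nan))
    return pd.DataFrame(rows, columns=["subject_id", "region", "metric", "value"])


def apply_region_exclusions(table: pd.DataFrame, exclusion_set) -> pd.DataFrame:
    """Drop the given regions from a long regional table.

    Names absent from the table are skipped with a logged warning rather
    than raising, so a standard exclusion list can be applied to an atlas
    subset.
    """
    exclusion_set = set(exclusion_set)
    present = set(table["region"].unique())
    for name in sorted(exclusion_set - present):
        log.warning("exclusion region %r not present in table; skipped", name)
    if not exclusion_set & present:
        return table.copy()
    return table[~table["region"].isin(exclusion_set)].reset_index(drop=True)
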