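"""Lesion masks, the subjects x voxels matrix, and patch compression.

Binary lesion masks in a shared template grid are stacked into a
subjects x voxels design.  Voxels lesioned in fewer than a minimum number
of subjects (default 5) carry no mappable signal and are dropped; the
surviving columns are then losslessly compressed into *patches* — maximal
sets of voxels with an identical lesioned/intact pattern across subjects.
Patch multiplicities (voxel counts) let downstream kernels reproduce the
full-voxel computation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionMask",
    "LesionMatrix",
    "PatchedMatrix",
    "load_cohort",
    "build_matrix",
    "compress_patches",
    "expand_map",
    "summarize_regions",
    "damage_diagnostics",
    "write_mask",
]


@dataclass(frozen=True)
class LesionMask:
    """One subject's binary lesion volume in template space."""

    subject_id: str
    volume: np.ndarray  # 3-d uint8, values in {0, 1}
    affine: np.ndarray  # 4x4
    voxel_dims: tuple[float, float, float]  # mm

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    @property
    def lesion_volume_mm3(self) -> float:
        return float(self.volume.sum()) * self.voxel_volume_mm3

    @property
    def n_lesioned_voxels(self) -> int:
        return int(self.volume.sum())


@dataclass(frozen=True)
class LesionMatrix:
    """Subjects x retained-voxels binary design with provenance.

    ``voxel_index`` maps each retained column to its linear index in the
    flattened (C-order) template grid.  Lesion volumes are recorded from
    the *unfiltered* masks, so the coverage filter never changes them.
    """

    matrix: np.ndarray  # n_subjects x n_voxels, uint8
    voxel_index: np.ndarray  # linear indices into the flattened grid
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_dims: tuple[float, float, float]
    subject_ids: tuple[str, ...]
    lesion_volumes_mm3: np.ndarray  # per subject, pre-filter
    filter_min_subjects: int

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    @property
    def lesion_voxel_counts(self) -> np.ndarray:
        """Per-subject lesion size in voxels of the working grid (pre-filter)."""
        return np.round(
            self.lesion_volumes_mm3 / float(np.prod(self.voxel_dims))
        ).astype(int)


@dataclass(frozen=True)
class PatchedMatrix:
    """Lossless column-compression of a LesionMatrix.

    ``patch_members[j]`` lists the voxel linear indices sharing pattern j;
    ``patch_sizes[j]`` (the multiplicity) is its voxel count.  Patches are
    ordered by their smallest member linear index, so the compression is
    deterministic.
    """

    matrix: np.ndarray  # n_subjects x n_patches, uint8
    patch_members: tuple[tuple[int, ...], ...]
    patch_sizes: np.ndarray

    @property
    def n_patches(self) -> int:
        return self.matrix.shape[1]


def load_cohort(paths, expected_grid: tuple[int, int, int] | None = None) -> list[LesionMask]:
    """Load and validate a cohort of binary NIfTI lesion masks.

    All masks must share grid shape and affine; any value outside {0, 1}
    is rejected.  Subject ids are taken from the file stem.
    """
    masks: list[LesionMask] = []
    ref_affine = None
    ref_shape = expected_grid
    for path in paths:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        sid = _stem(path)
        bad = np.setdiff1d(np.unique(data), [0, 1])
        if bad.size:
            raise ValueError(
                f"mask {sid} is not binary; offending values: {bad.tolist()}"
            )
        if ref_shape is None:
            ref_shape = tuple(data.shape)
        elif tuple(data.shape) != tuple(ref_shape):
            raise ValueError(
                f"grid mismatch for subject {sid}: {data.shape} vs {tuple(ref_shape)}"
            )
        if ref_affine is None:
            ref_affine = img.affine
        elif not np.allclose(img.affine, ref_affine, atol=1e-4):
            raise ValueError(f"affine mismatch for subject {sid}")
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        masks.append(
            LesionMask(
                subject_id=sid,
                volume=data.astype(np.uint8),
                affine=np.asarray(img.affine, dtype=float),
                voxel_dims=zooms,
            )
        )
    return masks


def _stem(path) -> str:
    name = str(path).rsplit("/", 1)[-1]
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def write_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.volume.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.voxel_dims)
    nib.save(img, str(path))


def build_matrix(masks: list[LesionMask], min_subjects: int = 5) -> LesionMatrix:
    """Stack masks into a subjects x voxels design and apply the coverage filter.

    Voxel columns lesioned in fewer than ``min_subjects`` subjects are
    dropped (the mapping cannot distinguish damage effects from noise where
    almost nobody is lesioned).  Lesion volumes are computed before
    filtering.  ``min_subjects`` may also be given as a fraction in (0, 1),
    interpreted as a proportion of the cohort and rounded up.
    """
    if not masks:
        raise ValueError("empty cohort")
    if 0 < min_subjects < 1:
        min_subjects = int(np.ceil(min_subjects * len(masks)))
    min_subjects = int(min_subjects)
    if len(masks) < min_subjects:
        raise ValueError(
            f"need at least {min_subjects} masks, got {len(masks)}"
        )
    shape = masks[0].volume.shape
    flat = np.vstack([m.volume.reshape(-1) for m in masks]).astype(np.uint8)
    coverage = flat.sum(axis=0)
    keep = np.flatnonzero(coverage >= min_subjects)
    if keep.size == 0:
        raise ValueError(
            f"no voxel is lesioned in at least {min_subjects} subjects"
        )
    volumes = np.array([m.lesion_volume_mm3 for m in masks])
    return LesionMatrix(
        matrix=flat[:, keep],
        voxel_index=keep,
        grid_shape=tuple(shape),
        affine=masks[0].affine,
        voxel_dims=masks[0].voxel_dims,
        subject_ids=tuple(m.subject_id for m in masks),
        lesion_volumes_mm3=volumes,
        filter_min_subjects=min_subjects,
    )


def compress_patches(lm: LesionMatrix) -> PatchedMatrix:
    """Group identical voxel columns into patches.

    Deterministic: patches are ordered by the smallest linear voxel index
    among their members.
    """
    if lm.n_voxels == 0:
        raise ValueError("empty lesion matrix")
    cols, inverse = np.unique(lm.matrix, axis=1, return_inverse=True)
    inverse = inverse.ravel()
    n_patches = cols.shape[1]
    members = [[] for _ in range(n_patches)]
    for col_pos, patch in enumerate(inverse):
        members[patch].append(int(lm.voxel_index[col_pos]))
    order = np.argsort([m[0] for m in members], kind="stable")
    members = [tuple(members[i]) for i in order]
    matrix = cols[:, order].astype(np.uint8)
    sizes = np.array([len(m) for m in members])
    return PatchedMatrix(
        matrix=matrix, patch_members=tuple(members), patch_sizes=sizes
    )


def expand_map(
    patch_values: np.ndarray,
    pm: PatchedMatrix,
    lm: LesionMatrix,
    fill_value: float = np.nan,
) -> np.ndarray:
    """Broadcast one value per patch onto a 3-d voxel map.

    Every voxel of a patch receives the patch's value; voxels outside the
    filtered coverage get ``fill_value``.
    """
    patch_values = np.asarray(patch_values, dtype=float)
    if patch_values.shape != (pm.n_patches,):
        raise ValueError(
            f"expected {pm.n_patches} patch values, got {patch_values.shape}"
        )
    out = np.full(int(np.prod(lm.grid_shape)), fill_value, dtype=float)
    for val, mem in zip(patch_values, pm.patch_members):
        out[list(mem)] = val
    return out.reshape(lm.grid_shape)


def summarize_regions(
    voxel_map: np.ndarray,
    atlas_volume: np.ndarray,
    voxel_dims: tuple[float, float, float],
    min_volume_mm3: float = 100.0,
    region_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-atlas-region volume of flagged voxels.

    ``voxel_map`` is boolean-like (non-zero, non-NaN = flagged).  Rows
    below ``min_volume_mm3`` are kept but marked sub-threshold rather than
    dropped, matching the reporting convention of keeping only regions
    larger than ~100 mm3 in the headline table.  Sorted by volume
    descending.
    """
    atlas_volume = np.asarray(atlas_volume)
    if atlas_volume.shape != voxel_map.shape:
        raise ValueError(
            f"atlas grid {atlas_volume.shape} does not match map {voxel_map.shape}"
        )
    flagged = np.nan_to_num(np.asarray(voxel_map, dtype=float), nan=0.0) != 0
    vox_mm3 = float(np.prod(voxel_dims))
    rows = []
    for label in np.unique(atlas_volume[atlas_volume > 0]):
        n = int(np.count_nonzero(flagged & (atlas_volume == label)))
        if n == 0:
            continue
        vol = n * vox_mm3
        rows.append(
            (
                int(label),
                (region_names or {}).get(int(label), f"region_{int(label)}"),
                vol,
                vol >= min_volume_mm3,
            )
        )
    df = pd.DataFrame(
        rows, columns=["region_label", "region_name", "volume_mm3", "above_threshold"]
    )
    return df.sort_values("volume_mm3", ascending=False).reset_index(drop=True)


def damage_diagnostics(
    lm: LesionMatrix, atlas_volume: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-region damage correlations and centroid distances.

    For each atlas region, the proportion damaged per subject is the
    fraction of its voxels lesioned (unfiltered coverage is not needed:
    only retained voxels carry damage shared by >= min_subjects, but
    proportion damage here uses the filtered matrix columns, which is what
    the mapping sees).  Returns (correlation matrix, distance matrix in mm)
    as labelled DataFrames.  Regions damaged in no subject are excluded
    with a warning-free drop; correlations need >= 3 subjects.
    """
    import warnings

    if lm.n_subjects < 3:
        raise ValueError("damage diagnostics require at least 3 subjects")
    atlas_volume = np.asarray(atlas_volume)
    if atlas_volume.shape != lm.grid_shape:
        raise ValueError("atlas grid does not match lesion matrix grid")
    atlas_flat = atlas_volume.reshape(-1)
    labels = [int(v) for v in np.unique(atlas_volume[atlas_volume > 0])]
    props, kept, centroids = [], [], []
    for label in labels:
        region_lin = np.flatnonzero(atlas_flat == label)
        cols = np.flatnonzero(np.isin(lm.voxel_index, region_lin))
        damage = (
            lm.matrix[:, cols].sum(axis=1) / region_lin.size
            if cols.size
            else np.zeros(lm.n_subjects)
        )
        if np.ptp(damage) == 0:
            warnings.warn(
                f"region {label} has constant damage across subjects; excluded",
                stacklevel=2,
            )
            continue
        kept.append(label)
        props.append(damage)
        com = ndimage.center_of_mass(atlas_volume == label)
        centroids.append(nib.affines.apply_affine(lm.affine, com))
    if len(kept) < 2:
        raise ValueError("fewer than 2 usable regions for diagnostics")
    P = np.vstack(props)
    corr = np.corrcoef(P)
    C = np.vstack(centroids)
    dist = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=-1)
    idx = pd.Index(kept, name="region")
    return (
        pd.DataFrame(corr, index=idx, columns=idx),
        pd.DataFrame(dist, index=idx, columns=idx),
    )
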