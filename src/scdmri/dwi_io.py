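"""Study bundles, ROI sets, and file I/O (NIfTI + FSL gradient tables).

A *study bundle* on disk is a directory containing::

    dwi.nii    4D float32 magnitude volume (x, y, slice, volume)
    dwi.bval   b-values in s/mm², one row
    dwi.bvec   direction components, three rows
    meta.json  subject / group / timepoint / protocol metadata

Label maps are integer NIfTI volumes using the label table below.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from . import schemes
from .schemes import GradientScheme, B0_THRESHOLD_S_MM2

__all__ = [
    "DWIStudy", "RoiSet",
    "load_study", "save_study", "extract_roi",
    "save_labels", "load_labels",
    "LABELS", "LABEL_NAMES", "WM_LABELS", "GM_LABELS", "ROI_NAMES",
    "StudyValidationError", "VolumeCountMismatchError",
    "NonUnitDirectionError", "NegativeBValueError", "EmptyRoiError",
]

# Fixed label table (portable across label maps written by this package).
LABELS = {
    "background": 0,
    "vWM": 1, "dWM": 2, "vlWM": 3, "dlWM": 4,
    "vGM": 5, "dGM": 6,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
WM_LABELS = ("vWM", "dWM", "vlWM", "dlWM")
GM_LABELS = ("vGM", "dGM")
#: the six reportable ROIs, in table order
ROI_NAMES = WM_LABELS + GM_LABELS


class StudyValidationError(ValueError):
    """Base class for study-bundle validation failures."""


class VolumeCountMismatchError(StudyValidationError):
    pass


class NonUnitDirectionError(StudyValidationError):
    pass


class NegativeBValueError(StudyValidationError):
    pass


class EmptyRoiError(ValueError):
    pass


@dataclass
class DWIStudy:
    """One subject/protocol/session: 4D magnitude data + geometry + scheme."""

    data: np.ndarray                 # (nx, ny, nslice, nvol), magnitude
    voxel_size: tuple                # (dx, dy, dz) in mm
    scheme: GradientScheme
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise StudyValidationError("data must be 4D (x, y, slice, volume)")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise VolumeCountMismatchError(
                f"data has {self.data.shape[3]} volumes but the scheme "
                f"defines {self.scheme.n_volumes}"
            )
        if np.any(self.data < 0):
            raise StudyValidationError("magnitude data must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise StudyValidationError("voxel_size must be three positive mm")

    @property
    def shape(self):
        return self.data.shape

    def b0_volumes(self) -> np.ndarray:
        """The unweighted volumes, shape (nx, ny, nslice, n_b0)."""
        return self.data[..., : self.scheme.n_b0]

    def weighted_volumes(self) -> np.ndarray:
        return self.data[..., self.scheme.n_b0:]


@dataclass
class RoiSet:
    """An integer label map plus name lookup, including the two unions
    ``wholeWM`` (four WM sectors) and ``wholeGM`` (two GM sectors)."""

    label_map: np.ndarray
    label_names: dict = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map)
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise ValueError("label map must be an integer volume")
        self._by_name = {v: k for k, v in self.label_names.items()}

    def available(self):
        names = sorted(set(self.label_names[v]
                           for v in np.unique(self.label_map)
                           if v in self.label_names))
        return names + ["wholeWM", "wholeGM"]

    def mask(self, label) -> np.ndarray:
        """Boolean mask for a label name, label integer, or union name."""
        if label == "wholeWM":
            return np.isin(self.label_map, [self._by_name[n] for n in WM_LABELS])
        if label == "wholeGM":
            return np.isin(self.label_map, [self._by_name[n] for n in GM_LABELS])
        if isinstance(label, str):
            if label not in self._by_name:
                raise EmptyRoiError(
                    f"unknown label {label!r}; available: {self.available()}")
            value = self._by_name[label]
        else:
            value = int(label)
        return self.label_map == value

    def cord_mask(self) -> np.ndarray:
        """All in-cord voxels (every non-background label)."""
        return self.mask("wholeWM") | self.mask("wholeGM")


def extract_roi(values: np.ndarray, rois: RoiSet, label) -> np.ndarray:
    """Return all voxel values of a scalar map inside a ROI, raster order.

    Raises :class:`EmptyRoiError` for an unknown or empty label (a ROI
    statistic on zero voxels would otherwise surface as a silent NaN).
    """
    values = np.asarray(values)
    if values.shape != rois.label_map.shape:
        raise ValueError(
            f"map shape {values.shape} != label map shape {rois.label_map.shape}")
    mask = rois.mask(label)
    if not mask.any():
        raise EmptyRoiError(
            f"ROI {label!r} contains no voxels; available: {rois.available()}")
    return values[mask]  # C-order boolean indexing == raster order


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_study(study: DWIStudy, out_dir) -> dict:
    """Write a study bundle; returns the file paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "image": os.path.join(out_dir, "dwi.nii"),
        "bval": os.path.join(out_dir, "dwi.bval"),
        "bvec": os.path.join(out_dir, "dwi.bvec"),
        "meta": os.path.join(out_dir, "meta.json"),
    }
    img = nib.Nifti1Image(study.data.astype(np.float32), _affine(study.voxel_size))
    img.header.set_zooms(study.voxel_size + (1.0,))
    nib.save(img, paths["image"])
    study.scheme.write_fsl(paths["bval"], paths["bvec"])
    with open(paths["meta"], "w") as fh:
        json.dump(study.meta, fh, indent=2, sort_keys=True)
    return paths


def load_study(image_path, bval_path, bvec_path, meta_path=None) -> DWIStudy:
    """Load a study bundle and validate it.

    Volumes with b < 50 s/mm² are classified as unweighted and moved to
    the front of the series (stable order) to match the package-wide
    b0-first convention.  Weighted directions are re-normalized to unit
    length; a weighted direction whose stored norm falls outside
    [0.99, 1.01] is rejected.
    """
    for p in (image_path, bval_path, bvec_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., None]
    bvals_s, dirs = schemes.read_fsl_tables(bval_path, bvec_path)
    if len(bvals_s) != data.shape[3]:
        raise VolumeCountMismatchError(
            f"{len(bvals_s)} gradient-table entries for {data.shape[3]} volumes")
    if np.any(bvals_s < 0):
        raise NegativeBValueError("negative b-value in bval file")

    is_b0 = bvals_s < B0_THRESHOLD_S_MM2
    norms = np.linalg.norm(dirs, axis=1)
    bad = ~is_b0 & ((norms < 0.99) | (norms > 1.01))
    if np.any(bad):
        raise NonUnitDirectionError(
            f"non-unit bvec columns at volumes {np.flatnonzero(bad).tolist()}")
    order = np.concatenate([np.flatnonzero(is_b0), np.flatnonzero(~is_b0)])
    data = data[..., order]
    wdirs = dirs[~is_b0] / norms[~is_b0, None]
    scheme = GradientScheme(wdirs, schemes.b_from_s_mm2(bvals_s[~is_b0]),
                            n_b0=int(is_b0.sum()))
    meta = {}
    if meta_path is not None and os.path.exists(str(meta_path)):
        with open(meta_path) as fh:
            meta = json.load(fh)
    zooms = img.header.get_zooms()[:3]
    return DWIStudy(data=data, voxel_size=tuple(float(z) for z in zooms),
                    scheme=scheme, meta=meta)


def load_bundle(bundle_dir) -> DWIStudy:
    """Load a bundle directory written by :func:`save_study`."""
    d = str(bundle_dir)
    return load_study(os.path.join(d, "dwi.nii"),
                      os.path.join(d, "dwi.bval"),
                      os.path.join(d, "dwi.bvec"),
                      os.path.join(d, "meta.json"))


def save_labels(label_map: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(label_map, dtype=np.int16),
                          _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))


def load_labels(path) -> RoiSet:
    img = nib.load(str(path))
    return RoiSet(label_map=np.asanyarray(img.dataobj).astype(np.int16))


def save_map(values: np.ndarray, voxel_size, path) -> None:
    """Write a scalar (3D) metric map as NIfTI-1 float32."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                          _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))


def load_map(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)
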