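"""Group-constrained, subject-specific fROI definition.

A participant's functional region of interest (fROI) is the top
fraction (default 10%) of gray-matter voxels, ranked by the localizer
contrast t value, inside a group-level parcel.  Parcels delimit where a
functional region may fall across the population; the t-map supplies
the participant-specific selection within them.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "VoxelContrastMap",
    "FROIDefinition",
    "qc_localizer",
    "define_froi",
    "extract_froi_timecourse",
    "load_nifti_map",
    "save_froi_mask_nifti",
]

DEFAULT_PARCELS = ("IFGorb", "IFG", "MFG", "AntTemp", "PostTemp")


@dataclass
class VoxelContrastMap:
    """Per-voxel localizer-contrast t statistics plus masks.

    All arrays are flat (order-of-storage linear indices); ``shape``
    records the original grid for NIfTI round-trips only — selection
    logic never uses spatial coordinates.
    """

    t_values: np.ndarray
    df: int | None
    gm_mask: np.ndarray
    parcel_masks: dict = field(default_factory=dict)
    shape: tuple | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.t_values = np.asarray(self.t_values, dtype=float).ravel()
        self.gm_mask = np.asarray(self.gm_mask, dtype=bool).ravel()
        if self.gm_mask.shape != self.t_values.shape:
            raise ValueError("gm_mask and t_values must share the voxel grid")
        self.parcel_masks = {
            k: np.asarray(v, dtype=bool).ravel() for k, v in self.parcel_masks.items()
        }
        for name, m in self.parcel_masks.items():
            if m.shape != self.t_values.shape:
                raise ValueError(f"parcel {name!r} does not share the voxel grid")


@dataclass
class FROIDefinition:
    """A subject-specific fROI: the selected voxel indices in one parcel."""

    froi: str
    voxel_indices: np.ndarray
    fraction: float = 0.10
    n_parcel_voxels: int = 0

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "froi": self.froi,
                    "voxel_indices": self.voxel_indices.tolist(),
                    "fraction": self.fraction,
                    "n_parcel_voxels": self.n_parcel_voxels,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "FROIDefinition":
        with open(path) as fh:
            return cls(**json.load(fh))


def qc_localizer(
    cmap: VoxelContrastMap, alpha: float = 0.001, min_voxels: int = 100
) -> tuple[bool, int]:
    """Localizer quality check: enough suprathreshold voxels in the parcels.

    Counts gray-matter voxels across all parcels whose t exceeds the
    one-tailed critical value at ``alpha`` (uncorrected).  A participant
    fails when the count is strictly below ``min_voxels`` ("fewer than
    100"), so exactly 100 passes.  Returns ``(passed, n_suprathreshold)``.
    """
    if cmap.df is None or cmap.df <= 0:
        raise ValueError("df is required to convert t to p")
    t_crit = sps.t.ppf(1 - alpha, cmap.df)
    in_parcels = np.zeros_like(cmap.gm_mask)
    for m in cmap.parcel_masks.values():
        in_parcels |= m
    sel = in_parcels & cmap.gm_mask
    n_supra = int(np.sum(cmap.t_values[sel] > t_crit))
    return n_supra >= min_voxels, n_supra


def define_froi(
    cmap: VoxelContrastMap, froi: str, fraction: float = 0.10
) -> FROIDefinition:
    """Select the top-``fraction`` voxels of a parcel by t value.

    The GM mask is applied before ranking; the selected count is
    ``ceil(fraction * m)`` over the m parcel-and-GM voxels (ceiling so a
    tiny parcel still yields a nonempty fROI).  Ties at the cutoff are
    broken by lowest linear voxel index, making selection a
    deterministic function of the map.
    """
    if froi not in cmap.parcel_masks:
        raise KeyError(f"parcel {froi!r} not in map (have {sorted(cmap.parcel_masks)})")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    candidates = np.nonzero(cmap.parcel_masks[froi] & cmap.gm_mask)[0]
    m = len(candidates)
    if m == 0:
        raise ValueError(f"parcel {froi!r} has no gray-matter voxels")
    k = math.ceil(fraction * m)
    t = cmap.t_values[candidates]
    # sort by (-t, index): highest t first, lowest index wins ties
    order = np.lexsort((candidates, -t))
    chosen = np.sort(candidates[order[:k]])
    return FROIDefinition(froi=froi, voxel_indices=chosen, fraction=fraction, n_parcel_voxels=m)


def extract_froi_timecourse(
    voxel_series: np.ndarray, definition: FROIDefinition
) -> np.ndarray:
    """Average the z-scored series of the fROI's voxels.

    ``voxel_series`` is (n_voxels, T) over the full grid or already
    restricted to the selected voxels (then n_voxels must equal the
    fROI size).  Each voxel is z-scored over time (n-1 convention) and
    the z-scored series are averaged; constant voxels are excluded with
    a warning, and an all-constant fROI is an error.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    if voxel_series.ndim != 2:
        raise ValueError("voxel_series must be 2-D (voxels x time)")
    k = len(definition.voxel_indices)
    if voxel_series.shape[0] == k:
        block = voxel_series
    else:
        block = voxel_series[definition.voxel_indices]
    sd = block.std(axis=1, ddof=1)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError(f"all voxels in fROI {definition.froi!r} are constant")
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} constant voxel(s) from fROI "
            f"{definition.froi!r}",
            stacklevel=2,
        )
    block = block[keep]
    z = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, ddof=1, keepdims=True)
    return z.mean(axis=0)


# ---------------------------------------------------------------------
# NIfTI I/O (thin wrappers; selection logic is index-based)
# ---------------------------------------------------------------------

def load_nifti_map(tmap_path, gm_path, parcel_paths: dict, df: int) -> VoxelContrastMap:
    """Assemble a VoxelContrastMap from NIfTI files (t-map, GM mask, parcels)."""
    import nibabel as nib

    img = nib.load(str(tmap_path))
    t = np.asarray(img.dataobj, dtype=float)
    gm = np.asarray(nib.load(str(gm_path)).dataobj) > 0.5
    parcels = {
        name: np.asarray(nib.load(str(p)).dataobj) > 0.5 for name, p in parcel_paths.items()
    }
    return VoxelContrastMap(
        t_values=t, df=df, gm_mask=gm, parcel_masks=parcels, shape=t.shape, affine=img.affine
    )


def save_froi_mask_nifti(definition: FROIDefinition, cmap: VoxelContrastMap, path) -> None:
    """Write the fROI as a binary NIfTI mask on the map's grid."""
    import nibabel as nib

    if cmap.shape is None:
        raise ValueError("map has no grid shape; cannot write NIfTI")
    mask = np.zeros(int(np.prod(cmap.shape)), dtype=np.uint8)
    mask[definition.voxel_indices] = 1
    affine = cmap.affine if cmap.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.reshape(cmap.shape), affine), str(path))
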