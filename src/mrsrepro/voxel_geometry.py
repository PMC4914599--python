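"""Oriented-cuboid MRS voxel geometry on a segmented anatomical grid.

An MRS voxel is a single cuboid volume of interest (a few ml) placed obliquely
in scanner space; the anatomical image it overlaps is segmented into gray
matter (GM), white matter (WM) and cerebrospinal fluid (CSF) probability maps
on a ~1 mm grid.  This module rasterizes the cuboid onto the grid
(cell-center-in-cuboid test), computes the voxel's tissue fractions, and
applies the CSF partial-volume correction

    C = C0 / (1 - F_CSF)

which rescales a water-scaled concentration because metabolite signal arises
from tissue, not CSF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelSpec",
    "SegmentationMaps",
    "TissueFractions",
    "GeometryError",
    "euler_to_matrix",
    "rasterize_voxel",
    "tissue_fractions",
    "voxel_tissue_fractions",
    "csf_correct",
    "csf_uncorrect",
    "gm_wm_ratio",
]


class GeometryError(ValueError):
    """Voxel does not intersect the segmentation grid, or the grid is degenerate."""


def euler_to_matrix(angles_deg, order: str = "xyz") -> np.ndarray:
    """Rotation matrix from extrinsic Euler angles in degrees, applied in ``order``."""
    mats = []
    for axis, ang in zip(order, angles_deg):
        c, s = np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))
        if axis == "x":
            m = [[1, 0, 0], [0, c, -s], [0, s, c]]
        elif axis == "y":
            m = [[c, 0, s], [0, 1, 0], [-s, 0, c]]
        elif axis == "z":
            m = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
        else:
            raise ValueError(f"unknown axis {axis!r}")
        mats.append(np.asarray(m, dtype=float))
    out = np.eye(3)
    for m in mats:
        out = m @ out
    return out


@dataclass(frozen=True)
class VoxelSpec:
    """Arbitrarily oriented cuboid voxel in scanner space.

    ``center`` in mm, ``dims`` the three edge lengths in mm (in the declared
    axis order, e.g. AP x LR x FH), ``rotation`` the orthonormal matrix
    mapping voxel-frame axes to scanner axes.
    """

    center: np.ndarray
    dims: np.ndarray
    rotation: np.ndarray = None  # type: ignore[assignment]
    region: str = ""

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        object.__setattr__(self, "dims", np.asarray(self.dims, dtype=float).reshape(3))
        rot = np.eye(3) if self.rotation is None else np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", rot.reshape(3, 3))
        if (self.dims <= 0).any():
            raise ValueError("all voxel dims must be > 0")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal (atol 1e-6)")

    @property
    def volume_ml(self) -> float:
        return float(np.prod(self.dims)) / 1000.0

    @classmethod
    def from_config(cls, cfg: dict) -> "VoxelSpec":
        """Build from a placement dict: ``center_mm``, ``dims_mm``, and either
        ``rotation`` (3x3) or ``euler_deg`` (+ optional ``order``)."""
        if "rotation" in cfg:
            rot = np.asarray(cfg["rotation"], dtype=float)
        elif "euler_deg" in cfg:
            rot = euler_to_matrix(cfg["euler_deg"], cfg.get("order", "xyz"))
        else:
            rot = np.eye(3)
        return cls(
            center=cfg["center_mm"], dims=cfg["dims_mm"], rotation=rot,
            region=cfg.get("region", ""),
        )


@dataclass(frozen=True)
class SegmentationMaps:
    """GM/WM/CSF probability volumes on a shared grid with a grid-to-mm affine."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        for name in ("gm", "wm", "csf"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float).reshape(4, 4))
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValueError("gm/wm/csf must share a shape")
        for name in ("gm", "wm", "csf"):
            a = getattr(self, name)
            if a.min() < -1e-9 or a.max() > 1 + 1e-9:
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
        if ((self.gm + self.wm + self.csf) > 1 + 1e-3).any():
            raise ValueError("tissue probabilities sum above 1 (tolerance 1e-3)")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @classmethod
    def from_nifti(cls, gm_path, wm_path, csf_path) -> "SegmentationMaps":
        """Load three single-volume NIfTI files; the affine is taken from the GM header."""
        import nibabel as nib

        gm_img = nib.load(str(gm_path))
        wm_img = nib.load(str(wm_path))
        csf_img = nib.load(str(csf_path))
        return cls(
            gm=np.asarray(gm_img.dataobj, dtype=float),
            wm=np.asarray(wm_img.dataobj, dtype=float),
            csf=np.asarray(csf_img.dataobj, dtype=float),
            affine=gm_img.affine,
        )

    def to_nifti(self, gm_path, wm_path, csf_path) -> None:
        import nibabel as nib

        for arr, path in ((self.gm, gm_path), (self.wm, wm_path), (self.csf, csf_path)):
            nib.save(nib.Nifti1Image(arr.astype(np.float64), self.affine), str(path))


@dataclass(frozen=True)
class TissueFractions:
    """GM/WM/CSF composition of one voxel, normalized to sum to 1."""

    f_gm: float
    f_wm: float
    f_csf: float
    n_grid_voxels: int = 1

    def __post_init__(self):
        total = self.f_gm + self.f_wm + self.f_csf
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"fractions must sum to 1, got {total}")
        if self.n_grid_voxels < 1:
            raise ValueError("n_grid_voxels must be >= 1")


def rasterize_voxel(voxel: VoxelSpec, maps: SegmentationMaps) -> np.ndarray:
    """Binary mask of grid cells whose center lies inside the oriented cuboid.

    The inclusion test is half-open per voxel-frame axis, coordinate in
    [-dim/2, +dim/2), so lattice-aligned boundaries are never double counted.
    Only the sub-grid covered by the cuboid's bounding box is evaluated.
    """
    shape = maps.gm.shape
    inv = np.linalg.inv(maps.affine)
    # cuboid corners in scanner mm -> grid index space, for a bounding box
    half = voxel.dims / 2.0
    signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    corners_mm = voxel.center + (signs * half) @ voxel.rotation.T
    corners_idx = (inv[:3, :3] @ corners_mm.T + inv[:3, 3:4]).T
    lo = np.maximum(np.floor(corners_idx.min(axis=0)) - 1, 0).astype(int)
    hi = np.minimum(np.ceil(corners_idx.max(axis=0)) + 1, np.array(shape) - 1).astype(int)
    if (lo > hi).any():
        raise GeometryError("voxel bounding box does not intersect the grid field of view")

    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[d], hi[d] + 1) for d in range(3)), indexing="ij"
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    centers_mm = (maps.affine[:3, :3] @ idx + maps.affine[:3, 3:4]).T
    local = (centers_mm - voxel.center) @ voxel.rotation  # voxel-frame coords
    inside = ((local >= -half) & (local < half)).all(axis=1)
    if not inside.any():
        raise GeometryError("voxel contains no grid cell centers (empty intersection)")
    mask = np.zeros(shape, dtype=bool)
    mask[ii.ravel()[inside], jj.ravel()[inside], kk.ravel()[inside]] = True
    return mask


def tissue_fractions(mask: np.ndarray, maps: SegmentationMaps) -> TissueFractions:
    """Tissue fractions inside a mask, normalized by total tissue probability.

    f_c = sum_mask p_c / sum_mask (p_gm + p_wm + p_csf); near-zero-probability
    background cells therefore contribute nothing.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("mask is empty")
    sums = np.array([maps.gm[mask].sum(), maps.wm[mask].sum(), maps.csf[mask].sum()])
    total = sums.sum()
    if total <= 0:
        raise GeometryError("all tissue probabilities are zero inside the mask")
    f = sums / total
    return TissueFractions(f_gm=float(f[0]), f_wm=float(f[1]), f_csf=float(f[2]),
                           n_grid_voxels=int(mask.sum()))


def voxel_tissue_fractions(voxel: VoxelSpec, maps: SegmentationMaps) -> TissueFractions:
    """Convenience: rasterize then compute fractions."""
    return tissue_fractions(rasterize_voxel(voxel, maps), maps)


def csf_correct(c0: float, f_csf: float):
    """CSF partial-volume correction C = C0 / (1 - F_CSF).

    Metabolite signal originates from GM and WM only, so the water-scaled
    concentration is rescaled by the non-CSF share of the voxel.  Accepts
    scalars or arrays; strictly increasing in ``f_csf``.
    """
    c0 = np.asarray(c0, dtype=float)
    f_csf = np.asarray(f_csf, dtype=float)
    if (f_csf < 0).any() or (f_csf >= 1).any():
        raise ValueError("f_csf must lie in [0, 1)")
    if (c0 < 0).any():
        raise ValueError("concentration must be >= 0")
    out = c0 / (1.0 - f_csf)
    return float(out) if out.ndim == 0 else out


def csf_uncorrect(c: float, f_csf: float):
    """Inverse of :func:`csf_correct`: C0 = C * (1 - F_CSF)."""
    c = np.asarray(c, dtype=float)
    f_csf = np.asarray(f_csf, dtype=float)
    if (f_csf < 0).any() or (f_csf >= 1).any():
        raise ValueError("f_csf must lie in [0, 1)")
    out = c * (1.0 - f_csf)
    return float(out) if out.ndim == 0 else out


def gm_wm_ratio(fractions: TissueFractions) -> float:
    """GM/WM ratio covariate; undefined when the WM fraction is zero."""
    if fractions.f_wm <= 0:
        raise ZeroDivisionError(
            "WM fraction is zero; GM/WM ratio undefined - use the GM fraction "
            "itself as covariate instead"
        )
    return fractions.f_gm / fractions.f_wm
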