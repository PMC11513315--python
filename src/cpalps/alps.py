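"""Diffusion-tensor analysis along the perivascular space (ALPS).

At the level of the lateral ventricle bodies, medullary veins run along the
x-axis (left-right), perpendicular to both the projection fibers (z,
superior-inferior) and the association fibers (y, anterior-posterior).
Water diffusivity along x in those two fiber populations therefore reflects
perivascular flow, and the index

    ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)

is ~1 when no preferential perivascular diffusion exists and rises with it.

The pipeline here: a 5 mm spherical ROI is placed at an explicit physical
coordinate, every ROI voxel is labeled by the dominant axis of its principal
eigenvector (projection if z, association if y, subcortical if x; ties
broken z > y > x), one representative voxel per fiber class is selected on a
shared x-index by maximum orientation, and the four diffusivities are read
as raw tensor diagonal entries in scanner axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import TensorVolume, VoxelVolume

PROJECTION, ASSOCIATION, SUBCORTICAL = 1, 2, 3
_LABEL_OF_AXIS = {2: PROJECTION, 1: ASSOCIATION, 0: SUBCORTICAL}


@dataclass
class ALPSRoi:
    """Spherical region of interest in physical mm coordinates."""

    center_mm: tuple[float, float, float]
    diameter_mm: float = 5.0
    hemisphere: str = "left"


@dataclass
class ALPSDiffusivities:
    """The four directional diffusivities entering the index (mm²/s)."""

    Dxproj: float
    Dyproj: float
    Dxassoc: float
    Dzassoc: float
    proj_voxel: tuple[int, int, int] | None = None
    assoc_voxel: tuple[int, int, int] | None = None


@dataclass
class ALPSResult:
    diffusivities: ALPSDiffusivities
    index: float
    qc: dict = field(default_factory=dict)


def make_sphere_roi(center_mm, diameter_mm: float, geometry: VoxelVolume) -> VoxelVolume:
    """Binary mask of voxels whose centers lie within the sphere.

    Distances are physical (mm), so anisotropic grids are handled correctly.
    """
    if diameter_mm <= max(geometry.spacing_mm):
        raise ValueError("diameter must exceed the largest voxel dimension")
    cx, cy, cz = geometry.voxel_centers_mm()
    center = np.asarray(center_mm, dtype=float)
    r2 = (cx - center[0]) ** 2 + (cy - center[1]) ** 2 + (cz - center[2]) ** 2
    mask = r2 <= (diameter_mm / 2.0) ** 2
    if not mask.any():
        raise ValueError("ROI sphere does not contain any voxel center")
    return geometry.like(mask.astype(np.uint8))


def classify_fiber_voxels(tensors: TensorVolume, roi: VoxelVolume) -> VoxelVolume:
    """Label ROI voxels by the dominant axis of the principal eigenvector.

    Labels: 1 projection (|v_z| largest), 2 association (|v_y| largest),
    3 subcortical (|v_x| largest); ties resolved in the order z > y > x.
    Voxels with non-finite tensors are left unlabeled (0).
    """
    m = roi.values > 0
    if not m.any():
        raise ValueError("ROI is empty")
    labels = np.zeros(tensors.shape, dtype=np.uint8)
    mats = tensors.as_matrices()[m]
    finite = np.isfinite(mats).all(axis=(1, 2))
    v = np.zeros((mats.shape[0], 3))
    if finite.any():
        _, vecs = np.linalg.eigh(mats[finite])
        v[finite] = vecs[:, :, 2]  # eigenvector of the largest eigenvalue
    absv = np.abs(v)
    # argmax over (z, y, x) order implements the documented tie-break
    pref = absv[:, [2, 1, 0]]
    dominant = np.argmax(pref, axis=1)  # 0->z, 1->y, 2->x
    lab = np.where(dominant == 0, PROJECTION, np.where(dominant == 1, ASSOCIATION, SUBCORTICAL))
    lab = np.where(finite, lab, 0).astype(np.uint8)
    labels[m] = lab
    return roi.like(labels)


def select_fiber_representatives(
    labels: VoxelVolume, tensors: TensorVolume, roi: VoxelVolume
) -> ALPSDiffusivities:
    """Pick one projection and one association voxel on a shared x-index.

    Restricted to x-indices where both fiber classes occur within the ROI,
    each class's representative maximizes the magnitude of its principal
    eigenvector's dominant component ("maximum orientation").  Diffusivities
    are the raw tensor diagonals at the chosen voxels.
    """
    m = (roi.values > 0) & (labels.values > 0)
    proj = m & (labels.values == PROJECTION)
    assoc = m & (labels.values == ASSOCIATION)
    x_proj = set(np.nonzero(proj)[0].tolist())
    x_assoc = set(np.nonzero(assoc)[0].tolist())
    shared = x_proj & x_assoc
    if not shared:
        missing = []
        if not x_proj:
            missing.append("projection")
        if not x_assoc:
            missing.append("association")
        what = " and ".join(missing) if missing else "a shared x-index for both classes"
        raise ValueError(f"ROI lacks {what or 'fiber voxels'}: no x-index holds both fiber classes")

    xs = np.array(sorted(shared))
    mats = tensors.as_matrices()

    def best(mask: np.ndarray, axis: int) -> tuple[int, int, int]:
        ix, iy, iz = np.nonzero(mask & np.isin(np.arange(tensors.shape[0]), xs)[:, None, None])
        _, vecs = np.linalg.eigh(mats[ix, iy, iz])
        score = np.abs(vecs[:, axis, 2])
        k = int(np.argmax(score))
        return int(ix[k]), int(iy[k]), int(iz[k])

    pvox = best(proj, axis=2)
    avox = best(assoc, axis=1)
    c = tensors.components
    return ALPSDiffusivities(
        Dxproj=float(c[pvox][0]),
        Dyproj=float(c[pvox][3]),
        Dxassoc=float(c[avox][0]),
        Dzassoc=float(c[avox][5]),
        proj_voxel=pvox,
        assoc_voxel=avox,
    )


def alps_index(d: ALPSDiffusivities) -> float:
    """ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)."""
    return (d.Dxproj + d.Dxassoc) / (d.Dyproj + d.Dzassoc)


def compute_alps(tensors: TensorVolume, roi: ALPSRoi) -> ALPSResult:
    """Full ALPS computation: ROI, fiber classification, selection, index."""
    geom = tensors.geometry()
    roi_mask = make_sphere_roi(roi.center_mm, roi.diameter_mm, geom)
    labels = classify_fiber_voxels(tensors, roi_mask)
    diff = select_fiber_representatives(labels, tensors, roi_mask)
    lab_in = labels.values[roi_mask.values > 0]
    qc = {
        "hemisphere": roi.hemisphere,
        "n_roi": int((roi_mask.values > 0).sum()),
        "n_projection": int((lab_in == PROJECTION).sum()),
        "n_association": int((lab_in == ASSOCIATION).sum()),
        "n_subcortical": int((lab_in == SUBCORTICAL).sum()),
        "n_skipped": int((lab_in == 0).sum()),
    }
    return ALPSResult(diffusivities=diff, index=alps_index(diff), qc=qc)
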