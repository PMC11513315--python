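"""Synthetic ground-truth generators.

Three families of inputs are simulated so every downstream stage can be
validated against known truth without any imaging data:

* T1-like intensity phantoms: a pair of ellipsoidal lateral ventricles whose
  in-mask voxels belong to three intensity classes — CSF (dark), choroid
  plexus (intermediate) and ventricular wall (bright, partial-volume shell) —
  optionally corrupted by a smooth multiplicative bias field.
* Diffusion-tensor phantoms with z-oriented projection fibers and y-oriented
  association fibers over an isotropic background, the geometry the ALPS
  index assumes.
* Subject cohorts: per-subject CP volume %, ALPS index and CERAD-K subtest
  z-scores drawn from group models (CP% and word-list-recognition z jointly
  bivariate normal).

Conventions: +y is anterior, so the choroid plexus blob occupies the
*low-y* (posterior) cap of each ventricle.  The ventricular wall is the
1-voxel inner boundary shell (26-neighborhood).  All generators are
deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume import TensorVolume, VoxelVolume

# class codes used in label volumes / class maps
CSF, CP, WALL = 1, 2, 3


# --------------------------------------------------------------------------
# T1 phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in physical mm coordinates."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semiaxes_mm
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class ClassParams:
    """Intensity model of one tissue class (Gaussian mean/SD)."""

    mean: float
    sd: float


@dataclass
class PhantomSpec:
    """Parameters of a two-ventricle T1 phantom.

    ``cp_fraction`` is the target fraction of *ventricle* voxels assigned to
    choroid plexus.  ``class_params`` keys are ``"csf"``, ``"cp"``,
    ``"wall"``; means must be strictly ordered CSF < CP < wall (T1
    convention: CSF darkest).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tiv_mm3: float = 50_000.0
    ventricle_geometry: Sequence[Ellipsoid] = field(
        default_factory=lambda: (
            Ellipsoid((22.0, 32.0, 32.0), (7.0, 13.0, 9.0)),
            Ellipsoid((42.0, 32.0, 32.0), (7.0, 13.0, 9.0)),
        )
    )
    cp_fraction: float = 0.15
    class_params: dict = field(
        default_factory=lambda: {
            "csf": ClassParams(30.0, 4.0),
            "cp": ClassParams(60.0, 4.0),
            "wall": ClassParams(90.0, 4.0),
        }
    )
    bias_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.cp_fraction < 1.0:
            raise ValueError("cp_fraction must lie in (0, 1)")
        p = self.class_params
        for name in ("csf", "cp", "wall"):
            if p[name].sd <= 0:
                raise ValueError(f"class {name!r} SD must be > 0")
        if not p["csf"].mean < p["cp"].mean < p["wall"].mean:
            raise ValueError("class means must be strictly ordered CSF < CP < wall")
        vent_volume = sum(e.volume_mm3 for e in self.ventricle_geometry)
        if self.tiv_mm3 <= vent_volume:
            raise ValueError("tiv_mm3 must exceed the total ventricle volume")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        spacing = np.asarray(self.spacing_mm, dtype=float)
        for e in self.ventricle_geometry:
            if np.any(np.asarray(e.semiaxes_mm) < 2.0 * spacing):
                raise ValueError("degenerate ellipsoid: every semi-axis must span >= 2 voxels")


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated phantom."""

    n_ventricle: int
    n_csf: int
    n_cp: int
    n_wall: int
    cp_volume_mm3: float
    cp_pct: float


def _rasterize_ellipsoid(ell: Ellipsoid, grid_shape, spacing_mm) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    mask = np.zeros(grid_shape, dtype=bool)
    q = np.zeros(grid_shape, dtype=float)
    for ax in range(3):
        coord = idx[ax] * spacing[ax]
        q += ((coord - ell.center_mm[ax]) / ell.semiaxes_mm[ax]) ** 2
    mask = q <= 1.0
    return mask


def inner_boundary_shell(mask: np.ndarray) -> np.ndarray:
    """1-voxel inner boundary of a binary mask (26-neighborhood)."""
    structure = np.ones((3, 3, 3), dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=structure)
    return mask & ~eroded


def generate_phantom(spec: PhantomSpec):
    """Build a T1 phantom with its ventricle mask and true CP mask.

    Returns ``(t1, ventricle_mask, true_cp_mask, truth)``.  The CP is a
    contiguous posterior (low-y) cap of the interior of each ventricle; the
    wall is the 1-voxel inner boundary shell; everything else in-mask is CSF.
    Intensities are drawn i.i.d. per class and multiplied by a smooth bias
    field when ``bias_amplitude > 0``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)

    vent_masks = [_rasterize_ellipsoid(e, shape, spec.spacing_mm) for e in spec.ventricle_geometry]
    ventricle = np.logical_or.reduce(vent_masks)
    n_vent = int(ventricle.sum())
    if n_vent == 0:
        raise ValueError("ventricle geometry rasterizes to an empty mask")

    wall = inner_boundary_shell(ventricle)

    # distribute the CP voxel budget over ventricles proportionally to size
    n_cp_total = int(round(spec.cp_fraction * n_vent))
    cp_mask = np.zeros(shape, dtype=bool)
    counts = [int(m.sum()) for m in vent_masks]
    assigned = 0
    for k, vm in enumerate(vent_masks):
        if k == len(vent_masks) - 1:
            n_cp_k = n_cp_total - assigned
        else:
            n_cp_k = int(round(n_cp_total * counts[k] / n_vent))
        assigned += n_cp_k
        interior = vm & ~wall & ~cp_mask
        ix, iy, iz = np.nonzero(interior)
        if n_cp_k > ix.size:
            raise ValueError(
                f"cp_fraction {spec.cp_fraction} incompatible with geometry: "
                f"ventricle {k} has {ix.size} interior voxels, needs {n_cp_k}"
            )
        # posterior cap: smallest y first; deterministic ties by (z, x)
        order = np.lexsort((ix, iz, iy))
        sel = order[:n_cp_k]
        cp_mask[ix[sel], iy[sel], iz[sel]] = True

    csf = ventricle & ~wall & ~cp_mask

    p = spec.class_params
    t1 = rng.normal(p["wall"].mean, p["wall"].sd, size=shape)  # parenchyma-like background
    for m, cp_ in ((csf, p["csf"]), (cp_mask, p["cp"]), (wall, p["wall"])):
        t1[m] = rng.normal(cp_.mean, cp_.sd, size=int(m.sum()))

    if spec.bias_amplitude > 0:
        bias = simulate_bias_field(shape, spec.spacing_mm, spec.bias_amplitude, spec.seed + 1)
        t1 = t1 * bias.values

    voxvol = float(np.prod(spec.spacing_mm))
    n_cp = int(cp_mask.sum())
    truth = PhantomTruth(
        n_ventricle=n_vent,
        n_csf=int(csf.sum()),
        n_cp=n_cp,
        n_wall=int(wall.sum()),
        cp_volume_mm3=n_cp * voxvol,
        cp_pct=100.0 * n_cp * voxvol / spec.tiv_mm3,
    )
    mk = lambda a, dt: VoxelVolume.from_spacing(a.astype(dt), spec.spacing_mm)
    return (
        mk(t1, np.float64),
        mk(ventricle, np.uint8),
        mk(cp_mask, np.uint8),
        truth,
    )


def simulate_bias_field(shape, spacing_mm, amplitude: float, seed: int) -> VoxelVolume:
    """Smooth multiplicative bias field with grid mean exactly 1.

    Built from a random low-order 3D polynomial in normalized coordinates,
    centered and scaled so that ``max |field - 1| == amplitude``.  Amplitude 0
    returns the constant-1 field.  Requires ``amplitude < 1`` so the field
    stays strictly positive.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude >= 1:
        raise ValueError("amplitude must be < 1 to keep the field positive")
    shape = tuple(shape)
    if amplitude == 0:
        return VoxelVolume.from_spacing(np.ones(shape), spacing_mm)
    rng = np.random.default_rng(seed)
    # normalized coordinates in [-1, 1] per axis
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coef = rng.normal(size=len(terms))
    raw = sum(c * t for c, t in zip(coef, terms))
    raw -= raw.mean()
    peak = np.abs(raw).max()
    if peak == 0:  # pathological draw; fall back to a plane
        raw = x - x.mean()
        peak = np.abs(raw).max()
    fieldv = 1.0 + amplitude * raw / peak
    return VoxelVolume.from_spacing(fieldv, spacing_mm)


# --------------------------------------------------------------------------
# tensor phantom
# --------------------------------------------------------------------------

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open voxel ranges


@dataclass
class TensorPhantomSpec:
    """Parameters of a two-fiber diffusion-tensor phantom.

    ``proj_region`` / ``assoc_region`` are axis-aligned half-open voxel
    boxes ``((x0, x1), (y0, y1), (z0, z1))``.  Fiber tensors are diagonal:
    the projection tensor must have its z entry strictly maximal (fibers run
    superior-inferior) and the association tensor its y entry (fibers run
    anterior-posterior).  The regions must be disjoint but share at least one
    x-index, mirroring how ALPS reads both fibers on one left-right line.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    proj_region: Box = ((4, 12), (4, 8), (4, 12))
    assoc_region: Box = ((4, 12), (8, 12), (4, 12))
    proj_tensor: tuple[float, float, float] = (1.2e-3, 0.6e-3, 1.8e-3)
    assoc_tensor: tuple[float, float, float] = (1.2e-3, 1.8e-3, 0.6e-3)
    background_diffusivity: float = 0.8e-3
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, diag in (("proj", self.proj_tensor), ("assoc", self.assoc_tensor)):
            if any(d <= 0 for d in diag):
                raise ValueError(f"{name}_tensor diagonal entries must be > 0")
        if not (self.proj_tensor[2] > self.proj_tensor[0] and self.proj_tensor[2] > self.proj_tensor[1]):
            raise ValueError("proj_tensor must have Dzz strictly maximal")
        if not (self.assoc_tensor[1] > self.assoc_tensor[0] and self.assoc_tensor[1] > self.assoc_tensor[2]):
            raise ValueError("assoc_tensor must have Dyy strictly maximal")
        if self.background_diffusivity <= 0:
            raise ValueError("background diffusivity must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if _boxes_overlap(self.proj_region, self.assoc_region):
            raise ValueError("proj_region and assoc_region overlap")
        px, ax = self.proj_region[0], self.assoc_region[0]
        if max(px[0], ax[0]) >= min(px[1], ax[1]):
            raise ValueError("regions must share at least one x-index")


def _boxes_overlap(a: Box, b: Box) -> bool:
    return all(max(a[d][0], b[d][0]) < min(a[d][1], b[d][1]) for d in range(3))


def _box_mask(box: Box, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


@dataclass
class TensorPhantomTruth:
    Dxproj: float
    Dyproj: float
    Dxassoc: float
    Dzassoc: float
    index: float


def generate_tensor_phantom(spec: TensorPhantomSpec):
    """Build a tensor phantom; returns ``(tensors, labels, truth)``.

    Labels: 0 background, 1 projection fiber, 2 association fiber.  Noise is
    i.i.d. Gaussian on each of the six tensor components; voxels whose noisy
    tensor is not positive-definite are redrawn (not clipped) so the noise
    distribution stays symmetric conditional on validity.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    comp = np.zeros(shape + (6,))
    d = spec.background_diffusivity
    comp[..., 0] = comp[..., 3] = comp[..., 5] = d

    proj = _box_mask(spec.proj_region, shape)
    assoc = _box_mask(spec.assoc_region, shape)
    for mask, diag in ((proj, spec.proj_tensor), (assoc, spec.assoc_tensor)):
        comp[mask, 0] = diag[0]
        comp[mask, 3] = diag[1]
        comp[mask, 5] = diag[2]
        comp[mask, 1] = comp[mask, 2] = comp[mask, 4] = 0.0

    if spec.noise_sd > 0:
        comp = comp + rng.normal(0.0, spec.noise_sd, size=comp.shape)
        comp = _redraw_non_spd(comp, rng, spec.noise_sd, base=_noise_free_components(spec, shape))

    labels = np.zeros(shape, dtype=np.uint8)
    labels[proj] = 1
    labels[assoc] = 2

    p, a = spec.proj_tensor, spec.assoc_tensor
    truth = TensorPhantomTruth(
        Dxproj=p[0], Dyproj=p[1], Dxassoc=a[0], Dzassoc=a[2],
        index=(p[0] + a[0]) / (p[1] + a[2]),
    )
    return (
        TensorVolume.from_spacing(comp, spec.spacing_mm),
        VoxelVolume.from_spacing(labels, spec.spacing_mm),
        truth,
    )


def _noise_free_components(spec: TensorPhantomSpec, shape) -> np.ndarray:
    comp = np.zeros(shape + (6,))
    comp[..., 0] = comp[..., 3] = comp[..., 5] = spec.background_diffusivity
    for box, diag in ((spec.proj_region, spec.proj_tensor), (spec.assoc_region, spec.assoc_tensor)):
        m = _box_mask(box, shape)
        comp[m, 0], comp[m, 3], comp[m, 5] = diag
        comp[m, 1] = comp[m, 2] = comp[m, 4] = 0.0
    return comp


def _redraw_non_spd(comp: np.ndarray, rng, noise_sd: float, base: np.ndarray, max_rounds: int = 100) -> np.ndarray:
    """Redraw noise at voxels whose tensor lost positive-definiteness."""
    tv = TensorVolume(comp)
    for _ in range(max_rounds):
        eig = np.linalg.eigvalsh(tv.as_matrices())
        bad = eig[..., 0] <= 0
        if not bad.any():
            return tv.components
        n_bad = int(bad.sum())
        tv.components[bad] = base[bad] + rng.normal(0.0, noise_sd, size=(n_bad, 6))
    raise RuntimeError("could not draw positive-definite tensors; noise_sd too large")


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

#: CERAD-K subtest columns in fixed table order, with the domain each belongs to
SUBTEST_COLUMNS = (
    "verbal_fluency_z",
    "trail_making_b_z",
    "stroop_z",
    "boston_naming_z",
    "word_list_memory_z",
    "word_list_recall_z",
    "word_list_recognition_z",
    "constructional_recall_z",
    "mmse_z",
)

COHORT_COLUMNS = ("subject_id", "group") + ("cp_pct", "alps") + SUBTEST_COLUMNS + ("impaired",)


@dataclass
class GroupModel:
    """Normal models for one group's measured quantities."""

    n: int
    cp_mean_pct: float
    cp_sd_pct: float
    alps_mean: float
    alps_sd: float

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n per group must be >= 2")
        if self.cp_sd_pct <= 0 or self.alps_sd <= 0:
            raise ValueError("group SDs must be > 0")


@dataclass
class CohortSpec:
    """Cohort simulator: patient and control group models plus the CERAD-K
    subtest model (patients only; controls are not tested).

    ``cp_recognition_corr`` is the correlation between CP volume % and the
    word-list-recognition z-score in the patient group; the pair is drawn
    from a bivariate normal and all other subtests independently.
    """

    esrd: GroupModel
    control: GroupModel
    subtest_means: dict
    subtest_sds: dict
    cp_recognition_corr: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        self.esrd.validate()
        self.control.validate()
        if not -1.0 < self.cp_recognition_corr < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")
        for c in SUBTEST_COLUMNS:
            if c not in self.subtest_means or c not in self.subtest_sds:
                raise ValueError(f"missing subtest model for {c}")
            if self.subtest_sds[c] <= 0:
                raise ValueError(f"subtest SD for {c} must be > 0")


def generate_cohort(spec: CohortSpec, seed: int | None = None):
    """Draw a cohort table (pandas DataFrame, columns :data:`COHORT_COLUMNS`).

    Patients: (CP%, word-list-recognition z) jointly bivariate normal with
    the configured correlation; remaining subtests independent normals; ALPS
    from the group normal.  Controls: CP% and ALPS only, cognitive columns
    NaN (the study battery was administered to patients only).  The impairment
    flag applies the strict z < -1.5 / >= 2 affected-domain rule.
    """
    import pandas as pd

    from .stats import classify_impairment, subtests_by_domain

    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rows = []
    g = spec.esrd
    r = spec.cp_recognition_corr
    sd_cp, sd_z = g.cp_sd_pct, spec.subtest_sds["word_list_recognition_z"]
    cov = np.array([[sd_cp**2, r * sd_cp * sd_z], [r * sd_cp * sd_z, sd_z**2]])
    if np.linalg.eigvalsh(cov)[0] <= 0:
        raise ValueError("implied (CP%, recognition z) covariance is not positive definite")
    mean = np.array([g.cp_mean_pct, spec.subtest_means["word_list_recognition_z"]])
    pair = rng.multivariate_normal(mean, cov, size=g.n)
    alps_e = rng.normal(g.alps_mean, g.alps_sd, size=g.n)
    others = {
        c: rng.normal(spec.subtest_means[c], spec.subtest_sds[c], size=g.n)
        for c in SUBTEST_COLUMNS
        if c != "word_list_recognition_z"
    }
    for i in range(g.n):
        row = {
            "subject_id": f"esrd_{i:03d}",
            "group": "ESRD",
            "cp_pct": pair[i, 0],
            "alps": alps_e[i],
            "word_list_recognition_z": pair[i, 1],
        }
        for c, v in others.items():
            row[c] = v[i]
        scores = {dom: {c: row[c] for c in cols} for dom, cols in subtests_by_domain().items()}
        row["impaired"] = classify_impairment(scores).impaired
        rows.append(row)

    g = spec.control
    cp_c = rng.normal(g.cp_mean_pct, g.cp_sd_pct, size=g.n)
    alps_c = rng.normal(g.alps_mean, g.alps_sd, size=g.n)
    for i in range(g.n):
        row = {
            "subject_id": f"ctrl_{i:03d}",
            "group": "control",
            "cp_pct": cp_c[i],
            "alps": alps_c[i],
            "impaired": np.nan,
        }
        rows.append(row)

    df = pd.DataFrame(rows)
    for c in COHORT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df[list(COHORT_COLUMNS)]
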