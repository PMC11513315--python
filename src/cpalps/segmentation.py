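"""Choroid plexus segmentation inside a lateral-ventricle mask.

The model: voxel intensities within the ventricle mask are a K=3 univariate
Gaussian mixture — CSF (darkest on T1), choroid plexus (intermediate) and
ventricular wall / partial-volume voxels (brightest).  The mixture is fitted
by EM, each voxel gets its maximum-a-posteriori class, the CP mask is cleaned
by rule (small-component removal and a wall-contamination rule), and the
surviving volume is normalized by total intracranial volume (TIV).

The tissue convention — CP is the *middle-mean* cluster — is the single most
consequential choice here and is applied after sorting components by mean,
so it is invariant to EM component ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import CP, CSF, WALL, inner_boundary_shell
from .volume import VoxelVolume, check_aligned

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureModel:
    """Fitted univariate Gaussian mixture, components sorted by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def K(self) -> int:
        return len(self.weights)

    def log_responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Log posterior class probabilities, shape (n, K)."""
        x = np.asarray(x, dtype=float)[:, None]
        lp = (
            np.log(self.weights)[None, :]
            - 0.5 * (_LOG_2PI + np.log(self.variances))[None, :]
            - 0.5 * (x - self.means[None, :]) ** 2 / self.variances[None, :]
        )
        return lp - _logsumexp(lp)[:, None]

    def map_labels(self, x: np.ndarray) -> np.ndarray:
        """Index (into the mean-sorted components) of the MAP component."""
        return np.argmax(self.log_responsibilities(x), axis=1)


def _logsumexp(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def fit_gmm_em(
    intensities,
    K: int = 3,
    init_strategy: str = "quantile",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureModel:
    """Fit a K-component univariate Gaussian mixture by EM.

    Initialization splits the sorted sample into K equal-count chunks
    (``"quantile"``, deterministic) or uses k-means (``"kmeans"``, seeded).
    Convergence: relative log-likelihood change below ``tol``.  A variance
    floor of ``1e-6 x sample variance`` is applied at every M-step.
    Components are returned sorted by ascending mean.  Variances use the
    maximum-likelihood (biased, 1/n) normalization throughout, including the
    K=1 closed form.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("intensities contain non-finite values")
    if K < 1:
        raise ValueError("K must be >= 1")
    if x.size < 10 * K:
        raise ValueError(f"need at least {10 * K} samples for K={K}, got {x.size}")
    if np.unique(x).size < K:
        raise ValueError("K exceeds the number of distinct intensity values")

    var_floor = 1e-6 * float(np.var(x))
    var_floor = max(var_floor, np.finfo(float).tiny)

    if K == 1:
        mu, var = float(np.mean(x)), max(float(np.var(x)), var_floor)
        ll = float(np.sum(-0.5 * (_LOG_2PI + np.log(var)) - 0.5 * (x - mu) ** 2 / var))
        return MixtureModel(
            weights=np.array([1.0]), means=np.array([mu]), variances=np.array([var]),
            loglik_trace=np.array([ll]), converged=True, n_iter=0,
        )

    if init_strategy == "quantile":
        xs = np.sort(x)
        chunks = np.array_split(xs, K)
        means = np.array([c.mean() for c in chunks])
        variances = np.array([max(c.var(), var_floor) for c in chunks])
        weights = np.array([c.size / x.size for c in chunks])
    elif init_strategy == "kmeans":
        from scipy.cluster.vq import kmeans2

        rng = np.random.default_rng(seed)
        centroids, lab = kmeans2(x[:, None], K, minit="++", seed=rng)
        means = centroids.ravel().astype(float)
        variances = np.array(
            [max(x[lab == k].var(), var_floor) if np.any(lab == k) else x.var() for k in range(K)]
        )
        weights = np.array([max(np.mean(lab == k), 1.0 / x.size) for k in range(K)])
        weights = weights / weights.sum()
    else:
        raise ValueError(f"unknown init_strategy {init_strategy!r}")

    trace: list[float] = []
    converged = False
    n_iter = 0
    xx = x[:, None]
    for n_iter in range(1, max_iter + 1):
        # E-step
        lp = (
            np.log(weights)[None, :]
            - 0.5 * (_LOG_2PI + np.log(variances))[None, :]
            - 0.5 * (xx - means[None, :]) ** 2 / variances[None, :]
        )
        lse = _logsumexp(lp)
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(lp - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, np.finfo(float).tiny)
        weights = nk / x.size
        means = (resp * xx).sum(axis=0) / nk
        variances = (resp * (xx - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, var_floor)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * max(abs(prev), 1.0):
                converged = True
                break

    order = np.argsort(means)
    return MixtureModel(
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
    )


def estimate_bias_field(t1: VoxelVolume, mask: VoxelVolume, scale_mm: float = 48.0) -> VoxelVolume:
    """Estimate a smooth multiplicative bias field by homomorphic filtering.

    Log-intensities within the mask are smoothed with a broad Gaussian
    (``scale_mm`` standard deviation, per-axis in voxels), using
    mask-normalized convolution so voxels outside the mask do not leak in;
    the exponentiated result is renormalized to mean 1 over the mask.
    Dividing ``t1`` by the returned field yields the corrected image.
    """
    check_aligned(t1, mask, ("t1", "mask"))
    m = mask.values > 0
    if not m.any():
        raise ValueError("mask is empty")
    vals = np.asarray(t1.values, dtype=float)
    if np.all(vals[m] == 0):
        raise ValueError("all in-mask intensities are zero")
    if np.any(vals[m] <= 0):
        raise ValueError("bias estimation requires strictly positive in-mask intensities")
    logi = np.zeros_like(vals)
    logi[m] = np.log(vals[m])
    sigma_vox = scale_mm / t1.spacing_mm
    num = ndimage.gaussian_filter(logi, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m.astype(float), sigma=sigma_vox)
    smooth = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    smooth -= smooth[m].mean()
    fieldv = np.exp(smooth)
    fieldv /= fieldv[m].mean()
    return t1.like(fieldv)


def refine_mask(
    mask: VoxelVolume,
    min_component_vox: int = 5,
    boundary_shell: VoxelVolume | None = None,
) -> VoxelVolume:
    """Rule-based cleanup of a binary CP mask (idempotent).

    Removes 26-connected components smaller than ``min_component_vox`` and,
    when a shell is supplied, any voxels on the 1-voxel inner boundary of the
    ventricle (wall-contamination rule).  This replaces the expert's manual
    removal of obvious non-CP voxels.
    """
    m = mask.values > 0
    if boundary_shell is not None:
        check_aligned(mask, boundary_shell, ("mask", "boundary_shell"))
        m = m & ~(boundary_shell.values > 0)
    structure = np.ones((3, 3, 3), dtype=bool)
    labeled, n = ndimage.label(m, structure=structure)
    if n:
        sizes = np.bincount(labeled.ravel())
        keep = sizes >= min_component_vox
        keep[0] = False
        m = keep[labeled]
    return mask.like(m.astype(np.uint8))


def compute_normalized_volume(cp_mask: VoxelVolume, tiv_mm3: float) -> tuple[float, float]:
    """CP volume in mm³ and as a percentage of total intracranial volume."""
    if tiv_mm3 <= 0:
        raise ValueError("tiv_mm3 must be > 0")
    mm3 = float((cp_mask.values > 0).sum()) * cp_mask.voxel_volume_mm3
    return mm3, 100.0 * mm3 / tiv_mm3


@dataclass
class SegmentationOptions:
    K: int = 3
    init_strategy: str = "quantile"
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    min_component_vox: int = 5
    wall_rule: bool = True
    bias_correct: bool = False
    bias_scale_mm: float = 48.0
    #: minimum standardized separation |mu_cp - mu_neighbor| / pooled SD below
    #: which the CP component is considered merged with a neighbor
    min_separation: float = 1.0


@dataclass
class SegmentationResult:
    cp_mask: VoxelVolume
    class_map: VoxelVolume
    mixture: MixtureModel
    cp_volume_mm3: float
    cp_volume_pct: float
    qc: dict = field(default_factory=dict)


def segment_cp(
    t1: VoxelVolume,
    ventricle_mask: VoxelVolume,
    tiv_mm3: float,
    options: SegmentationOptions | None = None,
) -> SegmentationResult:
    """Segment the choroid plexus within the lateral-ventricle mask.

    Fits a K-component mixture to in-mask intensities, assigns each voxel to
    its MAP component, maps mean-sorted components to tissues (lowest = CSF,
    middle = CP, highest = wall), applies :func:`refine_mask`, and reports
    TIV-normalized volume.  If the CP component is not separated from a
    neighboring component by at least ``options.min_separation`` pooled SDs
    the fit is flagged degenerate and the CP mask is emptied, since the data
    then give no evidence of a distinct intermediate-intensity tissue.
    """
    opts = options or SegmentationOptions()
    check_aligned(t1, ventricle_mask, ("t1", "ventricle_mask"))
    if tiv_mm3 <= 0:
        raise ValueError("tiv_mm3 must be > 0")
    m = ventricle_mask.values > 0
    if not m.any():
        raise ValueError("ventricle mask is empty")

    work = t1
    if opts.bias_correct:
        fieldvol = estimate_bias_field(t1, ventricle_mask, opts.bias_scale_mm)
        work = t1.like(t1.values / fieldvol.values)

    x = np.asarray(work.values, dtype=float)[m]
    mix = fit_gmm_em(
        x, K=opts.K, init_strategy=opts.init_strategy, tol=opts.tol,
        max_iter=opts.max_iter, seed=opts.seed,
    )

    labels = mix.map_labels(x)  # indices into mean-sorted components
    # tissue codes: component 0 -> CSF, middle components -> CP, last -> wall
    tissue_of = np.full(mix.K, CP, dtype=np.uint8)
    tissue_of[0] = CSF
    tissue_of[mix.K - 1] = WALL
    class_map = np.zeros(t1.shape, dtype=np.uint8)
    class_map[m] = tissue_of[labels]

    qc: dict = {
        "converged": mix.converged,
        "iterations": mix.n_iter,
        "n_csf": int((class_map == CSF).sum()),
        "n_cp_raw": int((class_map == CP).sum()),
        "n_wall": int((class_map == WALL).sum()),
        "warnings": [],
    }

    cp_idx = np.arange(mix.K)[tissue_of == CP]
    degenerate = False
    for k in cp_idx:
        for j in (k - 1, k + 1):
            if 0 <= j < mix.K:
                sep = abs(mix.means[k] - mix.means[j]) / np.sqrt(
                    0.5 * (mix.variances[k] + mix.variances[j])
                )
                if sep < opts.min_separation:
                    degenerate = True
    if degenerate:
        qc["warnings"].append(
            "degenerate components: CP cluster not separated from a neighbor; CP mask emptied"
        )

    cp_raw = (class_map == CP) if not degenerate else np.zeros(t1.shape, dtype=bool)
    shell = ventricle_mask.like(inner_boundary_shell(m).astype(np.uint8)) if opts.wall_rule else None
    cp_clean = refine_mask(
        t1.like(cp_raw.astype(np.uint8)),
        min_component_vox=opts.min_component_vox,
        boundary_shell=shell,
    )
    qc["n_removed_by_cleanup"] = int(cp_raw.sum()) - int((cp_clean.values > 0).sum())

    mm3, pct = compute_normalized_volume(cp_clean, tiv_mm3)
    return SegmentationResult(
        cp_mask=cp_clean,
        class_map=t1.like(class_map),
        mixture=mix,
        cp_volume_mm3=mm3,
        cp_volume_pct=pct,
        qc=qc,
    )
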