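"""Voxelwise grey-matter regression with cluster-extent FWE inference.

The statistical core of the package: ordinary least squares fitted at every
voxel of a grey-matter density stack, a one-sided contrast on the predictor
of interest, cluster formation at an uncorrected voxelwise threshold
(default p < 0.01, 18-connectivity), and family-wise-error control of
cluster extent by Freedman-Lane permutation of reduced-model residuals
(null distribution = maximum suprathreshold cluster extent per permutation).

Design matrices for the three report models:

* model1     — quantitative naming score + {education, brain parenchymal
               ratio, left hippocampal volume, age}; positive contrast.
* model2     — qualitative (mean-SMI) score + the same four covariates +
               quantitative score; negative contrast (low-SMI success is
               hypothesised to go with more preserved grey matter).
* structcov  — an ROI volume + {age, intracranial volume, grey-matter
               ratio}; positive contrast (structural-covariance validation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _all_permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "ContrastSpec",
    "StatMap",
    "ClusterResult",
    "MODEL_COLUMNS",
    "build_design",
    "fit_voxelwise",
    "smooth_map",
    "form_clusters",
    "cluster_fwe",
    "report_clusters",
]

#: Predictor of interest, covariates, and contrast direction per model.
MODEL_COLUMNS: dict[str, dict] = {
    "model1": {
        "interest": "quantitative",
        "covariates": [
            "education",
            "brain_parenchymal_ratio",
            "left_hippocampus_ml",
            "age",
        ],
        "direction": "positive",
    },
    "model2": {
        "interest": "qualitative",
        "covariates": [
            "education",
            "brain_parenchymal_ratio",
            "left_hippocampus_ml",
            "age",
            "quantitative",
        ],
        "direction": "negative",
    },
    "structcov": {
        "interest": "roi_volume",
        "covariates": ["age", "icv_ml", "gm_ratio"],
        "direction": "positive",
    },
}

#: SPM-style 18-neighbour connectivity (faces + edges, not corners).
CONNECTIVITY_18 = ndimage.generate_binary_structure(3, 2)


@dataclass(frozen=True)
class ContrastSpec:
    """One-sided contrast: weights over design columns plus a tail."""

    weights: np.ndarray
    direction: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.any(w):
            raise ValueError("contrast weights are all zero")
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "positive" else -1.0


@dataclass
class StatMap:
    """Per-voxel GLM output on the analysis grid.

    ``beta``, ``t`` and ``z`` are 3D arrays (NaN outside ``mask``); ``z`` is
    the normal-quantile transform of the *directional* t tail probability,
    so large positive z always means evidence in the hypothesised tail.
    ``mask`` excludes voxels with zero residual variance.
    """

    beta: np.ndarray
    t: np.ndarray
    z: np.ndarray
    df: int
    mask: np.ndarray
    direction: str = "positive"


@dataclass
class ClusterResult:
    """Significant-cluster summary plus the maps behind it."""

    stat: StatMap
    labels: np.ndarray  # 3D int labels, sorted by descending extent
    table: pd.DataFrame  # cluster, extent_voxels, p_fwe, peak_z, peak i/j/k
    null_max_extent: np.ndarray
    t_threshold: float


# ---------------------------------------------------------------------------
# Design construction


def build_design(
    scores: pd.DataFrame, model: str
) -> tuple[pd.DataFrame, ContrastSpec]:
    """Assemble the named design matrix for one of the report models.

    All predictor columns are mean-centred (the intercept carries the grand
    mean); centring leaves the contrast t unchanged but conditions X'X.
    Raises on rank deficiency, naming the offending columns.
    """
    if model not in MODEL_COLUMNS:
        raise ValueError(f"unknown model {model!r}; choose {sorted(MODEL_COLUMNS)}")
    layout = MODEL_COLUMNS[model]
    cols = [layout["interest"], *layout["covariates"]]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ValueError(f"scores table lacks columns {missing}")
    X = pd.DataFrame({"intercept": np.ones(len(scores))}, index=scores.index)
    for c in cols:
        v = scores[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in column {c!r}")
        X[c] = v - v.mean()
    _check_rank(X)
    n, p = X.shape
    if n <= p + 10:
        raise ValueError(f"too few rows ({n}) for {p} columns (need > p + 10)")
    weights = np.zeros(X.shape[1])
    weights[X.columns.get_loc(layout["interest"])] = 1.0
    return X, ContrastSpec(weights=weights, direction=layout["direction"])


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify collinear columns from the QR diagonal
        _, R = np.linalg.qr(A)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad = [X.columns[i] for i in np.where(diag <= tol)[0]]
        raise ValueError(f"design matrix is rank deficient (collinear: {bad})")


# ---------------------------------------------------------------------------
# Voxelwise OLS


class _GLMEngine:
    """Precomputed quantities for fast repeated contrast-t evaluation.

    With Q an orthonormal basis of X and a = X (X'X)^-1 c, the contrast
    numerator is a'Y and the residual sum of squares is
    sum(Y^2) - sum((Q'Y)^2) per voxel, so each evaluation is two matrix
    products.
    """

    def __init__(self, X: np.ndarray, c: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        self.rank = np.linalg.matrix_rank(X)
        if self.rank < self.p:
            raise ValueError("design matrix is rank deficient")
        self.df = self.n - self.rank
        if self.df < 1:
            raise ValueError("no residual degrees of freedom")
        self.Q, _ = np.linalg.qr(X)
        XtX_inv = np.linalg.inv(X.T @ X)
        self.a = X @ (XtX_inv @ c)  # numerator functional, orthogonal to nuisance
        self.cXXc = float(c @ XtX_inv @ c)

    def contrast_and_t(self, Y: np.ndarray, ss_y: np.ndarray | None = None):
        """Return (c'beta_hat, t, valid) per voxel for response matrix Y."""
        if ss_y is None:
            ss_y = np.einsum("ij,ij->j", Y, Y)
        qty = self.Q.T @ Y
        rss = ss_y - np.einsum("ij,ij->j", qty, qty)
        rss = np.maximum(rss, 0.0)
        num = self.a @ Y
        # zero residual variance -> t undefined (1e-10 relative absorbs the
        # cancellation error of the sum-of-squares identity)
        tiny = np.maximum(ss_y, 1.0) * 1e-10
        valid = rss > tiny
        denom = np.sqrt(rss / self.df * self.cXXc)
        t = np.full(Y.shape[1], np.nan)
        np.divide(num, denom, out=t, where=valid)
        return num, t, valid


def fit_voxelwise(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    contrast: ContrastSpec,
    mask: np.ndarray,
) -> StatMap:
    """Ordinary least squares at every in-mask voxel.

    ``Y`` is participants x voxels with voxels enumerated in C order over
    ``mask`` (a 3D boolean array); rows align with the design rows.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    mask = np.asarray(mask, dtype=bool)
    if Y.shape[0] != Xa.shape[0]:
        raise ValueError("Y rows must align with design rows")
    if Y.shape[1] != int(mask.sum()):
        raise ValueError("Y columns must match the number of in-mask voxels")
    eng = _GLMEngine(Xa, contrast.weights)
    cbeta, t, valid = eng.contrast_and_t(np.asarray(Y, dtype=float))
    s = contrast.sign * t
    with np.errstate(invalid="ignore"):
        z = _t_to_z(s, eng.df)
    beta3 = _unmask(cbeta, mask)
    t3 = _unmask(np.where(valid, t, np.nan), mask)
    z3 = _unmask(np.where(valid, z, np.nan), mask)
    mask_valid = mask.copy()
    mask_valid[mask] = valid
    return StatMap(
        beta=beta3, t=t3, z=z3, df=eng.df, mask=mask_valid,
        direction=contrast.direction,
    )


def _t_to_z(s: np.ndarray, df: int) -> np.ndarray:
    """Map a (directional) t value to the z with the same tail probability."""
    # work in log space so very large |t| does not saturate at z = inf
    logp_upper = stats.t.logsf(s, df)
    return stats.norm.isf(np.exp(np.clip(logp_upper, -700.0, 0.0)))


def _unmask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    out[mask] = values
    return out


# ---------------------------------------------------------------------------
# Smoothing


def smooth_map(img: np.ndarray, fwhm_mm: float, voxel_mm: float | Sequence[float]) -> np.ndarray:
    """Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxel units.
    Reflective boundary handling relocates kernel mass that would leave the
    grid, so the total image sum is conserved.  fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(img, dtype=float).copy()
    voxel = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (img.ndim,))
    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel
    return ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma=sigma_vox, mode="reflect")


# ---------------------------------------------------------------------------
# Cluster formation and permutation FWE


def form_clusters(
    stat: StatMap, p_form: float = 0.01
) -> tuple[np.ndarray, np.ndarray, float]:
    """Label suprathreshold voxels by 18-connectivity.

    The one-sided cluster-forming threshold is the t quantile at ``p_form``
    in the contrast's tail.  Returns (labels, extents, t_threshold) with
    labels renumbered in order of descending extent (label 1 = largest).
    An empty suprathreshold set yields an all-zero label map.
    """
    if not 0 < p_form < 1:
        raise ValueError("p_form must be in (0, 1)")
    t_crit = float(stats.t.isf(p_form, stat.df))
    sign = 1.0 if stat.direction == "positive" else -1.0
    with np.errstate(invalid="ignore"):
        supra = (sign * np.nan_to_num(stat.t, nan=-np.inf * sign)) >= t_crit
    supra &= stat.mask
    labels, extents = _label_and_sort(supra)
    return labels, extents, t_crit


def _label_and_sort(supra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    raw, n = ndimage.label(supra, structure=CONNECTIVITY_18)
    if n == 0:
        return raw, np.zeros(0, dtype=int)
    counts = np.bincount(raw.ravel())[1:]
    order = np.argsort(-counts, kind="stable")
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[raw], counts[order]


def _max_extent(supra: np.ndarray) -> int:
    raw, n = ndimage.label(supra, structure=CONNECTIVITY_18)
    if n == 0:
        return 0
    return int(np.bincount(raw.ravel())[1:].max())


def cluster_fwe(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    contrast: ContrastSpec,
    mask: np.ndarray,
    p_form: float = 0.01,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> ClusterResult:
    """Cluster-extent FWE inference by Freedman-Lane permutation.

    The predictor of interest (the single non-zero contrast weight) is the
    column whose association with Y is broken: Y is residualized on the
    nuisance columns, the residual rows are permuted, and the full model is
    refitted per permutation.  The null distribution is the maximum
    suprathreshold cluster extent per permutation; each observed cluster's
    FWE p is (1 + #{null max >= extent}) / (1 + n_perm).

    With ``exhaustive=True`` (or whenever n_perm >= n!) all n! row
    permutations are enumerated and p = #{null max >= extent} / n!
    (the identity permutation reproduces the observed statistic).
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Y = np.asarray(Y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = Xa.shape[0]
    w = contrast.weights
    nz = np.flatnonzero(w)
    if len(nz) != 1:
        raise ValueError("permutation inference needs a single-column contrast")

    stat = fit_voxelwise(Y, Xa, contrast, mask)
    labels, extents, t_crit = form_clusters(stat, p_form)

    # Freedman-Lane: residualize Y on the nuisance design
    Z = np.delete(Xa, nz[0], axis=1)
    if Z.size:
        Qz, _ = np.linalg.qr(Z)
        E = Y - Qz @ (Qz.T @ Y)
    else:
        E = Y.copy()
    eng = _GLMEngine(Xa, w)
    sign = contrast.sign

    if not exhaustive and n <= 20 and n_perm >= math.factorial(n):
        exhaustive = True

    # The null loop runs in single precision: extents are integer counts and
    # permutation t values sit far from machine resolution, so float32 only
    # perturbs voxels exactly at the forming threshold.
    E32 = E.astype(np.float32)
    Q32 = eng.Q.astype(np.float32)
    a32 = eng.a.astype(np.float32)
    ss_e = np.einsum("ij,ij->j", E32, E32)  # invariant under row permutation
    scale = np.float32(eng.cXXc / eng.df)

    def perm_max_extent(idx: np.ndarray) -> int:
        Ep = E32[idx]
        qty = Q32.T @ Ep
        rss = np.maximum(ss_e - np.einsum("ij,ij->j", qty, qty), 0.0)
        num = (a32 @ Ep) * np.float32(sign)
        supra_flat = (rss > ss_e * 1e-5) & (num >= t_crit * np.sqrt(rss * scale))
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = supra_flat
        return _max_extent(supra)

    if exhaustive:
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9")
        null_max = np.array(
            [perm_max_extent(np.array(p)) for p in _all_permutations(range(n))],
            dtype=int,
        )
        p_fwe = np.array(
            [(null_max >= e).sum() / len(null_max) for e in extents]
        )
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        null_max = np.empty(n_perm, dtype=int)
        for k in range(n_perm):
            null_max[k] = perm_max_extent(rng.permutation(n))
        p_fwe = np.array(
            [(1 + (null_max >= e).sum()) / (1 + n_perm) for e in extents]
        )

    rows = []
    for lab, (extent, p) in enumerate(zip(extents, p_fwe), start=1):
        in_cluster = labels == lab
        zvals = np.where(in_cluster, stat.z, -np.inf)
        peak = np.unravel_index(np.nanargmax(np.nan_to_num(zvals, nan=-np.inf)), zvals.shape)
        rows.append(
            {
                "cluster": lab,
                "extent_voxels": int(extent),
                "p_fwe": float(p),
                "peak_z": float(stat.z[peak]),
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "extent_voxels", "p_fwe", "peak_z", "peak_i", "peak_j", "peak_k"],
    )
    return ClusterResult(
        stat=stat, labels=labels, table=table,
        null_max_extent=null_max, t_threshold=t_crit,
    )


# ---------------------------------------------------------------------------
# Reporting


def report_clusters(
    result: ClusterResult,
    masks: Mapping[str, np.ndarray] | None = None,
    z_floor: float = 3.50,
    fwe_alpha: float = 0.05,
    voxel_mm: float | Sequence[float] = 1.0,
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """One row per reportable local maximum of each significant cluster.

    Local maxima are in-cluster voxels that are maximal over their 26
    neighbourhood with z above ``z_floor``; each row is annotated with the
    names of the ROI masks containing the peak.  mm coordinates come from a
    diagonal voxel-size affine with the given origin.
    """
    z = np.nan_to_num(result.stat.z, nan=-np.inf)
    voxel = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    origin = np.asarray(origin_mm, dtype=float)
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = ndimage.maximum_filter(z, footprint=footprint, mode="constant", cval=-np.inf) == z
    rows = []
    for _, crow in result.table.iterrows():
        if crow["p_fwe"] > fwe_alpha:
            continue
        lab = int(crow["cluster"])
        in_cluster = result.labels == lab
        peaks = np.argwhere(in_cluster & is_max & (z > z_floor))
        # strongest peaks first
        peaks = sorted(map(tuple, peaks), key=lambda p: -z[p])
        for ijk in peaks:
            roi_names = []
            if masks:
                roi_names = [name for name, m in masks.items() if m[ijk]]
            mm = origin + np.asarray(ijk) * voxel
            rows.append(
                {
                    "cluster": lab,
                    "p_fwe": float(crow["p_fwe"]),
                    "extent_voxels": int(crow["extent_voxels"]),
                    "peak_z": float(z[ijk]),
                    "i": ijk[0],
                    "j": ijk[1],
                    "k": ijk[2],
                    "x_mm": float(mm[0]),
                    "y_mm": float(mm[1]),
                    "z_mm": float(mm[2]),
                    "rois": ",".join(roi_names),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "p_fwe", "extent_voxels", "peak_z",
            "i", "j", "k", "x_mm", "y_mm", "z_mm", "rois",
        ],
    )
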