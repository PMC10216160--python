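"""Global and regional volumetry plus residualized score-volume correlation.

Volumes are integrals of tissue density over the voxel grid (modulated maps:
summing density times voxel volume yields millilitres).  The post-hoc
analysis regresses the qualitative (mean-SMI) score on the quantitative
count, standardizes the residuals, and correlates them with mediotemporal
ROI volumes using one-tailed tests whose direction is fixed a priori by the
whole-brain contrast (negative for the qualitative score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TissueSet",
    "VolumetricSummary",
    "tissue_volumes",
    "roi_volume",
    "residualize",
    "roi_correlation",
    "roi_correlation_table",
    "collinearity_vif",
]


@dataclass
class TissueSet:
    """Grey/white/CSF density maps on one shared grid.

    ``voxel_mm`` is the edge length per axis in mm (scalar or 3-sequence).
    Densities are unitless voxel occupancy fractions, >= 0.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_mm: float | Sequence[float] = 1.0

    def __post_init__(self) -> None:
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ValueError("tissue maps must share one grid")
        for name in ("gm", "wm", "csf"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise ValueError(f"{name} density has negative values")

    @property
    def voxel_volume_mm3(self) -> float:
        v = np.broadcast_to(np.asarray(self.voxel_mm, dtype=float), (3,))
        return float(np.prod(v))


@dataclass(frozen=True)
class VolumetricSummary:
    gm_ml: float
    wm_ml: float
    csf_ml: float
    icv_ml: float  # intracranial volume = gm + wm + csf
    bpr: float  # brain parenchymal ratio = (gm + wm) / icv


def tissue_volumes(tissues: TissueSet) -> VolumetricSummary:
    """Integrate each tissue map to ml and derive ICV and parenchymal ratio."""
    vv = tissues.voxel_volume_mm3
    gm = float(tissues.gm.sum()) * vv / 1000.0
    wm = float(tissues.wm.sum()) * vv / 1000.0
    csf = float(tissues.csf.sum()) * vv / 1000.0
    icv = gm + wm + csf
    if icv <= 0:
        raise ValueError("zero intracranial volume")
    return VolumetricSummary(
        gm_ml=gm, wm_ml=wm, csf_ml=csf, icv_ml=icv, bpr=(gm + wm) / icv
    )


def roi_volume(
    gm: np.ndarray, mask: np.ndarray, voxel_mm: float | Sequence[float]
) -> float:
    """Grey-matter volume (ml) inside a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != gm.shape:
        raise ValueError("mask must share the grey-matter grid")
    if not mask.any():
        raise ValueError("empty ROI mask")
    v = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    return float(gm[mask].sum()) * float(np.prod(v)) / 1000.0


def residualize(
    qualitative: Sequence[float], quantitative: Sequence[float]
) -> np.ndarray:
    """Standardized residuals of qualitative regressed on quantitative.

    OLS with intercept; residuals are divided by their sample standard
    deviation (ddof=1), giving scores with mean 0, SD 1, orthogonal to the
    quantitative predictor.
    """
    y = np.asarray(qualitative, dtype=float)
    x = np.asarray(quantitative, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("inputs must be paired 1D sequences")
    if len(y) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite inputs")
    if np.ptp(x) == 0:
        raise ValueError("quantitative scores have zero variance")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=1)
    if sd <= max(np.abs(y).max(), 1.0) * 1e-10:
        raise ValueError(
            "residuals are identically zero; qualitative is an exact linear "
            "function of quantitative"
        )
    return resid / sd


def roi_correlation(
    residuals: Sequence[float],
    volumes: Sequence[float],
    tail: str = "negative",
) -> tuple[float, float]:
    """Pearson r between residual scores and ROI volumes, one-tailed p.

    p comes from t = r sqrt((n-2)/(1-r^2)) evaluated in the requested tail.
    """
    if tail not in ("negative", "positive"):
        raise ValueError(f"unknown tail {tail!r}")
    res = np.asarray(residuals, dtype=float)
    vol = np.asarray(volumes, dtype=float)
    if res.shape != vol.shape or res.ndim != 1:
        raise ValueError("inputs must be paired 1D sequences")
    n = len(res)
    if n < 10:
        raise ValueError("need at least 10 pairs")
    if np.ptp(vol) == 0:
        raise ValueError("constant ROI volumes")
    r = float(stats.pearsonr(res, vol).statistic)
    p = r_one_tailed_p(r, n, tail)
    return r, p


def r_one_tailed_p(r: float, n: int, tail: str = "negative") -> float:
    """Closed-form one-tailed p for a Pearson r at sample size n."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    if tail == "negative":
        return float(stats.t.cdf(t, n - 2))
    return float(stats.t.sf(t, n - 2))


def roi_correlation_table(
    residuals: Sequence[float],
    roi_volumes: Mapping[str, Sequence[float]],
    tail: str = "negative",
) -> pd.DataFrame:
    """One-tailed residual-score correlation per named ROI.

    The six mediotemporal ROIs are each tested in the same a-priori tail; no
    multiple-testing correction is applied across ROIs (flagged in the
    ``uncorrected`` column so downstream reports state it explicitly).
    """
    rows = []
    for name, vols in roi_volumes.items():
        r, p = roi_correlation(residuals, vols, tail=tail)
        rows.append(
            {
                "roi": name,
                "n": len(np.asarray(vols)),
                "r": r,
                "p_one_tailed": p,
                "tail": tail,
                "uncorrected": True,
            }
        )
    return pd.DataFrame(rows)


def collinearity_vif(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Two-variable variance inflation factor, 1 / (1 - r^2).

    Returns inf for perfectly correlated inputs.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1D sequences")
    r = float(stats.pearsonr(a, b).statistic)
    if 1.0 - r * r <= 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r * r)
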