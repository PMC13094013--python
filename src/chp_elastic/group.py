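"""Group-level inference on CVR maps.

Voxel-wise one-sample t and covariate-regression maps with uncorrected
p-thresholding plus cluster-extent filtering (default p < 0.005, cluster
size > 50 voxels), and subject-level ROI regressions with a sex covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import ndimage, stats

from .cvr import CVRMap
from .errors import InvalidArgumentError


@dataclass(frozen=True)
class Cluster:
    label: int
    size: int
    peak_t: float
    peak_index: tuple[int, int, int]


@dataclass
class ClusterResult:
    """Thresholded voxel-wise test result.

    ``surviving_mask`` is the union of clusters that exceeded the extent
    threshold; ``zero_variance_mask`` flags voxels where the test statistic
    was undefined (t set to 0).
    """

    t_map: np.ndarray
    p_threshold: float
    cluster_min: int
    clusters: list[Cluster]
    surviving_mask: np.ndarray
    direction: str
    zero_variance_mask: np.ndarray = field(default=None)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise InvalidArgumentError("connectivity must be 6 or 26")


def _stack(maps: list[CVRMap]) -> tuple[np.ndarray, np.ndarray]:
    if len(maps) < 3:
        raise InvalidArgumentError("need at least 3 subjects")
    common = maps[0].mask.copy()
    for m in maps[1:]:
        if m.values.shape != common.shape:
            raise InvalidArgumentError("maps must share a common grid")
        common &= m.mask
    data = np.stack([m.values for m in maps], axis=0)
    return data, common


def _threshold_and_cluster(
    t_map: np.ndarray,
    p_map: np.ndarray,
    mask: np.ndarray,
    direction: str,
    p_threshold: float,
    cluster_min: int,
    connectivity: int,
    zero_var: np.ndarray,
) -> ClusterResult:
    sign_ok = t_map < 0 if direction == "negative" else t_map > 0
    supra = mask & sign_ok & (p_map < p_threshold) & ~zero_var
    labeled, n = ndimage.label(supra, structure=_structure(connectivity))
    clusters: list[Cluster] = []
    surviving = np.zeros_like(supra)
    for lab in range(1, n + 1):
        members = labeled == lab
        size = int(members.sum())
        if size > cluster_min:
            tvals = np.where(members, t_map, 0.0)
            flat = np.abs(tvals).argmax()
            peak = np.unravel_index(flat, t_map.shape)
            clusters.append(Cluster(lab, size, float(t_map[peak]), tuple(int(i) for i in peak)))
            surviving |= members
    clusters.sort(key=lambda c: -c.size)
    return ClusterResult(
        t_map=t_map,
        p_threshold=p_threshold,
        cluster_min=cluster_min,
        clusters=clusters,
        surviving_mask=surviving,
        direction=direction,
        zero_variance_mask=zero_var,
    )


def one_sample_t_map(
    maps: list[CVRMap],
    direction: str = "negative",
    p_threshold: float = 0.005,
    cluster_min: int = 50,
    connectivity: int = 26,
) -> ClusterResult:
    """Voxel-wise one-sample t-test of subject maps against 0.

    t = mean / (sd / sqrt(n)); one-sided p in the direction of interest;
    voxels pass at p < p_threshold, then connected components larger than
    ``cluster_min`` voxels survive. Zero-variance voxels get t = 0 and are
    flagged, not an error.
    """
    if direction not in ("negative", "positive"):
        raise InvalidArgumentError("direction must be 'negative' or 'positive'")
    data, mask = _stack(maps)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = mask & (sd == 0)
    t_map = np.zeros_like(mean)
    ok = mask & ~zero_var
    t_map[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    df = n - 1
    p_map = np.ones_like(mean)
    if direction == "negative":
        p_map[ok] = stats.t.cdf(t_map[ok], df)
    else:
        p_map[ok] = stats.t.sf(t_map[ok], df)
    return _threshold_and_cluster(
        t_map, p_map, mask, direction, p_threshold, cluster_min, connectivity, zero_var
    )


def regression_map(
    maps: list[CVRMap],
    covariate: np.ndarray,
    direction: str = "positive",
    p_threshold: float = 0.005,
    cluster_min: int = 50,
    connectivity: int = 26,
) -> ClusterResult:
    """Voxel-wise simple regression of subject maps on a covariate (e.g. age).

    The t-statistic of the slope is thresholded exactly as in
    :func:`one_sample_t_map`; the default direction 'positive' targets
    age-related attenuation of negative CVR.
    """
    data, mask = _stack(maps)
    x = np.asarray(covariate, float)
    if x.shape != (data.shape[0],):
        raise InvalidArgumentError("covariate length must equal the number of subjects")
    if np.std(x) == 0:
        raise InvalidArgumentError("covariate is constant")
    n = data.shape[0]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = data - data.mean(axis=0)
    slope = np.tensordot(xc, yc, axes=(0, 0)) / sxx
    resid = yc - slope[None] * xc[:, None, None, None]
    df = n - 2
    mse = (resid**2).sum(axis=0) / df
    se = np.sqrt(mse / sxx)
    zero_var = mask & (se == 0)
    t_map = np.zeros_like(slope)
    ok = mask & ~zero_var
    t_map[ok] = slope[ok] / se[ok]
    p_map = np.ones_like(slope)
    if direction == "negative":
        p_map[ok] = stats.t.cdf(t_map[ok], df)
    else:
        p_map[ok] = stats.t.sf(t_map[ok], df)
    return _threshold_and_cluster(
        t_map, p_map, mask, direction, p_threshold, cluster_min, connectivity, zero_var
    )


@dataclass(frozen=True)
class RoiRegressionResult:
    beta: float
    ci95: tuple[float, float]
    p: float
    predictor: str
    n: int


def roi_regression(table: pd.DataFrame, predictor: str = "age") -> RoiRegressionResult:
    """OLS of subject ROI values on age or group, with sex as covariate.

    roi_value ~ intercept + predictor + sex; returns the predictor
    coefficient with its normal-theory 95% CI and two-sided p. For the
    categorical ``group`` predictor the coefficient is the old-minus-young
    contrast.
    """
    required = {"roi_value", predictor, "sex"}
    if not required.issubset(table.columns):
        raise InvalidArgumentError(f"table must contain columns {sorted(required)}")
    if table["roi_value"].isna().any():
        raise InvalidArgumentError("roi_value contains missing entries")
    if table["sex"].nunique() < 2:
        raise InvalidArgumentError("sex covariate needs at least 2 levels")
    if predictor == "age":
        formula = "roi_value ~ age + C(sex)"
        term = "age"
        if (table["age"] <= 0).any():
            raise InvalidArgumentError("ages must be positive")
    elif predictor == "group":
        if table["group"].nunique() < 2:
            raise InvalidArgumentError("group predictor needs at least 2 levels")
        formula = "roi_value ~ C(group, Treatment('young')) + C(sex)"
        term = "C(group, Treatment('young'))[T.old]"
    else:
        raise InvalidArgumentError("predictor must be 'age' or 'group'")
    fit = smf.ols(formula, data=table).fit()
    if term not in fit.params.index:
        raise InvalidArgumentError(f"design is rank deficient; missing term {term!r}")
    ci = fit.conf_int().loc[term]
    return RoiRegressionResult(
        beta=float(fit.params[term]),
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues[term]),
        predictor=predictor,
        n=len(table),
    )


def roi_extract(cvr_map: CVRMap, roi_mask: np.ndarray) -> float:
    """Mean map value over an ROI (intersected with the map's valid mask)."""
    return cvr_map.mean_in(roi_mask)
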