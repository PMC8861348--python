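"""HU-error metrics, rank statistics and cohort summaries.

Mirrors the validation machinery of an sCT-vs-CT comparison study:

* mean error (ME) and mean absolute error (MAE) in HU by region, with
  the superior and inferior end slabs excluded to avoid regions of image
  degradation at the edge of the imaged volume;
* an exact / normal-approximation Mann-Whitney U test for comparing
  per-patient metric distributions between methods or cohorts;
* cohort summary tables: median and IQR for percentage dose differences,
  mean +/- 1 SD for gamma and HU-error quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ImageVolume

# gamma lives in its own module; re-exported here for a single evaluation surface
from .gamma import GammaCriteria, GammaResult, STANDARD_CRITERIA, gamma_3d  # noqa: F401


@dataclass(frozen=True)
class HUErrorReport:
    me: float
    mae: float
    region: str
    n_voxels: int


def end_slab_slices(n_slices: int, spacing_z: float, exclusion_mm: float) -> int:
    """Number of axial slices removed from each end for a given exclusion depth."""
    return int(math.ceil(exclusion_mm / spacing_z)) if exclusion_mm > 0 else 0


def hu_error(
    sct: ImageVolume,
    ct: ImageVolume,
    region: np.ndarray,
    region_name: str = "whole_body",
    exclusion_mm: float = 30.0,
) -> HUErrorReport:
    """ME and MAE of sCT vs CT over ``region``, end slabs excluded.

    The top and bottom ``exclusion_mm`` of the volume (rounded up to
    whole slices) do not contribute.
    """
    if not sct.same_grid(ct):
        raise ValueError("sCT and CT are on different grids")
    mask = np.asarray(region, dtype=bool).copy()
    k = end_slab_slices(mask.shape[0], sct.spacing[0], exclusion_mm)
    if k > 0:
        mask[:k] = False
        if k > 0:
            mask[-k:] = False
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"region {region_name!r} is empty after end-slab exclusion")
    diff = np.asarray(sct.data, dtype=float)[mask] - np.asarray(ct.data, dtype=float)[mask]
    return HUErrorReport(
        me=float(diff.mean()), mae=float(np.abs(diff).mean()), region=region_name, n_voxels=n
    )


def hu_error_by_region(
    sct: ImageVolume,
    ct: ImageVolume,
    body: np.ndarray,
    bone: np.ndarray,
    exclusion_mm: float = 30.0,
) -> dict[str, HUErrorReport]:
    """Whole-body, bone and soft-tissue (body minus bone) HU error reports."""
    regions = {
        "whole_body": body,
        "bone": bone,
        "soft_tissue": body & ~bone,
    }
    return {
        name: hu_error(sct, ct, mask, name, exclusion_mm) for name, mask in regions.items()
    }


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_value: float  # two-sided
    method: str  # "exact" or "normal_approx"


def _exact_u_distribution(n: int, m: int) -> np.ndarray:
    """Counts of subsets of {1..n+m} of size n by their U statistic (no ties).

    ``dist[u]`` is the number of placements of the first sample among the
    pooled ranks giving U = u; the full null distribution over all
    C(n+m, n) equally likely arrangements.
    """
    nm = n * m
    dp = np.zeros((n + 1, nm + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, n + m + 1):
        # assigning pooled rank i as the k-th smallest of sample a adds
        # (i - k) to U (the number of b values below it)
        for k in range(min(i, n), 0, -1):
            shift = i - k
            if shift > nm:
                continue
            dp[k, shift:] += dp[k - 1, : nm + 1 - shift]
    return dp[n]


def mann_whitney_u(a, b, exact_max_n: int = 8) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution by full enumeration when
    ``min(n, m) <= exact_max_n`` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must contain at least one value")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    # U of sample a: number of (a_i, b_j) pairs with a_i > b_j (+1/2 per tie)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    u_a = float(gt) + 0.5 * float(eq)

    if not has_ties and min(n, m) <= exact_max_n:
        dist = _exact_u_distribution(n, m)
        total = dist.sum()
        p_le = dist[: int(u_a) + 1].sum() / total
        p_ge = dist[int(math.ceil(u_a)) :].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u=u_a, p_value=float(p), method="exact")

    mu = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (nm * (nm - 1)) if nm > 1 else 0.0
    var = n * m / 12.0 * (nm + 1 - tie_term)
    if var <= 0:
        return MannWhitneyResult(u=u_a, p_value=1.0, method="normal_approx")
    z = (abs(u_a - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * 0.5 * math.erfc(z / math.sqrt(2.0)))
    return MannWhitneyResult(u=u_a, p_value=p, method="normal_approx")


def _iqr(values: np.ndarray) -> tuple[float, float]:
    """25th/75th percentiles with linear interpolation."""
    lo, hi = np.percentile(values, [25.0, 75.0])
    return float(lo), float(hi)


#: metric-name fragments summarized as median (IQR); everything else mean +/- SD
MEDIAN_METRIC_HINTS = ("pdd", "dose_diff")


def summarize_cohort(per_case: pd.DataFrame, grouping: str = "all") -> pd.DataFrame:
    """Cohort summary table from tidy per-case metrics.

    ``per_case`` needs columns ``case, group, method, metric, value``.
    Percentage-dose-difference metrics (name containing ``pdd`` or
    ``dose_diff``) are summarized as median with 25th/75th-percentile
    IQR; gamma and HU-error metrics as mean +/- 1 SD (sample SD, reported
    as 0 for a single case).  ``grouping`` is ``all`` or one of the group
    labels present (e.g. ``male`` / ``female``).
    """
    required = {"case", "group", "method", "metric", "value"}
    if not required.issubset(per_case.columns):
        raise ValueError(f"per-case table must have columns {sorted(required)}")
    if grouping == "all":
        df = per_case
    else:
        if grouping not in set(per_case["group"]):
            raise ValueError(f"unknown group label {grouping!r}")
        df = per_case[per_case["group"] == grouping]

    rows = []
    for (method, metric), sub in df.groupby(["method", "metric"], sort=True):
        values = sub["value"].to_numpy(dtype=float)
        is_median_metric = any(h in str(metric).lower() for h in MEDIAN_METRIC_HINTS)
        lo, hi = _iqr(values)
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        rows.append(
            {
                "method": method,
                "group": grouping,
                "metric": metric,
                "n": values.size,
                "summary": "median_iqr" if is_median_metric else "mean_sd",
                "median": float(np.median(values)),
                "iqr_low": lo,
                "iqr_high": hi,
                "mean": float(np.mean(values)),
                "sd": sd,
            }
        )
    return pd.DataFrame(rows)
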