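"""Small-area descriptive statistics: rates, SHRs, variation measures,
pairwise SHR correlations, and Moran's I with a permutation test.

These are the classical summaries computed before any model fitting:
crude and directly standardized rates per 100,000 person-years, the
extremal quotient restricted to the 5th-95th percentile band (EQ5-95),
a moment-based empirical-Bayes estimate of between-area relative-risk
variance, and global spatial autocorrelation of a surface on the area
graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .areal import AreaConditionData, AreaGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with a random-relabeling permutation p-value."""

    i_statistic: float
    p_value: float
    n_permutations: int

    def __post_init__(self):
        if not self.p_value >= 1.0 / (self.n_permutations + 1):
            raise ValueError("permutation p-value below attainable minimum")


def crude_rate(count: int, person_years: float, per: float = 100_000.0) -> float:
    """Admissions per ``per`` person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / person_years * per


def direct_standardized_rate(area_stratum_rates, standard_weights) -> float:
    """Directly age-standardized rate: weighted mean of stratum rates.

    Weights are normalized internally from standard-population
    person-years; they must not all be zero.
    """
    r = np.asarray(area_stratum_rates, dtype=float)
    w = np.asarray(standard_weights, dtype=float)
    if r.shape != w.shape:
        raise ValueError("rates and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot == 0:
        raise ValueError("all-zero standard weights")
    return float(r @ (w / tot))


def shr(observed: int, expected: float) -> float:
    """Standardized hospitalization ratio observed/expected."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    if observed < 0:
        raise ValueError("observed must be non-negative")
    return observed / expected


def eq_quantile(rates, lower: float = 0.05, upper: float = 0.95,
                min_areas: int = 20) -> float | None:
    """Extremal quotient after trimming beyond the 5th/95th percentiles.

    Returns the ratio of the interpolated upper to lower percentile
    (linear-interpolation, "type 7" quantiles). Undefined (``None``) when
    fewer than ``min_areas`` areas are available or the lower percentile
    is zero — the latter occurs for rare conditions where >=5% of areas
    record no admissions.
    """
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        raise ValueError("empty rates vector")
    if (r < 0).any():
        raise ValueError("negative rate")
    if r.size < min_areas:
        return None
    q_lo, q_hi = np.quantile(r, [lower, upper])  # numpy default is type-7 linear
    if q_lo == 0:
        return None
    return float(q_hi / q_lo)


def eb_variance(observed, expected) -> float:
    """Moment estimator of between-area relative-risk variance.

    Under ``o_i ~ Poisson(e_i * rho_i)`` with ``E[rho]=1`` and
    ``Var(rho)=tau^2``, ``Var(o_i/e_i) = tau^2 + 1/e_i`` (to first
    order), so ``tau^2`` is estimated by
    ``max(0, mean_i[(o_i/e_i - 1)^2 - 1/e_i])``.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(max(0.0, np.mean((o / e - 1.0) ** 2 - 1.0 / e)))


def shr_correlations(shr_matrix, conditions=None):
    """Pairwise Pearson correlations of SHRs across areas.

    Returns ``(r, p)`` DataFrames, symmetric with unit diagonal and
    two-sided t-test p-values. Pairs involving a zero-variance column
    get NaN.
    """
    x = np.asarray(shr_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("shr_matrix must be 2-D (areas x conditions)")
    n, j = x.shape
    if n < 3:
        raise ValueError("need at least 3 areas")
    if conditions is None:
        conditions = [f"c{k}" for k in range(j)]
    r = np.eye(j)
    p = np.zeros((j, j))
    sd = x.std(axis=0)
    for a in range(j):
        for b in range(a + 1, j):
            if sd[a] == 0 or sd[b] == 0:
                r[a, b] = r[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
            else:
                res = stats.pearsonr(x[:, a], x[:, b])
                r[a, b] = r[b, a] = res.statistic
                p[a, b] = p[b, a] = res.pvalue
    return (pd.DataFrame(r, index=conditions, columns=conditions),
            pd.DataFrame(p, index=conditions, columns=conditions))


def _moran_statistic(z: np.ndarray, edges: np.ndarray) -> float:
    # I = (N / sum w) * (sum_ij w_ij z_i z_j) / (sum z^2), binary symmetric w;
    # each undirected edge contributes twice to both sums.
    n = z.size
    cross = 2.0 * np.sum(z[edges[:, 0]] * z[edges[:, 1]])
    w_sum = 2.0 * edges.shape[0]
    return (n / w_sum) * cross / np.sum(z * z)


def morans_i(values, graph: AreaGraph, n_permutations: int = 999,
             seed: int | None = None) -> MoranResult:
    """Moran's I on the area graph with binary (non-row-standardized)
    weights, and a two-sided permutation p-value
    ``(1 + #{|I*| >= |I|}) / (n_permutations + 1)``.

    Isolated areas are excluded (with a warning) since they contribute
    no weight.
    """
    v = np.asarray(values, dtype=float)
    if v.size != graph.n_areas:
        raise ValueError("values length must equal number of areas")
    edges = np.asarray(graph.edges(), dtype=int)
    if edges.size == 0:
        raise ValueError("graph has no edges")
    isolated = graph.isolated_areas()
    if isolated:
        logger.warning("excluding %d isolated area(s) from Moran's I", len(isolated))
        idx = graph.index
        keep = np.array([a not in set(isolated) for a in graph.area_ids])
        remap = -np.ones(graph.n_areas, dtype=int)
        remap[keep] = np.arange(keep.sum())
        edges = np.column_stack([remap[edges[:, 0]], remap[edges[:, 1]]])
        v = v[keep]
    if v.std() == 0:
        raise ValueError("constant values vector")
    z = v - v.mean()
    i_obs = _moran_statistic(z, edges)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        if abs(_moran_statistic(zp, edges)) >= abs(i_obs):
            hits += 1
    return MoranResult(i_statistic=float(i_obs),
                       p_value=(1 + hits) / (n_permutations + 1),
                       n_permutations=n_permutations)


def area_standardized_rates(table, graph: AreaGraph, conditions=None,
                            per: float = 100_000.0) -> pd.DataFrame:
    """Directly age-standardized rate per area and condition, using the
    whole-region stratum person-years as the standard population."""
    df = table.frame
    if conditions is None:
        conditions = table.conditions
    py = (df.drop_duplicates(subset=["area_id", "stratum_id"])
            .pivot(index="area_id", columns="stratum_id", values="person_years")
            .reindex(index=graph.area_ids).fillna(0.0))
    std_w = py.to_numpy(float).sum(axis=0)
    out = {}
    for cond in conditions:
        c = (df[df["condition"] == cond]
             .pivot(index="area_id", columns="stratum_id", values="count")
             .reindex(index=graph.area_ids, columns=py.columns).fillna(0.0)
             .to_numpy(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            stratum_rates = np.where(py.to_numpy(float) > 0,
                                     c / np.maximum(py.to_numpy(float), 1e-300), 0.0)
        out[cond] = [direct_standardized_rate(stratum_rates[i], std_w) * per
                     for i in range(len(graph.area_ids))]
    return pd.DataFrame(out, index=list(graph.area_ids))


def variation_table(data: AreaConditionData, per: float = 100_000.0,
                    area_rates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-condition summary mirroring the descriptive table: total
    admissions, regional crude rate per 100,000 person-years, EQ5-95 of
    area rates, and the EB variance statistic.

    ``area_rates``, if given, supplies per-area (directly standardized)
    rates for the EQ computation; otherwise crude area rates are used.
    """
    total_py = float(data.person_years.sum())
    rows = []
    if area_rates is None:
        rate_mat = data.observed / data.person_years[:, None] * per
        area_rates = pd.DataFrame(rate_mat, columns=list(data.conditions))
    for j, cond in enumerate(data.conditions):
        n = int(data.observed[:, j].sum())
        eq = eq_quantile(area_rates[cond].to_numpy())
        rows.append({
            "condition": cond,
            "n": n,
            "crude_rate": crude_rate(n, total_py, per),
            "eq_5_95": np.nan if eq is None else eq,
            "eb_variance": eb_variance(data.observed[:, j], data.expected[:, j]),
        })
    return pd.DataFrame(rows).set_index("condition")
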