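"""All-pairs antibody correlation analysis.

Spearman rank correlations between every pair of antibody measurement
columns of an integrated matrix, with category labels (like antigen /
same antibody / same platform), kernel density estimates of the
correlation distributions, and Fisher-transform two-sided z-tests
comparing median correlations between groups.

The z-test treats each group median as a single correlation observed on
``n_eff`` samples.  That is an approximation on two counts (pairs are
mutually dependent, and a median of correlations is not itself a single
correlation); it is retained as the field-standard summary comparison and
the caveat is recorded in the result object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, SchemaError
from .integration import IntegratedMatrix

__all__ = [
    "pairwise_correlations",
    "split_and_summarise",
    "GroupSummary",
    "DensityEstimate",
    "silverman_bandwidth",
    "kde",
    "MedianComparison",
    "compare_median_correlations",
]


def pairwise_correlations(
    integrated: IntegratedMatrix, min_complete: int = 3
) -> pd.DataFrame:
    """Spearman r_s for every unordered pair of measurement columns.

    Returns one row per pair with uid/platform provenance and the category
    flags used by the distribution analyses.  Pairs with fewer than
    ``min_complete`` pairwise-complete samples are dropped; the count of
    dropped pairs is attached as ``frame.attrs['n_dropped']``.
    """
    values = integrated.values
    ann = integrated.column_annotations.loc[values.columns]
    X = values.to_numpy(dtype=float)
    m = X.shape[1]
    labels = list(values.columns)

    if not np.isnan(X).any():
        R = np.apply_along_axis(stats.rankdata, 0, X)
        C = np.corrcoef(R.T)
        get = lambda i, j: float(C[i, j])
        n_obs = lambda i, j: X.shape[0]
    else:
        def get(i, j):
            mask = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
            if mask.sum() < min_complete:
                return np.nan
            return float(stats.spearmanr(X[mask, i], X[mask, j]).statistic)

        def n_obs(i, j):
            return int((~(np.isnan(X[:, i]) | np.isnan(X[:, j]))).sum())

    uid = ann["antibody_uid"].to_numpy()
    klass = ann["antigen_class"].to_numpy()
    plat = ann["platform_id"].to_numpy()

    rows, dropped = [], 0
    for i, j in combinations(range(m), 2):
        r = get(i, j)
        if np.isnan(r):
            dropped += 1
            continue
        rows.append(
            {
                "column_1": labels[i],
                "column_2": labels[j],
                "uid_1": uid[i],
                "uid_2": uid[j],
                "platform_1": plat[i],
                "platform_2": plat[j],
                "r_s": r,
                "n_samples": n_obs(i, j),
                "like_antigen": klass[i] == klass[j],
                "same_antibody": uid[i] == uid[j],
                "same_platform": plat[i] == plat[j],
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["n_dropped"] = dropped
    return frame


@dataclass
class GroupSummary:
    name: str
    values: np.ndarray
    median: float
    n: int


def _summary(name: str, values: pd.Series) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    return GroupSummary(
        name=name,
        values=v,
        median=float(np.median(v)) if len(v) else np.nan,
        n=len(v),
    )


def split_and_summarise(pairs: pd.DataFrame, grouping: str) -> dict[str, GroupSummary]:
    """Split the pair table into the study's comparison groups.

    Groupings: ``like_vs_all`` (same-antigen-class pairs vs all pairs),
    ``same_vs_different_antibody`` (within like-antigen pairs),
    ``platform_pair_same_antibody`` / ``platform_pair_different_antibody``
    (cross-platform like-antigen pairs split by platform combination) and
    ``same_vs_cross_platform`` (different-antibody like-antigen pairs).
    Empty groups yield an explicit empty summary.
    """
    known = (
        "like_vs_all", "same_vs_different_antibody", "platform_pair_same_antibody",
        "platform_pair_different_antibody", "same_vs_cross_platform",
    )
    if grouping not in known:
        raise ConfigError(f"unknown grouping {grouping!r}; choose from {known}")
    like = pairs[pairs["like_antigen"]]
    if grouping == "like_vs_all":
        groups = {"like_antigen": like["r_s"], "all_antibodies": pairs["r_s"]}
    elif grouping == "same_vs_different_antibody":
        groups = {
            "same_antibody": like.loc[like["same_antibody"], "r_s"],
            "different_antibody": like.loc[~like["same_antibody"], "r_s"],
        }
    elif grouping in ("platform_pair_same_antibody", "platform_pair_different_antibody"):
        want_same = grouping.endswith("same_antibody")
        sel = like[(like["same_antibody"] == want_same) & ~like["same_platform"]]
        groups = {
            "-".join(sorted(key)): grp["r_s"]
            for key, grp in sel.groupby(
                sel[["platform_1", "platform_2"]].apply(frozenset, axis=1)
            )
        }
    elif grouping == "same_vs_cross_platform":
        diff = like[~like["same_antibody"]]
        groups = {
            "same_platform": diff.loc[diff["same_platform"], "r_s"],
            "cross_platform": diff.loc[~diff["same_platform"], "r_s"],
        }
    else:
        raise ConfigError(f"unknown grouping {grouping!r}")
    return {name: _summary(name, vals) for name, vals in groups.items()}


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool = False


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def kde(
    values, bandwidth: str | float = "silverman", n_grid: int = 512
) -> DensityEstimate:
    """Gaussian kernel density estimate on a grid spanning data +/- 3 bandwidths."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise SchemaError("kernel density estimation needs at least 2 values")
    h = silverman_bandwidth(v) if bandwidth == "silverman" else float(bandwidth)
    if not np.isfinite(h) or h <= 0:
        warnings.warn("zero-variance input: degenerate (spike) density", stacklevel=2)
        h = 1e-6
        grid = np.linspace(v[0] - 1e-3, v[0] + 1e-3, n_grid)
        degenerate = True
    else:
        grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, n_grid)
        degenerate = False
    z = (grid[:, None] - v[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (len(v) * h * np.sqrt(2 * np.pi))
    return DensityEstimate(grid=grid, density=density, bandwidth=h, degenerate=degenerate)


@dataclass
class MedianComparison:
    median_1: float
    median_2: float
    n_eff: int
    z: float
    p: float
    note: str = (
        "z-test treats each group median as one correlation at n_eff samples; "
        "pair dependence is ignored"
    )


def compare_median_correlations(
    group_1, group_2, n_eff: int
) -> MedianComparison:
    """Fisher-transform two-sided z-test on two median correlations.

    z = (atanh(m1) - atanh(m2)) / sqrt(2 / (n_eff - 3)); ``n_eff`` is the
    number of samples underlying each correlation.
    """
    if n_eff <= 3:
        raise ConfigError("n_eff must exceed 3 for the Fisher z-test")
    m1 = float(np.median(np.asarray(group_1, dtype=float)))
    m2 = float(np.median(np.asarray(group_2, dtype=float)))
    if abs(m1) >= 1 or abs(m2) >= 1:
        raise ConfigError("median correlation of +/-1 has an infinite Fisher transform")
    z = (np.arctanh(m1) - np.arctanh(m2)) / np.sqrt(2.0 / (n_eff - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return MedianComparison(median_1=m1, median_2=m2, n_eff=n_eff, z=float(z), p=float(p))
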