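"""Per-platform spot-level processing and normalisation.

Turns raw spot intensities into one processed binary-log intensity per
(sample, antibody).  Two representative normalisation strategies are
provided, mirroring the diversity of in-house RPPA pipelines without
re-implementing any of them:

``dilution_fit``
    Ordinary least squares of log2(intensity) on the serial-dilution step;
    the fitted intercept is the log2 intensity at the undiluted spot.  A
    slope near -1 per step indicates in-range two-fold dilution behaviour.

``total_protein``
    Spot-wise division of the undiluted antibody signal by the sample's
    total-protein stain signal, then log2.

Technical replicate spots are combined by their median before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, SchemaError

__all__ = [
    "DilutionFit",
    "ProcessedIntensityMatrix",
    "aggregate_technical_replicates",
    "fit_dilution_series",
    "fit_dilution_matrix",
    "normalise_total_protein",
    "log2_matrix",
    "qc_dynamic_range",
    "process_platform",
]

SPOT_COLUMNS = ["sample_id", "antibody_id", "dilution_step", "technical_replicate", "intensity"]


@dataclass(frozen=True)
class DilutionFit:
    """OLS fit of one (sample, antibody) dilution series on the log2 scale."""

    intercept: float  # log2 intensity at dilution step 0
    slope: float  # log2 per step; -1 is ideal two-fold behaviour
    r2: float
    n_points: int
    flag: str  # "ok" | "floored" | "insufficient"


@dataclass
class ProcessedIntensityMatrix:
    """One platform's processed log2 intensities (samples x antibodies)."""

    values: pd.DataFrame  # index sample_id, columns antibody_id
    platform_id: str
    method: str
    qc: pd.DataFrame  # same shape, string flags ("" where clean)

    @property
    def n_readings(self) -> int:
        return int(self.values.notna().sum().sum())


def aggregate_technical_replicates(spots: pd.DataFrame) -> pd.DataFrame:
    """Median of technical replicate spots per (sample, antibody, dilution step)."""
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise SchemaError(f"spot table lacks columns {sorted(missing)}")
    agg = (
        spots.groupby(["sample_id", "antibody_id", "dilution_step"], sort=True)["intensity"]
        .median()
        .reset_index()
    )
    return agg


def fit_dilution_series(
    steps, intensities, detection_floor: float | None = None
) -> DilutionFit:
    """Least-squares fit of log2(intensity) against integer dilution step.

    Points at or below the detection floor (or non-positive) are treated as
    censored and excluded; a series with every point censored is flagged
    unquantifiable rather than raising.
    """
    x = np.asarray(steps, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.shape != y.shape:
        raise SchemaError("steps and intensities must have equal length")
    ok = y > 0
    if detection_floor is not None:
        ok &= y > detection_floor
    if not ok.any():
        return DilutionFit(np.nan, np.nan, np.nan, 0, "floored")
    x, y = x[ok], np.log2(y[ok])
    if len(np.unique(x)) < 2:
        return DilutionFit(np.nan, np.nan, np.nan, int(ok.sum()), "insufficient")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 if sst < 1e-300 else 1.0 - float((resid**2).sum()) / sst
    return DilutionFit(float(intercept), float(slope), float(r2), int(len(x)), "ok")


def fit_dilution_matrix(
    aggregated: pd.DataFrame, detection_floor: float | None = None
) -> pd.DataFrame:
    """Vectorised dilution fits for every (sample, antibody) series.

    Returns a frame indexed by (sample_id, antibody_id) with columns
    intercept, slope, r2, n_points, flag.  Identical in result to calling
    :func:`fit_dilution_series` per series.
    """
    wide = aggregated.pivot_table(
        index=["sample_id", "antibody_id"],
        columns="dilution_step",
        values="intensity",
        aggfunc="first",
    )
    steps = wide.columns.to_numpy(dtype=float)
    y = wide.to_numpy(dtype=float)
    ok = y > 0
    if detection_floor is not None:
        ok &= y > detection_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ly = np.where(ok, np.log2(np.where(ok, y, 1.0)), np.nan)

    n = ok.sum(axis=1)
    x = np.where(ok, steps[None, :], np.nan)
    # distinct usable steps per series
    n_distinct = np.array([len(np.unique(row[~np.isnan(row)])) for row in x])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        xm = np.nanmean(x, axis=1)
        ym = np.nanmean(ly, axis=1)
        dx = x - xm[:, None]
        dy = ly - ym[:, None]
        sxx = np.nansum(dx**2, axis=1)
        sxy = np.nansum(dx * dy, axis=1)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ym - slope * xm
        resid = dy - slope[:, None] * dx
        sse = np.nansum(resid**2, axis=1)
        sst = np.nansum(dy**2, axis=1)
        r2 = np.where(sst < 1e-300, 1.0, 1.0 - sse / np.where(sst > 0, sst, 1.0))

    flag = np.where(n == 0, "floored", np.where(n_distinct < 2, "insufficient", "ok"))
    bad = flag != "ok"
    for arr in (intercept, slope, r2):
        arr[bad] = np.nan
    return pd.DataFrame(
        {
            "intercept": intercept,
            "slope": slope,
            "r2": r2,
            "n_points": n,
            "flag": flag,
        },
        index=wide.index,
    )


def normalise_total_protein(values: pd.DataFrame, total_protein: pd.Series) -> pd.DataFrame:
    """Divide each sample's antibody intensities by its total-protein signal."""
    missing = set(values.index) - set(total_protein.index)
    if missing:
        raise SchemaError(f"no total-protein value for samples {sorted(missing)}")
    tp = total_protein.loc[values.index]
    bad = tp[tp <= 0]
    if len(bad):
        raise ConfigError(
            "non-positive total-protein signal for samples: "
            + ", ".join(map(str, bad.index))
        )
    return values.div(tp, axis=0)


def log2_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Elementwise binary logarithm; non-positive entries become missing.

    Returns (log2 matrix, flag matrix).  Non-positive inputs are flagged
    "nonpositive" and excluded with a warning; missing inputs propagate.
    """
    arr = values.to_numpy(dtype=float)
    nonpos = np.isfinite(arr) & (arr <= 0)
    if nonpos.any():
        warnings.warn(
            f"{int(nonpos.sum())} non-positive intensities excluded from log2 transform",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    flags = np.where(nonpos, "nonpositive", "")
    return (
        pd.DataFrame(out, index=values.index, columns=values.columns),
        pd.DataFrame(flags, index=values.index, columns=values.columns),
    )


def qc_dynamic_range(
    fits: pd.DataFrame, slope_band: tuple[float, float] = (-1.5, -0.5)
) -> dict:
    """Dynamic-range QC summary over fitted dilution series.

    Reports the fraction of quantifiable series whose slope lies within
    ``slope_band`` (ideal two-fold behaviour is -1 per step), overall and
    per antibody, plus the fraction of series below detection.
    """
    ok = fits["flag"] == "ok"
    in_band = ok & fits["slope"].between(*slope_band)
    per_ab = pd.DataFrame(
        {
            "n_series": fits.groupby(level="antibody_id").size(),
            "frac_in_range": in_band.groupby(level="antibody_id").sum()
            / ok.groupby(level="antibody_id").sum().replace(0, np.nan),
            "frac_below_detection": (fits["flag"] == "floored")
            .groupby(level="antibody_id")
            .mean(),
        }
    )
    n_ok = int(ok.sum())
    return {
        "slope_band": slope_band,
        "n_series": int(len(fits)),
        "frac_in_range": float(in_band.sum() / n_ok) if n_ok else np.nan,
        "frac_below_detection": float((fits["flag"] == "floored").mean()),
        "per_antibody": per_ab,
    }


def process_platform(
    spots: pd.DataFrame,
    platform_id: str,
    method: str = "dilution_fit",
    total_protein: pd.Series | None = None,
    detection_floor: float | None = None,
) -> ProcessedIntensityMatrix:
    """Spot table -> processed log2 intensity matrix for one platform."""
    agg = aggregate_technical_replicates(spots)
    if method == "dilution_fit":
        fits = fit_dilution_matrix(agg, detection_floor=detection_floor)
        values = fits["intercept"].unstack("antibody_id")
        qc = fits["flag"].where(fits["flag"] != "ok", "").unstack("antibody_id")
    elif method == "total_protein":
        if total_protein is None:
            raise ConfigError("total_protein method requires a total-protein signal")
        undiluted = (
            agg[agg["dilution_step"] == agg["dilution_step"].min()]
            .pivot(index="sample_id", columns="antibody_id", values="intensity")
        )
        normed = normalise_total_protein(undiluted, total_protein)
        values, qc = log2_matrix(normed)
    else:
        raise ConfigError(f"unknown normalisation method {method!r}")
    values.index.name = "sample_id"
    return ProcessedIntensityMatrix(
        values=values, platform_id=platform_id, method=method, qc=qc
    )
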