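"""Trait preprocessing and tree-ring drought indices.

Two dendrochronological indices summarize the growth response to a discrete
drought event from a tree's basal area increment (BAI) series:

* Resistance = mean BAI of the drought year divided by the mean BAI of the
  four preceding years; 1 means the tree was unaffected, smaller values mean
  a stronger growth reduction.
* Mean sensitivity = mean over consecutive years of
  |2 (BAI_{t+1} - BAI_t) / (BAI_{t+1} + BAI_t)|, the classic measure of
  year-to-year climate responsiveness.

Both are ratios of BAI values and therefore invariant to rescaling a series
by any positive constant.

Phenotype tables are plain pandas DataFrames with columns ``tree``, ``site``,
``replication``, ``group`` and one column per trait; each tree appears at
exactly one site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

PHENOTYPE_ID_COLS = ["tree", "site", "replication", "group"]


@dataclass
class RingSeries:
    """Per-tree annual basal area increments."""

    tree: str
    years: np.ndarray
    bai: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.bai = np.asarray(self.bai, dtype=float)
        if self.years.size != self.bai.size:
            raise DataError("years and bai must have equal length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise DataError("years must be strictly increasing")
        if np.any(self.bai < 0):
            raise DataError("BAI must be nonnegative")


@dataclass
class DroughtIndices:
    tree: str
    resistance: float
    sensitivity: float
    n_years: int


def ring_width_to_bai(
    tree: str, years, widths, initial_radius: float = 0.0
) -> RingSeries:
    """Convert ring widths to basal area increments.

    BAI_t = pi * (R_t^2 - R_{t-1}^2) with R_t the cumulative radius.
    """
    widths = np.asarray(widths, dtype=float)
    if np.any(widths < 0):
        raise DataError("ring widths must be nonnegative")
    radii = initial_radius + np.cumsum(widths)
    prev = np.concatenate([[initial_radius], radii[:-1]])
    bai = math.pi * (radii**2 - prev**2)
    return RingSeries(tree=str(tree), years=np.asarray(years, dtype=int), bai=bai)


def resistance(
    series: RingSeries, drought_year: int = 2015, pre_window: int = 4
) -> float:
    """Drought resistance: BAI_drought / mean BAI of the pre-drought window."""
    if pre_window < 1:
        raise ParameterError("pre_window must be >= 1")
    years = series.years
    need = list(range(drought_year - pre_window, drought_year + 1))
    present = set(years.tolist())
    missing = [y for y in need if y not in present]
    if missing:
        raise DataError(f"series does not cover required years: {missing}")
    lookup = dict(zip(years.tolist(), series.bai))
    pre = np.array([lookup[y] for y in need[:-1]])
    if pre.mean() == 0:
        raise DataError("zero pre-drought mean BAI: resistance undefined")
    return float(lookup[drought_year] / pre.mean())


def mean_sensitivity(series: RingSeries, skip_zero_pairs: bool = False) -> float:
    """Mean absolute relative year-to-year BAI change.

    Uses 1/(n-1) * sum_t |2 (BAI_{t+1} - BAI_t) / (BAI_{t+1} + BAI_t)| over
    consecutive years; pairs straddling a gap in the year sequence are
    excluded and n counts the years entering the retained pairs.
    """
    years, bai = series.years, series.bai
    if years.size < 2:
        raise DataError("mean sensitivity needs at least 2 years")
    consecutive = np.diff(years) == 1
    sums = bai[1:] + bai[:-1]
    diffs = bai[1:] - bai[:-1]
    use = consecutive.copy()
    if (sums[use] == 0).any():
        if not skip_zero_pairs:
            raise DataError("consecutive BAI pair sums to zero: term undefined")
        use &= sums != 0
    if not use.any():
        raise DataError("no usable consecutive year pairs")
    terms = np.abs(2.0 * diffs[use] / sums[use])
    return float(terms.mean())


def drought_indices(
    series: RingSeries, drought_year: int = 2015, pre_window: int = 4
) -> DroughtIndices:
    return DroughtIndices(
        tree=series.tree,
        resistance=resistance(series, drought_year, pre_window),
        sensitivity=mean_sensitivity(series),
        n_years=int(series.years.size),
    )


def bai_weighted_mean(
    values, weights, years=None, first_year: int = 1995
) -> float:
    """BAI-weighted average of a per-ring measurement.

    Rings before ``first_year`` are excluded from both sums (juvenile rings
    carry less reliable measurements).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise DataError("values and weights must align")
    if np.any(weights < 0):
        raise DataError("weights must be nonnegative")
    if years is not None:
        years = np.asarray(years, dtype=int)
        keep = years >= first_year
        values, weights = values[keep], weights[keep]
    total = weights.sum()
    if total == 0:
        raise DataError("all weights zero after the year cut")
    return float(np.sum(values * weights) / total)


def log_transform(values) -> np.ndarray:
    """Natural-log transform of a strictly positive trait vector.

    Missing values pass through; nonpositive values raise with row indices.
    """
    x = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isnan(x) & (x <= 0))
    if bad.size:
        raise DataError(f"nonpositive values at rows {bad[:10].tolist()}")
    return np.log(x)


def design_adjust(
    table: pd.DataFrame, trait: str, site: str | None = None
) -> pd.Series:
    """Subtract estimated replication effects from a trait, per site.

    The replication effect is the count-weighted deviation of the replication
    mean from the site grand mean (effects sum to zero weighted by counts),
    so the grand mean of the adjusted values equals the original grand mean.
    A site with a single replication is returned unchanged with a warning.
    """
    import warnings

    if "replication" not in table.columns:
        raise DataError("phenotype table lacks a replication column")
    df = table if site is None else table[table["site"] == site]
    out = df[trait].astype(float).copy()
    for s, sub in df.groupby("site"):
        y = sub[trait].astype(float)
        obs = y.notna()
        reps = sub.loc[obs, "replication"]
        if reps.nunique() < 2:
            warnings.warn(
                f"site {s!r}: fewer than 2 replications for {trait!r}; "
                "replication effect confounded with the mean, data unchanged",
                stacklevel=2,
            )
            continue
        grand = y[obs].mean()
        rep_means = y[obs].groupby(reps).mean()
        effects = rep_means - grand
        adj = y - sub["replication"].map(effects).fillna(0.0)
        out.loc[sub.index] = adj
    return out


def standardize(values) -> np.ndarray:
    """Z-scores with the n-1 variance denominator; missing stays missing."""
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise DataError("standardize needs >= 2 non-missing values")
    sd = np.std(x[obs], ddof=1)
    if sd == 0:
        raise DataError("zero variance: cannot standardize")
    out = x.copy()
    out[obs] = (x[obs] - x[obs].mean()) / sd
    return out


def trait_summary(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait n, mean, SD, CV (= SD/mean), min and max over non-missing values."""
    if traits is None:
        traits = [c for c in table.columns if c not in PHENOTYPE_ID_COLS]
    rows = []
    for t in traits:
        x = table[t].astype(float).dropna()
        if len(x) == 0:
            rows.append({"trait": t, "n": 0, "mean": np.nan, "sd": np.nan,
                         "cv": np.nan, "min": np.nan, "max": np.nan})
            continue
        mean = x.mean()
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        rows.append(
            {
                "trait": t,
                "n": int(len(x)),
                "mean": mean,
                "sd": sd,
                "cv": sd / mean if mean != 0 else np.nan,
                "min": x.min(),
                "max": x.max(),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def rings_to_indices(
    rings: dict[str, RingSeries],
    drought_year: int = 2015,
    pre_window: int = 4,
) -> pd.DataFrame:
    """Drought indices for a collection of ring series, one row per tree."""
    rows = []
    for tree, series in rings.items():
        try:
            di = drought_indices(series, drought_year, pre_window)
        except DataError:
            rows.append({"tree": tree, "resistance": np.nan,
                         "sensitivity": np.nan, "n_years": series.years.size})
            continue
        rows.append(
            {
                "tree": tree,
                "resistance": di.resistance,
                "sensitivity": di.sensitivity,
                "n_years": di.n_years,
            }
        )
    return pd.DataFrame(rows).set_index("tree")
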