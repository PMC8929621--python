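"""Genetic-parameter reporting: heritabilities, genetic correlations,
correlation-strength classes, cross-site (G x E) matrices and recovery
scoring against simulation truth.

Narrow-sense heritability is re-parameterized from the variance components as

    h2 = sigma2_a / (sigma2_a + sigma2_e)

(the design variance is excluded from the denominator), and the genetic
correlation between responses i and j as

    r_a = sigma_a(i,j) / sqrt(sigma2_a(i) * sigma2_a(j)).

Standard errors come from the delta method applied to the inverse
average-information matrix.  Correlations are labelled strong when
|r_a| >= 0.70, moderate between 0.40 and 0.70, and low/weak at or below
0.40.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, StructuralError
from .reml import FitResult, VarianceComponents

STRONG = "strong"
MODERATE = "moderate"
LOW_WEAK = "low/weak"

#: variances below this are treated as zero when forming correlations
_VAR_FLOOR = 1e-12


@dataclass
class GeneticParameters:
    """Per-response h2 and per-pair r_a derived from one fit."""

    source: str  # relationship kind the fit used (A, G, blended)
    heritabilities: pd.DataFrame  # response, h2, h2_raw, se
    correlations: pd.DataFrame  # response_i, response_j, r_a, se, label


def _resolve(vc: VarianceComponents, response) -> int:
    if isinstance(response, (int, np.integer)):
        return int(response)
    try:
        return vc.responses.index(response)
    except ValueError:
        raise StructuralError(f"unknown response {response!r}") from None


def heritability(vc: VarianceComponents, response) -> tuple[float, float]:
    """Narrow-sense heritability with its delta-method standard error."""
    i = _resolve(vc, response)
    sa = float(vc.sigma_a[i, i])
    se_ = float(vc.sigma_e[i, i])
    tot = sa + se_
    if tot <= 0:
        raise DataError("zero total variance: heritability undefined")
    h2 = sa / tot
    se_out = np.nan
    if vc.asymptotic_covariance is not None and vc.param_names:
        try:
            ka, ke = vc.index_a(i, i), vc.index_e(i, i)
        except ValueError:
            return h2, np.nan
        grad = np.zeros(len(vc.param_names))
        grad[ka] = se_ / tot**2
        grad[ke] = -sa / tot**2
        var = float(grad @ vc.asymptotic_covariance @ grad)
        se_out = float(np.sqrt(var)) if var >= 0 else np.nan
    return h2, se_out


def genetic_correlation(vc: VarianceComponents, pair) -> tuple[float, float]:
    """Genetic correlation for a response pair, with delta-method SE.

    Returns ``(nan, nan)`` when either genetic variance is (numerically)
    zero, mirroring the NA cells of sparse-data reports.
    """
    i, j = (_resolve(vc, p) for p in pair)
    sii, sjj = float(vc.sigma_a[i, i]), float(vc.sigma_a[j, j])
    sij = float(vc.sigma_a[i, j])
    if sii <= _VAR_FLOOR or sjj <= _VAR_FLOOR:
        return np.nan, np.nan
    r = sij / np.sqrt(sii * sjj)
    se_out = np.nan
    if vc.asymptotic_covariance is not None and vc.param_names:
        try:
            kii, kjj, kij = vc.index_a(i, i), vc.index_a(j, j), vc.index_a(i, j)
        except ValueError:
            return r, np.nan
        grad = np.zeros(len(vc.param_names))
        grad[kij] = 1.0 / np.sqrt(sii * sjj)
        grad[kii] = -r / (2.0 * sii)
        grad[kjj] = -r / (2.0 * sjj)
        var = float(grad @ vc.asymptotic_covariance @ grad)
        se_out = float(np.sqrt(var)) if var >= 0 else np.nan
    return float(r), se_out


def classify_correlation(r: float) -> str:
    """Strength label for a genetic correlation (on its magnitude)."""
    if np.isnan(r):
        raise ParameterError("cannot classify NA correlation")
    if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
        raise ParameterError(f"correlation out of [-1, 1]: {r}")
    a = abs(r)
    if a >= 0.70:
        return STRONG
    if a > 0.40:
        return MODERATE
    return LOW_WEAK


def genetic_parameters(fit: FitResult, source: str = "A") -> GeneticParameters:
    """Summarize one fit into h2 and r_a tables with SEs and labels."""
    vc = fit.vc
    h_rows, c_rows = [], []
    r = len(vc.responses)
    for i, name in enumerate(vc.responses):
        h2, se = heritability(vc, i)
        h_rows.append(
            {
                "response": name,
                "h2": float(np.clip(h2, 0.0, 1.0)),
                "h2_raw": h2,
                "se": se,
            }
        )
    for i in range(r):
        for j in range(i + 1, r):
            ra, se = genetic_correlation(vc, (i, j))
            c_rows.append(
                {
                    "response_i": vc.responses[i],
                    "response_j": vc.responses[j],
                    "r_a": ra,
                    "se": se,
                    "label": classify_correlation(float(np.clip(ra, -1, 1)))
                    if not np.isnan(ra)
                    else "NA",
                }
            )
    return GeneticParameters(
        source=source,
        heritabilities=pd.DataFrame(h_rows),
        correlations=pd.DataFrame(
            c_rows, columns=["response_i", "response_j", "r_a", "se", "label"]
        ),
    )


def _split_site(name: str) -> tuple[str, str]:
    if "@" not in name:
        raise StructuralError(f"response {name!r} is not a trait@site label")
    t, s = name.split("@", 1)
    return t, s


def cross_site_report(
    fits: dict[str, FitResult | None], sites: list[str] | None = None
) -> dict[str, dict[str, pd.DataFrame]]:
    """Site x site genetic-correlation matrices per trait.

    ``fits`` maps trait -> multivariate sites-as-traits FitResult (``None``
    when the trait could not be analysed).  Output per trait: symmetric ``r``
    matrix (diagonal 1), ``se`` matrix and strength ``label`` matrix, with
    NA where a site lacked data.
    """
    if sites is None:
        found = set()
        for fit in fits.values():
            if fit is not None:
                for name in fit.vc.responses:
                    found.add(_split_site(name)[1])
        sites = sorted(found)
    out = {}
    for trait, fit in fits.items():
        r_mat = pd.DataFrame(np.nan, index=sites, columns=sites)
        se_mat = pd.DataFrame(np.nan, index=sites, columns=sites)
        lab = pd.DataFrame("NA", index=sites, columns=sites)
        if fit is not None:
            names = fit.vc.responses
            for name in names:
                t, s = _split_site(name)
                if t != trait:
                    raise StructuralError(
                        f"fit for {trait!r} contains response {name!r}"
                    )
            present = [_split_site(n)[1] for n in names]
            bad = [s for s in present if s not in sites]
            if bad:
                raise StructuralError(f"inconsistent site labels: {bad}")
            for a in range(len(names)):
                for b in range(a + 1, len(names)):
                    ra, se = genetic_correlation(fit.vc, (a, b))
                    sa, sb = present[a], present[b]
                    r_mat.loc[sa, sb] = r_mat.loc[sb, sa] = ra
                    se_mat.loc[sa, sb] = se_mat.loc[sb, sa] = se
                    if not np.isnan(ra):
                        label = classify_correlation(float(np.clip(ra, -1, 1)))
                        lab.loc[sa, sb] = lab.loc[sb, sa] = label
            for s in present:
                r_mat.loc[s, s] = 1.0
                se_mat.loc[s, s] = 0.0
                lab.loc[s, s] = STRONG
        out[trait] = {"r": r_mat, "se": se_mat, "label": lab}
    return out


def recovery_report(estimates: pd.DataFrame, truth: dict[str, float]) -> pd.DataFrame:
    """Bias, RMSE and 95% Wald coverage of estimates against known truth.

    ``estimates`` needs columns ``parameter``, ``estimate`` and ``se``
    (``replicate`` optional); ``truth`` maps each parameter to its
    generating value.
    """
    need = {"parameter", "estimate", "se"}
    if not need <= set(estimates.columns):
        raise StructuralError(f"estimates table needs columns {sorted(need)}")
    params = set(estimates["parameter"])
    if params != set(truth):
        raise StructuralError(
            f"parameter sets differ: estimates {sorted(params)} vs "
            f"truth {sorted(truth)}"
        )
    rows = []
    for param, grp in estimates.groupby("parameter"):
        true = float(truth[param])
        est = grp["estimate"].to_numpy(dtype=float)
        se = grp["se"].to_numpy(dtype=float)
        err = est - true
        covered = np.abs(err) <= 1.96 * se
        rows.append(
            {
                "parameter": param,
                "truth": true,
                "n": len(est),
                "mean_estimate": float(est.mean()),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "coverage": float(np.mean(covered)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def heritability_table(
    fits: dict[tuple[str, str, str], FitResult]
) -> pd.DataFrame:
    """Trait x site x relationship-source heritability table.

    ``fits`` maps (trait, site, source) -> univariate FitResult.  A and G
    fits of the same data appear side by side; the report never averages
    across relationship sources.
    """
    rows = []
    for (trait, site, source), fit in fits.items():
        h2, se = heritability(fit.vc, 0)
        rows.append(
            {
                "trait": trait,
                "site": site,
                "source": source,
                "h2": float(np.clip(h2, 0.0, 1.0)),
                "se": se,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(
        rows, columns=["trait", "site", "source", "h2", "se", "flags"]
    )
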