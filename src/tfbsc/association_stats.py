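"""Univariate association machinery for conservation analyses.

Binomial proportions are reported with 95% Wilson score intervals; 2x2
tables are tested by chi-square (Fisher's exact test when any expected
count falls below 5) with the odds ratio cross-product; ordered and
discrete predictors are tested by analysis of deviance of a binomial GLM
(a third-degree polynomial for distance); per-TF screens repeat the global
tests on each eligible TF's sites; the epistasis test compares the
between-species conservation of sites whose promoter also carries a site
for a negative genetic-interaction partner of their TF (E-MAP score < -3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .integrated_model import (
    SeparationError,
    deviance_compare,
    fit_binomial_glm,
    orthogonal_poly,
)

logger = logging.getLogger("tfbsc")

__all__ = [
    "AssociationResult",
    "wilson_interval",
    "equal_population_bins",
    "two_level_association",
    "trend_test",
    "binned_proportions",
    "per_tf_screen",
    "epistasis_pair_test",
    "permutation_p_value",
]


@dataclass
class AssociationResult:
    feature: str
    comparison: str
    groups: pd.DataFrame          # one row per group/bin: n, k, prop, lo, hi
    test: str
    p_value: float
    odds_ratio: float | None = None
    direction: float | None = None
    extra: dict = field(default_factory=dict)


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def equal_population_bins(values, k: int) -> tuple[np.ndarray, list]:
    """Assign values to `k` bins of near-equal population, never splitting
    ties across a bin edge.

    Returns (bin index per value, list of (lo, hi) value ranges).
    """
    if k < 2:
        raise ValueError("need at least 2 bins")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < k:
        raise ValueError("fewer values than bins")
    if np.unique(values).size == 1:
        raise ValueError("values have no spread")
    order = np.argsort(values, kind="stable")
    sv = values[order]
    # tentative cuts at equal counts, snapped to the nearest tie boundary
    cuts = []
    for i in range(1, k):
        c = round(n * i / k)
        lo = c
        while 0 < lo < n and sv[lo - 1] == sv[lo]:
            lo -= 1
        hi = c
        while 0 < hi < n and sv[hi - 1] == sv[hi]:
            hi += 1
        cuts.append(lo if (c - lo) <= (hi - c) else hi)
    cuts = sorted(set(c for c in cuts if 0 < c < n))
    bins_sorted = np.zeros(n, dtype=int)
    prev = 0
    for b, c in enumerate(cuts):
        bins_sorted[prev:c] = b
        prev = c
    bins_sorted[prev:] = len(cuts)
    assignment = np.empty(n, dtype=int)
    assignment[order] = bins_sorted
    edges = []
    for b in range(len(cuts) + 1):
        sel = values[assignment == b]
        edges.append((float(sel.min()), float(sel.max())))
    return assignment, edges


def two_level_association(table) -> tuple[float, float, str]:
    """Odds ratio and test for a 2x2 count table.

    OR uses the cross product, with the Haldane-Anscombe 0.5 correction
    only when a cell is zero.  The chi-square test is used by default,
    Fisher's exact test when any expected count is below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("a row or column of the table is all zero")
    a, b = t[0]
    c, d = t[1]
    if (t == 0).any():
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(t)
        test = "fisher"
    else:
        res = stats.chi2_contingency(t)
        p, test = res.pvalue, "chi2"
    return float(odds_ratio), float(p), test


def trend_test(
    outcome,
    predictor,
    covariates: pd.DataFrame | None = None,
    distance_poly: bool = False,
) -> dict:
    """Analysis-of-deviance trend test from a binomial GLM.

    The p-value comes from the chi-square distribution of the deviance
    difference between fits with and without the predictor.  With
    ``distance_poly`` the predictor enters as a third-degree polynomial
    (its three columns tested jointly).  Separation is flagged in the
    result rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    n = len(y)
    base = [np.ones(n)]
    if covariates is not None:
        base.extend(np.asarray(covariates, dtype=float).T)
    if distance_poly:
        pred_cols = list(orthogonal_poly(x, 3).T)
    else:
        if np.unique(x).size < 2:
            raise ValueError("predictor needs at least 2 levels")
        pred_cols = [x]
    try:
        reduced = fit_binomial_glm(np.column_stack(base), y)
        full = fit_binomial_glm(np.column_stack(base + pred_cols), y)
    except SeparationError as err:
        return {"ok": False, "reason": str(err), "p_value": None,
                "deviance_drop": None, "direction": None}
    chi2, df, p = deviance_compare(full, reduced)
    direction = float(np.sign(full.beta[len(base)]))
    return {
        "ok": True, "deviance_drop": chi2, "df": df, "p_value": p,
        "direction": direction,
    }


def binned_proportions(
    outcome, groups, feature: str, comparison: str, level: float = 0.95
) -> pd.DataFrame:
    """Per-group conserved counts, proportions and Wilson intervals."""
    df = pd.DataFrame({"y": np.asarray(outcome, dtype=float), "g": groups})
    rows = []
    for g, sub in df.groupby("g", sort=True):
        n, k = len(sub), int(sub["y"].sum())
        lo, hi = wilson_interval(k, n, level)
        rows.append(
            {"feature": feature, "comparison": comparison, "group": g,
             "n": n, "conserved": k, "proportion": k / n, "lo": lo, "hi": hi}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-TF screen

FEATURE_KINDS = {
    "distance": "distance",
    "strength": "continuous",
    "copy_number": "discrete",
    "n_tfs_in_promoter": "discrete",
    "subtelomeric": "categorical",
    "divergent_promoter": "categorical",
    "in_nfr": "categorical",
    "overlaps_other_site": "categorical",
    "tf_essential": "categorical",
    "target_essential": "categorical",
    "target_is_regulator": "categorical",
    "tf_hierarchy": "categorical",
}


def _tf_eligible(x: pd.Series, kind: str) -> bool:
    if kind == "distance":
        return x.nunique() >= 4       # four instances at different distances
    if kind in ("discrete", "continuous"):
        return x.nunique() >= 2
    # categorical: every category observed for this TF
    return x.nunique() == x.dtype.categories.size if hasattr(x.dtype, "categories") \
        else x.nunique() >= 2


def per_tf_screen(
    feature: str, data: pd.DataFrame, outcome_col: str = "between"
) -> tuple[pd.DataFrame, dict]:
    """Repeat an association test for each eligible TF.

    `data` needs columns tf_id, `feature`, and the outcome.  Eligibility:
    distance requires >= 4 distinct distances; discrete variables >= 2
    values; categorical variables at least one instance of every category
    observed globally.  The summary reports the fraction of eligible TFs
    whose effect sign matches the pooled effect, and the fraction both
    significant at 0.05 and concordant.
    """
    kind = FEATURE_KINDS.get(feature, "discrete")
    data = data.dropna(subset=[feature, outcome_col])
    y_all = data[outcome_col].astype(float)
    x_all = data[feature]

    def _direction(x, y):
        if kind == "categorical":
            x_codes = pd.factorize(x, sort=True)[0].astype(float)
        else:
            x_codes = x.astype(float)
        res = trend_test(y, x_codes, distance_poly=(kind == "distance"))
        if not res["ok"] or res["p_value"] is None:
            return None
        return res

    global_res = _direction(x_all, y_all)
    if global_res is None:
        raise ValueError("pooled trend test failed")
    global_sign = global_res["direction"]

    n_categories = x_all.nunique()
    rows, ineligible = [], []
    for tf, sub in data.groupby("tf_id", sort=True):
        x, y = sub[feature], sub[outcome_col].astype(float)
        if kind == "distance":
            ok = x.nunique() >= 4
        elif kind == "categorical":
            ok = x.nunique() == n_categories
        else:
            ok = x.nunique() >= 2
        ok = ok and y.nunique() == 2
        if not ok:
            ineligible.append(tf)
            continue
        res = _direction(x, y)
        if res is None:
            ineligible.append(tf)
            continue
        rows.append(
            {"tf_id": tf, "n": len(sub), "p_value": res["p_value"],
             "direction": res["direction"],
             "concordant": res["direction"] == global_sign}
        )
    table = pd.DataFrame(rows, columns=["tf_id", "n", "p_value", "direction",
                                        "concordant"])
    n_elig = len(table)
    summary = {
        "feature": feature,
        "n_eligible": n_elig,
        "ineligible": ineligible,
        "global_direction": global_sign,
        "fraction_concordant": float(table["concordant"].mean()) if n_elig else np.nan,
        "fraction_significant_concordant": float(
            ((table["p_value"] < 0.05) & table["concordant"]).mean()
        ) if n_elig else np.nan,
    }
    return table, summary


def epistasis_pair_test(features: pd.DataFrame, calls: pd.DataFrame) -> AssociationResult:
    """Between-species conservation of sites co-occurring with a negative
    genetic-interaction partner of their TF versus other sites.

    `features` must carry the ``emap_partner`` flag (promoter also contains
    a site for a TF whose E-MAP score with this site's TF is < -3).
    """
    if "emap_partner" not in features.columns:
        raise ValueError("features lack the emap_partner flag (empty E-MAP table?)")
    df = features.drop_duplicates("site_id").merge(
        calls[["site_id", "between"]], on="site_id"
    ).dropna(subset=["between"])
    flag = df["emap_partner"].astype(bool)
    if flag.nunique() < 2:
        raise ValueError("no contrast: all sites fall in a single co-occurrence group")
    y = df["between"].astype(bool)
    table = np.array(
        [
            [int((flag & y).sum()), int((flag & ~y).sum())],
            [int((~flag & y).sum()), int((~flag & ~y).sum())],
        ]
    )
    odds_ratio, p, test = two_level_association(table)
    groups = binned_proportions(
        y.to_numpy(), np.where(flag, "partner_in_promoter", "no_partner"),
        "emap_partner", "between",
    )
    return AssociationResult(
        feature="emap_partner", comparison="between", groups=groups,
        test=test, p_value=p, odds_ratio=odds_ratio,
        direction=float(np.sign(np.log(odds_ratio))),
        extra={"table": table},
    )


def permutation_p_value(
    statistic, outcome, n_permutations: int = 1000, seed: int = 0
) -> float:
    """Empirical label-shuffling p-value for any outcome statistic.

    `statistic` maps a permuted outcome vector to a scalar; the returned p
    is the fraction of permutations with a statistic at least as extreme
    (two-sided around the permutation mean), with the +1 correction.
    """
    rng = np.random.default_rng(seed)
    outcome = np.asarray(outcome)
    observed = statistic(outcome)
    perm = np.array(
        [statistic(rng.permutation(outcome)) for _ in range(n_permutations)]
    )
    center = perm.mean()
    extreme = np.abs(perm - center) >= abs(observed - center)
    return float((extreme.sum() + 1) / (n_permutations + 1))
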