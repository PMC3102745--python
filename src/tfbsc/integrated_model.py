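"""The integrated binomial model of binding-site conservation.

Conservation (a binary outcome per site) is modeled with a logistic GLM,
eta = sum_i beta_i x_i, mu = logistic(eta), fitted by iteratively
re-weighted least squares.  Distance to the TSS enters as a third-degree
polynomial (orthogonalized, unit-SD columns); the regulator hierarchy as an
ordered three-level factor (top > core > bottom) with linear and quadratic
contrasts; the remaining covariates as indicators or counts.  Model
selection proceeds backwards from all main effects plus first-order
interactions, repeatedly dropping the least significant droppable term by
analysis of deviance (chi-square on the deviance difference, alpha = 0.05),
interactions before main effects and never a main effect still contained
in a retained interaction.  Predictive performance is the ROC AUC under
seeded, outcome-stratified ten-fold cross-validation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("tfbsc")

__all__ = [
    "MODEL_TERMS",
    "DEFAULT_TERMS",
    "SeparationError",
    "FittedModel",
    "CVResult",
    "orthogonal_poly",
    "hierarchy_contrasts",
    "build_design_matrix",
    "fit_binomial_glm",
    "deviance_compare",
    "stepwise_reduce",
    "roc_auc",
    "cross_validated_auc",
    "single_feature_aucs",
    "per_tf_auc",
    "validated_site_shift",
]

HIERARCHY_ORDER = ("bottom", "core", "top")
# contrast rows for (bottom, core, top): orthonormal linear and quadratic
_LIN = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)
_QUAD = np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)

# term name -> (kind, feature column); the design matrix builder knows how
# to expand each kind into columns
MODEL_TERMS = {
    "strength": ("continuous", "strength"),
    "distance": ("poly3", "distance"),
    "hierarchy": ("ordered3", "tf_hierarchy"),
    "subtelomeric": ("indicator", "subtelomeric"),
    "tf_essential": ("indicator", "tf_essential"),
    "divergent": ("indicator", "divergent_promoter"),
    "target_is_regulator": ("indicator_regulator", "target_is_regulator"),
    "overlaps_other_site": ("indicator", "overlaps_other_site"),
    "n_tfs": ("count", "n_tfs_in_promoter"),
    "target_essential": ("indicator_essential", "target_essential"),
    "in_nfr": ("indicator", "in_nfr"),
    "copy_number": ("count", "copy_number"),
    "emap_partner": ("indicator", "emap_partner"),
}

# the start set of the integrated model
DEFAULT_TERMS = [
    "strength", "distance", "hierarchy", "subtelomeric", "tf_essential",
    "divergent", "target_is_regulator", "overlaps_other_site", "n_tfs",
    "target_essential", "in_nfr", "copy_number",
]


class SeparationError(RuntimeError):
    """The likelihood is unbounded (complete or quasi-complete separation)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class FittedModel:
    terms: list
    columns: list
    beta: np.ndarray
    se: np.ndarray
    deviance: float
    null_deviance: float
    n: int
    mu: np.ndarray = field(repr=False)
    eta: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def coef_table(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame(
            {
                "term": self.columns,
                "estimate": self.beta,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def wald_interval(self, level: float = 0.95) -> pd.DataFrame:
        zc = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "term": self.columns,
                "lo": self.beta - zc * self.se,
                "hi": self.beta + zc * self.se,
            }
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = X[self.columns].to_numpy(dtype=float) @ self.beta
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CVResult:
    k: int
    fold_aucs: np.ndarray
    mean_auc: float
    se_auc: float
    roc_points: pd.DataFrame


# ---------------------------------------------------------------------------
# design matrix

def orthogonal_poly(x: np.ndarray, degree: int = 3) -> np.ndarray:
    """Degree-1..`degree` polynomial columns of `x`, mutually orthogonal and
    orthogonal to the intercept, scaled to unit standard deviation.

    The fitted probabilities of a GLM are invariant to the basis; the
    orthogonalized basis keeps the fit well conditioned and makes the
    per-degree deviance decomposition meaningful.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if len(np.unique(x)) <= degree:
        raise ValueError("not enough distinct values for the polynomial basis")
    xc = x - x.mean()
    M = np.column_stack([np.ones(n)] + [xc ** d for d in range(1, degree + 1)])
    Q, _ = np.linalg.qr(M)
    cols = Q[:, 1:] * np.sqrt(n)
    # fix signs so each column correlates positively with its raw power
    for j in range(degree):
        s = np.sign(cols[:, j] @ (xc ** (j + 1)))
        if s < 0:
            cols[:, j] = -cols[:, j]
    return cols


def hierarchy_contrasts(levels) -> np.ndarray:
    """(n, 2) linear and quadratic ordered contrasts for bottom/core/top."""
    idx = np.array([HIERARCHY_ORDER.index(v) for v in levels])
    return np.column_stack([_LIN[idx], _QUAD[idx]])


def build_design_matrix(
    features: pd.DataFrame,
    terms=None,
    add_intercept: bool = True,
    drop_unassigned_hierarchy: bool = True,
    drop_constant: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Expand a covariate table into named design columns.

    Returns ``(X, term_map)`` where ``term_map`` maps each retained term to
    its column names.  Rows with an unassigned regulator hierarchy are
    excluded when the hierarchy term is requested.  Terms constant in the
    data are dropped with a warning.
    """
    terms = list(DEFAULT_TERMS if terms is None else terms)
    df = features
    if "hierarchy" in terms and drop_unassigned_hierarchy:
        keep = df["tf_hierarchy"] != "unassigned"
        if not keep.all():
            logger.warning(
                "%d rows with unassigned hierarchy excluded", (~keep).sum()
            )
            df = df[keep]
    X = pd.DataFrame(index=df.index)
    if add_intercept:
        X["intercept"] = 1.0
    term_map = {}
    for term in terms:
        if term not in MODEL_TERMS:
            raise KeyError(f"unknown model term {term!r}")
        kind, col = MODEL_TERMS[term]
        if kind == "continuous":
            vals = df[col].to_numpy(dtype=float)
            cols = {term: vals}
        elif kind == "count":
            cols = {term: df[col].to_numpy(dtype=float)}
        elif kind == "indicator":
            cols = {term: df[col].astype(bool).to_numpy().astype(float)}
        elif kind == "indicator_regulator":
            cols = {term: (df[col] != "none").to_numpy().astype(float)}
        elif kind == "indicator_essential":
            cols = {term: (df[col] != "none").to_numpy().astype(float)}
        elif kind == "poly3":
            try:
                P = orthogonal_poly(df[col].to_numpy(dtype=float), 3)
            except ValueError:
                logger.warning("term %s dropped: too few distinct values", term)
                continue
            cols = {f"{term}_{d}": P[:, d - 1] for d in (1, 2, 3)}
        elif kind == "ordered3":
            C = hierarchy_contrasts(df[col])
            cols = {f"{term}_lin": C[:, 0], f"{term}_quad": C[:, 1]}
        else:  # pragma: no cover
            raise AssertionError(kind)
        arr = np.column_stack(list(cols.values()))
        if drop_constant and np.allclose(arr.std(axis=0), 0):
            logger.warning("term %s dropped: single level in data", term)
            continue
        for name, v in cols.items():
            X[name] = v
        term_map[term] = list(cols)
    return X, term_map


def add_interactions(
    X: pd.DataFrame, term_map: dict, pairs=None
) -> tuple[pd.DataFrame, dict]:
    """Append first-order interaction blocks (column-wise products).

    Multi-column terms (distance, hierarchy) interact as blocks.  Returns
    the extended matrix and a term map including entries like
    ``"strength:distance"``.
    """
    full_map = dict(term_map)
    mains = list(term_map)
    if pairs is None:
        pairs = list(itertools.combinations(mains, 2))
    new_cols = {}
    for a, b in pairs:
        cols = []
        for ca in term_map[a]:
            for cb in term_map[b]:
                name = f"{ca}:{cb}"
                prod = X[ca].to_numpy() * X[cb].to_numpy()
                if np.allclose(prod.std(), 0):
                    continue
                new_cols[name] = prod
                cols.append(name)
        if cols:
            full_map[f"{a}:{b}"] = cols
    X = pd.concat([X, pd.DataFrame(new_cols, index=X.index)], axis=1)
    return X, full_map


# ---------------------------------------------------------------------------
# IRLS fit

def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    return float(
        -2.0 * (y @ np.log(np.clip(mu, eps, 1)) +
                (1 - y) @ np.log(np.clip(1 - mu, eps, 1)))
    )


def fit_binomial_glm(
    X, y, max_iter: int = 50, tol: float = 1e-8, terms=None
) -> FittedModel:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the relative deviance change drops below `tol`.
    Complete separation and rank deficiency raise :class:`SeparationError`
    with diagnostics rather than returning a spurious fit.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        columns = [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n <= p:
        raise ValueError("more columns than observations")
    if y.min() == y.max():
        raise SeparationError(
            "outcome has a single level", {"mean_y": float(y.mean())}
        )
    # alias linearly dependent columns (pivoted QR), as R's glm does
    from scipy.linalg import qr as _qr

    _, R, piv = _qr(Xa, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > 1e-9 * max(diag.max(), 1.0)).sum())
    if rank < p:
        keep = np.sort(piv[:rank])
        aliased = [columns[i] for i in sorted(piv[rank:])]
        logger.warning("aliased (dropped) collinear columns: %s", aliased)
        Xa = Xa[:, keep]
        columns = [columns[i] for i in keep]
        p = rank
    beta = np.zeros(p)
    eta = Xa @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(y, mu)
    converged = False
    for _ in range(max_iter):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = Xa * w[:, None]
        H = Xa.T @ WX
        try:
            beta_new = np.linalg.solve(H, WX.T @ z)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "ill-conditioned information matrix",
                {"cond": float(np.linalg.cond(H))},
            )
        eta = Xa @ beta_new
        mu = 1.0 / (1.0 + np.exp(-eta))
        dev_new = _deviance(y, mu)
        delta = abs(dev - dev_new) / (abs(dev_new) + 0.1)
        beta, dev = beta_new, dev_new
        if delta < tol:
            converged = True
            break
    perfect = ((y == 1) & (mu > 1 - 1e-6)) | ((y == 0) & (mu < 1e-6))
    if np.abs(beta).max() > 1e3 or perfect.all():
        raise SeparationError(
            "complete or quasi-complete separation detected",
            {"max_abs_beta": float(np.abs(beta).max()), "deviance": dev},
        )
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = Xa.T @ (Xa * w[:, None])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    # null model: intercept only
    p_bar = y.mean()
    null_dev = _deviance(y, np.full(n, p_bar))
    return FittedModel(
        terms=list(terms) if terms is not None else [],
        columns=columns, beta=beta, se=se, deviance=dev,
        null_deviance=null_dev, n=n, mu=mu, eta=eta, converged=converged,
    )


def deviance_compare(full: FittedModel, reduced: FittedModel):
    """Likelihood-ratio comparison of nested fits: (chi2, df, p)."""
    if full.n != reduced.n:
        raise ValueError("models fitted on different rows")
    if not set(reduced.columns) <= set(full.columns):
        raise ValueError("models are not nested")
    chi2 = reduced.deviance - full.deviance
    df = len(full.columns) - len(reduced.columns)
    if df == 0:
        return 0.0, 0, 1.0
    chi2 = max(chi2, 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def stepwise_reduce(
    X: pd.DataFrame,
    y,
    term_map: dict,
    alpha: float = 0.05,
) -> tuple[FittedModel, pd.DataFrame]:
    """Backward elimination by analysis of deviance.

    Each round drops the single least significant droppable term whose
    drop p-value is >= `alpha`; interactions are considered before main
    effects, and a main effect is droppable only once no retained
    interaction contains it (marginality).  Returns the final fit and the
    elimination log.
    """
    y = np.asarray(y, dtype=float)
    retained = {t: list(cols) for t, cols in term_map.items()}

    def _cols(terms):
        out = ["intercept"] if "intercept" in X.columns else []
        for t in terms:
            out.extend(retained[t])
        return out

    current = fit_binomial_glm(X[_cols(retained)], y, terms=list(retained))
    # columns aliased out of the start fit stay out of every nested fit
    kept = set(current.columns)
    for t in list(retained):
        retained[t] = [c for c in retained[t] if c in kept]
        if not retained[t]:
            del retained[t]
    current = fit_binomial_glm(X[_cols(retained)], y, terms=list(retained))
    log = []
    step = 0
    while True:
        interactions = [t for t in retained if ":" in t]
        in_interaction = set()
        for t in interactions:
            in_interaction.update(t.split(":"))
        mains = [t for t in retained if ":" not in t and t not in in_interaction]
        best = None
        for group in (interactions, mains):
            for term in group:
                rest = [t for t in retained if t != term]
                reduced = fit_binomial_glm(X[_cols(rest)], y, terms=rest)
                chi2, df, p = deviance_compare(current, reduced)
                if best is None or p > best[1]:
                    best = (term, p, chi2, df, reduced)
            if best is not None and best[1] >= alpha:
                break  # drop an interaction before looking at main effects
            best = None
        if best is None:
            break
        term, p, chi2, df, reduced = best
        step += 1
        log.append(
            {"step": step, "dropped": term, "chi2": chi2, "df": df, "p": p}
        )
        del retained[term]
        current = reduced
    log_df = pd.DataFrame(log, columns=["step", "dropped", "chi2", "df", "p"])
    return current, log_df


def anova_table(X: pd.DataFrame, y, fit: FittedModel) -> pd.DataFrame:
    """Single-term deletions from the final model: df, deviance, LRT p."""
    y = np.asarray(y, dtype=float)
    rows = []
    term_cols = {t: [c for c in fit.columns if c == t or c.startswith(t + "_")]
                 for t in fit.terms}
    for term in fit.terms:
        cols = [c for c in fit.columns if c not in term_cols[term]]
        reduced = fit_binomial_glm(X[cols], y)
        chi2, df, p = deviance_compare(fit, reduced)
        rows.append(
            {"term": term, "df": df, "deviance_increase": chi2,
             "residual_deviance": reduced.deviance, "p": p}
        )
    return pd.DataFrame(rows).sort_values(
        "deviance_increase", ascending=False, ignore_index=True
    )


# ---------------------------------------------------------------------------
# ROC / cross-validation

def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Mann-Whitney AUC (ties count 1/2) and the ROC curve points."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("both outcome classes are required for a ROC curve")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _thr = roc_curve(labels, scores)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr})


def _stratified_folds(y, k, seed):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validated_auc(
    X: pd.DataFrame, y, k: int = 10, seed: int = 0
) -> CVResult:
    """Outcome-stratified k-fold CV of the model defined by `X`'s columns."""
    y = np.asarray(y, dtype=int)
    if len(y) < 10 * k:
        raise ValueError("too few rows for the requested number of folds")
    fold_aucs = []
    pooled_scores = np.empty(len(y))
    for train, test in _stratified_folds(y, k, seed):
        if y[test].min() == y[test].max():
            raise ValueError("a fold contains a single outcome class")
        fit = fit_binomial_glm(X.iloc[train], y[train])
        scores = fit.predict(X.iloc[test])
        pooled_scores[test] = scores
        fold_aucs.append(roc_auc_score(y[test], scores))
    fold_aucs = np.asarray(fold_aucs)
    fpr, tpr, _ = roc_curve(y, pooled_scores)
    return CVResult(
        k=k,
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        se_auc=float(fold_aucs.std(ddof=1) / np.sqrt(k)),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
    )


def single_feature_aucs(
    features: pd.DataFrame, y, terms=None, k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """CV AUC of each feature alone (same folds for every feature)."""
    terms = list(DEFAULT_TERMS if terms is None else terms)
    rows = []
    for term in terms:
        X, tm = build_design_matrix(features, [term])
        if term not in tm:
            continue
        yy = np.asarray(y, dtype=int)
        if len(X) != len(features):
            yy = yy[X.index.to_numpy()]  # features carries a range index
        cv = cross_validated_auc(X, yy, k=k, seed=seed)
        rows.append(
            {"feature": term, "mean_auc": cv.mean_auc, "se_auc": cv.se_auc}
        )
    return pd.DataFrame(rows).sort_values(
        "mean_auc", ascending=False, ignore_index=True
    )


def per_tf_auc(
    X: pd.DataFrame, y, tf_ids, min_n: int = 20
) -> tuple[pd.DataFrame, dict]:
    """Global-model scores evaluated within each TF's sites.

    TFs with fewer than `min_n` rows or a single outcome class are listed
    as ineligible.  Returns (per-TF table, summary with median and IQR).
    """
    y = np.asarray(y, dtype=int)
    tf_ids = np.asarray(tf_ids)
    fit = fit_binomial_glm(X, y)
    scores = fit.mu
    rows, excluded = [], []
    for tf in sorted(set(tf_ids)):
        mask = tf_ids == tf
        if mask.sum() < min_n or y[mask].min() == y[mask].max():
            excluded.append(tf)
            continue
        rows.append(
            {"tf_id": tf, "n": int(mask.sum()),
             "auc": float(roc_auc_score(y[mask], scores[mask]))}
        )
    if not rows:
        raise ValueError("no TF passes the per-TF evaluation requirements")
    table = pd.DataFrame(rows)
    summary = {
        "median_auc": float(table["auc"].median()),
        "iqr": (
            float(table["auc"].quantile(0.25)),
            float(table["auc"].quantile(0.75)),
        ),
        "n_tfs": len(table),
        "excluded": excluded,
    }
    return table, summary


def validated_site_shift(model_scores: pd.Series, validated_ids) -> dict:
    """Compare model scores of experimentally validated sites to all sites.

    Returns kernel-density curves for both distributions, a one-sided
    Mann-Whitney p (validated > overall), and the median shift.
    """
    validated_ids = list(validated_ids)
    if len(validated_ids) < 5:
        raise ValueError("validated subset too small (need >= 5 sites)")
    missing = set(validated_ids) - set(model_scores.index)
    if missing:
        raise KeyError(f"validated ids not scored: {sorted(missing)[:5]}")
    val = model_scores.loc[validated_ids].to_numpy(dtype=float)
    overall = model_scores.to_numpy(dtype=float)
    grid = np.linspace(overall.min(), overall.max(), 256)
    kde_val = stats.gaussian_kde(val)(grid) if val.std() > 0 else None
    kde_all = stats.gaussian_kde(overall)(grid)
    if np.array_equal(np.sort(val), np.sort(overall)):
        p = 0.5
    else:
        p = float(
            stats.mannwhitneyu(val, overall, alternative="greater").pvalue
        )
    return {
        "grid": grid,
        "density_validated": kde_val,
        "density_overall": kde_all,
        "p_value": p,
        "median_shift": float(np.median(val) - np.median(overall)),
    }
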