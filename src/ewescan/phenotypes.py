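"""Phenotype adjustment and high/low fecundity group formation.

The fecundity outcome (0/1/2 lambs per mating per year) is modelled with a
Gaussian identity-link linear model y = b0 + b1*x1 after Wald screening of
the candidate covariates (record year, age, body condition, hours to
estrus, number of births); in practice only the intercept and body
condition survive screening.  Ewes are then split into high/low fecundity
subpopulations by agglomerative hierarchical clustering (complete linkage
by default) on the Euclidean distances of the model-adjusted phenotypes,
and the group difference is tested with Welch's unequal-variance t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
import statsmodels.api as sm

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["ewe_id", "year", "age", "body_condition", "hours_to_estrus",
                 "n_births", "fecundity"]
COVARIATES = ["year", "age", "body_condition", "hours_to_estrus", "n_births"]


@dataclass
class GlmFit:
    params: pd.Series            # coefficient estimates (incl. intercept)
    bse: pd.Series               # standard errors
    wald: pd.Series              # (estimate/se)^2
    wald_p: pd.Series            # chi-squared(1) upper tail
    fitted: pd.Series            # per ewe, indexed by ewe_id
    accuracy: float              # fraction with round(fitted) == observed
    retained: list[str]          # covariates with Wald p < alpha (screening)
    dropped: list[str] = field(default_factory=list)  # aliased/constant covariates


@dataclass
class GroupAssignment:
    labels: pd.Series            # ewe_id -> "high"/"low"
    group_means: dict[str, float]
    group_se: dict[str, float]
    t_stat: float
    df: float
    p_value: float
    linkage_matrix: np.ndarray | None = None

    def members(self, group: str) -> list[str]:
        return self.labels.index[self.labels == group].tolist()


def validate_phenotypes(table: pd.DataFrame, aggregated: bool = False) -> pd.DataFrame:
    """Check PhenotypeTable invariants.  Aggregated (per-ewe) tables carry a
    mean fecundity in [0, 2]; raw ewe-year tables the categorical {0,1,2}."""
    missing = [c for c in PHENO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if aggregated:
        if ((table["fecundity"] < 0) | (table["fecundity"] > 2)).any():
            raise ValueError("aggregated fecundity must lie in [0, 2]")
    elif not table["fecundity"].isin([0, 1, 2]).all():
        raise ValueError("fecundity must be 0, 1 or 2")
    bc = table["body_condition"]
    if ((bc < 1) | (bc > 5)).any():
        raise ValueError("body condition must lie in [1, 5]")
    return table


def aggregate_per_ewe(table: pd.DataFrame) -> pd.DataFrame:
    """One row per ewe: mean fecundity across years, covariates from the
    latest record."""
    validate_phenotypes(table)
    latest = (table.sort_values(["ewe_id", "year"]).groupby("ewe_id").tail(1)
              .set_index("ewe_id"))
    mean_fec = table.groupby("ewe_id")["fecundity"].mean()
    out = latest.drop(columns=["fecundity"]).join(mean_fec)
    return out.reset_index()


def _design(table: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix with constant; drops constant or aliased covariates."""
    X = table[covariates].astype(float)
    dropped = [c for c in covariates if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"covariates constant across ewes, excluded: {dropped}")
        X = X.drop(columns=dropped)
    X = sm.add_constant(X, has_constant="add")
    # detect aliasing (rank-deficient design) and drop offenders greedily
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        for c in reversed([c for c in X.columns if c != "const"]):
            X2 = X.drop(columns=[c])
            if np.linalg.matrix_rank(X2.to_numpy()) == X2.shape[1]:
                warnings.warn(f"covariate {c} is collinear with the others, excluded")
                dropped.append(c)
                X = X2
                break
    return X, dropped


def _fit(table: pd.DataFrame, covariates: list[str], alpha: float = 0.05) -> GlmFit:
    y = table["fecundity"].astype(float).to_numpy()
    X, dropped = _design(table, covariates)
    res = sm.OLS(y, X).fit()
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    wald = (params / bse) ** 2
    wald_p = pd.Series(st.chi2.sf(wald, df=1), index=X.columns)
    fitted = pd.Series(np.asarray(res.fittedvalues), index=table["ewe_id"].to_numpy())
    predicted = np.clip(np.rint(np.asarray(res.fittedvalues)), 0, 2)
    observed_cat = np.clip(np.rint(y), 0, 2)
    accuracy = float((predicted == observed_cat).mean())
    retained = [c for c in X.columns if c != "const" and wald_p[c] < alpha]
    return GlmFit(params=params, bse=bse, wald=wald, wald_p=wald_p,
                  fitted=fitted, accuracy=accuracy, retained=retained,
                  dropped=dropped)


def screen_covariates(table: pd.DataFrame, alpha: float = 0.05) -> GlmFit:
    """Full-model least squares fit of fecundity on all candidate covariates
    with per-coefficient Wald chi-squared screening at ``alpha``."""
    validate_phenotypes(table, aggregated=True)
    return _fit(table, COVARIATES, alpha=alpha)


def fit_final_model(table: pd.DataFrame) -> GlmFit:
    """Final model: fecundity ~ intercept + body condition.

    ``accuracy`` is the fraction of ewes whose fitted value, rounded to the
    nearest of {0,1,2}, equals the observed outcome.  A constant body
    condition degrades to an intercept-only fit with a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 ewes to fit the final model")
    fit = _fit(table, ["body_condition"])
    if "body_condition" in fit.dropped:
        logger.warning("body condition constant: intercept-only model")
    return fit


def assign_groups(adjusted: pd.Series, k: int = 2,
                  linkage: str = "complete") -> GroupAssignment:
    """Hierarchical clustering of model-adjusted phenotypes into high/low.

    ``adjusted`` is indexed by ewe id.  Clustering is agglomerative on the
    pairwise Euclidean distances of the adjusted values, the tree is cut at
    ``k`` (=2) clusters, and the higher-mean cluster is labelled "high".
    The group difference is tested with Welch's t-test on the adjusted
    values.
    """
    if adjusted.nunique() < 2:
        raise ValueError("all adjusted phenotypes identical: no group structure")
    values = adjusted.to_numpy(dtype=float).reshape(-1, 1)
    Z = sch.linkage(values, method=linkage, metric="euclidean")
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    means = {c: values[flat == c].mean() for c in np.unique(flat)}
    if len(means) != 2:
        raise ValueError(f"clustering produced {len(means)} groups, expected 2")
    high_cluster = max(means, key=means.get)
    labels = pd.Series(np.where(flat == high_cluster, "high", "low"),
                       index=adjusted.index, name="group")
    a = adjusted[labels == "high"].to_numpy()
    b = adjusted[labels == "low"].to_numpy()
    t, df, p = welch_t_test(a, b)
    return GroupAssignment(
        labels=labels,
        group_means={"high": float(a.mean()), "low": float(b.mean())},
        group_se={"high": float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else float("nan"),
                  "low": float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else float("nan")},
        t_stat=t, df=df, p_value=p, linkage_matrix=Z,
    )


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, Satterthwaite df, two-sided p.

    Degenerate case: both groups with zero variance and equal means gives
    t = 0, p = 1 (df reported as n_a + n_b - 2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.inf) if diff > 0 else float(-np.inf), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    # Satterthwaite; terms with zero variance contribute nothing
    denom = 0.0
    if va > 0:
        denom += (va / na) ** 2 / (na - 1)
    if vb > 0:
        denom += (vb / nb) ** 2 / (nb - 1)
    df = se2 ** 2 / denom
    p = 2.0 * st.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def dendrogram_newick(assignment: GroupAssignment, ids: list[str]) -> str:
    """Newick text export of the clustering tree (branch lengths = merge
    heights)."""
    Z = assignment.linkage_matrix
    if Z is None:
        raise ValueError("assignment carries no linkage matrix")
    tree = sch.to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
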