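"""Per-sample HGT prevalence, environmental preprocessing, and a
permutation-null random forest of prevalence on environmental variables.

The prevalence of a feature in a sample is the proportion of genomes
present in that sample with at least one instance of the feature (an HGT
call, a mobile-genetic-element hit, a plasmid/virus/provirus contig).
Environmental variables are de-duplicated at |Spearman rho| >= 0.95 and
summarized by average-linkage clustering on the distance |1 - rho|.

Variable importance significance follows a permutation-null scheme: a
random-forest regressor is fit to the observed response, then refit B
times with the response shuffled; the p-value of a variable is the raw
proportion of null replicates whose importance is at least the observed
one (which admits p = 0; a (b+1)/(B+1) variant is available behind a
flag). The forest is a bagged ensemble of unpruned regression trees with
mtry = floor(p/3) features per split; importance is permutation
importance (increase in mean squared error when one predictor column is
shuffled), never impurity importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr, wilcoxon

from .occurrence import OccurrenceMatrix, bh_adjust

logger = logging.getLogger(__name__)


def hgt_prevalence(
    m: OccurrenceMatrix, genome_flags: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample proportion of present genomes carrying each feature.

    ``genome_flags`` is indexed by genome with one boolean column per
    feature (dataset-level genome properties, e.g. ">= 1 cluster-RBH
    event"). Samples with zero present genomes are excluded.
    """
    flags = genome_flags.reindex(m.genomes).fillna(False).astype(bool)
    P = m.presence.values.astype(float)
    n_present = P.sum(axis=1)
    rows = []
    for si, sample in enumerate(m.samples):
        if n_present[si] == 0:
            continue
        row = {"sample": sample, "n_present": int(n_present[si])}
        for feature in flags.columns:
            row[feature] = float(P[si] @ flags[feature].values) / n_present[si]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def env_redundancy_filter(
    variables: pd.DataFrame, rho_thresh: float = 0.95
) -> list[str]:
    """Greedily retain one representative per group of variables pairwise
    correlated at |Spearman rho| >= ``rho_thresh``; the first-listed
    variable of each group is kept. Constant variables (undefined rho)
    are dropped with a warning."""
    if len(variables) < 2:
        raise ValueError("need at least two samples")
    cols = []
    for c in variables.columns:
        if variables[c].nunique() < 2:
            logger.warning("dropping constant variable %r", c)
        else:
            cols.append(c)
    rho = variables[cols].corr(method="spearman").abs()
    kept: list[str] = []
    for c in cols:
        if all(rho.loc[c, k] < rho_thresh for k in kept):
            kept.append(c)
    return kept


@dataclass
class VariableDendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix, average method
    distances: pd.DataFrame  # |1 - rho| matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def env_cluster(variables: pd.DataFrame) -> VariableDendrogram:
    """Average-linkage hierarchical clustering of variables on the
    distance |1 - Spearman rho|."""
    if variables.shape[1] < 2:
        raise ValueError("need at least two variables")
    for c in variables.columns:
        if variables[c].nunique() < 2:
            raise ValueError(f"constant variable {c!r}: correlation undefined")
    rho = variables.corr(method="spearman")
    dist = (1.0 - rho).abs()
    np.fill_diagonal(dist.values, 0.0)
    Z = average(squareform(dist.values, checks=False))
    return VariableDendrogram(
        labels=list(variables.columns), linkage=Z, distances=dist
    )


# ---------------------------------------------------------------------------
# random forest with permutation-null importance


def _rf_params(p: int, mtry: int | None, seed: int) -> dict:
    mtry = mtry if mtry is not None else max(1, p // 3)
    return dict(
        boosting="rf",
        objective="regression",
        bagging_freq=1,
        bagging_fraction=0.632,
        feature_fraction=min(1.0, mtry / p),
        min_data_in_leaf=5,
        num_threads=1,
        verbose=-1,
        seed=seed,
        deterministic=True,
        force_row_wise=True,
    )


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, params: dict):
    return lgb.train(
        params, lgb.Dataset(X, label=y, params={"verbose": -1}),
        num_boost_round=n_trees,
    )


def _perm_importance(
    booster, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permutation importance: increase in MSE when one predictor column is
    shuffled, one permutation pass per variable. A single stacked predict
    call keeps the per-replicate cost low."""
    n, p = X.shape
    mats = [X]
    for j in range(p):
        Xp = X.copy()
        Xp[:, j] = Xp[rng.permutation(n), j]
        mats.append(Xp)
    preds = booster.predict(np.vstack(mats)).reshape(p + 1, n)
    mse = np.mean((preds - y[None, :]) ** 2, axis=1)
    return mse[1:] - mse[0]


@dataclass
class ImportanceResult:
    table: pd.DataFrame  # variable, importance, p, p_adj, significant, sign
    null_importances: pd.DataFrame  # B x variables
    n_trees: int
    n_null: int


def rf_importance_test(
    X: pd.DataFrame,
    y,
    n_trees: int = 10_000,
    B: int = 1000,
    seed: int = 0,
    mtry: int | None = None,
    alpha: float = 0.05,
    pseudocount: bool = False,
) -> ImportanceResult:
    """Permutation-null significance of random-forest variable importance.

    Fits a forest of ``n_trees`` trees to (X, y), then refits on ``B``
    response-shuffled replicates (a fresh permutation each, all seeded)
    and records each variable's permutation importance. p = proportion of
    null importances >= the observed one (raw, so p = 0 can occur; set
    ``pseudocount`` for the (b+1)/(B+1) variant), BH-adjusted across
    variables, significant at adjusted p < ``alpha``. The marginal
    association sign comes from Spearman correlation with the response.

    Deterministic for fixed (seed, B, n_trees).
    """
    y = np.asarray(y, dtype=float)
    if B <= 0:
        raise ValueError("B must be positive")
    if len(X) < 2:
        raise ValueError("need at least two samples")
    if len(X) < 10:
        raise ValueError("fewer than 10 samples: the forest would be meaningless")
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")

    Xv = np.ascontiguousarray(X.values, dtype=float)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=B + 1)

    booster = _fit_forest(Xv, y, n_trees, _rf_params(p, mtry, int(fit_seeds[0])))
    observed = _perm_importance(booster, Xv, y, rng)

    null = np.empty((B, p))
    for b in range(B):
        ys = y[rng.permutation(n)]
        nb = _fit_forest(Xv, ys, n_trees, _rf_params(p, mtry, int(fit_seeds[b + 1])))
        null[b] = _perm_importance(nb, Xv, ys, rng)

    exceed = (null >= observed[None, :]).sum(axis=0)
    if pseudocount:
        pvals = (exceed + 1) / (B + 1)
    else:
        pvals = exceed / B
    p_adj = np.array(bh_adjust(list(pvals)))
    signs = []
    for j in range(p):
        rho = spearmanr(Xv[:, j], y).statistic
        signs.append(0 if np.isnan(rho) else int(np.sign(rho)))

    table = pd.DataFrame(
        {
            "variable": list(X.columns),
            "importance": observed,
            "p": pvals,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "sign": signs,
            "null_q50": np.quantile(null, 0.5, axis=0),
            "null_q95": np.quantile(null, 0.95, axis=0),
        }
    )
    return ImportanceResult(
        table=table,
        null_importances=pd.DataFrame(null, columns=list(X.columns)),
        n_trees=n_trees,
        n_null=B,
    )


def paired_fraction_test(
    small: pd.DataFrame, large: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank comparison of feature prevalence between
    matched size-fraction samples.

    ``small`` and ``large`` are indexed by biological sample (matched
    pairs) with one column per feature. Requires at least 5 matched pairs.
    The mean fold change is the mean of per-pair large/small ratios, with
    pairs at small = 0 excluded from the fold mean (their count is
    reported); the ratio of means is also emitted. All differences zero
    gives p = 1 by convention.
    """
    common = small.index.intersection(large.index)
    if len(common) < 5:
        raise ValueError(f"need at least 5 matched pairs, got {len(common)}")
    small, large = small.loc[common], large.loc[common]
    features = features if features is not None else list(small.columns)
    rows = []
    for feat in features:
        s = small[feat].astype(float).values
        l = large[feat].astype(float).values
        diff = l - s
        if np.all(diff == 0):
            p = 1.0
        else:
            p = float(wilcoxon(l, s, zero_method="wilcox").pvalue)
        nonzero = s > 0
        ratios = l[nonzero] / s[nonzero]
        rows.append(
            dict(
                feature=feat,
                n_pairs=len(common),
                n_excluded_zero_small=int((~nonzero).sum()),
                mean_fold=float(ratios.mean()) if ratios.size else np.nan,
                fold_of_means=float(l.mean() / s.mean()) if s.mean() > 0 else np.nan,
                p=p,
            )
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(list(df["p"])) if len(df) else []
    return df
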