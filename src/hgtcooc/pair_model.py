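"""Pairwise genome feature table and logistic models of HGT.

One row per unordered genome pair at genus-or-broader divergence: whether
the pair has at least one cluster-RBH HGT event, whether it significantly
co-occurs, its patristic distance, the absolute difference in per-genome
median environmental values (medians over the samples each genome occupies),
and the size-fraction pair category (both_small / both_less_filtered /
other). Continuous predictors are rank-transformed to normal scores
(ordered quantile normalization) before logistic regression; binary and
categorical predictors are left untouched. Model quality is compared by
AIC and multicollinearity is screened with variance inflation factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from scipy.special import ndtri

from .genome_io import CROSS_GENUS_LEVELS, divergence_level
from .occurrence import OccurrenceMatrix

PAIR_FRACTION_LEVELS = ("other", "both_small", "both_less_filtered")


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass
class ModelFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    intercept: float
    aic: float
    vif: dict[str, float]
    n: int
    terms: tuple[str, ...] = ()


def build_pair_table(
    events,
    cooc: pd.DataFrame,
    phylo: pd.DataFrame,
    occ: OccurrenceMatrix,
    sample_env: pd.DataFrame,
    fraction_classes: dict[str, str],
    taxonomy: dict[str, tuple[str, ...]],
) -> pd.DataFrame:
    """Assemble the pair feature table.

    ``events`` are cluster-RBH HGT events; ``cooc`` is the hypergeometric
    co-occurrence table; ``phylo`` the patristic distance matrix;
    ``sample_env`` is indexed by sample with one column per environmental
    variable. Genomes without a single occupied sample are excluded. Pairs
    within a genus (or with identical taxonomy) are not emitted.
    """
    genomes = [g for g in occ.genomes if occ.presence[g].any()]
    env_vars = list(sample_env.columns)

    medians: dict[str, pd.Series] = {}
    for g in genomes:
        occupied = sorted(occ.occupied_samples(g))
        medians[g] = sample_env.loc[occupied, env_vars].median(axis=0)

    hgt_pairs = {
        frozenset((e.genome_a, e.genome_b))
        for e in events
        if e.method == "cluster_rbh"
    }
    sig = {
        frozenset((r.genome_a, r.genome_b))
        for r in cooc.itertuples(index=False)
        if r.significant
    }

    rows = []
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            level = divergence_level(taxonomy[a], taxonomy[b])
            if level not in CROSS_GENUS_LEVELS:
                continue
            fa = fraction_classes.get(a, "unclassified")
            fb = fraction_classes.get(b, "unclassified")
            if fa == fb == "small":
                pair_fraction = "both_small"
            elif fa == fb == "less_filtered":
                pair_fraction = "both_less_filtered"
            else:
                pair_fraction = "other"
            row = {
                "genome_a": a,
                "genome_b": b,
                "hgt": int(frozenset((a, b)) in hgt_pairs),
                "cooccur": int(frozenset((a, b)) in sig),
                "phylo_dist": float(phylo.loc[a, b]),
                "pair_fraction": pair_fraction,
                "level": level,
            }
            for v in env_vars:
                row[f"diff_{v}"] = abs(float(medians[a][v]) - float(medians[b][v]))
            rows.append(row)
    return pd.DataFrame(rows)


def ordered_quantile_normalize(values) -> np.ndarray:
    """Rank-based inverse-normal transform: r -> Phi^-1((r - 0.5) / n).

    Average ranks are used for ties, so the map is monotone in the input
    and the output has mean approximately 0 and unit-scale spread. Raises
    on constant input, for which no normalization exists.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d array with at least two values")
    if np.unique(x).size < 2:
        raise ValueError("constant input cannot be quantile-normalized")
    r = rankdata(x, method="average")
    return ndtri((r - 0.5) / x.size)


def _design(rows: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame, list[str]]:
    cols = {}
    names = []
    for t in terms:
        if t == "pair_fraction":
            for lvl in PAIR_FRACTION_LEVELS[1:]:  # "other" is the reference
                dummy = (rows["pair_fraction"] == lvl).astype(float)
                if dummy.sum() == 0:
                    continue  # level absent from the data: no column
                name = f"pair_fraction[{lvl}]"
                cols[name] = dummy
                names.append(name)
        else:
            cols[t] = rows[t].astype(float)
            names.append(t)
    X = pd.DataFrame(cols, index=rows.index)
    return X, names


def fit_logistic(rows: pd.DataFrame, terms: list[str]) -> ModelFit:
    """Maximum-likelihood logistic regression of the ``hgt`` flag.

    ``terms`` name columns of the pair table; ``pair_fraction`` expands to
    treatment-coded dummies with "other" as reference. Continuous
    predictors are expected to be normalized already. Perfect separation
    aborts the fit with :class:`SeparationError`.
    """
    y = rows["hgt"].astype(float).values
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("response is constant: no events (or only events)")
    X, names = _design(rows, list(terms))
    exog = sm.add_constant(X, prepend=True)
    try:
        import warnings

        with warnings.catch_warnings():
            # separation shows up as warnings before the diverging
            # coefficients below; both paths end in SeparationError
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and numerical failures
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (separation?)")
    if np.abs(np.asarray(res.params)[1:]).max(initial=0.0) > 50:
        raise SeparationError("diverging coefficients indicate perfect separation")

    vif = _vif(exog.values, names)
    params = dict(zip(exog.columns, res.params))
    bse = dict(zip(exog.columns, res.bse))
    return ModelFit(
        coefficients={k: float(v) for k, v in params.items() if k != "const"},
        standard_errors={k: float(v) for k, v in bse.items() if k != "const"},
        intercept=float(params["const"]),
        aic=float(res.aic),
        vif=vif,
        n=len(rows),
        terms=tuple(terms),
    )


def _vif(exog: np.ndarray, names: list[str]) -> dict[str, float]:
    """Variance inflation factors from auxiliary linear regressions of each
    predictor column on the remaining ones (constant included)."""
    out = {}
    for j, name in enumerate(names, start=1):  # column 0 is the constant
        y = exog[:, j]
        others = np.delete(exog, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
        out[name] = float(1.0 / max(1.0 - r2, 1e-12))
    return out


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits by ascending AIC with pairwise delta-AIC to the best.

    All fits must come from the same row set (equal n), otherwise AIC
    values are not comparable.
    """
    if len({f.n for f in fits}) > 1:
        raise ValueError("fits on differing row counts are not comparable")
    order = sorted(range(len(fits)), key=lambda i: fits[i].aic)
    best = fits[order[0]].aic
    rows = [
        dict(
            rank=r + 1,
            terms="+".join(fits[i].terms),
            aic=fits[i].aic,
            delta_aic=fits[i].aic - best,
        )
        for r, i in enumerate(order)
    ]
    return pd.DataFrame(rows)


@dataclass
class FoldChange:
    fold: float
    direction: str  # "increase" | "decrease" | "none"


def coef_to_fold(beta: float) -> FoldChange:
    """Convert a logistic coefficient to a fold change in odds.

    A coefficient b > 0 is an e^b-fold increase in the odds; b < 0 is a
    1/e^b-fold decrease (reported as a fold >= 1 with direction
    "decrease"); b = 0 is no change.
    """
    if not math.isfinite(beta):
        raise ValueError("coefficient must be finite")
    if beta == 0:
        return FoldChange(1.0, "none")
    if beta > 0:
        return FoldChange(math.exp(beta), "increase")
    return FoldChange(math.exp(-beta), "decrease")
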