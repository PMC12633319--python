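"""Functional enrichment of HGT-involved gene clusters and genes.

COG category labels are lifted from genes to clusters by strict majority
vote over the annotated members. Enrichment of each COG category among
clusters involved in at least one HGT event is tested with two-sided
Fisher's exact tests, stratified by (identity bin, divergence level), with
Benjamini-Hochberg correction pooled across all stratum x category tests.
The unit of observation is the cluster: a cluster appearing in many events
still counts once. Mobile-genetic-element features are tested per gene and
summarized as fold enrichments (ratios of proportions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .hgt_detect import HgtEvent
from .occurrence import bh_adjust

#: Eukaryote-specific COG categories; clusters annotated with only these
#: are excluded from testing.
EUKARYOTE_CATEGORIES = frozenset("ABYZ")


def majority_cog(labels: list) -> tuple[str, ...] | None:
    """COG letters carried by a strict majority of annotated members.

    ``labels`` holds one entry per cluster member: a string of one or more
    COG letters, or None/empty when the gene is unannotated. Multi-letter
    genes contribute to each of their letters. Returns the tuple of
    majority letters (sorted), or None when no letter reaches a strict
    majority (ties included) or no member is annotated.
    """
    annotated = [set(lab) for lab in labels if lab]
    if not annotated:
        return None
    counts: dict[str, int] = {}
    for letset in annotated:
        for letter in letset:
            counts[letter] = counts.get(letter, 0) + 1
    majority = tuple(
        sorted(letter for letter, c in counts.items() if c > len(annotated) / 2)
    )
    return majority or None


def is_eukaryote_specific(letters: tuple[str, ...] | None) -> bool:
    return bool(letters) and set(letters) <= EUKARYOTE_CATEGORIES


@dataclass
class EnrichmentResult:
    stratum: tuple[str, str]  # (identity_bin, level)
    category: str
    a: int  # HGT clusters in category
    b: int  # HGT clusters in other categories
    c: int  # non-HGT clusters in category
    d: int  # non-HGT clusters in other categories
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    direction: str = ""
    degenerate: bool = False


def assign_cluster_cogs(
    clusters, gene_cogs: dict[str, str]
) -> dict[str, tuple[str, ...]]:
    """Majority-rule COG assignment per cluster; clusters with no majority
    label or only eukaryote-specific labels are omitted."""
    out: dict[str, tuple[str, ...]] = {}
    for cluster in clusters:
        labels = [gene_cogs.get(gid) for _g, gid, _seq in cluster.members]
        letters = majority_cog(labels)
        if letters is None or is_eukaryote_specific(letters):
            continue
        out[cluster.cluster_id] = letters
    return out


def stratified_enrichment(
    cluster_cogs: dict[str, tuple[str, ...]],
    events: list[HgtEvent],
    pooled_bh: bool = True,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher's exact enrichment of COG categories among HGT clusters,
    per (identity bin, divergence level) stratum.

    ``cluster_cogs`` is the annotated cluster universe (clusters without a
    majority COG are already excluded). Every event must map to a cluster.
    BH correction is pooled across all stratum x category tests by
    default; set ``pooled_bh=False`` to correct within each stratum.
    """
    universe = sorted(cluster_cogs)
    strata: dict[tuple[str, str], set[str]] = {}
    for e in events:
        if e.cluster_id is None:
            raise ValueError("event without a cluster id")
        if e.cluster_id not in cluster_cogs:
            continue  # unannotated cluster: outside the tested universe
        strata.setdefault((e.identity_bin, e.level), set()).add(e.cluster_id)

    categories = sorted({c for letters in cluster_cogs.values() for c in letters})
    results: list[EnrichmentResult] = []
    for stratum in sorted(strata):
        hgt_set = strata[stratum]
        if not hgt_set:
            continue
        for cat in categories:
            in_cat = {cl for cl in universe if cat in cluster_cogs[cl]}
            a = len(hgt_set & in_cat)
            b = len(hgt_set) - a
            c = len(in_cat) - a
            d = len(universe) - len(hgt_set) - c
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            degenerate = not np.isfinite(odds)
            direction = "enriched" if odds > 1 or degenerate else "depleted"
            results.append(
                EnrichmentResult(
                    stratum=stratum,
                    category=cat,
                    a=a, b=b, c=c, d=d,
                    odds_ratio=float(odds),
                    p=float(p),
                    direction=direction,
                    degenerate=degenerate,
                )
            )

    if results:
        if pooled_bh:
            adj = bh_adjust([r.p for r in results])
            for r, q in zip(results, adj):
                r.p_adj = float(q)
        else:
            by_stratum: dict[tuple[str, str], list[EnrichmentResult]] = {}
            for r in results:
                by_stratum.setdefault(r.stratum, []).append(r)
            for rs in by_stratum.values():
                for r, q in zip(rs, bh_adjust([r.p for r in rs])):
                    r.p_adj = float(q)
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        dict(
            identity_bin=r.stratum[0],
            level=r.stratum[1],
            category=r.category,
            a=r.a, b=r.b, c=r.c, d=r.d,
            odds_ratio=r.odds_ratio,
            p=r.p,
            p_adj=r.p_adj,
            direction=r.direction,
            degenerate=int(r.degenerate),
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["identity_bin", "level", "category", "a", "b", "c", "d",
                 "odds_ratio", "p", "p_adj", "direction", "degenerate"],
    )


def mge_fold_enrichment(
    gene_flags: pd.DataFrame, hgt_genes: set[str]
) -> pd.DataFrame:
    """Per-gene fold enrichment of MGE features among HGT genes.

    ``gene_flags`` is indexed by gene id with one boolean/0-1 column per
    feature (mge_hit, plasmid_contig, ...). For each feature the fold is
    P(flag | HGT gene) / P(flag | non-HGT gene); folds below 1 are also
    reported as a depletion fold 1/fold. p-values come from two-sided
    Fisher's exact tests. Zero denominators are flagged and leave the fold
    undefined (NaN).
    """
    genes = gene_flags.index
    is_hgt = genes.isin(hgt_genes)
    n_hgt, n_other = int(is_hgt.sum()), int((~is_hgt).sum())
    rows = []
    for feature in gene_flags.columns:
        flags = gene_flags[feature].astype(bool).values
        a = int((flags & is_hgt).sum())
        b = n_hgt - a
        c = int((flags & ~is_hgt).sum())
        d = n_other - c
        _odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        p1 = a / n_hgt if n_hgt else np.nan
        p0 = c / n_other if n_other else np.nan
        depletion_fold = np.nan
        if n_hgt == 0 or n_other == 0 or (p1 == 0 and p0 == 0):
            fold, direction = np.nan, "undefined"  # zero denominator, flagged
        elif p1 == 0:  # absent from the HGT set: inverse ratio is infinite
            fold, depletion_fold, direction = 0.0, np.inf, "depleted"
        elif p0 == 0:
            fold, direction = np.inf, "enriched"
        else:
            fold = p1 / p0
            direction = "enriched" if fold >= 1 else "depleted"
            if fold < 1:
                depletion_fold = 1.0 / fold
        rows.append(
            dict(
                feature=feature,
                a=a, b=b, c=c, d=d,
                prop_hgt=p1,
                prop_other=p0,
                fold=fold,
                depletion_fold=depletion_fold,
                direction=direction,
                p=float(p),
            )
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(list(df["p"])) if len(df) else []
    return df
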