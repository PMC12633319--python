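"""Presence calling, prevalence filtering, size-fraction classification and
pairwise co-occurrence testing.

A genome is present in a sample when its breadth of coverage is at least
0.30; RPKM abundance is zeroed wherever the genome is absent, and samples
with no present genome are dropped. Genomes present in fewer than 10
samples are removed before testing. Pairwise co-occurrence is assessed with
an upper-tail hypergeometric test (the observed overlap is included in the
tail) and summarized by the co-occurrence ratio, observed shared samples
over the expectation n1*n2/N under random placement. Significance requires
a Benjamini-Hochberg adjusted p below 0.05 *and* a ratio strictly above 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceMatrix:
    """Samples x genomes presence and abundance with size-fraction labels."""

    presence: pd.DataFrame  # bool, samples x genomes
    abundance: pd.DataFrame  # float, same shape; 0 wherever absent
    sample_fractions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.presence.index.equals(self.abundance.index) or not (
            self.presence.columns.equals(self.abundance.columns)
        ):
            raise ValueError("presence and abundance dimensions differ")
        if self.presence.size:
            pres = self.presence.to_numpy(dtype=bool)
            if ((self.abundance.to_numpy(dtype=float) != 0) & ~pres).any():
                raise ValueError("non-zero abundance where presence is false")

    @property
    def samples(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.columns)

    def occupied_samples(self, genome: str) -> set[str]:
        col = self.presence[genome]
        return set(col.index[col])


def call_presence(
    coverage: pd.DataFrame, breadth_thresh: float = 0.30
) -> OccurrenceMatrix:
    """Presence calling from a long coverage table.

    ``coverage`` has columns sample, genome, breadth, rpkm. Presence is
    breadth >= ``breadth_thresh`` (inclusive); abundance is zeroed where
    absent; samples in which no genome is present are dropped.
    """
    required = {"sample", "genome", "breadth", "rpkm"}
    if not required.issubset(coverage.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    breadth = coverage.pivot(index="sample", columns="genome", values="breadth")
    rpkm = coverage.pivot(index="sample", columns="genome", values="rpkm")
    if breadth.isna().any().any():
        raise ValueError("coverage table is not a complete sample x genome grid")
    if (breadth.values < 0).any() or (breadth.values > 1).any():
        raise ValueError("breadth values must lie in [0, 1]")
    presence = breadth >= breadth_thresh
    abundance = rpkm.where(presence, 0.0)
    occupied = presence.any(axis=1)
    if (~occupied).any():
        logger.info("dropping %d samples with no present genome", int((~occupied).sum()))
    presence, abundance = presence[occupied], abundance[occupied]
    return OccurrenceMatrix(presence=presence, abundance=abundance)


def prevalence_filter(m: OccurrenceMatrix, min_samples: int = 10) -> OccurrenceMatrix:
    """Remove genomes present in fewer than ``min_samples`` samples
    (a genome present in exactly ``min_samples`` is retained)."""
    prev = m.presence.sum(axis=0)
    keep = prev[prev >= min_samples].index
    if len(keep) == 0:
        logger.warning("prevalence filter removed every genome")
    return OccurrenceMatrix(
        presence=m.presence[keep],
        abundance=m.abundance[keep],
        sample_fractions=m.sample_fractions,
    )


def hypergeom_cooccurrence(m: OccurrenceMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric co-occurrence test for every genome pair.

    For a pair with prevalences n1, n2 in N samples and k shared samples,
    p = P(X >= k) where X is the overlap of a random n1-subset with a
    fixed n2-subset of the N samples (the observed k is included in the
    tail). Benjamini-Hochberg adjustment is applied jointly across all
    tested pairs. The co-occurrence ratio is k / (n1*n2/N); pairs with a
    zero prevalence get p = 1 and ratio = 0 by convention.
    """
    P = m.presence.values.astype(np.int64)
    N, G = P.shape
    if N == 0:
        raise ValueError("no samples")
    if G < 2:
        raise ValueError("need at least two genomes")
    genomes = m.genomes
    K = P.T @ P
    prev = P.sum(axis=0)
    iu, ju = np.triu_indices(G, k=1)
    k = K[iu, ju].astype(float)
    n1, n2 = prev[iu].astype(float), prev[ju].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = n1 * n2 / N
        ratio = np.where(expected > 0, k / expected, 0.0)
    p = np.where(
        (n1 == 0) | (n2 == 0),
        1.0,
        hypergeom.sf(k - 1, N, n1.astype(int), n2.astype(int)),
    )
    p = np.clip(p, 0.0, 1.0)
    p_adj = bh_adjust(list(p)) if len(p) else []
    df = pd.DataFrame(
        {
            "genome_a": [genomes[i] for i in iu],
            "genome_b": [genomes[j] for j in ju],
            "k": k.astype(int),
            "n1": n1.astype(int),
            "n2": n2.astype(int),
            "N": N,
            "p": p,
            "p_adj": p_adj,
            "ratio": ratio,
        }
    )
    df["significant"] = (df["p_adj"] < alpha) & (df["ratio"] > 1.0)
    return df


def simple_cooccurrence(samples_a: set, samples_b: set) -> float:
    """|A ∩ B| / min(|A|, |B|).

    A genome found in every sample trivially scores 1.0 with everything,
    which is why the hypergeometric route is the focal one.
    """
    if not samples_a or not samples_b:
        raise ValueError("simple co-occurrence is undefined for empty sample sets")
    return len(samples_a & samples_b) / min(len(samples_a), len(samples_b))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def classify_fraction_enrichment(
    m: OccurrenceMatrix,
    small_upper_um: float = 3.0,
    lessfiltered_upper_um: float = 20.0,
    majority: float = 0.75,
) -> dict[str, str]:
    """Assign each genome to a size-fraction group.

    Samples are grouped by their upper filter bound: ``small`` when it is
    at most ``small_upper_um`` (free-living cells), ``less_filtered`` when
    it is at least ``lessfiltered_upper_um`` (particle-attached cells
    admitted); bounds in between belong to neither group. A genome joins a
    group when strictly more than ``majority`` of its occupied samples are
    in that group *and* its median abundance over occupied samples is
    highest in that group; otherwise it is unclassified.
    """
    group_of: dict[str, str | None] = {}
    for sample, (lo, hi) in m.sample_fractions.items():
        if hi <= small_upper_um:
            group_of[sample] = "small"
        elif hi >= lessfiltered_upper_um:
            group_of[sample] = "less_filtered"
        else:
            group_of[sample] = None

    out: dict[str, str] = {}
    for genome in m.genomes:
        occupied = [s for s in m.samples if m.presence.at[s, genome]]
        if not occupied:
            out[genome] = "unclassified"
            continue
        labels = [group_of.get(s) for s in occupied]
        verdict = "unclassified"
        for grp in ("small", "less_filtered"):
            share = sum(1 for g in labels if g == grp) / len(occupied)
            if share <= majority:
                continue
            med = {}
            for g2 in ("small", "less_filtered"):
                vals = [
                    m.abundance.at[s, genome]
                    for s, lab in zip(occupied, labels)
                    if lab == g2
                ]
                med[g2] = float(np.median(vals)) if vals else -np.inf
            other = "less_filtered" if grp == "small" else "small"
            if med[grp] > med[other]:
                verdict = grp
        out[genome] = verdict
    return out
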