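"""Putative HGT calling between genomes of different genera.

Two complementary routes are implemented:

* ``cluster_genes`` + ``call_rbh_events`` — the focal approach: greedy
  incremental clustering of protein-coding genes at >= 95% identity over
  >= 95% of both lengths, followed by reciprocal-closest-match calling
  within clusters, restricted to genome pairs whose taxonomies diverge at
  the genus level or broader.
* ``call_region_events`` — the sensitive region-network approach: tabular
  local-alignment hits (12-column outfmt-6 style) filtered at >= 500 bp and
  >= 95% identity are intersected with gene intervals; per genome pair and
  gene only the highest-bit-score hit survives.

In both routes, calls whose genes sit on contigs shorter than 5 kb are
removed *after* event calling. Events carry an identity bin (">=99" for
recent transfers, "95-99" for older ones) and the divergence level of the
genome pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .genome_io import CROSS_GENUS_LEVELS, divergence_level

BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[tuple[str, str, np.ndarray]]  # (genome, gene, uint8 seq)
    representative: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster without members")


@dataclass
class HgtEvent:
    genome_a: str
    genome_b: str
    gene_a: str
    gene_b: str
    identity: float
    identity_bin: str
    level: str
    method: str
    cluster_id: str | None = None
    tie_broken: bool = False
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError("HGT event within a single genome")
        if self.level not in CROSS_GENUS_LEVELS:
            raise ValueError(f"event at ineligible divergence level {self.level!r}")
        expected = ">=99" if self.identity >= 0.99 else "95-99"
        if self.identity_bin != expected:
            raise ValueError("identity_bin inconsistent with identity")


def identity_bin(identity: float) -> str:
    """">=99" for identity >= 0.99, else "95-99"."""
    return ">=99" if identity >= 0.99 else "95-99"


def _as_u8(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def pairwise_identity(seq_a, seq_b) -> float:
    """Fraction of matching positions between two equal-length sequences.

    This is 1 - hamming distance / length; sequences must be pre-aligned
    (or substitution-only, as in the synthetic generator).
    """
    a, b = _as_u8(seq_a), _as_u8(seq_b)
    if len(a) != len(b):
        raise ValueError(
            f"pairwise_identity needs equal lengths, got {len(a)} and {len(b)}"
        )
    if len(a) == 0:
        raise ValueError("empty sequences")
    return float((a == b).mean())


def _alignment_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Identity between possibly unequal-length sequences via global
    alignment edit distance (edlib), normalized by the longer length."""
    if len(a) == len(b):
        return pairwise_identity(a, b)
    res = edlib.align(a.tobytes().decode(), b.tobytes().decode(), mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def cluster_genes(
    genes: list[tuple[str, str, object]],
    identity_thresh: float = 0.95,
    length_ratio: float = 0.95,
    coverage: float = 0.95,
) -> list[GeneCluster]:
    """Greedy incremental clustering, longest sequence first.

    Each sequence joins the first existing cluster whose *representative*
    it matches at >= ``identity_thresh`` over >= ``coverage`` of both
    lengths with a length ratio >= ``length_ratio``; otherwise it founds a
    new cluster with itself as representative. Ties in the longest-first
    ordering are broken by (genome id, gene id) so the outcome does not
    depend on input order.
    """
    items = [(g, gid, _as_u8(seq)) for g, gid, seq in genes]
    for g, gid, seq in items:
        if len(seq) == 0:
            raise ValueError(f"empty sequence for {g}/{gid}")
    items.sort(key=lambda t: (-len(t[2]), t[0], t[1]))

    min_ratio = max(length_ratio, coverage)
    clusters: list[GeneCluster] = []
    # representatives grouped by length for a vectorized hamming pass
    rep_by_len: dict[int, tuple[list[int], list[np.ndarray]]] = {}

    for g, gid, seq in items:
        n = len(seq)
        best: int | None = None
        # equal-length representatives: single vectorized comparison
        if n in rep_by_len:
            idxs, seqs = rep_by_len[n]
            ident = (np.stack(seqs) == seq[None, :]).mean(axis=1)
            ok = np.nonzero(ident >= identity_thresh)[0]
            if ok.size:
                best = idxs[int(ok[0])]
        # unequal-length representatives within the admissible ratio
        for length, (idxs, seqs) in rep_by_len.items():
            if length == n:
                continue
            if min(length, n) / max(length, n) < min_ratio:
                continue
            for ci, rep in zip(idxs, seqs):
                if best is not None and ci >= best:
                    continue
                if _alignment_identity(seq, rep) >= identity_thresh:
                    best = ci
        if best is None:
            cid = len(clusters)
            clusters.append(
                GeneCluster(f"C{cid + 1:05d}", [(g, gid, seq)], (g, gid))
            )
            rep_by_len.setdefault(n, ([], []))[0].append(cid)
            rep_by_len[n][1].append(seq)
        else:
            clusters[best].members.append((g, gid, seq))
    return clusters


def call_rbh_events(
    clusters: list[GeneCluster],
    taxonomy: dict[str, tuple[str, ...]],
    gene_locations: dict[tuple[str, str], tuple[str, int]] | None = None,
    min_identity: float = 0.95,
    min_contig_bp: int = 5000,
) -> list[HgtEvent]:
    """Reciprocal-closest-match HGT calls within gene clusters.

    For every unordered genome pair (A, B) in a cluster whose taxonomies
    diverge at genus level or broader, gene a (in A) and gene b (in B)
    form an event iff each is the other's highest-identity partner in the
    opposite genome and their identity is >= ``min_identity``. Reciprocal
    ties are broken by lexicographic gene id and flagged. Events whose
    genes sit on contigs shorter than ``min_contig_bp`` are removed after
    calling; ``gene_locations`` maps (genome, gene) -> (contig, contig
    length) and may be omitted to skip the contig filter.
    """
    events: list[HgtEvent] = []
    for cluster in clusters:
        by_genome: dict[str, list[tuple[str, np.ndarray]]] = {}
        for g, gid, seq in cluster.members:
            if g not in taxonomy:
                raise KeyError(f"genome {g!r} absent from taxonomy")
            by_genome.setdefault(g, []).append((gid, seq))
        genomes = sorted(by_genome)
        for i, ga in enumerate(genomes):
            for gb in genomes[i + 1 :]:
                level = divergence_level(taxonomy[ga], taxonomy[gb])
                if level not in CROSS_GENUS_LEVELS:
                    continue
                a_genes = sorted(by_genome[ga])
                b_genes = sorted(by_genome[gb])
                ident = np.array(
                    [
                        [_alignment_identity(sa, sb) for _, sb in b_genes]
                        for _, sa in a_genes
                    ]
                )
                best_b = ident.argmax(axis=1)  # argmax -> first = lexicographic
                best_a = ident.argmax(axis=0)
                for ai, (gid_a, _) in enumerate(a_genes):
                    bi = int(best_b[ai])
                    if int(best_a[bi]) != ai:
                        continue
                    identity = float(ident[ai, bi])
                    if identity < min_identity:
                        continue
                    tie = (
                        int((ident[ai] == identity).sum()) > 1
                        or int((ident[:, bi] == identity).sum()) > 1
                    )
                    events.append(
                        HgtEvent(
                            genome_a=ga,
                            genome_b=gb,
                            gene_a=gid_a,
                            gene_b=b_genes[bi][0],
                            identity=identity,
                            identity_bin=identity_bin(identity),
                            level=level,
                            method="cluster_rbh",
                            cluster_id=cluster.cluster_id,
                            tie_broken=tie,
                        )
                    )
    if gene_locations is not None:
        events = [
            e
            for e in events
            if gene_locations[(e.genome_a, e.gene_a)][1] >= min_contig_bp
            and gene_locations[(e.genome_b, e.gene_b)][1] >= min_contig_bp
        ]
    return events


def read_blast_tsv(path_or_buf) -> pd.DataFrame:
    """Read 12-column tabular local-alignment hits (BLAST outfmt 6).

    Sequence ids follow the ``genome|contig`` convention.
    """
    df = pd.read_csv(path_or_buf, sep="\t", names=BLAST_COLUMNS, comment="#")
    return df


def _split_seqid(seqid: str) -> tuple[str, str]:
    parts = str(seqid).split("|")
    if len(parts) < 2:
        raise ValueError(f"seqid {seqid!r} does not follow genome|contig")
    return parts[0], parts[1]


def call_region_events(
    hits: pd.DataFrame,
    gene_inventory: dict[str, dict],
    taxonomy: dict[str, tuple[str, ...]],
    min_len_bp: int = 500,
    min_identity: float = 0.95,
    min_contig_bp: int = 5000,
) -> list[HgtEvent]:
    """Region-network HGT flags from tabular local-alignment hits.

    Hits of length >= ``min_len_bp`` and identity >= ``min_identity``
    between different-genus genomes are intersected with gene intervals on
    their contigs (an overlap of >= 1 bp flags the gene; 0-based half-open
    arithmetic internally). Where several retained hits overlap the same
    gene for the same genome pair, only the highest-bit-score hit is kept.
    Flags on contigs shorter than ``min_contig_bp`` are dropped after
    calling. ``gene_inventory`` maps genome -> {"contigs": {...},
    "genes": {...}} as produced by the generator or the GFF3 reader.

    One event is emitted per (genome pair, flagged gene); the partner
    coordinates are recorded as a region token.
    """
    hits = hits.copy()
    hits["pident_frac"] = hits["pident"] / 100.0
    keep = (hits["length"] >= min_len_bp) & (hits["pident_frac"] >= min_identity)
    hits = hits[keep]

    # index genes by (genome, contig)
    genes_by_contig: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    contig_len: dict[tuple[str, str], int] = {}
    for genome, inv in gene_inventory.items():
        for contig, length in inv["contigs"].items():
            contig_len[(genome, contig)] = length
        for gid, (contig, start, end, _strand) in inv["genes"].items():
            genes_by_contig.setdefault((genome, contig), []).append(
                (gid, start - 1, end)  # half-open
            )

    best: dict[tuple, tuple[float, dict]] = {}
    for row in hits.itertuples(index=False):
        q_genome, q_contig = _split_seqid(row.qseqid)
        s_genome, s_contig = _split_seqid(row.sseqid)
        if q_genome == s_genome:
            continue
        level = divergence_level(taxonomy[q_genome], taxonomy[s_genome])
        if level not in CROSS_GENUS_LEVELS:
            continue
        sides = (
            (q_genome, q_contig, int(row.qstart), int(row.qend), s_genome,
             s_contig, int(row.sstart), int(row.send)),
            (s_genome, s_contig, int(row.sstart), int(row.send), q_genome,
             q_contig, int(row.qstart), int(row.qend)),
        )
        for genome, contig, start, end, other, o_contig, o_start, o_end in sides:
            lo, hi = min(start, end), max(start, end)
            clen = contig_len.get((genome, contig))
            if clen is None:
                raise KeyError(f"unknown contig {genome}|{contig}")
            if not 1 <= lo <= hi <= clen:
                raise ValueError(
                    f"hit coordinates [{lo}, {hi}] outside contig {genome}|{contig}"
                )
            h0, h1 = lo - 1, hi  # half-open
            for gid, g0, g1 in genes_by_contig.get((genome, contig), []):
                if min(h1, g1) - max(h0, g0) >= 1:
                    pair = frozenset((genome, other))
                    key = (pair, genome, gid)
                    rec = dict(
                        genome=genome,
                        other=other,
                        gene=gid,
                        contig=contig,
                        identity=float(row.pident_frac),
                        level=level,
                        region=f"{o_contig}:{min(o_start, o_end)}-{max(o_start, o_end)}",
                        bitscore=float(row.bitscore),
                    )
                    if key not in best or best[key][0] < rec["bitscore"]:
                        best[key] = (rec["bitscore"], rec)

    events = []
    for _, rec in sorted(best.values(), key=lambda t: (t[1]["genome"], t[1]["gene"], t[1]["other"])):
        if contig_len[(rec["genome"], rec["contig"])] < min_contig_bp:
            continue
        events.append(
            HgtEvent(
                genome_a=rec["genome"],
                genome_b=rec["other"],
                gene_a=rec["gene"],
                gene_b=rec["region"],
                identity=rec["identity"],
                identity_bin=identity_bin(rec["identity"]),
                level=rec["level"],
                method="region_network",
                bitscore=rec["bitscore"],
            )
        )
    return events


def level_rates(
    events: list[HgtEvent], pair_levels: dict[frozenset, str] | list[str]
) -> pd.DataFrame:
    """Per-level event counts normalized by the number of genome
    comparisons at that level.

    ``pair_levels`` gives the divergence level of every genome pair in the
    analysis (a mapping pair -> level, or simply the list of levels).
    Returns a DataFrame with event count, pair count, rate = count/pairs
    and the normalized share rate / sum(rates). With zero events all
    shares are reported as 0 and the ``no_events`` flag is set.
    """
    levels = (
        list(pair_levels.values())
        if isinstance(pair_levels, dict)
        else list(pair_levels)
    )
    pair_counts = pd.Series(levels).value_counts()
    ev_counts: dict[str, int] = {}
    for e in events:
        ev_counts[e.level] = ev_counts.get(e.level, 0) + 1
    for level, k in ev_counts.items():
        if pair_counts.get(level, 0) == 0:
            raise ValueError(f"{k} events at level {level!r} but zero genome pairs")
    order = [lv for lv in ("genus", "family", "order", "class", "phylum", "domain") if lv in pair_counts.index]
    rows = []
    for lv in order:
        n_pairs = int(pair_counts[lv])
        n_ev = ev_counts.get(lv, 0)
        rows.append([lv, n_ev, n_pairs, n_ev / n_pairs])
    df = pd.DataFrame(rows, columns=["level", "events", "pairs", "rate"])
    total = df["rate"].sum()
    df["share"] = df["rate"] / total if total > 0 else 0.0
    df.attrs["no_events"] = total == 0
    return df


def events_to_frame(events: list[HgtEvent]) -> pd.DataFrame:
    rows = [
        dict(
            genome_a=e.genome_a,
            genome_b=e.genome_b,
            gene_a=e.gene_a,
            gene_b=e.gene_b,
            identity=e.identity,
            identity_bin=e.identity_bin,
            level=e.level,
            method=e.method,
            cluster_id=e.cluster_id or "",
            tie_broken=int(e.tie_broken),
        )
        for e in events
    ]
    cols = [
        "genome_a", "genome_b", "gene_a", "gene_b", "identity",
        "identity_bin", "level", "method", "cluster_id", "tie_broken",
    ]
    return pd.DataFrame(rows, columns=cols)
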