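import numpy as np
import pandas as pd
import pytest

from hgtcooc.genome_io import RANKS
from hgtcooc.hgt_detect import (
    BLAST_COLUMNS,
    call_rbh_events,
    call_region_events,
    cluster_genes,
    level_rates,
    pairwise_identity,
)

from conftest import make_taxonomy

TAX = {
    "A": make_taxonomy(genus="gA", species="sA"),
    "B": make_taxonomy(genus="gB", species="sB"),
    "C": make_taxonomy(genus="gA", species="sC"),  # same genus as A
    "D": make_taxonomy(family="f2", genus="gD", species="sD"),
}


def seq_with_identity(base: str, identity: float) -> str:
    """Mutate a fraction of positions, cycling each to the next base."""
    n_sub = round((1 - identity) * len(base))
    order = "ACGT"
    out = list(base)
    for i in range(n_sub):
        out[i] = order[(order.index(out[i]) + 1) % 4]
    return "".join(out)


@pytest.fixture
def base300():
    rng = np.random.default_rng(42)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, 300))


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("AAAA", "AAAT", 0.75), ("ACGT", "ACGT", 1.0), ("ACGT", "TGCA", 0.0)],
    )
    def test_hamming_fraction(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACGT", "ACG")


class TestClusterGenes:
    def test_identical_genes_co_cluster(self, base300):
        clusters = cluster_genes([("A", "a1", base300), ("B", "b1", base300)])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 2

    def test_length_ratio_forbids_co_clustering(self, base300):
        short = base300[:200]
        clusters = cluster_genes([("A", "a1", base300), ("B", "b1", short)])
        assert len(clusters) == 2

    def test_three_gene_partition_matches_membership_rule(self, base300):
        """Identities AB=0.97, AC=BC<<0.95 must yield {A,B},{C}; the oracle
        checks every pairwise identity directly."""
        a = base300
        b = seq_with_identity(a, 0.97)
        c = seq_with_identity(a, 0.40)
        assert pairwise_identity(a, b) >= 0.95
        assert pairwise_identity(a, c) < 0.95
        assert pairwise_identity(b, c) < 0.95
        clusters = cluster_genes(
            [("A", "a1", a), ("B", "b1", b), ("C", "c1", c)]
        )
        parts = sorted(
            sorted(m[1] for m in cl.members) for cl in clusters
        )
        assert parts == [["a1", "b1"], ["c1"]]

    def test_membership_invariant(self, community):
        """Every member matches its representative at >= 95% identity
        (equal-length synthetic genes)."""
        genomes = community["genomes"]
        genes = [
            (g, gid, s) for g, seqs in genomes.items() for gid, s in seqs.items()
        ][:200]
        for cl in cluster_genes(genes):
            rep = next(
                s for g, gid, s in cl.members if (g, gid) == cl.representative
            )
            for _g, _gid, s in cl.members:
                assert pairwise_identity(s, rep) >= 0.95

    def test_empty_input(self):
        assert cluster_genes([]) == []


class TestCallRbh:
    def test_single_cross_genus_pair(self, base300):
        b = seq_with_identity(base300, 0.96)
        clusters = cluster_genes([("A", "a1", base300), ("B", "b1", b)])
        locs = {("A", "a1"): ("c1", 6000), ("B", "b1"): ("c2", 6000)}
        events = call_rbh_events(clusters, TAX, locs)
        assert len(events) == 1
        ev = events[0]
        assert {ev.genome_a, ev.genome_b} == {"A", "B"}
        assert ev.identity_bin == "95-99"
        assert ev.level == "genus"

    def test_same_genus_pair_excluded(self, base300):
        b = seq_with_identity(base300, 0.96)
        clusters = cluster_genes([("A", "a1", base300), ("C", "c1", b)])
        assert call_rbh_events(clusters, TAX) == []

    def test_reciprocal_best_only(self, base300):
        """a1-b1 at 0.99 and a2-b1 at 0.97: only (a1, b1) is reciprocal."""
        a1 = base300
        b1 = seq_with_identity(base300, 0.99)
        a2 = seq_with_identity(base300, 0.97)

        # brute-force oracle over all cross-genome gene pairs
        pool = {("A", "a1"): a1, ("A", "a2"): a2, ("B", "b1"): b1}
        def best_partner(src, other_genome):
            cands = [
                (k, pairwise_identity(pool[src], v))
                for k, v in pool.items()
                if k[0] == other_genome
            ]
            return max(cands, key=lambda t: (t[1], [-ord(c) for c in t[0][1]]))[0]

        assert best_partner(("A", "a1"), "B") == ("B", "b1")
        assert best_partner(("B", "b1"), "A") == ("A", "a1")

        clusters = cluster_genes(
            [("A", "a1", a1), ("A", "a2", a2), ("B", "b1", b1)]
        )
        events = call_rbh_events(clusters, TAX)
        assert len(events) == 1
        assert (events[0].gene_a, events[0].gene_b) == ("a1", "b1")
        assert events[0].identity_bin == ">=99"

    def test_contig_filter_applied_after_calling(self, base300):
        b = seq_with_identity(base300, 0.99)
        clusters = cluster_genes([("A", "a1", base300), ("B", "b1", b)])
        locs = {("A", "a1"): ("c1", 4999), ("B", "b1"): ("c2", 6000)}
        assert call_rbh_events(clusters, TAX, locs) == []

    def test_invariant_to_input_order(self, base300):
        b = seq_with_identity(base300, 0.99)
        c = seq_with_identity(base300, 0.97)
        genes = [("A", "a1", base300), ("B", "b1", b), ("D", "d1", c)]
        ev1 = call_rbh_events(cluster_genes(genes), TAX)
        ev2 = call_rbh_events(cluster_genes(genes[::-1]), TAX)
        key = lambda e: (e.genome_a, e.genome_b, e.gene_a, e.gene_b)
        assert sorted(map(key, ev1)) == sorted(map(key, ev2))

    def test_missing_taxonomy_raises(self, base300):
        clusters = cluster_genes(
            [("A", "a1", base300), ("Z", "z1", seq_with_identity(base300, 0.99))]
        )
        with pytest.raises(KeyError):
            call_rbh_events(clusters, TAX)


def _hit(qseqid, sseqid, pident, length, qstart, qend, sstart, send, bitscore):
    return dict(
        qseqid=qseqid, sseqid=sseqid, pident=pident, length=length,
        mismatch=0, gapopen=0, qstart=qstart, qend=qend, sstart=sstart,
        send=send, evalue=1e-50, bitscore=bitscore,
    )


INVENTORY = {
    "A": {
        "contigs": {"c1": 6000},
        "genes": {"a1": ("c1", 1001, 1900, "+")},
    },
    "B": {
        "contigs": {"c2": 6000},
        "genes": {"b1": ("c2", 2001, 2900, "+")},
    },
}


class TestCallRegions:
    def test_overlapping_hit_flags_gene(self):
        hits = pd.DataFrame(
            [_hit("A|c1", "B|c2", 96.0, 600, 1600, 2199, 2500, 3099, 800)],
            columns=BLAST_COLUMNS,
        )
        events = call_region_events(hits, INVENTORY, TAX)
        flagged = {(e.genome_a, e.gene_a) for e in events}
        assert ("A", "a1") in flagged  # 300 bp overlap with a1
        assert ("B", "b1") in flagged

    def test_short_hit_discarded(self):
        hits = pd.DataFrame(
            [_hit("A|c1", "B|c2", 99.0, 499, 1600, 2098, 2500, 2998, 900)],
            columns=BLAST_COLUMNS,
        )
        assert call_region_events(hits, INVENTORY, TAX) == []

    def test_highest_bitscore_hit_retained(self):
        hits = pd.DataFrame(
            [
                _hit("A|c1", "B|c2", 96.0, 600, 1200, 1799, 2500, 3099, 800),
                _hit("A|c1", "B|c2", 97.0, 600, 1300, 1899, 2600, 3199, 600),
            ],
            columns=BLAST_COLUMNS,
        )
        events = call_region_events(hits, INVENTORY, TAX)
        a_events = [e for e in events if e.genome_a == "A" and e.gene_a == "a1"]
        assert len(a_events) == 1
        assert a_events[0].bitscore == 800

    def test_out_of_bounds_coordinates_rejected(self):
        hits = pd.DataFrame(
            [_hit("A|c1", "B|c2", 96.0, 600, 5800, 6399, 2500, 3099, 800)],
            columns=BLAST_COLUMNS,
        )
        with pytest.raises(ValueError):
            call_region_events(hits, INVENTORY, TAX)

    def test_region_approach_covers_rbh_calls(self, community):
        """Hits generated from the planted transfers themselves flag every
        gene that the cluster-RBH route calls."""
        from hgtcooc.hgt_detect import cluster_genes, call_rbh_events

        genomes = community["genomes"]
        inv = community["inventories"]
        tax = community["taxonomy"]
        genes = [
            (g, gid, s) for g, seqs in genomes.items() for gid, s in seqs.items()
        ]
        locs = {
            (g, gid): (c, inv[g]["contigs"][c])
            for g in inv
            for gid, (c, *_r) in inv[g]["genes"].items()
        }
        rbh = call_rbh_events(cluster_genes(genes), tax, locs)

        rows = []
        for d, r, dg, rg, _t, realized in community["gt"].planted_events:
            cd, sd, ed, _ = inv[d]["genes"][dg]
            cr, sr, er, _ = inv[r]["genes"][rg]
            rows.append(
                _hit(
                    f"{d}|{cd}", f"{r}|{cr}", realized * 100, ed - sd + 1,
                    sd, ed, sr, er, 1000.0,
                )
            )
        hits = pd.DataFrame(rows, columns=BLAST_COLUMNS)
        region = call_region_events(hits, inv, tax)
        flagged = {(e.genome_a, e.gene_a) for e in region}
        for e in rbh:
            assert (e.genome_a, e.gene_a) in flagged
            assert (e.genome_b, e.gene_b) in flagged


class TestLevelRates:
    def test_hand_computed_rates_and_shares(self, base300):
        b = seq_with_identity(base300, 0.99)

        def ev(ga, gb, level):
            from hgtcooc.hgt_detect import HgtEvent

            return HgtEvent(
                genome_a=ga, genome_b=gb, gene_a="x", gene_b="y",
                identity=0.99, identity_bin=">=99", level=level,
                method="cluster_rbh",
            )

        events = [ev("A", "B", "genus"), ev("A", "D", "genus"), ev("B", "D", "family")]
        pair_levels = ["genus"] * 4 + ["family"] * 8
        df = level_rates(events, pair_levels).set_index("level")
        assert df.loc["genus", "rate"] == pytest.approx(0.5)
        assert df.loc["family", "rate"] == pytest.approx(0.125)
        assert df.loc["genus", "share"] == pytest.approx(0.8)
        assert df.loc["family", "share"] == pytest.approx(0.2)

    def test_no_events_flagged(self):
        df = level_rates([], ["genus"] * 3)
        assert (df["share"] == 0).all()
        assert df.attrs["no_events"]

    def test_single_level_share_is_one(self, base300):
        from hgtcooc.hgt_detect import HgtEvent

        ev = HgtEvent(
            genome_a="A", genome_b="B", gene_a="x", gene_b="y",
            identity=0.99, identity_bin=">=99", level="genus",
            method="cluster_rbh",
        )
        df = level_rates([ev], ["genus", "genus"])
        assert df["share"].iloc[0] == pytest.approx(1.0)

    def test_events_without_pairs_inconsistent(self):
        from hgtcooc.hgt_detect import HgtEvent

        ev = HgtEvent(
            genome_a="A", genome_b="B", gene_a="x", gene_b="y",
            identity=0.99, identity_bin=">=99", level="domain",
            method="cluster_rbh",
        )
        with pytest.raises(ValueError):
            level_rates([ev], ["genus"])
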