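"""Synthetic marine-community generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a nested seven-rank taxonomy with a consistent phylogeny, genomes
whose protein-coding genes are unrelated between genera except for planted
horizontal transfers, and niche-structured sample occupancy in which
genomes with similar niche preferences co-occur across samples.

Planted transfers copy a donor gene into a recipient genome of a different
genus and then apply per-site substitutions so that the realized nucleotide
identity matches a target drawn from ``hgt_identity_range``. Which
cross-genus pairs receive a transfer follows a logistic function of niche
overlap (weight ``beta_cooc``) and patristic distance (weight
``-beta_phylo``), so the same ecological/phylogenetic effects the pair
model estimates are present in the ground truth.

Everything is driven by a single integer seed; identical configurations
produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import RANKS, divergence_level, patristic_distances

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic community.

    Defaults describe a desk-scale community: 50 genomes spread over a
    nested taxonomy with 20 species, 200 samples, 20 genes of 900 bp per
    genome on 10 kb contigs, and 20 planted recent transfers (identity in
    [0.99, 1.0]). ``beta_cooc``/``beta_phylo`` are the log-odds effects of
    niche overlap and patristic distance on the probability that a
    cross-genus pair receives a planted transfer.
    """

    n_genomes: int = 50
    n_samples: int = 200
    ranks_per_level: tuple[int, ...] = (1, 2, 3, 4, 6, 10, 20)
    genes_per_genome: int = 20
    gene_length_bp: int = 900
    contig_length_bp: int = 10_000
    n_planted_hgt: int = 20
    hgt_identity_range: tuple[float, float] = (0.99, 1.0)
    niche_dims: int = 2
    env_variable_names: tuple[str, ...] = ("temperature", "salinity", "oxygen")
    beta_cooc: float = 2.0
    beta_phylo: float = 1.5
    fraction_labels: tuple[tuple[float, float], ...] = (
        (0.22, 3.0),
        (0.22, 200.0),
    )
    seed: int = 1

    def __post_init__(self) -> None:
        counts = (
            self.n_genomes,
            self.n_samples + 1,  # zero samples allowed (degenerate case)
            self.genes_per_genome,
            self.gene_length_bp,
            self.contig_length_bp,
            self.niche_dims,
        )
        if any(c <= 0 for c in counts):
            raise ConfigError("all counts must be positive")
        if self.n_planted_hgt < 0 or self.n_samples < 0:
            raise ConfigError("negative counts are not allowed")
        if len(self.ranks_per_level) != len(RANKS):
            raise ConfigError(f"ranks_per_level needs {len(RANKS)} entries")
        if any(c <= 0 for c in self.ranks_per_level):
            raise ConfigError("rank counts must be positive")
        for parent, child in zip(self.ranks_per_level, self.ranks_per_level[1:]):
            if child < parent:
                raise ConfigError(
                    "rank counts cannot nest: each level needs at least as "
                    "many taxa as its parent level"
                )
        lo, hi = self.hgt_identity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("hgt_identity_range must satisfy 0 <= lo <= hi <= 1")
        if self.gene_length_bp > self.contig_length_bp:
            raise ConfigError("genes cannot be longer than contigs")


@dataclass
class GroundTruth:
    """Record of everything the generator planted.

    ``planted_events`` rows are (donor genome, recipient genome, donor gene
    id, recipient gene id, target identity, realized identity).
    """

    planted_events: list[tuple[str, str, str, str, float, float]]
    niche_centers: dict[str, np.ndarray]
    true_pair_effects: dict[str, float] = field(default_factory=dict)
    #: per-genome size-fraction habitat preference
    #: ("small" | "less_filtered" | None)
    fraction_preference: dict[str, str | None] = field(default_factory=dict)

    @property
    def planted_pairs(self) -> set[frozenset[str]]:
        return {frozenset((d, r)) for d, r, *_ in self.planted_events}


# ---------------------------------------------------------------------------
# taxonomy and tree


def _rank_name(level: int, index: int) -> str:
    return f"{RANKS[level][0]}{index + 1:02d}"


def simulate_taxonomy_and_tree(cfg: SimConfig) -> tuple[pd.DataFrame, str]:
    """Nested 7-rank taxonomy and a consistent ultrametric-ish phylogeny.

    Children at each level are distributed round-robin over the taxa of the
    level above, so every parent taxon has at least one child and the
    hierarchy nests. The tree follows the taxonomy topology with positive
    branch lengths that shrink geometrically with depth, so patristic
    distance is in expectation smaller within lower ranks.

    Returns (taxonomy table with columns genome + the 7 ranks, newick text).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.ranks_per_level

    # parent index of each taxon, per level
    parents: list[np.ndarray] = [np.zeros(counts[0], dtype=int)]
    for level in range(1, len(counts)):
        parents.append(np.arange(counts[level]) % counts[level - 1])

    # lineage of every species: indices at each level
    lineages = []
    for sp in range(counts[-1]):
        idx = sp
        lineage = [0] * len(counts)
        for level in range(len(counts) - 1, -1, -1):
            lineage[level] = idx
            idx = parents[level][idx] if level > 0 else 0
        lineages.append(lineage)

    genome_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genomes)]
    species_of = [i % counts[-1] for i in range(cfg.n_genomes)]

    rows = []
    for gid, sp in zip(genome_ids, species_of):
        rows.append(
            [gid] + [_rank_name(level, lineages[sp][level]) for level in range(7)]
        )
    taxonomy = pd.DataFrame(rows, columns=["genome"] + list(RANKS))

    # Build the tree recursively over the taxonomy hierarchy. Branch length
    # at depth k ~ U(0.5, 1.5) * 2^-k: deeper splits are shorter, so
    # within-genus tips are closer than cross-phylum tips in expectation.
    children: list[dict[int, list[int]]] = []
    for level in range(1, len(counts)):
        mapping: dict[int, list[int]] = {}
        for child, parent in enumerate(parents[level]):
            mapping.setdefault(int(parent), []).append(child)
        children.append(mapping)
    tips_of_species: dict[int, list[str]] = {}
    for gid, sp in zip(genome_ids, species_of):
        tips_of_species.setdefault(sp, []).append(gid)

    def blen(depth: int) -> float:
        return float(rng.uniform(0.5, 1.5) * 2.0 ** (-depth))

    def newick_of(level: int, index: int) -> str:
        if level == len(counts) - 1:  # species: attach genome tips
            tips = tips_of_species.get(index, [])
            subs = [f"{t}:{blen(level + 1):.6f}" for t in tips]
        else:
            subs = [
                f"{newick_of(level + 1, c)}:{blen(level + 1):.6f}"
                for c in children[level].get(index, [])
            ]
        if not subs:
            return ""
        if len(subs) == 1:
            # collapse unary internal nodes by folding the branch upward
            return subs[0].rsplit(":", 1)[0] + f":{float(subs[0].rsplit(':', 1)[1]):.6f}"
        return "(" + ",".join(subs) + ")"

    if cfg.n_genomes == 1:
        newick = f"({genome_ids[0]}:0.000000);"
    else:
        top = [
            f"{newick_of(1, c)}:{blen(1):.6f}" for c in children[0].get(0, [])
        ]
        top = [t for t in top if not t.startswith(":")]
        newick = "(" + ",".join(top) + ");" if len(top) > 1 else f"({top[0]});"
    return taxonomy, newick


# ---------------------------------------------------------------------------
# genomes and planted transfers


def _random_gene(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_to_identity(
    rng: np.random.Generator, seq: np.ndarray, target: float
) -> tuple[np.ndarray, float]:
    """Substitute sites so that identity to ``seq`` is as close as possible
    to ``target`` (substitution-only, so hamming identity is exact)."""
    length = len(seq)
    n_sub = int(round((1.0 - target) * length))
    out = seq.copy()
    if n_sub:
        pos = rng.choice(length, size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub)
        idx = np.searchsorted(_BASES, out[pos])
        out[pos] = _BASES[(idx + shift) % 4]
    return out, 1.0 - n_sub / length


def _genes_per_contig(cfg: SimConfig) -> int:
    spacing = 100
    return max(1, (cfg.contig_length_bp - spacing) // (cfg.gene_length_bp + spacing))


def simulate_genomes(
    cfg: SimConfig,
    taxonomy: pd.DataFrame,
    newick: str,
    verify_background: bool = True,
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, dict], GroundTruth]:
    """Gene inventories with planted cross-genus transfers.

    Background genes are i.i.d. uniform nucleotides, so cross-genus
    background identity sits near 25% — far below any calling threshold —
    which is verified post hoc when ``verify_background`` is set.

    Returns (genome -> {gene id -> uint8 sequence},
    genome -> gene coordinate inventory, GroundTruth).
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    genome_ids = list(taxonomy["genome"])
    tax = {
        row["genome"]: tuple(row[r] for r in RANKS)
        for _, row in taxonomy.iterrows()
    }

    # niche centers: genus-level centers plus per-genome jitter, so niche
    # similarity correlates with (but is not determined by) phylogeny
    genus_of = {g: tax[g][5] for g in genome_ids}
    genus_centers = {
        gen: rng.normal(0.0, 1.0, size=cfg.niche_dims)
        for gen in sorted(set(genus_of.values()))
    }
    niche_centers = {
        g: genus_centers[genus_of[g]] + rng.normal(0.0, 0.4, size=cfg.niche_dims)
        for g in genome_ids
    }

    # size-fraction habitat preference: most genomes are neutral, a quarter
    # prefer the small (free-living) fraction and a few the less-filtered
    # (particle-attached) one — roughly the split seen in ocean MAG surveys
    pref_draw = rng.random(len(genome_ids))
    fraction_preference: dict[str, str | None] = {}
    for g, u in zip(genome_ids, pref_draw):
        if u < 0.25:
            fraction_preference[g] = "small"
        elif u < 0.37:
            fraction_preference[g] = "less_filtered"
        else:
            fraction_preference[g] = None

    # background genes
    genomes: dict[str, dict[str, np.ndarray]] = {}
    per_contig = _genes_per_contig(cfg)
    inventories: dict[str, dict] = {}
    for g in genome_ids:
        seqs = {}
        genes = {}
        n_contigs = math.ceil(cfg.genes_per_genome / per_contig)
        for k in range(cfg.genes_per_genome):
            gene_id = f"{g}_g{k + 1:03d}"
            seqs[gene_id] = _random_gene(rng, cfg.gene_length_bp)
            contig = f"{g}_c{k // per_contig + 1:02d}"
            slot = k % per_contig
            start = 100 + slot * (cfg.gene_length_bp + 100) + 1
            genes[gene_id] = (contig, start, start + cfg.gene_length_bp - 1, "+")
        contigs = {
            f"{g}_c{i + 1:02d}": cfg.contig_length_bp for i in range(n_contigs)
        }
        genomes[g] = seqs
        inventories[g] = {"contigs": contigs, "genes": genes}

    # candidate cross-genus pairs, weighted by niche overlap and phylogeny
    events: list[tuple[str, str, str, str, float, float]] = []
    effects = {"beta_cooc": cfg.beta_cooc, "beta_phylo": cfg.beta_phylo}
    if cfg.n_planted_hgt > 0:
        pairs = [
            (a, b)
            for i, a in enumerate(genome_ids)
            for b in genome_ids[i + 1 :]
            if divergence_level(tax[a], tax[b]) != "species"
            and divergence_level(tax[a], tax[b]) != "identical"
        ]
        if cfg.n_planted_hgt > len(pairs):
            raise ConfigError(
                f"n_planted_hgt={cfg.n_planted_hgt} exceeds the "
                f"{len(pairs)} available cross-genus pairs"
            )
        dist = patristic_distances(newick, genome_ids)
        dvals = np.array([dist.loc[a, b] for a, b in pairs])
        sq = np.array(
            [
                float(np.sum((niche_centers[a] - niche_centers[b]) ** 2))
                for a, b in pairs
            ]
        )

        def _z(x: np.ndarray) -> np.ndarray:
            s = x.std()
            return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

        # niche overlap = standardized negative squared niche distance;
        # both predictors are z-scored so the beta weights are comparable
        overlap = _z(-sq)
        dnorm = _z(dvals)
        logit = cfg.beta_cooc * overlap - cfg.beta_phylo * dnorm
        # calibrate the intercept so per-pair inclusion probabilities
        # sum to the requested event count: pairs then sit on the steep
        # part of the logistic rather than its saturated top
        lo_b, hi_b = -50.0, 50.0
        for _ in range(200):
            b0 = (lo_b + hi_b) / 2
            total = float(np.sum(1.0 / (1.0 + np.exp(-(b0 + logit)))))
            if total > cfg.n_planted_hgt:
                hi_b = b0
            else:
                lo_b = b0
        w = 1.0 / (1.0 + np.exp(-(b0 + logit)))
        effects["intercept"] = float(b0)
        chosen = rng.choice(
            len(pairs), size=cfg.n_planted_hgt, replace=False, p=w / w.sum()
        )
        used_genes: set[tuple[str, str]] = set()
        lo, hi = cfg.hgt_identity_range
        for idx in sorted(int(c) for c in chosen):
            donor, recipient = pairs[idx]
            donor_gene = next(
                gid for gid in genomes[donor] if (donor, gid) not in used_genes
            )
            recip_gene = next(
                gid
                for gid in genomes[recipient]
                if (recipient, gid) not in used_genes
            )
            used_genes.add((donor, donor_gene))
            used_genes.add((recipient, recip_gene))
            target = float(rng.uniform(lo, hi))
            mutated, realized = _mutate_to_identity(
                rng, genomes[donor][donor_gene], target
            )
            genomes[recipient][recip_gene] = mutated
            events.append(
                (donor, recipient, donor_gene, recip_gene, target, realized)
            )

    gt = GroundTruth(
        planted_events=events,
        niche_centers=niche_centers,
        true_pair_effects=effects,
        fraction_preference=fraction_preference,
    )
    if verify_background:
        _verify_background_identity(genomes, tax, gt)
    return genomes, inventories, gt


def _verify_background_identity(
    genomes: dict[str, dict[str, np.ndarray]],
    tax: dict[str, tuple[str, ...]],
    gt: GroundTruth,
    ceiling: float = 0.90,
) -> None:
    """Assert that no non-planted cross-genus gene pair reaches ``ceiling``
    identity. Vectorized hamming over the stacked gene matrix."""
    ids = [(g, gid) for g in sorted(genomes) for gid in genomes[g]]
    lengths = {len(s) for seqs in genomes.values() for s in seqs.values()}
    if len(lengths) != 1:
        return  # mixed lengths cannot arise from one config
    mat = np.stack([genomes[g][gid] for g, gid in ids])
    genome_idx = np.array(
        [list(sorted(genomes)).index(g) for g, _ in ids], dtype=int
    )
    planted = {
        frozenset(((d, dg), (r, rg))) for d, r, dg, rg, _, _ in gt.planted_events
    }
    length = mat.shape[1]
    chunk = 128
    for i0 in range(0, len(ids), chunk):
        block = mat[i0 : i0 + chunk]
        matches = (block[:, None, :] == mat[None, :, :]).sum(axis=2)
        ident = matches / length
        hits = np.argwhere(ident >= ceiling)
        for bi, j in hits:
            i = i0 + int(bi)
            j = int(j)
            if i >= j:
                continue
            ga, gida = ids[i]
            gb, gidb = ids[j]
            if ga == gb:
                continue
            if genome_idx[i] == genome_idx[j]:
                continue
            if tax[ga][5] == tax[gb][5]:
                continue  # same genus: outside the detector's scope
            if frozenset(((ga, gida), (gb, gidb))) in planted:
                continue
            raise AssertionError(
                f"background identity {ident[bi, j]:.3f} between "
                f"{ga}/{gida} and {gb}/{gidb} reaches {ceiling}"
            )


# ---------------------------------------------------------------------------
# occupancy and environment


def simulate_occupancy(
    cfg: SimConfig, gt: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample occupancy with niche structure, plus sample metadata.

    Each sample carries a latent niche-space position; a genome's presence
    probability decays with the squared distance between its niche center
    and that position, so genomes with similar niches co-occur. Breadth of
    coverage is drawn from two beta distributions — present-intent
    Beta(6, 2.5), absent-intent Beta(1.3, 10) — so values straddle the
    0.30 presence threshold on both sides. RPKM is positive for
    present-intent cells.

    Returns (coverage table: sample, genome, breadth, rpkm;
    sample metadata: sample, filter bounds, one column per variable).
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    genome_ids = sorted(gt.niche_centers)
    env_cols = list(cfg.env_variable_names)
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    meta_rows = []
    cov_rows = []
    centers = np.stack([gt.niche_centers[g] for g in genome_ids]) if genome_ids else None
    prefs = [gt.fraction_preference.get(g) for g in genome_ids]
    # each environmental variable reads the niche plane at its own angle,
    # so variables are correlated but not redundant
    if cfg.niche_dims >= 2:
        loadings = [
            (math.cos(math.pi * k / max(1, len(env_cols))),
             math.sin(math.pi * k / max(1, len(env_cols))))
            for k in range(len(env_cols))
        ]
    else:
        loadings = [(1.0, 0.0)] * len(env_cols)
    for si, sample in enumerate(sample_ids):
        z = rng.normal(0.0, 1.0, size=cfg.niche_dims)
        env = [
            float(
                a * z[0]
                + (b * z[1] if cfg.niche_dims >= 2 else 0.0)
                + rng.normal(0.0, 0.3)
            )
            for a, b in loadings
        ]
        lower, upper = cfg.fraction_labels[si % len(cfg.fraction_labels)]
        meta_rows.append([sample, lower, upper] + env)
        if upper <= 3.0:
            group = "small"
        elif upper >= 20.0:
            group = "less_filtered"
        else:
            group = None

        # habitat-preferring genomes are shifted toward samples of their
        # fraction group and are more abundant there
        sq = np.sum((centers - z[None, :]) ** 2, axis=1)
        pref_shift = np.array(
            [
                0.0 if p is None or group is None else (1.0 if p == group else -2.5)
                for p in prefs
            ]
        )
        p_present = 1.0 / (1.0 + np.exp(-(2.0 - sq + pref_shift)))
        present = rng.random(len(genome_ids)) < p_present
        breadth = np.where(
            present,
            rng.beta(6.0, 2.5, size=len(genome_ids)),
            rng.beta(1.3, 10.0, size=len(genome_ids)),
        )
        rpkm = np.where(
            present, 10.0 ** rng.normal(1.0, 0.5, size=len(genome_ids)), 0.0
        )
        rpkm = rpkm * np.where(pref_shift > 0, 1.5, 1.0)
        for g, b, a in zip(genome_ids, breadth, rpkm):
            cov_rows.append([sample, g, round(float(b), 6), round(float(a), 6)])

    coverage = pd.DataFrame(
        cov_rows, columns=["sample", "genome", "breadth", "rpkm"]
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample", "filter_lower_um", "filter_upper_um"] + env_cols
    )
    metadata[env_cols] = metadata[env_cols].round(6)
    return coverage, metadata


# ---------------------------------------------------------------------------
# annotations (pipeline plumbing: labels independent of planted transfers)

COG_LETTERS = "CDEFGHIJKLMNOPQTUV"


def simulate_annotations(
    cfg: SimConfig, genomes: dict[str, dict[str, np.ndarray]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random COG letters and MGE flags per gene, independent of any
    planted transfer (a true functional null)."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3)))
    rows_cog, rows_mge = [], []
    letters = list(COG_LETTERS)
    for g in sorted(genomes):
        for gid in genomes[g]:
            if rng.random() < 0.8:
                rows_cog.append([gid, letters[int(rng.integers(len(letters)))]])
            rows_mge.append(
                [gid]
                + [int(rng.random() < q) for q in (0.05, 0.03, 0.03, 0.02)]
            )
    cog = pd.DataFrame(rows_cog, columns=["gene", "cog"])
    mge = pd.DataFrame(
        rows_mge,
        columns=["gene", "mge_hit", "plasmid_contig", "virus_contig", "provirus_contig"],
    )
    return cog, mge


# ---------------------------------------------------------------------------
# writers


def write_fasta(genomes, inventories, path) -> None:
    """All genes in one FASTA, headers ``genome|contig|gene``."""
    with open(path, "w") as fh:
        for g in sorted(genomes):
            genes = inventories[g]["genes"]
            for gid in genomes[g]:
                contig = genes[gid][0]
                fh.write(f">{g}|{contig}|{gid}\n")
                fh.write(genomes[g][gid].tobytes().decode() + "\n")


def write_gff3(inventories, outdir) -> None:
    outdir = Path(outdir)
    for g in sorted(inventories):
        with open(outdir / f"{g}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for contig, length in sorted(inventories[g]["contigs"].items()):
                fh.write(f"##sequence-region {contig} 1 {length}\n")
            for gid, (contig, start, end, strand) in inventories[g]["genes"].items():
                fh.write(
                    f"{contig}\thgtcooc\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={gid}\n"
                )


def write_dataset(cfg: SimConfig, outdir) -> GroundTruth:
    """Generate and write the complete synthetic dataset to ``outdir``.

    Emits genes.fna, per-genome GFF3 files, tree.nwk, taxonomy.tsv,
    genome_metadata.tsv, coverage.tsv, sample_metadata.tsv,
    gene_cog.tsv, gene_mge.tsv and ground_truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxonomy, newick = simulate_taxonomy_and_tree(cfg)
    genomes, inventories, gt = simulate_genomes(cfg, taxonomy, newick)
    coverage, metadata = simulate_occupancy(cfg, gt)
    cog, mge = simulate_annotations(cfg, genomes)

    (outdir / "tree.nwk").write_text(newick + "\n")
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    write_fasta(genomes, inventories, outdir / "genes.fna")
    gff_dir = outdir / "gff"
    gff_dir.mkdir(exist_ok=True)
    write_gff3(inventories, gff_dir)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 4)))
    qual = pd.DataFrame(
        {
            "genome": sorted(genomes),
            "completeness": np.round(rng.uniform(80.0, 100.0, len(genomes)), 2),
            "contamination": np.round(rng.uniform(0.0, 4.0, len(genomes)), 2),
        }
    )
    qual.to_csv(outdir / "genome_metadata.tsv", sep="\t", index=False)

    coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False, float_format="%.6g")
    metadata.to_csv(
        outdir / "sample_metadata.tsv", sep="\t", index=False, float_format="%.6g"
    )
    cog.to_csv(outdir / "gene_cog.tsv", sep="\t", index=False)
    mge.to_csv(outdir / "gene_mge.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        gt.planted_events,
        columns=[
            "donor",
            "recipient",
            "donor_gene",
            "recipient_gene",
            "target_identity",
            "realized_identity",
        ],
    )
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False, float_format="%.8g")
    return gt
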