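"""Genome records, quality filtering, taxonomy comparison and patristic distances.

Genomes are described by a seven-rank GTDB-style taxonomy
(domain, phylum, class, order, family, genus, species), assembly quality
metrics (completeness and contamination, both percentages), contig lengths,
and a gene inventory with 1-based inclusive GFF3 coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Divergence levels at which a genome pair is eligible for HGT calling
#: (i.e. the two genomes are "at least in different genera").
CROSS_GENUS_LEVELS = frozenset(
    {"genus", "family", "order", "class", "phylum", "domain"}
)

_GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class TaxonomyError(ValueError):
    """Malformed taxonomy (wrong rank count or rank order)."""


@dataclass
class GenomeRecord:
    """One genome: identity, taxonomy, quality and gene inventory.

    ``genes`` maps gene id -> (contig_id, start, end, strand) with 1-based
    inclusive coordinates (the GFF3 dialect). Conversion to 0-based
    half-open happens only inside interval arithmetic (see
    :mod:`hgtcooc.hgt_detect`).
    """

    genome_id: str
    taxonomy: tuple[str, ...]
    completeness: float
    contamination: float
    contigs: dict[str, int] = field(default_factory=dict)
    genes: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxonomy = tuple(self.taxonomy)
        if len(self.taxonomy) != len(RANKS):
            raise TaxonomyError(
                f"{self.genome_id}: expected {len(RANKS)} ranks, "
                f"got {len(self.taxonomy)}"
            )
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"{self.genome_id}: completeness outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"{self.genome_id}: negative contamination")
        for gene_id, (contig_id, start, end, _strand) in self.genes.items():
            if contig_id not in self.contigs:
                raise ValueError(
                    f"{self.genome_id}/{gene_id}: unknown contig {contig_id!r}"
                )
            if not 1 <= start <= end <= self.contigs[contig_id]:
                raise ValueError(
                    f"{self.genome_id}/{gene_id}: interval [{start}, {end}] "
                    f"outside contig bounds"
                )


def qc_filter(
    records: list[GenomeRecord],
    min_completeness: float = 75.0,
    max_contamination: float = 5.0,
) -> list[GenomeRecord]:
    """Keep genomes with completeness strictly above ``min_completeness``
    and contamination strictly below ``max_contamination``.

    Both inequalities are strict: a genome at exactly 75% completeness or
    exactly 5% contamination is excluded. Input order is preserved.
    """
    if not 0 <= min_completeness <= 100 or not 0 <= max_contamination <= 100:
        raise ValueError("QC thresholds must lie in [0, 100]")
    return [
        r
        for r in records
        if r.completeness > min_completeness and r.contamination < max_contamination
    ]


def divergence_level(tax_a: tuple[str, ...], tax_b: tuple[str, ...]) -> str:
    """Lowest taxonomic level at which two classifications first differ.

    Ranks are scanned from domain down to species; the first rank whose
    names differ is returned. Unassigned ranks (empty strings) compare as
    different from any named rank *and from each other*: two unplaced
    genomes are never treated as members of the same taxon. Returns
    ``"identical"`` when all seven ranks match (and are assigned).
    """
    tax_a, tax_b = tuple(tax_a), tuple(tax_b)
    if len(tax_a) != len(RANKS) or len(tax_b) != len(RANKS):
        raise TaxonomyError("taxonomies must carry exactly the 7 canonical ranks")
    for rank, a, b in zip(RANKS, tax_a, tax_b):
        if a == "" or b == "" or a != b:
            return rank
    return "identical"


def parse_taxonomy_string(s: str) -> tuple[str, ...]:
    """Split a GTDB-style lineage string (``d__...;p__...;...``) into the
    7-rank tuple, with rank prefixes stripped. Short lineages are padded
    with unassigned ranks."""
    parts = [p.strip() for p in s.split(";")]
    ranks = []
    for i in range(len(RANKS)):
        name = parts[i] if i < len(parts) else ""
        if name.startswith(_GTDB_PREFIXES):
            name = name[3:]
        ranks.append(name)
    return tuple(ranks)


def read_taxonomy_tsv(path_or_buf) -> dict[str, tuple[str, ...]]:
    """Read a genome taxonomy table.

    Accepts either one column per rank (``genome`` + the 7 ranks) or a
    two-column table with a GTDB lineage string in the second column.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, comment="#").fillna("")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    out: dict[str, tuple[str, ...]] = {}
    if all(r in cols for r in RANKS):
        for _, row in df.iterrows():
            out[row[cols[0]]] = tuple(row[r] for r in RANKS)
    elif len(cols) >= 2:
        for _, row in df.iterrows():
            out[row[cols[0]]] = parse_taxonomy_string(row[cols[1]])
    else:
        raise TaxonomyError("taxonomy table needs rank columns or a lineage column")
    return out


def read_gff3(path_or_buf) -> dict[str, tuple[str, int, int, str]]:
    """Read CDS features from a GFF3 file into a gene inventory.

    Returns gene id -> (contig, start, end, strand), coordinates 1-based
    inclusive as in the file. Only ``CDS`` features are considered; the
    gene id is taken from the ``ID=`` attribute.
    """
    genes: dict[str, tuple[str, int, int, str]] = {}
    if hasattr(path_or_buf, "read"):
        handle = path_or_buf
    else:
        handle = open(path_or_buf)
    with handle if handle is not path_or_buf else io.StringIO(handle.read()) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            contig, _src, _type, start, end, _score, strand, _phase, attrs = parts[:9]
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                raise ValueError(f"CDS feature without ID attribute: {line!r}")
            genes[gene_id] = (contig, int(start), int(end), strand)
    return genes


def patristic_distances(newick: str, ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise patristic distance (sum of branch lengths on the tip-to-tip
    path) between the named tips of a newick tree.

    Returns a symmetric DataFrame with a zero diagonal, indexed by tip
    label in the order of ``ids`` (or tree order when ``ids`` is None).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if ids is None:
        ids = [t.label for t in tree.taxon_namespace]
    missing = [i for i in ids if i not in taxa]
    if missing:
        raise KeyError(f"tips not found in tree: {missing}")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)
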