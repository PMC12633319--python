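"""End-to-end orchestration: synthetic data (or user inputs) through HGT
calling, co-occurrence, enrichment, pair-level and sample-level models.

Every stage writes a TSV with a provenance comment line (tool version,
configuration hash, seed); the run manifest records per-stage row counts
and wall time. A rerun with an identical configuration reproduces
identical outputs byte for byte (all stochastic stages are seeded).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, enrichment, hgt_detect, occurrence, pair_model, sample_model, syndata
from .genome_io import RANKS, divergence_level, patristic_distances, qc_filter, GenomeRecord
from .occurrence import OccurrenceMatrix


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the published defaults."""

    sim: syndata.SimConfig = field(default_factory=syndata.SimConfig)
    breadth_thresh: float = 0.30
    min_prevalence: int = 10
    min_identity: float = 0.95
    recent_identity: float = 0.99
    min_hit_len_bp: int = 500
    min_contig_bp: int = 5000
    majority: float = 0.75
    small_upper_um: float = 3.0
    lessfiltered_upper_um: float = 20.0
    alpha: float = 0.05
    rho_thresh: float = 0.95
    min_completeness: float = 75.0
    max_contamination: float = 5.0
    rf_trees: int = 500
    rf_perms: int = 200
    seed: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = syndata.SimConfig(**self.sim)
        checks = [
            0 <= self.breadth_thresh <= 1,
            self.min_prevalence >= 0,
            0 <= self.min_identity <= self.recent_identity <= 1,
            self.min_hit_len_bp > 0,
            self.min_contig_bp >= 0,
            0 < self.majority < 1,
            0 < self.small_upper_um <= self.lessfiltered_upper_um,
            0 < self.alpha < 1,
            0 < self.rho_thresh <= 1,
            self.rf_trees > 0,
            self.rf_perms > 0,
        ]
        if not all(checks):
            raise syndata.ConfigError("RunConfig threshold outside documented range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str, index=False) -> int:
    with open(path, "w") as fh:
        fh.write(provenance)
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")
    return len(df)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order on a synthetic community.

    Returns the run manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = f"# hgtcooc {__version__} config={cfg.config_hash()} seed={cfg.seed}\n"
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": [],
    }
    state: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                rows = fn()
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            manifest["stages"].append(
                {
                    "name": name,
                    "rows": rows,
                    "seconds": round(time.perf_counter() - t0, 3),
                }
            )
            return fn

        return deco

    @stage("syndata")
    def _syndata():
        sim = cfg.sim if cfg.sim.seed == cfg.seed else syndata.SimConfig(
            **{**asdict(cfg.sim), "seed": cfg.seed}
        )
        state["sim"] = sim
        state["gt"] = syndata.write_dataset(sim, outdir / "syndata")
        state["taxonomy_df"], state["newick"] = syndata.simulate_taxonomy_and_tree(sim)
        state["genomes"], state["inventories"], _ = syndata.simulate_genomes(
            sim, state["taxonomy_df"], state["newick"], verify_background=False
        )
        state["coverage"], state["metadata"] = syndata.simulate_occupancy(sim, state["gt"])
        state["cog"], state["mge"] = syndata.simulate_annotations(sim, state["genomes"])
        return len(state["genomes"])

    @stage("genome_qc")
    def _qc():
        qual = pd.read_csv(outdir / "syndata" / "genome_metadata.tsv", sep="\t")
        tax = {
            row["genome"]: tuple(row[r] for r in RANKS)
            for _, row in state["taxonomy_df"].iterrows()
        }
        records = [
            GenomeRecord(
                genome_id=r.genome,
                taxonomy=tax[r.genome],
                completeness=float(r.completeness),
                contamination=float(r.contamination),
                contigs=state["inventories"][r.genome]["contigs"],
                genes=state["inventories"][r.genome]["genes"],
            )
            for r in qual.itertuples(index=False)
        ]
        kept = qc_filter(records, cfg.min_completeness, cfg.max_contamination)
        state["taxonomy"] = tax
        state["records"] = kept
        state["phylo"] = patristic_distances(
            state["newick"], [r.genome_id for r in kept]
        )
        return len(kept)

    @stage("hgt_rbh")
    def _hgt():
        keep = {r.genome_id for r in state["records"]}
        genes = [
            (g, gid, seq)
            for g, seqs in state["genomes"].items()
            if g in keep
            for gid, seq in seqs.items()
        ]
        clusters = hgt_detect.cluster_genes(genes, cfg.min_identity)
        locations = {
            (g, gid): (c, state["inventories"][g]["contigs"][c])
            for g in keep
            for gid, (c, *_rest) in state["inventories"][g]["genes"].items()
        }
        events = hgt_detect.call_rbh_events(
            clusters,
            state["taxonomy"],
            locations,
            min_identity=cfg.min_identity,
            min_contig_bp=cfg.min_contig_bp,
        )
        state["clusters"] = clusters
        state["events"] = events
        pair_levels = {}
        ids = sorted(keep)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                pair_levels[frozenset((a, b))] = divergence_level(
                    state["taxonomy"][a], state["taxonomy"][b]
                )
        state["pair_levels"] = pair_levels
        _write_tsv(hgt_detect.events_to_frame(events), outdir / "hgt_events.tsv", prov)
        rates = hgt_detect.level_rates(
            events, {p: lv for p, lv in pair_levels.items() if lv != "species"}
        )
        _write_tsv(rates, outdir / "hgt_level_rates.tsv", prov)
        return len(events)

    @stage("occurrence")
    def _occur():
        m = occurrence.call_presence(state["coverage"], cfg.breadth_thresh)
        m = occurrence.prevalence_filter(m, cfg.min_prevalence)
        m.sample_fractions = {
            r.sample: (float(r.filter_lower_um), float(r.filter_upper_um))
            for r in state["metadata"].itertuples(index=False)
            if r.sample in set(m.samples)
        }
        state["occ"] = m
        state["fractions"] = occurrence.classify_fraction_enrichment(
            m, cfg.small_upper_um, cfg.lessfiltered_upper_um, cfg.majority
        )
        frac = pd.DataFrame(
            sorted(state["fractions"].items()), columns=["genome", "fraction_class"]
        )
        _write_tsv(frac, outdir / "fraction_classes.tsv", prov)
        pres = m.presence.astype(int)
        pres.insert(0, "sample", pres.index)
        _write_tsv(pres, outdir / "presence.tsv", prov)
        return len(m.samples)

    @stage("cooccurrence")
    def _cooc():
        cooc = occurrence.hypergeom_cooccurrence(state["occ"], cfg.alpha)
        state["cooc"] = cooc
        return _write_tsv(cooc, outdir / "cooccurrence.tsv", prov)

    @stage("enrichment")
    def _enrich():
        gene_cogs = dict(zip(state["cog"]["gene"], state["cog"]["cog"]))
        cluster_cogs = enrichment.assign_cluster_cogs(state["clusters"], gene_cogs)
        results = enrichment.stratified_enrichment(
            cluster_cogs, state["events"], alpha=cfg.alpha
        )
        _write_tsv(
            enrichment.enrichment_to_frame(results), outdir / "cog_enrichment.tsv", prov
        )
        flags = state["mge"].set_index("gene")
        hgt_genes = {e.gene_a for e in state["events"]} | {
            e.gene_b for e in state["events"]
        }
        mge = enrichment.mge_fold_enrichment(flags, hgt_genes)
        return _write_tsv(mge, outdir / "mge_enrichment.tsv", prov)

    @stage("pair_model")
    def _pairs():
        env_cols = list(state["sim"].env_variable_names)
        sample_env = state["metadata"].set_index("sample")[env_cols]
        table = pair_model.build_pair_table(
            state["events"],
            state["cooc"],
            state["phylo"],
            state["occ"],
            sample_env,
            state["fractions"],
            state["taxonomy"],
        )
        fitted = None
        comparison = None
        if len(table) and 0 < table["hgt"].sum() < len(table):
            norm = table.copy()
            cont = [
                c
                for c in ["phylo_dist"] + [f"diff_{v}" for v in env_cols]
                if norm[c].nunique() > 1
            ]
            for c in cont:
                norm[c] = pair_model.ordered_quantile_normalize(norm[c].values)
            # at desk scale a sparse fraction category can be quasi-
            # separated (no events in it); drop the term and refit
            for terms in (
                ["cooccur"] + cont + ["pair_fraction"],
                ["cooccur"] + cont,
            ):
                try:
                    fitted = pair_model.fit_logistic(norm, terms)
                    nested = pair_model.fit_logistic(norm, terms[1:])
                    comparison = pair_model.compare_models([fitted, nested])
                    break
                except (pair_model.SeparationError, ValueError):
                    fitted = None
        _write_tsv(table, outdir / "pair_table.tsv", prov)
        if fitted is not None:
            coef = pd.DataFrame(
                [
                    {"term": t, "coef": fitted.coefficients[t],
                     "se": fitted.standard_errors[t], "vif": fitted.vif[t]}
                    for t in fitted.coefficients
                ]
            )
            coef.loc[len(coef)] = {
                "term": "(intercept)", "coef": fitted.intercept, "se": float("nan"),
                "vif": float("nan"),
            }
            _write_tsv(coef, outdir / "pair_model_coefficients.tsv", prov)
            comparison.to_json(outdir / "pair_model_aic.json", orient="records", indent=2)
        return len(table)

    @stage("sample_model")
    def _samples():
        m = state["occ"]
        hgt_genomes = {e.genome_a for e in state["events"]} | {
            e.genome_b for e in state["events"]
        }
        mge_by_gene = state["mge"].set_index("gene")
        gene_owner = {
            gid: g for g, seqs in state["genomes"].items() for gid in seqs
        }
        flag_cols = list(mge_by_gene.columns)
        flags = pd.DataFrame(
            {
                "hgt": [g in hgt_genomes for g in m.genomes],
            },
            index=m.genomes,
        )
        for col in flag_cols:
            flagged_genomes = {
                gene_owner[gid]
                for gid, v in mge_by_gene[col].items()
                if v and gid in gene_owner
            }
            flags[col] = [g in flagged_genomes for g in m.genomes]
        prev = sample_model.hgt_prevalence(m, flags)
        out = prev.reset_index()
        _write_tsv(out, outdir / "sample_prevalence.tsv", prov)

        env_cols = list(state["sim"].env_variable_names)
        env = state["metadata"].set_index("sample")[env_cols].loc[prev.index]
        kept = sample_model.env_redundancy_filter(env, cfg.rho_thresh)
        result = sample_model.rf_importance_test(
            env[kept],
            prev["hgt"].values,
            n_trees=cfg.rf_trees,
            B=cfg.rf_perms,
            seed=cfg.seed,
        )
        return _write_tsv(result.table, outdir / "rf_importance.tsv", prov)

    manifest["total_seconds"] = round(
        sum(s["seconds"] for s in manifest["stages"]), 3
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
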