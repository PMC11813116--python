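"""Orchestration of the full miRNA→bacteria targeting pipeline.

One TOML config file names every input/output path and carries every study
threshold as data (edit budget, MFE gate, classifier confidence, all count
filters, sPLS settings, protein-search rules, global seed).  Stages run in
the order screen → mfe → classify → aggregate → correlate → triples, each
reading and writing plain TSV so any stage can be resumed from its
serialized inputs; a JSON run manifest records per-stage record counts and
wall time.  Identical config + seed gives byte-identical outputs.

The ``mirbact`` console script exposes each stage as a subcommand plus
``simulate`` (synthetic data with ground truth) and ``run-all``.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import sys
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import formats, synth
from .assoc import correlate
from .duplex import DuplexConfig, DuplexResult, EnergyParams, call_hit, duplex_mfe, load_energy_params
from .formats import Alphabet, CountMatrix, FormatError
from .hits import FilterConfig, HitTable, aggregate_hits, display_filter, select_features, select_samples
from .screen import CandidateSite, ScreenConfig, screen_sample
from .taxo import KmerDB, TaxonomyTree, build_kmer_db, classify_pairs
from .triples import (
    ProteinIndex,
    ProteinSearchConfig,
    assign_best_hit,
    build_triples,
    translated_search,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ConfigError",
    "load_config",
    "run_all",
    "main",
]

SITE_COLUMNS = [
    "sample", "mirna_id", "read_id", "mate", "orientation", "start", "end",
    "edits", "target_rna",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 from the CLI)."""


@dataclass
class PipelineConfig:
    mirnas: Path
    samples: list[dict]  # each: {id, r1, r2}
    genomes: Path
    taxonomy: Path
    proteome: Path | None
    mirna_counts: Path | None
    outdir: Path
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    duplex: DuplexConfig = field(default_factory=DuplexConfig)
    energy_params: Path | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    taxo_k: int = 21
    taxo_confidence: float = 0.1
    assoc: dict = field(default_factory=dict)
    protein: ProteinSearchConfig = field(default_factory=ProteinSearchConfig)

    def validate(self) -> None:
        missing = []
        paths = [self.mirnas, self.genomes, self.taxonomy]
        paths += [p for p in (self.proteome, self.mirna_counts,
                              self.energy_params) if p]
        for s in self.samples:
            paths += [Path(s["r1"]), Path(s["r2"])]
        for p in paths:
            if not Path(p).exists():
                missing.append(str(p))
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        if not self.samples:
            raise ConfigError("no samples configured")


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, seconds: float,
               removed: list[dict] | None = None) -> None:
        self.stages.append({
            "stage": stage,
            "records_in": n_in,
            "records_out": n_out,
            "removed": removed or [],
            "wall_seconds": round(seconds, 3),
        })

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        base = Path(path).parent
        def _p(key, section="paths", optional=False):
            value = raw.get(section, {}).get(key)
            if value is None:
                if optional:
                    return None
                raise ConfigError(f"config missing [{section}] {key}")
            return base / value

        screen_raw = raw.get("screen", {})
        duplex_raw = raw.get("duplex", {})
        cfg = PipelineConfig(
            mirnas=_p("mirnas"),
            samples=[
                {"id": s["id"], "r1": str(base / s["r1"]), "r2": str(base / s["r2"])}
                for s in raw.get("samples", [])
            ],
            genomes=_p("genomes"),
            taxonomy=_p("taxonomy"),
            proteome=_p("proteome", optional=True),
            mirna_counts=_p("mirna_counts", optional=True),
            outdir=base / raw.get("paths", {}).get("outdir", "out"),
            seed=int(raw.get("seed", 0)),
            screen=ScreenConfig(**screen_raw),
            duplex=DuplexConfig(**duplex_raw),
            energy_params=_p("energy_params", optional=True),
            filters=FilterConfig(**raw.get("filters", {})),
            taxo_k=int(raw.get("taxo", {}).get("k", 21)),
            taxo_confidence=float(raw.get("taxo", {}).get("confidence", 0.1)),
            assoc=raw.get("assoc", {}),
            protein=ProteinSearchConfig(**raw.get("protein", {})),
        )
    except (TypeError, KeyError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    return cfg


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def sites_to_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.mirna_id, s.read_id, s.mate, s.orientation,
             s.start, s.end, s.edit_distance, s.target_rna)
            for s in sites
        ],
        columns=SITE_COLUMNS,
    )


def frame_to_sites(df: pd.DataFrame) -> list[CandidateSite]:
    return [
        CandidateSite(
            mirna_id=r.mirna_id, read_id=r.read_id, mate=int(r.mate),
            orientation=r.orientation, start=int(r.start), end=int(r.end),
            edit_distance=int(r.edits), target_rna=r.target_rna,
            sample_id=r.sample,
        )
        for r in df.itertuples()
    ]


def stage_screen(cfg: PipelineConfig) -> pd.DataFrame:
    """Screen every sample's read pairs against the miRNA panel."""
    mirnas = formats.read_fasta(cfg.mirnas, Alphabet.RNA)
    all_sites: list[CandidateSite] = []
    for sample in cfg.samples:
        pairs = formats.read_fastq_pairs(sample["r1"], sample["r2"], sample["id"])
        sites = screen_sample(mirnas, pairs, cfg.screen)
        _log("screen", f"{sample['id']}: {len(pairs)} pairs → {len(sites)} sites")
        all_sites.extend(sites)
    return sites_to_frame(all_sites)


def score_sites(
    sites: pd.DataFrame,
    mirnas: list[formats.SequenceRecord],
    params: EnergyParams | None = None,
    duplex_cfg: DuplexConfig | None = None,
) -> pd.DataFrame:
    """Attach duplex dG and the hit call to every candidate site.

    MFE is memoised on the (miRNA, target) sequence pair — identical
    windows recur across reads.
    """
    params = params or EnergyParams()
    duplex_cfg = duplex_cfg or DuplexConfig()
    seq_of = {m.id: m.as_rna().sequence for m in mirnas}
    cache: dict[tuple[str, str], DuplexResult] = {}
    dgs, hits = [], []
    for row in sites.itertuples():
        key = (row.mirna_id, row.target_rna)
        result = cache.get(key)
        if result is None:
            result = duplex_mfe(seq_of[row.mirna_id], row.target_rna, params)
            cache[key] = result
        dgs.append(result.dG if result.is_duplex else np.nan)
        hits.append(call_hit(result, duplex_cfg))
    out = sites.copy()
    out["dG"] = dgs
    out["hit"] = hits
    return out


def stage_mfe(cfg: PipelineConfig, sites: pd.DataFrame) -> pd.DataFrame:
    mirnas = formats.read_fasta(cfg.mirnas, Alphabet.RNA)
    params = (
        load_energy_params(cfg.energy_params) if cfg.energy_params else None
    )
    scored = score_sites(sites, mirnas, params, cfg.duplex)
    _log("mfe", f"{len(scored)} sites scored, {int(scored['hit'].sum())} pass "
                f"{cfg.duplex.mfe_max} kcal/mol")
    return scored


def stage_classify(cfg: PipelineConfig) -> pd.DataFrame:
    tree = TaxonomyTree.from_table(formats.read_taxonomy_table(cfg.taxonomy))
    genome_records = formats.read_fasta(cfg.genomes, Alphabet.DNA)
    db = build_kmer_db({g.id: g for g in genome_records}, tree, cfg.taxo_k)
    out = []
    for sample in cfg.samples:
        pairs = formats.read_fastq_pairs(sample["r1"], sample["r2"], sample["id"])
        df = classify_pairs(db, pairs, cfg.taxo_confidence)
        df.insert(0, "sample", sample["id"])
        out.append(df)
        _log("classify", f"{sample['id']}: {len(df)} pairs, "
             f"{(df['node_id'] != 'unclassified').sum()} classified")
    return pd.concat(out, ignore_index=True)


def stage_aggregate(
    cfg: PipelineConfig, scored: pd.DataFrame, taxa: pd.DataFrame
) -> tuple[HitTable, dict]:
    sites = frame_to_sites(scored)
    results = {}
    for site, dg in zip(sites, scored["dG"]):
        key = (site.mirna_id, site.read_id, site.mate, site.orientation)
        results[key] = DuplexResult(None) if np.isnan(dg) else DuplexResult(float(dg))
    table = aggregate_hits(sites, results, taxa, cfg.duplex)
    summary = table.summary()
    shown = display_filter(table, cfg.filters.display_min_hits)
    _log("aggregate", f"{len(table.entries)} (sample, miRNA, taxon) entries; "
         f"median hits/sample {summary['median_hits_per_sample']}")
    return shown, summary


def stage_correlate(cfg: PipelineConfig, taxa: pd.DataFrame) -> pd.DataFrame:
    """sPLS/CIM of the miRNA count matrix against per-sample taxon counts.

    Taxon abundances are the per-sample counts of classified read pairs
    per taxon (the metagenomic count matrix of the correlation analysis)."""
    if cfg.mirna_counts is None:
        raise ConfigError("correlate stage needs paths.mirna_counts")
    mirna_counts = formats.read_count_matrix(cfg.mirna_counts)
    classified = taxa[taxa["node_id"] != "unclassified"]
    taxon_df = (
        classified.groupby(["sample", "node_id"]).size().unstack(fill_value=0)
        .reindex(mirna_counts.sample_ids, fill_value=0)
    )
    taxon_counts = CountMatrix.from_frame(taxon_df)
    a = cfg.assoc
    n_samples = len(mirna_counts.sample_ids)
    if n_samples < 2:
        raise ConfigError("correlate stage needs at least 2 samples")
    ncomp = min(int(a.get("ncomp", 2)), n_samples - 1,
                len(mirna_counts.feature_ids), len(taxon_counts.feature_ids))
    result = correlate(
        mirna_counts, taxon_counts,
        ncomp=ncomp,
        keep_x=int(a.get("keepx", 20)), keep_y=int(a.get("keepy", 20)),
        n_perm=int(a.get("n_perm", 1000)), seed=cfg.seed,
    )
    rows = result.values.stack().rename("cim").reset_index()
    rows.columns = ["mirna_id", "taxon_id", "cim"]
    rows["p"] = result.p.stack().to_numpy()
    rows["q"] = result.q.stack().to_numpy()
    _log("correlate", f"{len(rows)} miRNA × taxon pairs, "
         f"{(rows['q'] < 0.05).sum()} at q<0.05")
    return rows


def stage_triples(
    cfg: PipelineConfig, scored: pd.DataFrame, taxa: pd.DataFrame
) -> pd.DataFrame:
    if cfg.proteome is None:
        raise ConfigError("triples stage needs paths.proteome")
    proteins = formats.read_fasta(cfg.proteome, Alphabet.PROTEIN)
    index = ProteinIndex(proteins, cfg.protein.seed_length)
    passing = scored[scored["hit"]]
    passing_mirnas: dict[str, set[str]] = {}
    sample_of: dict[str, str] = {}
    for row in passing.itertuples():
        pair_id = row.read_id.removesuffix("/1").removesuffix("/2")
        passing_mirnas.setdefault(pair_id, set()).add(row.mirna_id)
        sample_of[pair_id] = row.sample
    best_hits = {}
    for sample in cfg.samples:
        pairs = formats.read_fastq_pairs(sample["r1"], sample["r2"], sample["id"])
        wanted = {p.id: p for p in pairs if p.id in passing_mirnas}
        for pair_id, pair in wanted.items():
            h1 = translated_search(pair.mate1, index, cfg.protein, mate=1)
            h2 = translated_search(pair.mate2, index, cfg.protein, mate=2)
            best_hits[pair_id] = assign_best_hit(h1, h2, seed=cfg.seed)
    taxa_pairs = taxa.rename(columns={"read_id": "read_id"})
    triple_table = build_triples(best_hits, passing_mirnas, taxa_pairs, sample_of)
    _log("triples", f"{len(triple_table.entries)} distinct triples")
    return triple_table.entries


def run_all(config_path: str | Path) -> RunManifest:
    cfg = load_config(config_path)
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        __version__,
        hashlib.sha256(Path(config_path).read_bytes()).hexdigest(),
    )

    t0 = time.perf_counter()
    sites = stage_screen(cfg)
    formats.write_table(cfg.outdir / "sites.tsv", sites)
    manifest.record("screen", sum(1 for _ in cfg.samples), len(sites),
                    time.perf_counter() - t0)

    t0 = time.perf_counter()
    scored = stage_mfe(cfg, sites)
    formats.write_table(cfg.outdir / "scored.tsv", scored)
    manifest.record("mfe", len(sites), int(scored["hit"].sum()),
                    time.perf_counter() - t0)

    t0 = time.perf_counter()
    taxa = stage_classify(cfg)
    formats.write_table(cfg.outdir / "taxa.tsv", taxa)
    n_classified = int((taxa["node_id"] != "unclassified").sum())
    manifest.record("classify", len(taxa), n_classified,
                    time.perf_counter() - t0,
                    removed=[{
                        "rule": f"confidence<{cfg.taxo_confidence}",
                        "n": len(taxa) - n_classified,
                    }])

    t0 = time.perf_counter()
    table, summary = stage_aggregate(cfg, scored, taxa)
    formats.write_table(cfg.outdir / "hits.tsv", table.entries)
    with open(cfg.outdir / "hit_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest.record("aggregate", int(scored["hit"].sum()),
                    int(table.entries["count"].sum()),
                    time.perf_counter() - t0)

    if cfg.mirna_counts is not None:
        t0 = time.perf_counter()
        cim = stage_correlate(cfg, taxa)
        formats.write_table(cfg.outdir / "cim.tsv", cim)
        manifest.record("correlate", len(taxa), len(cim),
                        time.perf_counter() - t0)

    if cfg.proteome is not None:
        t0 = time.perf_counter()
        triples = stage_triples(cfg, scored, taxa)
        formats.write_table(cfg.outdir / "triples.tsv", triples)
        manifest.record("triples", int(scored["hit"].sum()), len(triples),
                        time.perf_counter() - t0)

    manifest.save(cfg.outdir / "manifest.json")
    return manifest


def simulate_dataset(
    outdir: str | Path,
    n_taxa: int = 4,
    genome_length: int = 10_000,
    n_mirnas: int = 6,
    sites_per_taxon: int = 5,
    n_pairs: int = 2000,
    n_samples: int = 2,
    read_length: int = 100,
    insert_length: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Path:
    """Generate a complete toy dataset plus a ready-to-run config TOML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirnas = synth.simulate_mirnas(n_mirnas, seed, gc=0.7)
    taxonomy, genomes, _proteomes, orf_table = synth.simulate_references(
        n_taxa, genome_length, seed=seed
    )
    orf_intervals = {
        t: [(r.start, r.end) for r in orf_table.itertuples()
            if r.taxon_id == t]
        for t in genomes
    }
    # sites go inside ORFs (stop-free) so the triples stage has joint
    # miRNA/protein evidence to work with
    genomes, planted = synth.plant_sites(
        genomes, mirnas, sites_per_taxon, edits=0, gc_boost=True, seed=seed,
        regions=orf_intervals, forbid_stops_in=orf_intervals,
        min_separation=50,
    )
    proteomes = synth.derive_proteomes(genomes, orf_table)

    formats.write_fasta(outdir / "mirnas.fasta", mirnas)
    formats.write_fasta(outdir / "genomes.fasta", list(genomes.values()))
    formats.write_fasta(
        outdir / "proteome.fasta",
        [p for plist in proteomes.values() for p in plist],
    )
    formats.write_table(outdir / "taxonomy.tsv", taxonomy.to_table())
    formats.write_table(
        outdir / "planted_sites.tsv",
        pd.DataFrame([asdict(s) for s in planted]),
    )

    leaves = sorted(genomes)
    abundances = {t: 1.0 / len(leaves) for t in leaves}
    sample_rows = []
    truth_frames = []
    for s in range(n_samples):
        sid = f"S{s + 1:03d}"
        pairs, truth = synth.simulate_read_pairs(
            genomes, abundances, n_pairs, read_length, insert_length,
            error_rate, seed=seed + s, sample_id=sid,
        )
        r1, r2 = outdir / f"{sid}_R1.fastq", outdir / f"{sid}_R2.fastq"
        formats.write_fastq_pairs(r1, r2, pairs)
        truth.insert(0, "sample", sid)
        truth_frames.append(truth)
        sample_rows.append((sid, r1.name, r2.name))
    formats.write_table(
        outdir / "read_truth.tsv", pd.concat(truth_frames, ignore_index=True)
    )

    spec = synth.make_latent_spec(
        1, n_mirnas, n_taxa, support=min(3, n_taxa), seed=seed
    )
    x, _y, _ = synth.simulate_count_matrices(
        max(n_samples, 2), n_mirnas, n_taxa, spec, seed=seed
    )
    x = CountMatrix(
        [f"S{s + 1:03d}" for s in range(n_samples)], x.feature_ids,
        x.counts[:n_samples],
    )
    formats.write_count_matrix(outdir / "mirna_counts.tsv", x)

    config = [
        f"seed = {seed}",
        "",
        "[paths]",
        'mirnas = "mirnas.fasta"',
        'genomes = "genomes.fasta"',
        'taxonomy = "taxonomy.tsv"',
        'proteome = "proteome.fasta"',
        'mirna_counts = "mirna_counts.tsv"',
        'outdir = "out"',
        "",
    ]
    for sid, r1, r2 in sample_rows:
        config += ["[[samples]]", f'id = "{sid}"', f'r1 = "{r1}"',
                   f'r2 = "{r2}"', ""]
    (outdir / "config.toml").write_text("\n".join(config))
    return outdir / "config.toml"


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="mirbact",
        description="Bacterial targets of host fecal miRNAs in metagenomes",
    )
    parser.add_argument("--version", action="version", version=__version__)
    sub = parser.add_subparsers(dest="command", required=True)

    p_sim = sub.add_parser("simulate", help="generate a toy dataset + config")
    p_sim.add_argument("--outdir", required=True)
    p_sim.add_argument("--seed", type=int, default=0)
    p_sim.add_argument("--n-taxa", type=int, default=4)
    p_sim.add_argument("--n-pairs", type=int, default=2000)
    p_sim.add_argument("--n-samples", type=int, default=2)

    for name in ("screen", "mfe", "classify", "aggregate", "correlate",
                 "triples", "run-all"):
        p = sub.add_parser(name, help=f"run the {name} stage")
        p.add_argument("--config", required=True)

    args = parser.parse_args(argv)
    try:
        if args.command == "simulate":
            path = simulate_dataset(
                args.outdir, seed=args.seed, n_taxa=args.n_taxa,
                n_pairs=args.n_pairs, n_samples=args.n_samples,
            )
            _log("simulate", f"config written to {path}")
            return 0
        cfg = load_config(args.config)
        cfg.validate()
        cfg.outdir.mkdir(parents=True, exist_ok=True)
        if args.command == "run-all":
            run_all(args.config)
            return 0
        if args.command == "screen":
            formats.write_table(cfg.outdir / "sites.tsv", stage_screen(cfg))
        elif args.command == "mfe":
            sites = formats.read_table(cfg.outdir / "sites.tsv")
            formats.write_table(cfg.outdir / "scored.tsv", stage_mfe(cfg, sites))
        elif args.command == "classify":
            formats.write_table(cfg.outdir / "taxa.tsv", stage_classify(cfg))
        elif args.command == "aggregate":
            scored = formats.read_table(cfg.outdir / "scored.tsv")
            taxa = formats.read_table(cfg.outdir / "taxa.tsv")
            table, summary = stage_aggregate(cfg, scored, taxa)
            formats.write_table(cfg.outdir / "hits.tsv", table.entries)
            with open(cfg.outdir / "hit_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2)
        elif args.command == "correlate":
            taxa = formats.read_table(cfg.outdir / "taxa.tsv")
            formats.write_table(
                cfg.outdir / "cim.tsv", stage_correlate(cfg, taxa)
            )
        elif args.command == "triples":
            scored = formats.read_table(cfg.outdir / "scored.tsv")
            taxa = formats.read_table(cfg.outdir / "taxa.tsv")
            formats.write_table(
                cfg.outdir / "triples.tsv", stage_triples(cfg, scored, taxa)
            )
        return 0
    except (ConfigError, FormatError) as exc:
        _log("error", str(exc))
        return 2


if __name__ == "__main__":
    sys.exit(main())
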