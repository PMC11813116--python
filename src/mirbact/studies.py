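"""Planted-truth validation studies run by the analysis drivers.

Each study generates synthetic data with known ground truth, runs the
relevant pipeline stages through the public library surface, and scores the
result against the truth.  They are used by the numbered analysis scripts,
the test suite and the acceptance script alike, so every reported number is
recomputed from scratch on each run.

Study dimensions are desk-scale stand-ins for the real experiment: a few
ten-kilobase genomes and thousands of read pairs exercise every code path
while keeping a full run in minutes.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from . import synth
from .assoc import (
    bh_adjust,
    cim_matrix,
    clr_transform,
    component_correlations,
    permutation_pvalues,
    spls_fit,
)
from .duplex import DuplexConfig
from .formats import CountMatrix
from .hits import aggregate_hits
from .pipeline import score_sites
from .screen import ScreenConfig, screen_sample
from .taxo import build_kmer_db, classify_pairs
from .triples import (
    ProteinIndex,
    ProteinSearchConfig,
    assign_best_hit,
    build_triples,
    translated_search,
)

__all__ = [
    "planted_site_dataset",
    "planted_recovery_study",
    "classifier_accuracy_study",
    "shared_segment_study",
    "spls_recovery_study",
    "null_calibration_study",
    "triple_recovery_study",
]


def planted_site_dataset(
    seed: int = 0,
    n_taxa: int = 4,
    n_mirnas: int = 6,
    sites_per_taxon: int = 5,
    n_pairs: int = 2000,
    n_samples: int = 2,
    genome_length: int = 10_000,
    read_length: int = 100,
    insert_length: int = 300,
    error_rate: float = 0.0,
    inside_orfs: bool = False,
):
    """Synthetic references with planted GC-rich 0-edit sites plus reads.

    One miRNA per taxon keeps leaf genomes disjoint; miRNAs are GC-rich
    (GC 0.7, 22 nt) so every admitted window passes the −20.0 kcal/mol gate.
    With ``inside_orfs`` the sites are planted inside annotated ORFs (and
    the proteome re-derived) so protein labels can be checked downstream.
    """
    mirnas = synth.simulate_mirnas(n_mirnas, seed, length_range=(22, 22), gc=0.7)
    taxonomy, genomes, _prot, orf_table = synth.simulate_references(
        n_taxa, genome_length, seed=seed
    )
    orf_intervals = {
        t: [(r.start, r.end) for r in orf_table.itertuples() if r.taxon_id == t]
        for t in genomes
    }
    if inside_orfs:
        # ORF space is limited; close co-placement only risks two sites on
        # one read, which read-level hit counting already tolerates
        genomes, planted = synth.plant_sites(
            genomes, mirnas, sites_per_taxon, edits=0, gc_boost=True,
            seed=seed, regions=orf_intervals, forbid_stops_in=orf_intervals,
            min_separation=50,
        )
    else:
        genomes, planted = synth.plant_sites(
            genomes, mirnas, sites_per_taxon, edits=0, gc_boost=True,
            seed=seed, avoid=orf_intervals, min_separation=insert_length,
        )
    proteomes = synth.derive_proteomes(genomes, orf_table)
    abundances = {t: 1.0 for t in genomes}
    samples = {}
    for s in range(n_samples):
        sid = f"S{s + 1:03d}"
        pairs, truth = synth.simulate_read_pairs(
            genomes, abundances, n_pairs, read_length, insert_length,
            error_rate, seed=seed + s, sample_id=sid,
        )
        samples[sid] = (pairs, truth)
    return {
        "mirnas": mirnas,
        "taxonomy": taxonomy,
        "genomes": genomes,
        "proteomes": proteomes,
        "orf_table": orf_table,
        "planted": planted,
        "samples": samples,
    }


def truth_hit_counts(
    planted, samples, max_edits: int = 3
) -> pd.DataFrame:
    """Expected hit table from the ground truth alone.

    A mate is a *covering mate* of a planted site when its genome interval
    overlaps the site by at least (site length − max_edits) bases — exactly
    the windows the fit screen admits for error-free reads and 0-edit
    sites.  Returns (sample_id, mirna_id, taxon_id) → count.
    """
    counts: dict[tuple[str, str, str], int] = {}
    by_taxon: dict[str, list] = {}
    for site in planted:
        by_taxon.setdefault(site.taxon_id, []).append(site)
    for sid, (_pairs, truth) in samples.items():
        for row in truth.itertuples():
            for mate_iv in (
                (row.mate1_start, row.mate1_end),
                (row.mate2_start, row.mate2_end),
            ):
                for site in by_taxon.get(row.taxon_id, ()):
                    overlap = min(mate_iv[1], site.end) - max(mate_iv[0], site.start)
                    if overlap >= (site.end - site.start) - max_edits:
                        key = (sid, site.mirna_id, site.taxon_id)
                        counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(
        [(s, m, t, c) for (s, m, t), c in sorted(counts.items())],
        columns=["sample_id", "mirna_id", "taxon_id", "count"],
    )


def planted_recovery_study(seed: int = 0, **dataset_kwargs) -> dict:
    """End-to-end screen→MFE→classify→aggregate against planted truth.

    Returns the pipeline hit table, the truth table, and exact-recovery
    recall/precision over (sample, miRNA, taxon) cells.
    """
    data = planted_site_dataset(seed=seed, **dataset_kwargs)
    cfg = ScreenConfig()
    all_sites = []
    all_taxa = []
    for sid, (pairs, _truth) in data["samples"].items():
        all_sites.extend(screen_sample(data["mirnas"], pairs, cfg))
    db = build_kmer_db(data["genomes"], data["taxonomy"], k=21)
    for sid, (pairs, _truth) in data["samples"].items():
        all_taxa.append(classify_pairs(db, pairs, confidence_threshold=0.1))
    assignments = pd.concat(all_taxa, ignore_index=True)

    from .pipeline import sites_to_frame, frame_to_sites
    scored = score_sites(sites_to_frame(all_sites), data["mirnas"])
    from .duplex import DuplexResult
    results = {
        (s.mirna_id, s.read_id, s.mate, s.orientation):
            DuplexResult(None) if np.isnan(dg) else DuplexResult(float(dg))
        for s, dg in zip(all_sites, scored["dG"])
    }
    table = aggregate_hits(all_sites, results, assignments, DuplexConfig())
    truth = truth_hit_counts(data["planted"], data["samples"], cfg.max_edits)

    merged = table.entries.merge(
        truth, on=["sample_id", "mirna_id", "taxon_id"], how="outer",
        suffixes=("_hit", "_truth"),
    ).fillna(0)
    tp = np.minimum(merged["count_hit"], merged["count_truth"]).sum()
    total_hits = merged["count_hit"].sum()
    total_truth = merged["count_truth"].sum()
    return {
        "data": data,
        "hit_table": table,
        "truth": truth,
        "recall": float(tp / total_truth) if total_truth else float("nan"),
        "precision": float(tp / total_hits) if total_hits else float("nan"),
        "exact_match": bool(
            (merged["count_hit"] == merged["count_truth"]).all()
        ),
        "summary": table.summary(),
    }


def classifier_accuracy_study(
    seed: int = 0,
    n_taxa: int = 4,
    genome_length: int = 10_000,
    n_pairs: int = 2000,
    confidence: float = 0.1,
) -> dict:
    """Classification accuracy on error-free reads from leaf-disjoint genomes."""
    _taxonomy, genomes, _prot, _orfs = synth.simulate_references(
        n_taxa, genome_length, seed=seed
    )
    taxonomy = _taxonomy
    pairs, truth = synth.simulate_read_pairs(
        genomes, {t: 1.0 for t in genomes}, n_pairs, seed=seed
    )
    db = build_kmer_db(genomes, taxonomy, k=21)
    assigned = classify_pairs(db, pairs, confidence)
    merged = assigned.merge(
        truth[["read_id", "taxon_id"]], on="read_id", validate="1:1"
    )
    accuracy = float((merged["node_id"] == merged["taxon_id"]).mean())
    return {"accuracy": accuracy, "n_pairs": len(pairs), "assignments": merged}


def shared_segment_study(
    seed: int = 0,
    genome_length: int = 10_000,
    segment_length: int = 1000,
    n_pairs: int = 200,
) -> dict:
    """Reads drawn entirely from a sister-shared segment label the parent."""
    taxonomy, genomes, _prot, _orfs = synth.simulate_references(
        4, genome_length, synth.TreeShape(shared_segments={0: segment_length}),
        seed=seed,
    )
    db = build_kmer_db(genomes, taxonomy, k=21)
    # locate the shared interval: identical stretch between the two sisters
    a, b = sorted(genomes)[:2]
    seq_a, seq_b = genomes[a].sequence, genomes[b].sequence
    same = [i for i in range(genome_length) if seq_a[i] == seq_b[i]]
    # longest identical run is the planted segment
    runs, start = [], same[0]
    for prev, cur in zip(same, same[1:]):
        if cur != prev + 1:
            runs.append((start, prev + 1))
            start = cur
    runs.append((start, same[-1] + 1))
    seg_start, seg_end = max(runs, key=lambda r: r[1] - r[0])
    from .formats import SequenceRecord

    segment = {"seg": SequenceRecord("seg", seq_a[seg_start:seg_end])}
    pairs, _truth = synth.simulate_read_pairs(
        segment, {"seg": 1.0}, n_pairs, seed=seed
    )
    assigned = classify_pairs(db, pairs, confidence_threshold=0.1)
    parent = taxonomy.parent(a)
    frac_parent = float((assigned["node_id"] == parent).mean())
    return {
        "parent": parent,
        "fraction_parent": frac_parent,
        "segment": (seg_start, seg_end),
    }


def spls_recovery_study(
    seed: int = 0,
    n_reps: int = 20,
    n_samples: int = 100,
    n_mirna: int = 20,
    n_taxa: int = 20,
    support: int = 3,
    loading_scale: float = 2.0,
    noise_sd: float = 0.5,
    depth: int = 100_000,
) -> dict:
    """Recovery of one planted latent factor by sPLS/CIM.

    Success for a replicate: the ``support²`` largest-|CIM| entries are
    exactly the support product pairs, with signs equal to the products of
    the planted loading signs.
    """
    successes = 0
    for rep in range(n_reps):
        rep_seed = seed + rep
        spec = synth.make_latent_spec(
            1, n_mirna, n_taxa, support, loading_scale, noise_sd, depth,
            seed=rep_seed,
        )
        x, y, _ = synth.simulate_count_matrices(
            n_samples, n_mirna, n_taxa, spec, seed=rep_seed
        )
        cx, cy = clr_transform(x), clr_transform(y)
        model = spls_fit(cx, cy, ncomp=1, keep_x=support, keep_y=support)
        cim = cim_matrix(cx, cy, model).to_numpy()
        sup_x = np.flatnonzero(spec.loadings_x[0])
        sup_y = np.flatnonzero(spec.loadings_y[0])
        expected = {(i, j) for i in sup_x for j in sup_y}
        flat_order = np.argsort(-np.abs(cim), axis=None)[: len(expected)]
        top = {divmod(int(k), n_taxa) for k in flat_order}
        signs_ok = all(
            np.sign(cim[i, j])
            == np.sign(spec.loadings_x[0, i] * spec.loadings_y[0, j])
            for i, j in expected
        )
        if top == expected and signs_ok:
            successes += 1
    return {"successes": successes, "n_reps": n_reps}


def null_calibration_study(
    seed: int = 0,
    n_reps: int = 20,
    n_perm: int = 1000,
    n_samples: int = 50,
    n_mirna: int = 100,
    n_taxa: int = 30,
    noise_sd: float = 1.0,
    depth: int = 50_000,
) -> dict:
    """Permutation-test calibration under the global null (no shared factors).

    Reports the fraction of entries at p < 0.05 in the first replicate and,
    over all replicates, how many yield zero BH discoveries at q < 0.05.
    """
    fractions = []
    no_discovery = 0
    for rep in range(n_reps):
        rep_seed = seed + rep
        spec = synth.make_latent_spec(
            0, n_mirna, n_taxa, noise_sd=noise_sd, depth=depth, seed=rep_seed
        )
        x, y, _ = synth.simulate_count_matrices(
            n_samples, n_mirna, n_taxa, spec, seed=rep_seed
        )
        cx, cy = clr_transform(x), clr_transform(y)
        model = spls_fit(cx, cy, ncomp=2, keep_x=20, keep_y=20)
        c_x, c_y = component_correlations(cx, cy, model)
        cim = c_x @ c_y.T
        p = permutation_pvalues(c_x, c_y, cim, n_iter=n_perm, seed=rep_seed)
        fractions.append(float((p < 0.05).mean()))
        q = bh_adjust(p)
        if not (q < 0.05).any():
            no_discovery += 1
    return {
        "fraction_p05": fractions[0],
        "fractions": fractions,
        "n_entries": n_mirna * n_taxa,
        "reps_without_discoveries": no_discovery,
        "n_reps": n_reps,
    }


def triple_recovery_study(seed: int = 0, **dataset_kwargs) -> dict:
    """Triples from sites planted inside ORFs: protein labels versus truth.

    A triple-contributing pair's protein label is correct when it names an
    ORF of the pair's source taxon that one of its mates overlaps.
    Reports the precision of the protein labels at error_rate 0.
    """
    dataset_kwargs.setdefault("n_pairs", 1500)
    data = planted_site_dataset(seed=seed, inside_orfs=True, **dataset_kwargs)
    cfg = ScreenConfig()
    pcfg = ProteinSearchConfig()
    proteins = [p for plist in data["proteomes"].values() for p in plist]
    index = ProteinIndex(proteins, pcfg.seed_length)
    db = build_kmer_db(data["genomes"], data["taxonomy"], k=21)
    orf_ivs = {
        r.protein_id: (r.taxon_id, r.start, r.end)
        for r in data["orf_table"].itertuples()
    }

    from .pipeline import sites_to_frame

    n_correct = 0
    n_total = 0
    triple_frames = []
    for sid, (pairs, truth) in data["samples"].items():
        sites = screen_sample(data["mirnas"], pairs, cfg)
        scored = score_sites(sites_to_frame(sites), data["mirnas"])
        assignments = classify_pairs(db, pairs, 0.1)
        passing = scored[scored["hit"]]
        passing_mirnas: dict[str, set[str]] = {}
        for row in passing.itertuples():
            pid = row.read_id.removesuffix("/1").removesuffix("/2")
            passing_mirnas.setdefault(pid, set()).add(row.mirna_id)
        pair_of = {p.id: p for p in pairs}
        best = {}
        for pid in passing_mirnas:
            pair = pair_of[pid]
            best[pid] = assign_best_hit(
                translated_search(pair.mate1, index, pcfg, 1),
                translated_search(pair.mate2, index, pcfg, 2),
                seed=seed,
            )
        triples = build_triples(
            best, passing_mirnas, assignments, {pid: sid for pid in passing_mirnas}
        )
        triple_frames.append(triples.entries)
        truth_by_read = {r.read_id: r for r in truth.itertuples()}
        for pid, hit in best.items():
            if hit is None:
                continue
            n_total += 1
            row = truth_by_read[pid]
            taxon, start, end = orf_ivs[hit.protein_id]
            mate_ivs = [
                (row.mate1_start, row.mate1_end),
                (row.mate2_start, row.mate2_end),
            ]
            if taxon == row.taxon_id and any(
                s < end and e > start for s, e in mate_ivs
            ):
                n_correct += 1
    entries = pd.concat(triple_frames, ignore_index=True)
    return {
        "precision": n_correct / n_total if n_total else float("nan"),
        "n_pairs_with_protein": n_total,
        "triples": entries,
    }
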