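"""Synthetic inputs with known ground truth for every pipeline stage.

Generates a small taxonomy with genomes and ORF-derived proteomes, plants
miRNA target sites (reverse complements of miRNAs, optionally with a
controlled number of edits) into the genomes, samples paired-end reads from
taxon abundances, and draws miRNA/taxon count matrices from a sparse
log-normal latent factor model.  Every generator is a pure function of its
parameters and an integer seed; each uses its own fixed sub-stream of the
seed so stages can be re-run independently and reproducibly.

Truth artifacts (planted-site lists, read→taxon tables with per-mate genome
intervals, latent loadings) are sufficient to score recall and precision of
the corresponding pipeline stage without reaching back into the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import Alphabet, CountMatrix, ReadPair, SequenceRecord, revcomp

__all__ = [
    "TreeShape",
    "PlantedSite",
    "LatentSpec",
    "simulate_mirnas",
    "simulate_references",
    "derive_proteomes",
    "plant_sites",
    "simulate_read_pairs",
    "make_latent_spec",
    "simulate_count_matrices",
]

# fixed sub-stream ids of the master seed, one per generator
_STREAM_MIRNAS = 0
_STREAM_REFERENCES = 1
_STREAM_SITES = 2
_STREAM_READS = 3
_STREAM_COUNTS = 4

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]
_CODON_TABLE = {
    codon: aa
    for codon, aa in zip(
        _CODONS,
        "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLLEDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF",
    )
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def translate(dna: str) -> str:
    """Standard-code translation of a DNA string (trailing partial codon dropped)."""
    return "".join(
        _CODON_TABLE[dna[i : i + 3]] for i in range(0, len(dna) - 2, 3)
    )


@dataclass(frozen=True)
class TreeShape:
    """Shape requests for the simulated taxonomy.

    Leaves are grouped into consecutive sister pairs, each under its own
    internal parent.  ``shared_segments`` maps a sister-pair index to a
    segment length: that many bases are copied from the first sister to the
    second at the same genome position, making those k-mers map to the
    parent node in the k-mer database.
    """

    shared_segments: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted miRNA target site (forward strand)."""

    taxon_id: str
    start: int
    end: int
    mirna_id: str
    edits_introduced: int
    strand: str = "+"


@dataclass
class LatentSpec:
    """Sparse latent factor model linking miRNA and taxon abundances.

    ``loadings_x`` (n_factors × n_mirna) and ``loadings_y`` (n_factors ×
    n_taxa) hold the sparse factor loadings on the log-abundance scale;
    ``noise_sd`` is the per-feature log-normal noise and ``depth`` the
    multinomial sequencing depth per sample (scalar or per-sample array).
    """

    n_factors: int
    loadings_x: np.ndarray
    loadings_y: np.ndarray
    noise_sd: float = 0.5
    depth: int | np.ndarray = 100_000

    def __post_init__(self) -> None:
        self.loadings_x = np.atleast_2d(np.asarray(self.loadings_x, dtype=float))
        self.loadings_y = np.atleast_2d(np.asarray(self.loadings_y, dtype=float))
        if self.n_factors:
            if self.loadings_x.shape[0] != self.n_factors or \
                    self.loadings_y.shape[0] != self.n_factors:
                raise ValueError("loadings rows must equal n_factors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if np.any(np.asarray(self.depth) <= 0):
            raise ValueError("depth must be > 0")
        if self.n_factors == 0 and self.noise_sd == 0:
            raise ValueError(
                "degenerate spec: no factors and no noise leaves counts constant"
            )


def simulate_mirnas(
    n: int,
    seed: int,
    length_range: tuple[int, int] = (20, 23),
    gc: float | None = None,
) -> list[SequenceRecord]:
    """Random mature miRNA sequences (RNA alphabet).

    ``gc`` fixes the expected GC fraction (draws per-base from {G,C} with
    probability gc); None gives uniform composition.
    """
    rng = _rng(seed, _STREAM_MIRNAS)
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if gc is None:
            seq = "".join(rng.choice(list("ACGU"), size=length))
        else:
            strong = rng.random(length) < gc
            seq = "".join(
                rng.choice(list("GC")) if s else rng.choice(list("AU"))
                for s in strong
            )
        records.append(SequenceRecord(f"mir-{i + 1:03d}", seq, Alphabet.RNA))
    return records


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_SENSE_CODONS, size=n_codons - 1)
    stop = _CODONS[int(rng.integers(0, 64))]
    while stop not in _STOPS:
        stop = _CODONS[int(rng.integers(0, 64))]
    return "ATG" + "".join(body) + stop


def simulate_references(
    n_taxa: int,
    genome_length: int,
    tree_shape: TreeShape | None = None,
    seed: int = 0,
    n_orfs: int = 4,
    orf_codons: tuple[int, int] = (60, 300),
):
    """Simulate a taxonomy with leaf genomes and ORF-derived proteomes.

    Returns ``(taxonomy, genomes, proteomes, orf_table)`` where ``genomes``
    and ``proteomes`` map leaf ids to a SequenceRecord / list of protein
    SequenceRecords, and ``orf_table`` records every placed ORF (taxon,
    protein_id, start, end; end includes the stop codon).  Leaf genomes are
    i.i.d. uniform over ACGT apart from the ORFs and any shared segments the
    tree shape requests.
    """
    from .taxo import TaxonomyTree

    if n_taxa < 2:
        raise ValueError("n_taxa must be ≥ 2")
    if genome_length < 1000:
        raise ValueError("genome_length must be ≥ 1000")
    tree_shape = tree_shape or TreeShape()
    rng = _rng(seed, _STREAM_REFERENCES)

    leaves = [f"t{i + 1:02d}" for i in range(n_taxa)]
    nodes: dict[str, tuple[str, str, str]] = {"root": ("root", "root", "root")}
    pair_of: dict[str, int] = {}
    for p in range(n_taxa // 2):
        parent = f"g{p + 1:02d}"
        nodes[parent] = ("root", "genus", parent)
        for leaf in leaves[2 * p : 2 * p + 2]:
            nodes[leaf] = (parent, "species", leaf)
            pair_of[leaf] = p
    if n_taxa % 2:
        nodes[leaves[-1]] = ("root", "species", leaves[-1])
    taxonomy = TaxonomyTree(nodes)

    seqs = {
        leaf: rng.choice(list("ACGT"), size=genome_length) for leaf in leaves
    }
    shared_intervals: dict[str, list[tuple[int, int]]] = {l: [] for l in leaves}
    for pair_idx, seg_len in sorted(tree_shape.shared_segments.items()):
        if pair_idx >= n_taxa // 2:
            raise ValueError(f"no sister pair with index {pair_idx}")
        if seg_len >= genome_length:
            raise ValueError("shared segment longer than genome")
        a, b = leaves[2 * pair_idx], leaves[2 * pair_idx + 1]
        start = int(rng.integers(0, genome_length - seg_len + 1))
        seqs[b][start : start + seg_len] = seqs[a][start : start + seg_len]
        for leaf in (a, b):
            shared_intervals[leaf].append((start, start + seg_len))

    orf_rows = []
    for leaf in leaves:
        placed: list[tuple[int, int]] = list(shared_intervals[leaf])
        for o in range(n_orfs):
            n_codons = int(rng.integers(orf_codons[0], orf_codons[1] + 1))
            length = 3 * (n_codons + 1)
            if length >= genome_length:
                raise ValueError(
                    f"genome_length {genome_length} too small for a "
                    f"{n_codons}-codon ORF"
                )
            for _ in range(200):
                start = int(rng.integers(0, genome_length - length + 1))
                if all(start >= e or start + length <= s for s, e in placed):
                    break
            else:
                raise ValueError(
                    "could not place ORFs without overlap; genome too small"
                )
            placed.append((start, start + length))
            orf = _random_orf(rng, n_codons)
            seqs[leaf][start : start + length] = list(orf)
            orf_rows.append((leaf, f"{leaf}.orf{o + 1:02d}", start, start + length))

    genomes = {
        leaf: SequenceRecord(leaf, "".join(seqs[leaf]), Alphabet.DNA)
        for leaf in leaves
    }
    orf_table = pd.DataFrame(
        orf_rows, columns=["taxon_id", "protein_id", "start", "end"]
    )
    proteomes = derive_proteomes(genomes, orf_table)
    return taxonomy, genomes, proteomes, orf_table


def derive_proteomes(
    genomes: dict[str, SequenceRecord], orf_table: pd.DataFrame
) -> dict[str, list[SequenceRecord]]:
    """Translate the annotated ORF intervals of (possibly modified) genomes."""
    proteomes: dict[str, list[SequenceRecord]] = {t: [] for t in genomes}
    for row in orf_table.itertuples():
        cds = genomes[row.taxon_id].sequence[row.start : row.end]
        protein = translate(cds).rstrip("*")
        if "*" in protein:
            raise ValueError(
                f"ORF {row.protein_id} contains an internal stop after "
                "modification; re-plant or avoid the interval"
            )
        proteomes[row.taxon_id].append(
            SequenceRecord(row.protein_id, protein, Alphabet.PROTEIN)
        )
    return proteomes


def _apply_edits(site: str, edits: int, rng: np.random.Generator) -> str:
    """Exactly ``edits`` random substitutions/insertions/deletions."""
    seq = list(site)
    for _ in range(edits):
        op = rng.choice(["sub", "ins", "del"])
        if op == "del" and len(seq) > 1:
            del seq[int(rng.integers(0, len(seq)))]
        elif op == "ins":
            seq.insert(int(rng.integers(0, len(seq) + 1)),
                       str(rng.choice(list("ACGT"))))
        else:
            pos = int(rng.integers(0, len(seq)))
            choices = [c for c in "ACGT" if c != seq[pos]]
            seq[pos] = str(rng.choice(choices))
    return "".join(seq)


def plant_sites(
    genomes: dict[str, SequenceRecord],
    mirnas: list[SequenceRecord],
    sites_per_taxon: int,
    edits: int = 0,
    gc_boost: bool = False,
    seed: int = 0,
    min_separation: int = 300,
    regions: dict[str, list[tuple[int, int]]] | None = None,
    avoid: dict[str, list[tuple[int, int]]] | None = None,
    forbid_stops_in: dict[str, list[tuple[int, int]]] | None = None,
    assignment: str = "per_taxon",
    max_tries: int = 500,
) -> tuple[dict[str, SequenceRecord], list[PlantedSite]]:
    """Write miRNA target sites into genomes and record the truth.

    Each site is the reverse complement of a miRNA in DNA form with exactly
    ``edits`` random edits, written onto the forward strand.  ``gc_boost``
    restricts planting to miRNAs with GC ≥ 0.5 and length ≥ 19 nt — the
    regime in which a recovered site is guaranteed to pass the −20.0
    kcal/mol duplex gate.  ``assignment`` chooses the miRNA per site:
    ``per_taxon`` (taxon i always uses miRNA i mod n, keeping leaf genomes
    disjoint) or ``cycle`` (round-robin across all sites).

    ``regions`` restricts placements to intervals; ``avoid`` excludes
    intervals; ``forbid_stops_in`` lists reading-frame intervals (ORFs) that
    must remain free of internal stop codons after planting — failing
    placements are re-drawn.
    """
    if assignment not in ("per_taxon", "cycle"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    rng = _rng(seed, _STREAM_SITES)
    eligible = mirnas
    if gc_boost:
        eligible = [
            m
            for m in mirnas
            if len(m) >= 19
            and (m.sequence.count("G") + m.sequence.count("C")) / len(m) >= 0.5
        ]
        if not eligible:
            raise ValueError("gc_boost: no miRNA with GC ≥ 0.5 and length ≥ 19")

    out_genomes: dict[str, SequenceRecord] = {}
    truth: list[PlantedSite] = []
    cycle_idx = 0
    for t_idx, (taxon, genome) in enumerate(sorted(genomes.items())):
        seq = list(genome.sequence)
        occupied: list[tuple[int, int]] = list((avoid or {}).get(taxon, []))
        allowed = (regions or {}).get(taxon)
        frames = (forbid_stops_in or {}).get(taxon, [])
        for s_idx in range(sites_per_taxon):
            if assignment == "per_taxon":
                mirna = eligible[t_idx % len(eligible)]
            else:
                mirna = eligible[cycle_idx % len(eligible)]
                cycle_idx += 1
            site_seq = _apply_edits(
                revcomp(mirna.as_dna().sequence), edits, rng
            )
            length = len(site_seq)
            placed = False
            for _ in range(max_tries):
                if allowed:
                    lo, hi = allowed[int(rng.integers(0, len(allowed)))]
                    if hi - lo < length:
                        continue
                    start = int(rng.integers(lo, hi - length + 1))
                else:
                    start = int(rng.integers(0, len(seq) - length + 1))
                end = start + length
                if any(
                    start - min_separation < e and end + min_separation > s
                    for s, e in occupied
                ):
                    continue
                backup = seq[start:end]
                seq[start:end] = list(site_seq)
                ok = True
                for fs, fe in frames:
                    if start < fe and end > fs:
                        protein = translate("".join(seq[fs:fe]))
                        if "*" in protein[:-1]:
                            ok = False
                            break
                if not ok:
                    seq[start:end] = backup
                    continue
                occupied.append((start, end))
                truth.append(
                    PlantedSite(taxon, start, end, mirna.id, edits, "+")
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place site {s_idx} in {taxon} after "
                    f"{max_tries} tries"
                )
        out_genomes[taxon] = SequenceRecord(
            genome.id, "".join(seq), Alphabet.DNA, genome.description
        )
    return out_genomes, truth


def simulate_read_pairs(
    genomes: dict[str, SequenceRecord],
    abundances: dict[str, float],
    n_pairs: int,
    read_length: int = 100,
    insert_length: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str = "S1",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Sample read pairs multinomially from taxon abundances.

    Fragments of ``insert_length`` are placed uniformly on a uniformly
    chosen strand; mate 1 is the fragment start, mate 2 the reverse
    complement of the fragment end; substitution errors are applied per base
    at ``error_rate``.  The truth table records the source taxon, fragment
    strand and each mate's genome interval.
    """
    if insert_length < read_length:
        raise ValueError("insert_length must be ≥ read_length")
    rng = _rng(seed, _STREAM_READS)
    taxa = sorted(genomes)
    probs = np.array([abundances[t] for t in taxa], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("abundances must be nonnegative and sum > 0")
    probs = probs / probs.sum()
    counts = rng.multinomial(n_pairs, probs)

    pairs: list[ReadPair] = []
    rows = []
    pair_no = 0
    for taxon, n_tax in zip(taxa, counts):
        genome = genomes[taxon].sequence
        if len(genome) < insert_length:
            raise ValueError(f"genome {taxon} shorter than insert_length")
        starts = rng.integers(0, len(genome) - insert_length + 1, size=n_tax)
        strands = rng.random(n_tax) < 0.5
        for start, minus in zip(starts, strands):
            start = int(start)
            end = start + insert_length
            fragment = genome[start:end]
            strand = "+"
            if minus:
                fragment = revcomp(fragment)
                strand = "-"
            m1 = fragment[:read_length]
            m2 = revcomp(fragment[-read_length:])
            if error_rate > 0:
                m1 = _add_errors(m1, error_rate, rng)
                m2 = _add_errors(m2, error_rate, rng)
            pair_no += 1
            read_id = f"{sample_id}:p{pair_no:06d}"
            pairs.append(
                ReadPair(
                    read_id,
                    SequenceRecord(f"{read_id}/1", m1, Alphabet.DNA),
                    SequenceRecord(f"{read_id}/2", m2, Alphabet.DNA),
                    sample_id,
                )
            )
            if strand == "+":
                m1_iv = (start, start + read_length)
                m2_iv = (end - read_length, end)
            else:
                m1_iv = (end - read_length, end)
                m2_iv = (start, start + read_length)
            rows.append(
                (read_id, taxon, start, end, strand,
                 m1_iv[0], m1_iv[1], m2_iv[0], m2_iv[1])
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "taxon_id", "frag_start", "frag_end", "strand",
            "mate1_start", "mate1_end", "mate2_start", "mate2_end",
        ],
    )
    return pairs, truth


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        chars[i] = str(rng.choice([c for c in "ACGT" if c != chars[i]]))
    return "".join(chars)


def make_latent_spec(
    n_factors: int,
    n_mirna: int,
    n_taxa: int,
    support: int = 3,
    loading_scale: float = 2.0,
    noise_sd: float = 0.5,
    depth: int = 100_000,
    seed: int = 0,
) -> LatentSpec:
    """Latent spec with disjoint supports of ``support`` features per factor.

    Factor f loads on miRNA features [f·s, (f+1)·s) and taxon features
    likewise, with magnitude ``loading_scale`` and random signs.
    """
    if n_factors * support > min(n_mirna, n_taxa) and n_factors > 0:
        raise ValueError("supports do not fit in the feature space")
    rng = _rng(seed, _STREAM_COUNTS)
    lx = np.zeros((max(n_factors, 1), n_mirna))
    ly = np.zeros((max(n_factors, 1), n_taxa))
    for f in range(n_factors):
        cols = slice(f * support, (f + 1) * support)
        lx[f, cols] = loading_scale * rng.choice([-1.0, 1.0], size=support)
        ly[f, cols] = loading_scale * rng.choice([-1.0, 1.0], size=support)
    return LatentSpec(n_factors, lx, ly, noise_sd, depth)


def simulate_count_matrices(
    n_samples: int,
    n_mirna: int,
    n_taxa: int,
    latent_spec: LatentSpec,
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix, LatentSpec]:
    """Draw paired count matrices sharing the latent factors of the spec.

    Per sample, factor scores are standard normal; log-abundance is
    scores·loadings plus N(0, noise_sd²) per feature; counts are multinomial
    from softmax(log-abundance) at the sequencing depth.
    """
    spec = latent_spec
    if spec.loadings_x.shape[1] != n_mirna or spec.loadings_y.shape[1] != n_taxa:
        raise ValueError("latent spec feature dimensions do not match")
    rng = _rng(seed, _STREAM_COUNTS)
    depth = np.broadcast_to(np.asarray(spec.depth), (n_samples,))

    scores = rng.standard_normal((n_samples, max(spec.n_factors, 1)))
    if spec.n_factors == 0:
        scores = np.zeros((n_samples, 1))

    def _draw(loadings: np.ndarray, n_features: int) -> np.ndarray:
        log_ab = scores @ loadings
        log_ab = log_ab + spec.noise_sd * rng.standard_normal(
            (n_samples, n_features)
        )
        log_ab -= log_ab.max(axis=1, keepdims=True)
        p = np.exp(log_ab)
        p /= p.sum(axis=1, keepdims=True)
        return np.vstack(
            [rng.multinomial(int(depth[s]), p[s]) for s in range(n_samples)]
        )

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    x = CountMatrix(
        samples, [f"mir-{j + 1:03d}" for j in range(n_mirna)],
        _draw(spec.loadings_x, n_mirna),
    )
    y = CountMatrix(
        samples, [f"t{j + 1:02d}" for j in range(n_taxa)],
        _draw(spec.loadings_y, n_taxa),
    )
    return x, y, spec
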