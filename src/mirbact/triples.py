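"""Protein context of candidate read pairs and miRNA/protein/taxon triples.

Each MFE-passing read pair is placed in protein space with a toy-scale
translated (blastx-style) search: the read is translated in all six frames,
exact amino-acid seed matches against the proteome are extended ungapped
under BLOSUM62 with an x-drop, and hits are kept at ≥90% identity and ≥80%
query coverage, at most 25 per read.  The pair's best hit is the
highest-bitscore member of the two mates' hit-list intersection (ties broken
at random with a fixed seed; union fallback when the intersection is empty).
Finally each pair's miRNA, protein and taxon labels are joined into triples
and aggregated per sample, with a PCA over the per-sample triple profiles.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .formats import ReadPair, SequenceRecord, revcomp
from .synth import translate
from .taxo import UNCLASSIFIED

__all__ = [
    "ProteinSearchConfig",
    "ProteinHit",
    "TripleCount",
    "translated_search",
    "assign_best_hit",
    "build_triples",
    "pca_triples",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ProteinSearchConfig:
    """Thresholds and scoring constants of the translated search.

    Identity/coverage/hit-cap are the study's 90% / 80% / 25 rules;
    karlin_lambda and karlin_k are ungapped BLOSUM62 Karlin–Altschul
    constants, used only to express scores as bitscores (ranking is
    invariant to this affine transform).
    """

    min_identity: float = 0.90
    min_query_coverage: float = 0.80
    max_hits_per_read: int = 25
    seed_length: int = 4
    karlin_lambda: float = 0.3176
    karlin_k: float = 0.134
    xdrop: float = 12.0
    coverage_basis: str = "nt"  # "nt" (aligned aa × 3 / read nt) or "aa"

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_hits_per_read < 1:
            raise ValueError("max_hits_per_read must be ≥ 1")
        if self.coverage_basis not in ("nt", "aa"):
            raise ValueError("coverage_basis must be 'nt' or 'aa'")


@dataclass(frozen=True)
class ProteinHit:
    read_id: str
    mate: int
    protein_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    identity: float
    query_coverage: float
    raw_score: float
    bitscore: float


@dataclass
class TripleCount:
    """(sample, miRNA, protein, taxon) → count."""

    entries: pd.DataFrame  # sample_id, mirna_id, protein_id, taxon_id, count

    def __post_init__(self) -> None:
        if (self.entries["count"] < 0).any():
            raise ValueError("triple counts must be ≥ 0")

    def to_matrix(self) -> pd.DataFrame:
        """Samples × triples matrix; triple labels join the three ids."""
        df = self.entries.copy()
        df["triple"] = (
            df["mirna_id"] + "|" + df["protein_id"] + "|" + df["taxon_id"]
        )
        return df.pivot_table(
            index="sample_id", columns="triple", values="count",
            aggfunc="sum", fill_value=0,
        )


def _six_frames(seq: str) -> list[tuple[int, int, str]]:
    """(frame, nt_offset, protein) for all six frames of a DNA read."""
    frames = []
    rc = revcomp(seq)
    for off in range(3):
        frames.append((off + 1, off, translate(seq[off:])))
        frames.append((-(off + 1), off, translate(rc[off:])))
    return frames


class ProteinIndex:
    """Exact amino-acid seed index over a set of proteins."""

    def __init__(self, proteins: Sequence[SequenceRecord], seed_length: int = 4):
        if not proteins:
            raise ValueError("proteins must be nonempty")
        self.seed_length = seed_length
        self.proteins = list(proteins)
        self.seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for pi, prot in enumerate(self.proteins):
            seq = prot.sequence
            for i in range(len(seq) - seed_length + 1):
                self.seeds[seq[i : i + seed_length]].append((pi, i))


def _extend_ungapped(
    query: str, subject: str, q0: int, s0: int, k: int, xdrop: float
) -> tuple[int, int, float, int]:
    """X-drop ungapped extension of a length-k seed both ways.

    Returns (q_start, aligned_length, score, matches) on the query frame.
    """
    score = sum(_BLOSUM62[query[q0 + i], subject[s0 + i]] for i in range(k))
    best = score
    # right
    qi, si = q0 + k, s0 + k
    best_right = 0
    cur = 0
    i = 0
    while qi + i < len(query) and si + i < len(subject):
        cur += _BLOSUM62[query[qi + i], subject[si + i]]
        if cur > best_right:
            best_right, right_ext = cur, i + 1
        if best_right - cur > xdrop:
            break
        i += 1
    right_ext = right_ext if best_right > 0 else 0
    # left
    best_left = 0
    cur = 0
    i = 1
    left_ext = 0
    while q0 - i >= 0 and s0 - i >= 0:
        cur += _BLOSUM62[query[q0 - i], subject[s0 - i]]
        if cur > best_left:
            best_left, left_ext = cur, i
        if best_left - cur > xdrop:
            break
        i += 1
    left_ext = left_ext if best_left > 0 else 0
    q_start = q0 - left_ext
    length = left_ext + k + right_ext
    total = sum(
        _BLOSUM62[query[q_start + i], subject[s0 - left_ext + i]]
        for i in range(length)
    )
    matches = sum(
        query[q_start + i] == subject[s0 - left_ext + i] for i in range(length)
    )
    return q_start, length, float(total), matches


def translated_search(
    read: SequenceRecord,
    proteins: Sequence[SequenceRecord] | ProteinIndex,
    cfg: ProteinSearchConfig | None = None,
    mate: int = 1,
) -> list[ProteinHit]:
    """Six-frame seeded ungapped search of one read against a proteome.

    Stop codons break the translated query into segments, each searched
    separately.  Hits below the identity or coverage thresholds are dropped;
    survivors are sorted by bitscore (descending, then protein id for
    determinism) and truncated to the per-read cap.
    """
    cfg = cfg or ProteinSearchConfig()
    index = (
        proteins
        if isinstance(proteins, ProteinIndex)
        else ProteinIndex(proteins, cfg.seed_length)
    )
    seq = read.sequence
    if len(seq) < 3 * cfg.seed_length:
        return []
    k = cfg.seed_length
    ln2 = math.log(2.0)
    best_per_protein: dict[str, ProteinHit] = {}
    for frame, _off, protein_query in _six_frames(seq):
        # stop codons break the frame into independently searched segments
        for segment in protein_query.split("*"):
            if len(segment) >= k:
                seen_diag: set[tuple[int, int]] = set()
                for i in range(len(segment) - k + 1):
                    for pi, sj in index.seeds.get(segment[i : i + k], ()):
                        diag = (pi, sj - i)
                        if diag in seen_diag:
                            continue
                        seen_diag.add(diag)
                        subject = index.proteins[pi].sequence
                        q_start, length, score, matches = _extend_ungapped(
                            segment, subject, i, sj, k, cfg.xdrop
                        )
                        identity = matches / length
                        if cfg.coverage_basis == "nt":
                            coverage = length * 3 / len(seq)
                        else:
                            coverage = length / (len(seq) // 3)
                        if identity < cfg.min_identity or \
                                coverage < cfg.min_query_coverage:
                            continue
                        bitscore = (cfg.karlin_lambda * score
                                    - math.log(cfg.karlin_k)) / ln2
                        hit = ProteinHit(
                            read.id, mate, index.proteins[pi].id, frame,
                            identity, min(coverage, 1.0), score, bitscore,
                        )
                        prev = best_per_protein.get(hit.protein_id)
                        if prev is None or hit.bitscore > prev.bitscore:
                            best_per_protein[hit.protein_id] = hit
    hits = sorted(
        best_per_protein.values(), key=lambda h: (-h.bitscore, h.protein_id)
    )
    return hits[: cfg.max_hits_per_read]


def assign_best_hit(
    hits1: Sequence[ProteinHit],
    hits2: Sequence[ProteinHit],
    seed: int = 0,
) -> ProteinHit | None:
    """Select the pair's final protein hit.

    Intersection (by protein id) of the mates' hit lists, scored per protein
    as the max bitscore over the two mates, wins; bitscore ties are broken
    uniformly at random with ``seed``.  An empty intersection falls back to
    the maximum-bitscore element of the union; two empty lists give None.
    """
    by_protein: dict[str, ProteinHit] = {}
    for hit in list(hits1) + list(hits2):
        prev = by_protein.get(hit.protein_id)
        if prev is None or hit.bitscore > prev.bitscore:
            by_protein[hit.protein_id] = hit
    if not by_protein:
        return None
    ids1 = {h.protein_id for h in hits1}
    ids2 = {h.protein_id for h in hits2}
    pool_ids = ids1 & ids2 or set(by_protein)
    pool = [by_protein[pid] for pid in sorted(pool_ids)]
    top = max(h.bitscore for h in pool)
    tied = [h for h in pool if h.bitscore == top]
    if len(tied) == 1:
        return tied[0]
    rng = np.random.default_rng(seed)
    return tied[int(rng.integers(0, len(tied)))]


def build_triples(
    best_hits: Mapping[str, ProteinHit | None],
    passing_mirnas: Mapping[str, set[str]],
    assignments: pd.DataFrame,
    sample_of: Mapping[str, str],
) -> TripleCount:
    """Join per-pair miRNA, protein and taxon labels into counted triples.

    ``best_hits`` and ``passing_mirnas`` are keyed by pair id;
    ``passing_mirnas`` lists the miRNAs with an MFE-passing site on either
    mate.  A pair lacking any of the three labels contributes nothing; a
    pair with several passing miRNAs contributes one count per miRNA.
    """
    taxon_of = dict(zip(assignments["read_id"], assignments["node_id"]))
    counts: dict[tuple[str, str, str, str], int] = {}
    for pair_id, mirnas in passing_mirnas.items():
        hit = best_hits.get(pair_id)
        taxon = taxon_of.get(pair_id)
        if hit is None or taxon is None or taxon == UNCLASSIFIED:
            continue
        sample = sample_of.get(pair_id)
        if sample is None:
            raise ValueError(f"no sample label for pair {pair_id!r}")
        for mirna in sorted(mirnas):
            key = (sample, mirna, hit.protein_id, taxon)
            counts[key] = counts.get(key, 0) + 1
    entries = pd.DataFrame(
        [(s, m, p, t, c) for (s, m, p, t), c in sorted(counts.items())],
        columns=["sample_id", "mirna_id", "protein_id", "taxon_id", "count"],
    )
    return TripleCount(entries)


def pca_triples(
    matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the samples × triples count matrix.

    Columns are centered; components are ordered by decreasing explained
    variance with the sign convention that each component's largest-|loading|
    entry is positive.  Returns (scores, loadings, explained_variance).
    """
    from sklearn.decomposition import PCA

    values = np.asarray(matrix, dtype=float)
    n_samples = values.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs ≥ 2 samples")
    if n_components is None:
        n_components = min(n_samples - 1, values.shape[1])
    if n_components > min(n_samples, values.shape[1]):
        raise ValueError("more components requested than data support")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(values)
    loadings = pca.components_
    for h in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[h]))
        if loadings[h, j] < 0:
            loadings[h] *= -1
            scores[:, h] *= -1
    return scores, loadings, pca.explained_variance_
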