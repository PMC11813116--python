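"""Kraken-style k-mer LCA taxonomic classification of read pairs.

A reference database maps every canonical k-mer of the labeled genomes to
the lowest common ancestor (LCA) of all leaves whose genomes contain it.  A
read pair is classified to the leaf-to-root path with the greatest total
mapped-k-mer weight; the assignment's confidence is the fraction of the
pair's k-mers (mapped or not) that fall inside the clade of the assigned
node, and the label moves rootward until the confidence threshold is met or
the pair is left unclassified.

Compared to Kraken 2 this stand-in uses plain canonical k-mers rather than
minimizers and spaced seeds; the classification semantics (LCA mapping,
path score, confidence definition) are the same.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .formats import FormatError, ReadPair, SequenceRecord, revcomp

__all__ = [
    "TaxonomyTree",
    "KmerDB",
    "TaxonAssignment",
    "UNCLASSIFIED",
    "build_kmer_db",
    "classify_read",
    "classify_pairs",
]

UNCLASSIFIED = "unclassified"


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: node_id → (parent_id, rank, name); root is its own parent."""

    nodes: dict[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        roots = [n for n, (p, _, _) in self.nodes.items() if p == n]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, got {roots}")
        self.root = roots[0]
        for node, (parent, _, _) in self.nodes.items():
            if parent not in self.nodes:
                raise ValueError(f"node {node!r} references unknown parent {parent!r}")
        # cycle check: every node must reach the root
        for node in self.nodes:
            seen = set()
            while node != self.root:
                if node in seen:
                    raise ValueError(f"cycle in taxonomy at {node!r}")
                seen.add(node)
                node = self.parent(node)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TaxonomyTree":
        return cls({
            str(r.node_id): (str(r.parent_id), str(r.rank), str(r.name))
            for r in table.itertuples()
        })

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, p, r, nm) for n, (p, r, nm) in sorted(self.nodes.items())],
            columns=["node_id", "parent_id", "rank", "name"],
        )

    def parent(self, node: str) -> str:
        return self.nodes[node][0]

    def path_to_root(self, node: str) -> list[str]:
        """Node and all its ancestors, leaf side first, root last."""
        path = [node]
        while node != self.root:
            node = self.parent(node)
            path.append(node)
        return path

    def lca(self, a: str, b: str) -> str:
        ancestors = set(self.path_to_root(a))
        for node in self.path_to_root(b):
            if node in ancestors:
                return node
        return self.root

    def is_ancestor(self, anc: str, node: str) -> bool:
        return anc in self.path_to_root(node)

    def leaves(self) -> list[str]:
        parents = {p for n, (p, _, _) in self.nodes.items() if p != n}
        return sorted(n for n in self.nodes if n not in parents)


@dataclass
class KmerDB:
    """Canonical k-mer → LCA node map over a taxonomy."""

    k: int
    mapping: dict[str, str]
    tree: TaxonomyTree

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 11 <= self.k <= 31:
            raise ValueError("k must be odd and within 11–31")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#mirbact-kmerdb\tv1\tk={self.k}\n")
            for kmer, node in sorted(self.mapping.items()):
                fh.write(f"{kmer}\t{node}\n")

    @classmethod
    def load(cls, path: str | Path, tree: TaxonomyTree) -> "KmerDB":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["#mirbact-kmerdb", "v1"]:
                raise FormatError(f"{path}: not a v1 k-mer DB")
            k = int(header[2].removeprefix("k="))
            mapping = {}
            for line in fh:
                kmer, node = line.rstrip("\n").split("\t")
                mapping[kmer] = node
        return cls(k, mapping, tree)


@dataclass(frozen=True)
class TaxonAssignment:
    read_id: str
    node_id: str  # a taxonomy node or UNCLASSIFIED
    confidence: float


def canonical_kmers(seq: str, k: int) -> list[str]:
    """Canonical (lexicographic min of k-mer and reverse complement) k-mers."""
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        out.append(min(kmer, revcomp(kmer)))
    return out


def build_kmer_db(
    genomes: Sequence[tuple[str, SequenceRecord]] | dict[str, SequenceRecord],
    taxonomy: TaxonomyTree,
    k: int = 21,
) -> KmerDB:
    """Map each canonical k-mer to the LCA of the leaves containing it.

    ``genomes`` associates leaf node ids with genome sequences.
    """
    items = genomes.items() if isinstance(genomes, dict) else genomes
    mapping: dict[str, str] = {}
    for node, genome in items:
        if node not in taxonomy.nodes:
            raise ValueError(f"genome labeled with unknown node {node!r}")
        for kmer in set(canonical_kmers(genome.sequence, k)):
            prev = mapping.get(kmer)
            mapping[kmer] = node if prev is None else taxonomy.lca(prev, node)
    return KmerDB(k, mapping, taxonomy)


def classify_read(
    db: KmerDB, pair: ReadPair, confidence_threshold: float = 0.1
) -> TaxonAssignment:
    """Classify one read pair; both mates' k-mers are pooled.

    The candidate label maximizes the total mapped-k-mer weight on its
    root-to-leaf path (ties broken by smallest node id); it is then walked
    rootward until the clade confidence reaches the threshold.
    """
    kmers = canonical_kmers(pair.mate1.sequence, db.k) + canonical_kmers(
        pair.mate2.sequence, db.k
    )
    total = len(kmers)
    weights: dict[str, int] = {}
    for kmer in kmers:
        node = db.mapping.get(kmer)
        if node is not None:
            weights[node] = weights.get(node, 0) + 1
    if not weights or total == 0:
        return TaxonAssignment(pair.id, UNCLASSIFIED, 0.0)
    tree = db.tree
    # best leaf-to-root path: sum of weights of nodes on the path
    candidates: set[str] = set()
    for node in weights:
        candidates.update(tree.path_to_root(node))
    best_node = None
    best_key: tuple[int, int] = (-1, 0)
    for node in sorted(candidates):
        path = tree.path_to_root(node)
        score = sum(weights.get(anc, 0) for anc in path)
        # among equally weighted paths prefer the shallowest node (so a pair
        # whose evidence sits entirely on an internal node is assigned there,
        # not to an arbitrary descendant leaf); sorted iteration with a
        # strict comparison breaks remaining ties by smallest node id
        key = (score, -len(path))
        if best_node is None or key > best_key:
            best_node, best_key = node, key
    label = best_node
    # clade confidence, moving rootward until the threshold is met
    while True:
        in_clade = sum(
            w for node, w in weights.items() if tree.is_ancestor(label, node)
        )
        confidence = in_clade / total
        if confidence >= confidence_threshold:
            return TaxonAssignment(pair.id, label, confidence)
        if label == tree.root:
            return TaxonAssignment(pair.id, UNCLASSIFIED, confidence)
        label = tree.parent(label)


def classify_pairs(
    db: KmerDB, pairs: Iterable[ReadPair], confidence_threshold: float = 0.1
) -> pd.DataFrame:
    """Classify many pairs; returns a table read_id, node_id, confidence."""
    rows = [
        classify_read(db, pair, confidence_threshold) for pair in pairs
    ]
    return pd.DataFrame(
        [(a.read_id, a.node_id, a.confidence) for a in rows],
        columns=["read_id", "node_id", "confidence"],
    )
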