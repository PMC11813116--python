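"""Inclusion filters and per-sample miRNA × taxon hit aggregation.

Implements the study's retention rules — features kept when they reach a
minimum read count in a minimum fraction of samples of at least one group,
samples kept when their miRNA and classified-metagenome totals reach the
per-sample-type minima — and aggregates MFE-passing, taxon-labeled
candidate sites into hit tables, with each mate of a pair counted
independently and unclassified reads excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .duplex import DuplexConfig, DuplexResult, call_hit
from .formats import CountMatrix
from .screen import CandidateSite
from .taxo import UNCLASSIFIED, TaxonomyTree

__all__ = [
    "FilterConfig",
    "HitTable",
    "select_features",
    "select_samples",
    "aggregate_hits",
    "display_filter",
]


@dataclass(frozen=True)
class FilterConfig:
    """All count/sample inclusion thresholds, at their study defaults."""

    mirna_min_reads: int = 10
    mirna_min_frac: float = 0.10
    taxon_min_reads: int = 100
    fecal_min_mirna_reads: int = 1000
    fecal_min_metagenome_reads: int = 100_000
    mucosal_min_reads: int = 2000
    screen_min_total_mirna_reads: int = 1000
    display_min_hits: int = 10
    frac_rounding: str = "ceil"  # how "10% of samples" is counted

    def __post_init__(self) -> None:
        for name in (
            "mirna_min_reads", "taxon_min_reads", "fecal_min_mirna_reads",
            "fecal_min_metagenome_reads", "mucosal_min_reads",
            "screen_min_total_mirna_reads", "display_min_hits",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.frac_rounding not in ("ceil", "floor"):
            raise ValueError("frac_rounding must be 'ceil' or 'floor'")


@dataclass
class HitTable:
    """(sample, miRNA, taxon) → hit count, with per-sample totals."""

    entries: pd.DataFrame  # columns: sample_id, mirna_id, taxon_id, count

    def __post_init__(self) -> None:
        required = ["sample_id", "mirna_id", "taxon_id", "count"]
        if list(self.entries.columns) != required:
            self.entries = self.entries[required]
        if (self.entries["count"] < 0).any():
            raise ValueError("hit counts must be ≥ 0")

    def sample_totals(self) -> pd.Series:
        return self.entries.groupby("sample_id")["count"].sum()

    def summary(self) -> dict[str, float]:
        """Median and IQR of per-sample hit totals."""
        totals = self.sample_totals()
        if totals.empty:
            return {"median_hits_per_sample": math.nan, "iqr_hits_per_sample": math.nan}
        q1, q3 = totals.quantile([0.25, 0.75])
        return {
            "median_hits_per_sample": float(totals.median()),
            "iqr_hits_per_sample": float(q3 - q1),
        }

    def to_matrix(self, sample_id: str | None = None) -> pd.DataFrame:
        df = self.entries
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        return df.pivot_table(
            index="mirna_id", columns="taxon_id", values="count",
            aggfunc="sum", fill_value=0,
        )


def _min_samples(n: int, frac: float, rounding: str) -> int:
    return math.ceil(frac * n) if rounding == "ceil" else math.floor(frac * n)


def select_features(
    matrix: CountMatrix,
    min_reads: int,
    min_frac: float,
    groups: Mapping[str, Sequence[str]] | None = None,
    frac_rounding: str = "ceil",
) -> list[str]:
    """Features with ≥ min_reads in ≥ min_frac of samples of some group.

    ``groups`` maps group labels to sample-id lists (e.g. the two diet
    groups); when absent the rule is applied over all samples.
    """
    if not matrix.sample_ids:
        raise ValueError("empty count matrix")
    df = matrix.to_frame()
    group_frames = [df] if groups is None else []
    if groups is not None:
        for label, samples in groups.items():
            unknown = set(samples) - set(matrix.sample_ids)
            if unknown:
                raise ValueError(f"group {label!r}: unknown samples {sorted(unknown)}")
            group_frames.append(df.loc[list(samples)])
    keep = pd.Series(False, index=df.columns)
    for gdf in group_frames:
        need = _min_samples(len(gdf), min_frac, frac_rounding)
        keep |= (gdf >= min_reads).sum(axis=0) >= need
    return [f for f in matrix.feature_ids if keep[f]]


def select_samples(
    mirna_matrix: CountMatrix,
    metagenome_totals: Mapping[str, int],
    sample_type: str,
    cfg: FilterConfig | None = None,
) -> list[str]:
    """Samples whose miRNA and classified-metagenome totals pass the minima.

    Fecal samples need ≥ 1000 miRNA and ≥ 100 000 classified metagenomic
    reads; mucosal samples need ≥ 2000 of each.
    """
    cfg = cfg or FilterConfig()
    if sample_type == "fecal":
        min_mirna, min_meta = cfg.fecal_min_mirna_reads, cfg.fecal_min_metagenome_reads
    elif sample_type == "mucosal":
        min_mirna = min_meta = cfg.mucosal_min_reads
    else:
        raise ValueError(f"unknown sample_type {sample_type!r}")
    missing = set(mirna_matrix.sample_ids) - set(metagenome_totals)
    if missing:
        raise ValueError(f"no metagenome totals for samples {sorted(missing)}")
    mirna_totals = mirna_matrix.totals()
    return [
        s
        for s in mirna_matrix.sample_ids
        if mirna_totals[s] >= min_mirna and metagenome_totals[s] >= min_meta
    ]


def aggregate_hits(
    sites: Sequence[CandidateSite],
    duplex_results: Mapping[tuple, DuplexResult] | Sequence[DuplexResult],
    assignments: pd.DataFrame,
    duplex_cfg: DuplexConfig | None = None,
    taxonomy: TaxonomyTree | None = None,
    level: str | None = None,
) -> HitTable:
    """Count MFE-passing, classified sites per (sample, miRNA, taxon).

    ``duplex_results`` is either parallel to ``sites`` or keyed by
    ``(mirna_id, read_id, mate, orientation)``.  ``assignments`` is the
    classifier output keyed by pair id (mate read ids with /1 or /2 suffixes
    are resolved to the pair).  Each mate contributes independently;
    unclassified reads contribute nothing.  With ``taxonomy`` and ``level``
    set, labels are rolled up to the first ancestor of that rank.
    """
    duplex_cfg = duplex_cfg or DuplexConfig()
    if not isinstance(duplex_results, Mapping):
        if len(duplex_results) != len(sites):
            raise ValueError("duplex_results must parallel sites")
        duplex_results = {
            (s.mirna_id, s.read_id, s.mate, s.orientation): r
            for s, r in zip(sites, duplex_results)
        }
    taxon_of = dict(zip(assignments["read_id"], assignments["node_id"]))

    def _roll_up(node: str) -> str:
        if taxonomy is None or level is None or node == UNCLASSIFIED:
            return node
        for anc in taxonomy.path_to_root(node):
            if taxonomy.nodes[anc][1] == level:
                return anc
        return UNCLASSIFIED

    counts: dict[tuple[str, str, str], int] = {}
    # one hit per (mirna, read, mate): a mate matching in both orientations
    # is still a single read-level hit
    counted: set[tuple[str, str, int]] = set()
    for site in sites:
        key = (site.mirna_id, site.read_id, site.mate, site.orientation)
        result = duplex_results.get(key)
        if result is None:
            raise ValueError(f"site {key} has no duplex result")
        if not call_hit(result, duplex_cfg):
            continue
        pair_id = site.read_id.removesuffix("/1").removesuffix("/2")
        taxon = taxon_of.get(pair_id, taxon_of.get(site.read_id))
        if taxon is None:
            raise ValueError(f"site references unknown read {site.read_id!r}")
        if taxon == UNCLASSIFIED:
            continue
        read_key = (site.mirna_id, site.read_id, site.mate)
        if read_key in counted:
            continue
        counted.add(read_key)
        taxon = _roll_up(taxon)
        if taxon == UNCLASSIFIED:
            continue
        entry = (site.sample_id, site.mirna_id, taxon)
        counts[entry] = counts.get(entry, 0) + 1
    entries = pd.DataFrame(
        [(s, m, t, c) for (s, m, t), c in sorted(counts.items())],
        columns=["sample_id", "mirna_id", "taxon_id", "count"],
    )
    return HitTable(entries)


def display_filter(table: HitTable, min_hits: int = 10) -> HitTable:
    """Keep taxa with at least ``min_hits`` total hits for some miRNA."""
    df = table.entries
    if df.empty:
        return HitTable(df.copy())
    per = df.groupby(["taxon_id", "mirna_id"])["count"].sum()
    keep = {t for (t, _m), c in per.items() if c >= min_hits}
    return HitTable(df[df["taxon_id"].isin(keep)].reset_index(drop=True))
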