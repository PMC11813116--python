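"""Candidate miRNA binding-site screening in metagenomic reads.

The screen admits a read when the miRNA's target-complementary sequence fits
somewhere inside it within a bounded number of edits (mismatches or indels).
The alignment is semi-global ("fit"): the full pattern is embedded in the
read with free end gaps on the read only, so the edit budget always refers
to the whole miRNA — edits cannot be hidden by clipping miRNA ends.

Since identical sequences do not hybridize, the pattern used by default is
the reverse complement of the miRNA in DNA form, scanned against both read
orientations; ``pattern="identity"`` preserves the literal
screen-with-the-miRNA reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .formats import ReadPair, SequenceRecord, dna_to_rna, revcomp

__all__ = [
    "ScreenConfig",
    "CandidateSite",
    "fit_edit_distance",
    "batch_fit_distances",
    "screen_read",
    "screen_sample",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Screening thresholds.

    max_edits: admit a window iff its fit edit distance is ≤ this (default 3).
    pattern: "revcomp" scans for the reverse complement of the miRNA
        (hybridization-consistent, default); "identity" scans for the miRNA
        sequence itself.
    min_mirna_reads / min_sample_frac: the upstream miRNA inclusion filter
        (≥10 reads in ≥10% of samples) applied by the hits module before
        screening.
    """

    max_edits: int = 3
    pattern: Literal["revcomp", "identity"] = "revcomp"
    min_mirna_reads: int = 10
    min_sample_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.max_edits < 0:
            raise ValueError("max_edits must be ≥ 0")
        if not 0 < self.min_sample_frac <= 1:
            raise ValueError("min_sample_frac must be in (0, 1]")
        if self.pattern not in ("revcomp", "identity"):
            raise ValueError(f"unknown pattern mode {self.pattern!r}")


@dataclass(frozen=True)
class CandidateSite:
    """A (miRNA, read, window) match surviving the edit screen.

    ``start``/``end`` are 0-based half-open coordinates on the read *as
    stored* (mate sequence as written in the FASTQ); ``orientation`` records
    which strand of the read matched.  ``target_rna`` is the matched window
    5'→3' on the matching strand, in RNA characters — the sequence handed to
    the duplex stage.
    """

    mirna_id: str
    read_id: str
    mate: int
    orientation: Literal["forward", "revcomp"]
    start: int
    end: int
    edit_distance: int
    target_rna: str
    sample_id: str = ""


def fit_edit_distance(pattern: str, text: str) -> tuple[int, tuple[int, int], str]:
    """Best fit of the full ``pattern`` inside ``text`` under unit edit costs.

    Returns ``(distance, (start, end), trace)`` where ``[start, end)`` is the
    text window achieving the minimum cost and ``trace`` is the alignment
    operation string over the window (M match, X mismatch, I insertion of a
    text base, D deletion of a pattern base).  Ties are broken by leftmost
    start, then shortest window.
    """
    if not pattern:
        raise ValueError("empty pattern")
    m, n = len(pattern), len(text)
    INF = m + n + 1
    # cell value = (cost, start); lexicographic minimisation propagates the
    # leftmost optimal start for every end column
    cost = [[0] * (n + 1) for _ in range(m + 1)]
    start = [[0] * (n + 1) for _ in range(m + 1)]
    op = [[""] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        start[0][j] = j
    for i in range(1, m + 1):
        cost[i][0] = i
        op[i][0] = "D"
    for i in range(1, m + 1):
        pi = pattern[i - 1]
        row, prow = cost[i], cost[i - 1]
        srow, psrow = start[i], start[i - 1]
        orow = op[i]
        for j in range(1, n + 1):
            sub = prow[j - 1] + (0 if pi == text[j - 1] else 1)
            best_c, best_s = sub, psrow[j - 1]
            best_o = "M" if pi == text[j - 1] else "X"
            dele = prow[j] + 1
            if dele < best_c or (dele == best_c and psrow[j] < best_s):
                best_c, best_s, best_o = dele, psrow[j], "D"
            ins = row[j - 1] + 1
            if ins < best_c or (ins == best_c and srow[j - 1] < best_s):
                best_c, best_s, best_o = ins, srow[j - 1], "I"
            row[j], srow[j], orow[j] = best_c, best_s, best_o
    # pick end: min cost, then leftmost start, then shortest window
    best = min(range(n + 1), key=lambda j: (cost[m][j], start[m][j], j))
    dist, s = cost[m][best], start[m][best]
    # traceback from (m, best)
    ops = []
    i, j = m, best
    while i > 0:
        o = op[i][j]
        ops.append(o)
        if o in ("M", "X"):
            i, j = i - 1, j - 1
        elif o == "D":
            i -= 1
        else:
            j -= 1
    trace = "".join(reversed(ops))
    return dist, (s, best), trace


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def batch_fit_distances(pattern: str, texts: np.ndarray) -> np.ndarray:
    """Minimum fit edit distance of ``pattern`` against many equal-length texts.

    ``texts`` is a (n_texts, text_len) uint8 array of ASCII codes.  Returns
    the distance per text; used for throughput in :func:`screen_sample`, with
    :func:`fit_edit_distance` re-run on the survivors for the window and trace.

    Row recurrence: after taking substitution/deletion minima, insertions
    (which consume text) are closed with a running ``min(base[k] + (j - k))``
    scan, implemented as an accumulate over ``base[j] - j``.
    """
    if texts.ndim != 2:
        raise ValueError("texts must be 2-D (n_texts, text_len)")
    n_texts, n = texts.shape
    m = len(pattern)
    pat = _encode(pattern)
    offsets = np.arange(n + 1)
    prev = np.zeros((n_texts, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i
        mismatch = (texts != pat[i - 1]).astype(np.int32)
        base = np.minimum(prev[:, :-1] + mismatch, prev[:, 1:] + 1)
        cur[:, 1:] = base
        # close insertions left-to-right
        shifted = cur - offsets[None, :]
        np.minimum.accumulate(shifted, axis=1, out=shifted)
        cur = shifted + offsets[None, :]
        prev = cur
    return prev.min(axis=1)


def _pattern_for(mirna: SequenceRecord, cfg: ScreenConfig) -> str:
    dna = mirna.as_dna().sequence
    return revcomp(dna) if cfg.pattern == "revcomp" else dna


def screen_read(
    mirna: SequenceRecord, read: SequenceRecord, cfg: ScreenConfig | None = None,
    mate: int = 1, sample_id: str = "",
) -> list[CandidateSite]:
    """Scan one read (both orientations) for one miRNA.

    At most one site per orientation is reported — the best-fit window; the
    hit unit downstream is the read, not the site.
    """
    cfg = cfg or ScreenConfig()
    pattern = _pattern_for(mirna, cfg)
    seq = read.as_dna().sequence
    sites: list[CandidateSite] = []
    for orientation, text in (("forward", seq), ("revcomp", revcomp(seq))):
        dist, (s, e), _ = fit_edit_distance(pattern, text)
        if dist <= cfg.max_edits:
            if orientation == "forward":
                start, end = s, e
            else:  # map window back onto the stored read
                start, end = len(seq) - e, len(seq) - s
            sites.append(
                CandidateSite(
                    mirna_id=mirna.id,
                    read_id=read.id,
                    mate=mate,
                    orientation=orientation,
                    start=start,
                    end=end,
                    edit_distance=dist,
                    target_rna=dna_to_rna(text[s:e]),
                    sample_id=sample_id,
                )
            )
    return sites


def screen_sample(
    mirnas: Sequence[SequenceRecord],
    pairs: Sequence[ReadPair],
    cfg: ScreenConfig | None = None,
) -> list[CandidateSite]:
    """Screen every mate of every pair against every miRNA.

    Mates are screened independently (each mate of a pair can contribute its
    own hit).  Output is sorted by (mirna_id, read_id, mate).  Equal-length
    mates are batched through the vectorised DP; survivors are re-aligned
    with the scalar DP to obtain windows and traces.
    """
    cfg = cfg or ScreenConfig()
    if not pairs:
        return []
    reads: list[tuple[SequenceRecord, int, str]] = []
    for pair in pairs:
        reads.append((pair.mate1, 1, pair.sample_id))
        reads.append((pair.mate2, 2, pair.sample_id))

    # group by read length so each group is a rectangular array
    by_len: dict[int, list[int]] = {}
    for idx, (rec, _, _) in enumerate(reads):
        by_len.setdefault(len(rec.sequence), []).append(idx)
    flagged: set[tuple[int, int]] = set()  # (mirna index, read index)
    for length, idxs in by_len.items():
        fwd = np.vstack([_encode(reads[i][0].sequence) for i in idxs])
        rev = np.vstack([_encode(revcomp(reads[i][0].sequence)) for i in idxs])
        for mi, mirna in enumerate(mirnas):
            pattern = _pattern_for(mirna, cfg)
            for oriented in (fwd, rev):
                dists = batch_fit_distances(pattern, oriented)
                for k in np.flatnonzero(dists <= cfg.max_edits):
                    flagged.add((mi, idxs[k]))
    sites: list[CandidateSite] = []
    for mi, ri in sorted(flagged):
        rec, mate, sample_id = reads[ri]
        sites.extend(screen_read(mirnas[mi], rec, cfg, mate, sample_id))
    sites.sort(key=lambda s: (s.mirna_id, s.read_id, s.mate, s.orientation))
    return sites
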