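"""Nearest-neighbor minimum free energy of a miRNA:target RNA duplex.

The model scores intermolecular base pairing only (no intramolecular
structure): a duplex is an antiparallel-monotone set of base pairs
(Watson–Crick plus GU wobble) and its free energy is

    dG = duplex_init + Σ stacking energies of adjacent pairs
       + Σ bulge / internal-loop penalties for unpaired stretches
       + terminal AU/GU penalties at both helix ends.

Stacking energies are the published Turner-2004 values for Watson–Crick and
GU stacks; loop penalties use an affine approximation (opening + per-base
extension + asymmetry), with loop spans capped so the dynamic program stays
quadratic.  No stacking bonus is applied across a loop.  All constants can
be overridden from a TSV parameter file.

A candidate read window is called a *hit* when its duplex MFE is at or below
the −20.0 kcal/mol gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PAIR_TYPES",
    "EnergyParams",
    "DuplexConfig",
    "DuplexResult",
    "load_energy_params",
    "duplex_mfe",
    "call_hit",
]

_RNA_CHARS = frozenset("ACGU")

# pair type order used by the stacking matrix
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
_PT = {p: i for i, p in enumerate(PAIR_TYPES)}

# Turner-2004 stacking free energies, kcal/mol at 37 °C, in the convention
# E(outer pair (x1,y1), inner pair (x2,y2)) = STACK[pt(x1,y1)][pt(y2,x2)]
# (the matrix is symmetric under that indexing).
_TURNER2004_STACK = np.array(
    [
        #  CG     GC     GU     UG     AU     UA
        [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],  # CG
        [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],  # GC
        [-2.10, -2.50,  1.30, -0.50, -1.40, -1.30],  # GU
        [-1.40, -1.50, -0.50,  0.30, -0.60, -1.00],  # UG
        [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],  # AU
        [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # UA
    ]
)

_WOBBLE = frozenset({"GU", "UG"})


def _default_bulge(length: int) -> float:
    return 3.3 + 0.5 * length


def _default_internal(len1: int, len2: int) -> float:
    return 1.7 + 0.4 * (len1 + len2) + 0.3 * abs(len1 - len2)


@dataclass
class EnergyParams:
    """Energy constants of the duplex model (kcal/mol)."""

    stack: np.ndarray = field(default_factory=lambda: _TURNER2004_STACK.copy())
    duplex_init: float = 4.09
    terminal_au: float = 0.45
    bulge_cost: callable = _default_bulge
    internal_loop_cost: callable = _default_internal
    max_loop: int = 10

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.shape != (6, 6):
            raise ValueError("stack table must be 6×6 over pair types "
                             f"{PAIR_TYPES}")
        wc = [_PT[p] for p in ("CG", "GC", "AU", "UA")]
        if np.any(self.stack[np.ix_(wc, wc)] > 0):
            raise ValueError("Watson–Crick stacking energies must be ≤ 0")
        if self.duplex_init <= 0:
            raise ValueError("duplex initiation must be > 0")
        for length in range(1, self.max_loop):
            if self.bulge_cost(length + 1) < self.bulge_cost(length) or \
                    self.bulge_cost(length) < 0:
                raise ValueError("bulge cost must be ≥ 0 and nondecreasing")

    def terminal_penalty(self, pair: str) -> float:
        """AU/GU closing penalty for a terminal pair such as 'AU'."""
        return self.terminal_au if ("A" in pair or pair in _WOBBLE) else 0.0

    def loop_cost_matrix(self) -> np.ndarray:
        """(max_loop+1)² matrix of loop penalties; [0,0] (stack case) is inf."""
        L = self.max_loop
        cost = np.full((L + 1, L + 1), math.inf)
        for g1 in range(L + 1):
            for g2 in range(L + 1):
                if g1 == 0 and g2 == 0:
                    continue
                if g1 == 0 or g2 == 0:
                    cost[g1, g2] = self.bulge_cost(g1 + g2)
                else:
                    cost[g1, g2] = self.internal_loop_cost(g1, g2)
        return cost


@dataclass(frozen=True)
class DuplexConfig:
    """Hit-calling threshold: a read is a hit iff dG ≤ mfe_max."""

    mfe_max: float = -20.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.mfe_max):
            raise ValueError("mfe_max must be finite")


@dataclass(frozen=True)
class DuplexResult:
    """MFE and one optimal base pairing of a duplex.

    ``pairing`` lists (i on miRNA, j on target) with i strictly increasing
    and j strictly decreasing (antiparallel).  ``dG`` is None when no pairing
    improves on the unbound state ("no duplex").
    """

    dG: float | None
    pairing: tuple[tuple[int, int], ...] = ()

    @property
    def is_duplex(self) -> bool:
        return self.dG is not None


def load_energy_params(path: str | Path) -> EnergyParams:
    """Read parameter overrides from TSV.

    Rows are either ``stack<TAB>XY/ZW<TAB>value`` — top strand 5'→3' bases
    ``XY`` over bottom strand 3'→5' bases ``ZW``, i.e. outer pair (X,Z) and
    inner pair (Y,W) — or scalar rows ``duplex_init``/``terminal_au`` with a
    value.  Unmentioned constants keep their defaults.
    """
    params = EnergyParams()
    stack = params.stack
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "stack":
                if len(fields) != 3 or len(fields[1]) != 5 or fields[1][2] != "/":
                    raise ValueError(f"{path}:{lineno}: bad stack row")
                x, y, _, z, w = fields[1]
                outer, inner = x + z, y + w
                if outer not in _PT or inner not in _PT:
                    raise ValueError(f"{path}:{lineno}: unknown pair in motif")
                # store symmetrically in the reversed-inner convention
                stack[_PT[outer], _PT[inner[::-1]]] = float(fields[2])
                stack[_PT[inner[::-1]], _PT[outer]] = float(fields[2])
            elif fields[0] in ("duplex_init", "terminal_au"):
                setattr(params, fields[0], float(fields[1]))
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {fields[0]!r}")
    return EnergyParams(stack, params.duplex_init, params.terminal_au)


def _validate_rna(seq: str, name: str) -> None:
    bad = set(seq) - _RNA_CHARS
    if bad:
        raise ValueError(f"{name}: non-RNA characters {sorted(bad)}")
    if not 2 <= len(seq) <= 50:
        raise ValueError(f"{name}: length must be 2–50, got {len(seq)}")


def _pair_type_matrix(a: str, b: str) -> np.ndarray:
    """pt[i, j] = pair-type index of (a[i], b[j]), or -1 if not pairable."""
    pt = np.full((len(a), len(b)), -1, dtype=np.int8)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            t = _PT.get(x + y)
            if t is not None:
                pt[i, j] = t
    return pt


def duplex_mfe(
    mirna_rna: str, target_rna: str, params: EnergyParams | None = None
) -> DuplexResult:
    """Global-minimum duplex free energy over all antiparallel pairings.

    Dynamic program over "last pair" states: ``E[i, j]`` is the minimum
    energy of a pairing whose most recent pair is (i, j), including the
    initiation term and the terminal penalty of the *first* pair; the
    closing terminal penalty is added on extraction.  Transitions cover the
    stack case and every bulge/internal loop up to ``max_loop`` unpaired
    bases per strand.
    """
    params = params or EnergyParams()
    _validate_rna(mirna_rna, "miRNA")
    _validate_rna(target_rna, "target")
    a, b = mirna_rna, target_rna
    m, n = len(a), len(b)
    pt_ab = _pair_type_matrix(a, b)           # pair (a[i], b[j])
    pt_ba = _pair_type_matrix(b, a)           # reversed pair (b[j], a[i])
    pairable = pt_ab >= 0
    if not pairable.any():
        return DuplexResult(None)

    term = np.zeros((m, n))
    for idx, p in enumerate(PAIR_TYPES):
        term[pt_ab == idx] = params.terminal_penalty(p)

    INF = math.inf
    E = np.full((m, n), INF)
    # opening a duplex at (i, j)
    E[pairable] = params.duplex_init + term[pairable]
    loop_cost = params.loop_cost_matrix()
    L = params.max_loop
    stack = params.stack
    for i in range(1, m):
        row = E[i]
        # stack case: previous pair (i-1, j+1)
        prev = E[i - 1]
        cand = np.full(n, INF)
        valid = pairable[i, : n - 1] & pairable[i - 1, 1:]
        jj = np.flatnonzero(valid)
        if jj.size:
            cand[jj] = prev[jj + 1] + stack[pt_ab[i - 1, jj + 1], pt_ba[jj, i]]
        # loop cases
        for g1 in range(L + 1):
            i2 = i - 1 - g1
            if i2 < 0:
                break
            prow = E[i2]
            for g2 in range(L + 1):
                if g1 == 0 and g2 == 0:
                    continue
                # previous pair column j2 = j + 1 + g2
                width = n - 1 - g2
                if width <= 0:
                    break
                c = prow[1 + g2:] + loop_cost[g1, g2]
                cand[:width] = np.minimum(cand[:width], c)
        cand[~pairable[i]] = INF
        np.minimum(row, cand, out=row, where=pairable[i])

    total = E + term
    best = np.nanmin(np.where(np.isfinite(total), total, np.nan))
    if not (best < 0):
        return DuplexResult(None)
    i, j = map(int, divmod(int(np.argmin(np.where(np.isfinite(total), total, INF))), n))
    pairing = _traceback(E, i, j, pt_ab, pt_ba, pairable, term, params)
    return DuplexResult(round(float(best), 10), tuple(pairing))


def _traceback(E, i, j, pt_ab, pt_ba, pairable, term, params) -> list[tuple[int, int]]:
    """Recover one optimal pairing ending at (i, j) by value matching."""
    stack = params.stack
    loop_cost = params.loop_cost_matrix()
    L = params.max_loop
    n = E.shape[1]
    pairs = [(i, j)]
    tol = 1e-9
    while True:
        target = E[i, j]
        if abs(target - (params.duplex_init + term[i, j])) < tol:
            break
        found = False
        for g1 in range(L + 1):
            i2 = i - 1 - g1
            if i2 < 0:
                break
            for g2 in range(L + 1):
                j2 = j + 1 + g2
                if j2 >= n:
                    break
                if not pairable[i2, j2]:
                    continue
                if g1 == 0 and g2 == 0:
                    step = stack[pt_ab[i2, j2], pt_ba[j, i]]
                else:
                    step = loop_cost[g1, g2]
                if abs(E[i2, j2] + step - target) < tol:
                    pairs.append((i2, j2))
                    i, j = i2, j2
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - defensive
            raise RuntimeError("duplex traceback failed")
    pairs.reverse()
    return pairs


def call_hit(result: DuplexResult, cfg: DuplexConfig | None = None) -> bool:
    """True iff the duplex MFE passes the gate (inclusive at the threshold)."""
    cfg = cfg or DuplexConfig()
    if not result.is_duplex:
        return False
    return result.dG <= cfg.mfe_max
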