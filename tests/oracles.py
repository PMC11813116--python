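"""Independent brute-force oracles used to check the dynamic programs.

These deliberately avoid the implementation's algorithms: the alignment
oracle enumerates text substrings with a plain Levenshtein distance, and
the duplex oracle enumerates every antiparallel monotone pairing.
"""

from __future__ import annotations

import itertools

from mirbact.duplex import EnergyParams, _PT


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def substring_levenshtein(pattern: str, text: str) -> int:
    """min over all substrings s of text of Levenshtein(pattern, s)."""
    best = len(pattern)
    for s in range(len(text) + 1):
        # Levenshtein against every prefix of text[s:] in one DP
        prev = list(range(len(pattern) + 1))
        best = min(best, prev[-1])
        for ct in text[s:]:
            cur = [0]
            for j, cp in enumerate(pattern, 1):
                cur.append(min(prev[j - 1] + (cp != ct), prev[j] + 1,
                               cur[-1] + 1))
            prev = cur
            best = min(best, prev[-1])
    return best


def brute_duplex_mfe(a: str, b: str, params: EnergyParams | None = None):
    """Exhaustive minimum over all antiparallel monotone pairings.

    Same energy terms and loop cap as the model; returns None when no
    pairing improves on the unbound state.
    """
    params = params or EnergyParams()
    loop = params.loop_cost_matrix()
    best = None
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for I in itertools.combinations(range(n), k):
            for J in itertools.combinations(range(m), k):
                Jd = tuple(reversed(J))
                if any(a[i] + b[j] not in _PT for i, j in zip(I, Jd)):
                    continue
                e = params.duplex_init
                e += params.terminal_penalty(a[I[0]] + b[Jd[0]])
                e += params.terminal_penalty(a[I[-1]] + b[Jd[-1]])
                ok = True
                pairs = list(zip(I, Jd))
                for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                    g1, g2 = i2 - i1 - 1, j1 - j2 - 1
                    if g1 > params.max_loop or g2 > params.max_loop:
                        ok = False
                        break
                    if g1 == 0 and g2 == 0:
                        e += params.stack[_PT[a[i1] + b[j1]],
                                          _PT[b[j2] + a[i2]]]
                    else:
                        e += loop[g1, g2]
                if ok and (best is None or e < best):
                    best = e
    return best if (best is not None and best < 0) else None
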