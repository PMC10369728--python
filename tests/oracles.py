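"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's dynamic-programming / closed-form
code paths: scores are computed by exhaustive enumeration so that the fast
implementations can be checked against them on small instances.
"""

from __future__ import annotations

import math

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_windows_brute(peptide: str, wmin: int, wmax: int) -> list[str]:
    """Every substring with length in [wmin, wmax] free of '*' and 'X'."""
    out = []
    n = len(peptide)
    for i in range(n):
        for j in range(i + wmin, min(i + wmax, n) + 1):
            sub = peptide[i:j]
            if "*" not in sub and "X" not in sub:
                out.append(sub)
    return out


def viterbi_brute(hmm, peptide: str) -> float:
    """Max log-odds (bits) over ALL local paths, by explicit enumeration.

    A path enters at any match state on any residue, moves through
    match/insert/delete states paying transition costs, and must end on a
    match state. Emitted residues score log(emission/background).
    """
    MM, MI, MD, IM, II, DM, DD = range(7)
    idx = [AA20.index(r) for r in peptide]
    n, M = len(idx), hmm.M
    lo_m = hmm.match_emissions - hmm.background
    lo_i = hmm.insert_emissions - hmm.background
    t = hmm.transitions
    best = [-math.inf]

    def walk(i: int, k: int, state: str, score: float) -> None:
        if state == "M":
            best[0] = max(best[0], score)
        if state == "M":
            if k + 1 <= M and i < n:
                walk(i + 1, k + 1, "M", score + t[k, MM] + lo_m[k, idx[i]])
            if i < n:
                walk(i + 1, k, "I", score + t[k, MI] + lo_i[k - 1, idx[i]])
            if k + 1 <= M:
                walk(i, k + 1, "D", score + t[k, MD])
        elif state == "I":
            if k + 1 <= M and i < n:
                walk(i + 1, k + 1, "M", score + t[k, IM] + lo_m[k, idx[i]])
            if i < n:
                walk(i + 1, k, "I", score + t[k, II] + lo_i[k - 1, idx[i]])
        else:  # D
            if k + 1 <= M and i < n:
                walk(i + 1, k + 1, "M", score + t[k, DM] + lo_m[k, idx[i]])
            if k + 1 <= M:
                walk(i, k + 1, "D", score + t[k, DD])

    for i in range(n):
        for k in range(1, M + 1):
            walk(i + 1, k, "M", lo_m[k - 1, idx[i]])
    return best[0] / math.log(2)


def trim_window_brute(qualities, window: int, min_mean: float) -> int:
    """Length retained by a naive scan of every full window left to right."""
    q = list(qualities)
    for i in range(len(q) - window + 1):
        if sum(q[i:i + window]) / window < min_mean:
            return i
    return len(q)


def best_serial_substitutions(peptide: str, scorer, free_positions,
                              max_steps: int):
    """Exhaustive search over all serial single-substitution sequences.

    Returns the best reachable score within max_steps accepted (strictly
    improving) substitutions. Exponential; only for tiny instances.
    """
    best = [scorer(peptide)]

    def rec(seq: str, score: float, steps: int) -> None:
        best[0] = max(best[0], score)
        if steps == 0:
            return
        for pos in free_positions:
            for res in AA20:
                if res == seq[pos - 1]:
                    continue
                cand = seq[:pos - 1] + res + seq[pos:]
                s = scorer(cand)
                if s > score:
                    rec(cand, s, steps - 1)

    rec(peptide, best[0], max_steps)
    return best[0]
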