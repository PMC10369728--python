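"""Self-contained profile-HMM machinery: HMMER3/f text I/O, profile
construction from an alignment, and local Viterbi alignment.

Candidates surviving the screen are annotated with profile-HMM domain hits
(e.g. the homeodomain family PF00046), and the best hit's envelope defines
the region the mutation optimizer must not touch.

Model layout follows the plan7 core: M match states with 20-way emission
distributions, per-node insert states, silent delete states, and seven
transition probabilities per node (M->M, M->I, M->D, I->M, I->I, D->M,
D->D). Alignment is local in both the query and the model: the path may
enter at any match state and exit after any match state at no cost
(Smith-Waterman-style), residues outside the alignment are emitted by the
background, and the score is the log-odds of the path versus the background
model, reported in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .physchem import STANDARD_RESIDUES

__all__ = [
    "ProfileHMM",
    "HmmHit",
    "read_hmmer3",
    "write_hmmer3",
    "build_from_alignment",
    "viterbi_local",
]

_AA_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}
# HMMER3 emission column order
_HMMER_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
LOG0 = float("-inf")

# transition column order in HMMER3/f files and in ProfileHMM.transitions
MM, MI, MD, IM, II, DM, DD = range(7)


@dataclass
class ProfileHMM:
    """A profile HMM with natural-log parameters.

    ``match_emissions``/``insert_emissions`` are (M, 20) log-probabilities
    in alphabetical residue order (rows 1..M map to array rows 0..M-1);
    ``transitions`` is (M+1, 7) with row 0 the begin node; ``background``
    is the 20-way null emission distribution (log).
    """

    name: str
    accession: str
    M: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    validated_tol: float = field(default=1e-4, repr=False)

    def __post_init__(self) -> None:
        me, ie, tr = (np.asarray(a, dtype=float) for a in
                      (self.match_emissions, self.insert_emissions, self.transitions))
        if me.shape != (self.M, 20) or ie.shape != (self.M, 20):
            raise ValueError("emission matrices must be (M, 20)")
        if tr.shape != (self.M + 1, 7):
            raise ValueError("transitions must be (M+1, 7)")
        tol = self.validated_tol
        for label, rows in (("match emission", me), ("insert emission", ie)):
            sums = np.exp(rows).sum(axis=1)
            bad = np.nonzero(np.abs(sums - 1.0) > tol)[0]
            if bad.size:
                raise ValueError(
                    f"{label} row {bad[0] + 1} sums to {sums[bad[0]]:.6f}, not 1")
        groups = ((("M->M", "M->I", "M->D"), (MM, MI, MD)),
                  (("I->M", "I->I"), (IM, II)),
                  (("D->M", "D->D"), (DM, DD)))
        for k in range(self.M + 1):
            for names, cols in groups:
                if k == 0 and names[0].startswith("D"):
                    continue  # begin node has no delete-out group in some writers
                s = float(np.exp(tr[k, list(cols)]).sum())
                if abs(s - 1.0) > max(tol, 1e-4):
                    raise ValueError(
                        f"transition group {'/'.join(names)} at node {k} "
                        f"sums to {s:.6f}, not 1")
        self.match_emissions, self.insert_emissions, self.transitions = me, ie, tr
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,):
            raise ValueError("background must have 20 entries")


@dataclass(frozen=True)
class HmmHit:
    query_start: int  # 1-based inclusive residue coordinates
    query_end: int
    hmm_from: int  # 1-based match-state coordinates
    hmm_to: int
    score_bits: float


# --------------------------------------------------------------------------
# HMMER3/f text format
# --------------------------------------------------------------------------

def _parse_value(tok: str) -> float:
    # stored as negative natural logs; '*' means probability zero
    return LOG0 if tok == "*" else -float(tok)


def _fmt_value(logp: float) -> str:
    return "      *" if logp == LOG0 else f"{-logp:.10f}"


def read_hmmer3(text: str) -> ProfileHMM:
    """Parse one HMMER3/f text profile (file path contents, not a path)."""
    lines = text.splitlines()
    if not lines or not lines[0].startswith("HMMER3/f"):
        raise ValueError("line 1: expected a 'HMMER3/f' header")
    name, acc, leng = "", "", None
    i = 1
    while i < len(lines) and not lines[i].startswith("HMM "):
        tok = lines[i].split(None, 1)
        if len(tok) == 2:
            if tok[0] == "NAME":
                name = tok[1].strip()
            elif tok[0] == "ACC":
                acc = tok[1].strip()
            elif tok[0] == "LENG":
                leng = int(tok[1])
            elif tok[0] == "ALPH" and tok[1].strip().lower() != "amino":
                raise ValueError(f"line {i + 1}: only amino alphabet supported")
        i += 1
    if i == len(lines):
        raise ValueError("missing 'HMM' alphabet line")
    alpha = lines[i].split()[1:]
    if "".join(alpha) != _HMMER_ALPHABET:
        raise ValueError(f"line {i + 1}: unexpected alphabet order")
    i += 2  # skip the transition-name line

    background = np.full(20, math.log(1 / 20))
    if i < len(lines) and lines[i].split()[:1] == ["COMPO"]:
        vals = lines[i].split()[1:21]
        background = np.array([_parse_value(v) for v in vals])
        i += 1
    # node 0: insert emissions + begin transitions
    try:
        ins0 = np.array([_parse_value(v) for v in lines[i].split()[:20]])
        tr0 = np.array([_parse_value(v) for v in lines[i + 1].split()[:7]])
    except (ValueError, IndexError):
        raise ValueError(f"line {i + 1}: malformed node-0 block") from None
    i += 2

    if leng is None:
        raise ValueError("missing LENG line")
    match_e, insert_e, trans = [], [ ], [tr0]
    node = 0
    while i < len(lines) and lines[i].strip() != "//":
        toks = lines[i].split()
        node += 1
        if not toks or toks[0] != str(node):
            raise ValueError(f"line {i + 1}: expected match line for node {node}")
        if len(toks) < 21:
            raise ValueError(f"line {i + 1}: truncated match emission line")
        match_e.append([_parse_value(v) for v in toks[1:21]])
        if i + 2 >= len(lines):
            raise ValueError(f"line {i + 2}: truncated model (node {node})")
        insert_e.append([_parse_value(v) for v in lines[i + 1].split()[:20]])
        trans.append([_parse_value(v) for v in lines[i + 2].split()[:7]])
        i += 3
    if i >= len(lines):
        raise ValueError("missing '//' terminator")
    if node != leng:
        raise ValueError(f"LENG says {leng} nodes but found {node}")
    # first insert distribution conventionally equals the others; keep rows 1..M
    _ = ins0
    return ProfileHMM(
        name=name, accession=acc, M=leng,
        match_emissions=np.array(match_e),
        insert_emissions=np.array(insert_e),
        transitions=np.array(trans),
        background=background,
    )


def read_hmmer3_file(path: str | Path) -> ProfileHMM:
    return read_hmmer3(Path(path).read_text())


def write_hmmer3(hmm: ProfileHMM) -> str:
    """Serialise to HMMER3/f text (values kept at 7 decimals for round-trips)."""
    out = [
        "HMMER3/f [pepmine]",
        f"NAME  {hmm.name or 'profile'}",
    ]
    if hmm.accession:
        out.append(f"ACC   {hmm.accession}")
    out += [
        f"LENG  {hmm.M}",
        "ALPH  amino",
        "HMM      " + "        ".join(_HMMER_ALPHABET),
        "         " + "  ".join(["m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d"]),
        "  COMPO  " + "  ".join(_fmt_value(v) for v in hmm.background),
        "         " + "  ".join(_fmt_value(v) for v in hmm.insert_emissions[0]),
        "         " + "  ".join(_fmt_value(v) for v in hmm.transitions[0]),
    ]
    for k in range(hmm.M):
        out.append(f"{k + 1:7d}  "
                   + "  ".join(_fmt_value(v) for v in hmm.match_emissions[k]))
        out.append("         " + "  ".join(_fmt_value(v) for v in hmm.insert_emissions[k]))
        out.append("         " + "  ".join(_fmt_value(v) for v in hmm.transitions[k + 1]))
    out.append("//")
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# profile construction
# --------------------------------------------------------------------------

_DEFAULT_TRANSITIONS = {  # probabilities, renormalised per group below
    MM: 0.90, MI: 0.05, MD: 0.05, IM: 0.50, II: 0.50, DM: 0.50, DD: 0.50,
}
_GAPS = frozenset("-.")


def build_from_alignment(aligned: list[str], pseudocount: float = 1.0,
                         name: str = "aligned", accession: str = "") -> ProfileHMM:
    """Profile from an aligned peptide set: columns with <= 50% gaps become
    match states; emissions are Laplace-smoothed column counts; transitions
    are fixed defaults; insert emissions and background are uniform."""
    if len(aligned) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(aligned[0])
    if any(len(s) != width for s in aligned):
        raise ValueError("ragged alignment: sequences differ in length")
    aligned = [s.upper() for s in aligned]

    match_cols = []
    for c in range(width):
        col = [s[c] for s in aligned]
        gaps = sum(ch in _GAPS for ch in col)
        if gaps * 2 <= len(col):
            match_cols.append(c)
    if not match_cols:
        raise ValueError("alignment has no match columns")

    me = []
    for c in match_cols:
        counts = np.full(20, pseudocount, dtype=float)
        n = 0
        for s in aligned:
            ch = s[c]
            if ch in _GAPS:
                continue
            if ch not in _AA_INDEX:
                raise ValueError(f"non-standard residue {ch!r} in alignment")
            counts[_AA_INDEX[ch]] += 1
            n += 1
        me.append(np.log(counts / (n + 20 * pseudocount)))

    M = len(match_cols)
    uniform = np.full(20, math.log(1 / 20))
    tr = np.empty(7)
    tr[[MM, MI, MD]] = np.log(np.array([0.90, 0.05, 0.05]))
    tr[[IM, II]] = np.log(0.5)
    tr[[DM, DD]] = np.log(0.5)
    return ProfileHMM(
        name=name, accession=accession, M=M,
        match_emissions=np.vstack(me),
        insert_emissions=np.tile(uniform, (M, 1)),
        transitions=np.tile(tr, (M + 1, 1)),
        background=uniform,
    )


# --------------------------------------------------------------------------
# local Viterbi
# --------------------------------------------------------------------------

def viterbi_local(hmm: ProfileHMM, peptide: str,
                  threshold_bits: float = 0.0) -> HmmHit | None:
    """Best local log-odds alignment of the peptide to the profile.

    Entry at any match state and exit after any match state are free;
    inserts and deletes inside the alignment pay their transition costs;
    emitted residues score log(emission/background). Returns None when the
    best score is below ``threshold_bits``.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    try:
        seq = np.array([_AA_INDEX[r] for r in peptide])
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None

    n, M = len(seq), hmm.M
    lo_m = hmm.match_emissions - hmm.background  # (M, 20) log-odds
    lo_i = hmm.insert_emissions - hmm.background
    t = hmm.transitions

    NEG = LOG0
    vm = np.full((n + 1, M + 1), NEG)
    vi = np.full((n + 1, M + 1), NEG)
    vd = np.full((n + 1, M + 1), NEG)
    # back-pointers: 0 entry, 1 from M, 2 from I, 3 from D
    pm = np.zeros((n + 1, M + 1), dtype=np.int8)
    pi = np.zeros((n + 1, M + 1), dtype=np.int8)
    pd_ = np.zeros((n + 1, M + 1), dtype=np.int8)

    for i in range(1, n + 1):
        res = seq[i - 1]
        for k in range(1, M + 1):
            emit = lo_m[k - 1, res]
            best, arg = 0.0, 0  # free entry
            if k > 1:
                cand = vm[i - 1, k - 1] + t[k - 1, MM]
                if cand > best:
                    best, arg = cand, 1
                cand = vi[i - 1, k - 1] + t[k - 1, IM]
                if cand > best:
                    best, arg = cand, 2
                cand = vd[i - 1, k - 1] + t[k - 1, DM]
                if cand > best:
                    best, arg = cand, 3
            vm[i, k] = emit + best
            pm[i, k] = arg

            # insert k consumes a residue, stays at node k (k < M relevant)
            cand_m = vm[i - 1, k] + t[k, MI]
            cand_i = vi[i - 1, k] + t[k, II]
            if cand_m >= cand_i:
                vi[i, k] = lo_i[k - 1, res] + cand_m
                pi[i, k] = 1
            else:
                vi[i, k] = lo_i[k - 1, res] + cand_i
                pi[i, k] = 2

            # delete k: silent, same query position
            if k > 1:
                cand_m = vm[i, k - 1] + t[k - 1, MD]
                cand_d = vd[i, k - 1] + t[k - 1, DD]
                if cand_m >= cand_d:
                    vd[i, k] = cand_m
                    pd_[i, k] = 1
                else:
                    vd[i, k] = cand_d
                    pd_[i, k] = 3

    # free exit after any match
    best_score = NEG
    bi = bk = 0
    for i in range(1, n + 1):
        k = int(np.argmax(vm[i, 1:])) + 1
        if vm[i, k] > best_score:
            best_score, bi, bk = float(vm[i, k]), i, k
    if not np.isfinite(best_score):
        return None
    bits = best_score / math.log(2)
    if bits < threshold_bits:
        return None

    # traceback to the entry match state
    i, k, state = bi, bk, "M"
    q_start, h_from = bi, bk
    while True:
        if state == "M":
            q_start, h_from = i, k
            arg = pm[i, k]
            if arg == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(arg)]
            i, k = i - 1, k - 1
        elif state == "I":
            arg = pi[i, k]
            state = "M" if arg == 1 else "I"
            i = i - 1
        else:  # D
            arg = pd_[i, k]
            state = "M" if arg == 1 else "D"
            k = k - 1

    return HmmHit(query_start=q_start, query_end=bi,
                  hmm_from=h_from, hmm_to=bk, score_bits=bits)
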