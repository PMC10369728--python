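"""Read quality control: trimming, filtering and 98%-identity dereplication.

The QC stage mirrors a PRINSEQ-style cleanup of pyrosequencing reads
followed by CD-HIT-454-style removal of artificial replicates:

1. terminal bases below a Phred threshold (default 15) are trimmed from
   both ends, then a sliding mean-quality window (size 15) truncates the
   read at the first window whose mean drops below the minimum;
2. reads are dropped when shorter than 60 bp, when their trinucleotide
   entropy (0-100 scale) is below 50, when ambiguous bases exceed 5% of
   the length, or when the mean quality over the trimmed read is below 15;
3. exact and near-identical replicates (>= 98% prefix identity to a longer
   retained read) are collapsed to one representative, longest first.

Entropy is the Shannon entropy of overlapping trinucleotide counts
normalised by the maximum attainable for the read length and scaled x100,
computed on the trimmed read.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RawRead",
    "QCParams",
    "QCOutcome",
    "sequence_entropy",
    "trim_read",
    "filter_read",
    "dereplicate",
    "run_qc",
]


@dataclass(frozen=True)
class RawRead:
    """A read with optional per-base Phred qualities (absent for FASTA)."""

    read_id: str
    bases: str
    qualities: tuple[int, ...] | None = None
    # 1-based inclusive interval retained from the original read, set by trim
    trimmed_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None:
            if len(self.qualities) != len(self.bases):
                raise ValueError("qualities must align with bases")
            if any(q < 0 for q in self.qualities):
                raise ValueError("Phred scores must be >= 0")
        object.__setattr__(self, "bases", self.bases.upper())
        if self.qualities is not None and not isinstance(self.qualities, tuple):
            object.__setattr__(self, "qualities", tuple(self.qualities))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QCParams:
    end_quality_threshold: int = 15
    trim_window: int = 15
    min_length: int = 60
    min_entropy: float = 50.0
    max_ambiguity_fraction: float = 0.05
    min_mean_quality: float = 15.0
    derep_identity: float = 0.98

    def __post_init__(self) -> None:
        if min(self.end_quality_threshold, self.trim_window, self.min_length) < 0:
            raise ValueError("thresholds must be non-negative")
        for frac in (self.max_ambiguity_fraction, self.derep_identity):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class QCOutcome:
    read_id: str
    passed: bool
    fail_reasons: frozenset[str]
    trimmed_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.passed != (len(self.fail_reasons) == 0):
            raise ValueError("passed must mirror empty fail_reasons")


def sequence_entropy(bases: str) -> float:
    """PRINSEQ-style trinucleotide entropy on a 0-100 scale."""
    n_triplets = len(bases) - 2
    if n_triplets < 1:
        return 0.0
    counts = Counter(bases[i:i + 3] for i in range(n_triplets))
    h = -sum((c / n_triplets) * math.log(c / n_triplets) for c in counts.values())
    h_max = math.log(min(n_triplets, 64))
    if h_max == 0:
        return 0.0
    return 100.0 * h / h_max


def trim_read(read: RawRead, params: QCParams = QCParams()) -> RawRead:
    """End-quality trim both ends, then sliding mean-quality truncation.

    FASTA reads (no qualities) pass through unchanged. The result is always
    a contiguous subsequence of the input; ``trimmed_range`` records the
    retained 1-based interval (None when the whole read is removed).
    """
    if read.qualities is None:
        return read
    q = np.asarray(read.qualities)
    lo, hi = 0, len(q)  # retained half-open interval
    while lo < hi and q[lo] < params.end_quality_threshold:
        lo += 1
    while hi > lo and q[hi - 1] < params.end_quality_threshold:
        hi -= 1

    w = params.trim_window
    if hi - lo >= w:
        qs = q[lo:hi].astype(float)
        means = np.convolve(qs, np.ones(w) / w, mode="valid")
        bad = np.nonzero(means < params.min_mean_quality)[0]
        if bad.size:
            hi = lo + int(bad[0])

    if hi <= lo:
        return replace(read, bases="", qualities=(), trimmed_range=None)
    return replace(
        read,
        bases=read.bases[lo:hi],
        qualities=tuple(read.qualities[lo:hi]),
        trimmed_range=(lo + 1, hi),
    )


TOO_SHORT = "TOO_SHORT"
LOW_ENTROPY = "LOW_ENTROPY"
AMBIGUOUS = "AMBIGUOUS"
LOW_MEAN_Q = "LOW_MEAN_Q"
DUPLICATE = "DUPLICATE"


def filter_read(read: RawRead, params: QCParams = QCParams()) -> QCOutcome:
    """Apply the four independent content filters to an (already trimmed) read."""
    reasons: set[str] = set()
    n = len(read)
    if n < params.min_length:
        reasons.add(TOO_SHORT)
    if sequence_entropy(read.bases) < params.min_entropy:
        reasons.add(LOW_ENTROPY)
    if n > 0:
        ambiguous = sum(1 for b in read.bases if b not in "ACGT")
        if ambiguous / n > params.max_ambiguity_fraction:
            reasons.add(AMBIGUOUS)
    if read.qualities is not None and n > 0:
        if float(np.mean(read.qualities)) < params.min_mean_quality:
            reasons.add(LOW_MEAN_Q)
    return QCOutcome(read.read_id, not reasons, frozenset(reasons),
                     read.trimmed_range)


def dereplicate(reads: list[RawRead], identity: float = 0.98
                ) -> tuple[list[RawRead], dict[str, str]]:
    """Greedy longest-first prefix clustering; one representative per cluster.

    A read joins a cluster when its ungapped prefix identity to the (equal
    or longer) representative -- matching positions / read length -- is at
    least ``identity``. Ties in length keep input order. Returns retained
    representatives in input order plus a member -> representative map.
    """
    order = sorted(range(len(reads)), key=lambda i: -len(reads[i]))
    rep_ids: list[str] = []
    rep_lens: list[int] = []
    buf = np.zeros((0, 0), dtype=np.uint8)
    n_reps = 0
    cluster_map: dict[str, str] = {}
    retained_idx: list[int] = []

    for i in order:
        read = reads[i]
        arr = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8)
        L = len(arr)
        rep = None
        if n_reps and L > 0:
            mism = np.count_nonzero(buf[:n_reps, :L] != arr, axis=1)
            ok = np.nonzero(mism <= (1.0 - identity) * L)[0]
            # a representative shorter than the read cannot host it as prefix
            for j in ok:
                if rep_lens[j] >= L:
                    rep = rep_ids[j]
                    break
        if rep is None:
            if buf.shape[0] == n_reps or buf.shape[1] < L:
                new = np.zeros((max(2 * n_reps + 4, n_reps + 1),
                                max(buf.shape[1], L)), dtype=np.uint8)
                new[:n_reps, :buf.shape[1]] = buf[:n_reps]
                buf = new
            buf[n_reps, :L] = arr
            rep_ids.append(read.read_id)
            rep_lens.append(L)
            n_reps += 1
            retained_idx.append(i)
            cluster_map[read.read_id] = read.read_id
        else:
            cluster_map[read.read_id] = rep
    retained = [reads[i] for i in sorted(retained_idx)]
    return retained, cluster_map


def run_qc(reads: list[RawRead], params: QCParams = QCParams()
           ) -> tuple[list[RawRead], list[QCOutcome]]:
    """Trim, filter and dereplicate a read set; returns survivors + report."""
    outcomes: dict[str, QCOutcome] = {}
    survivors: list[RawRead] = []
    for read in reads:
        trimmed = trim_read(read, params)
        outcome = filter_read(trimmed, params)
        outcomes[read.read_id] = outcome
        if outcome.passed:
            survivors.append(trimmed)
    retained, cluster_map = dereplicate(survivors, params.derep_identity)
    kept_ids = {r.read_id for r in retained}
    for read in survivors:
        if read.read_id not in kept_ids:
            out = outcomes[read.read_id]
            outcomes[read.read_id] = QCOutcome(
                read.read_id, False, frozenset({DUPLICATE}), out.trimmed_range)
    return retained, [outcomes[r.read_id] for r in reads]
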