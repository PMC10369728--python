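"""Constrained serial-mutation optimisation of a candidate peptide.

The selected candidate is improved by greedy best-improvement hill
climbing: every round evaluates the scorer on every single-residue
substitution at every position outside the protected interval (the
profile-HMM hit envelope, e.g. residues 1-31 of the 37-mer candidate) and
accepts the best strictly-improving one. The search halts when the score
reaches the stop threshold, when no substitution improves the score, or
when the accepted-mutation cap is reached. Ties break deterministically by
lowest position, then alphabetical target residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .physchem import STANDARD_RESIDUES, net_charge

__all__ = [
    "OptimizationConfig",
    "MutationStep",
    "OptimizationResult",
    "OptimizationError",
    "optimize",
    "apply_mutations",
    "parse_mutation",
]


class OptimizationError(RuntimeError):
    """Raised when the scorer fails on a candidate sequence."""


@dataclass(frozen=True)
class OptimizationConfig:
    protected_interval: tuple[int, int] | None = None  # 1-based inclusive
    allowed_residues: str = STANDARD_RESIDUES
    stop_threshold: float = 0.0
    max_accepted_mutations: int | None = None  # default: #unprotected positions
    require_charge_preservation: bool = False

    def __post_init__(self) -> None:
        if self.protected_interval is not None:
            lo, hi = self.protected_interval
            if lo < 1 or hi < lo:
                raise ValueError("protected_interval must be 1-based and ordered")
        if self.max_accepted_mutations is not None and self.max_accepted_mutations < 0:
            raise ValueError("mutation cap must be >= 0")
        bad = set(self.allowed_residues) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"non-standard residues in alphabet: {sorted(bad)}")


@dataclass(frozen=True)
class MutationStep:
    position: int  # 1-based
    from_residue: str
    to_residue: str
    score_before: float
    score_after: float

    @property
    def hgvs(self) -> str:
        return f"p.{self.from_residue}{self.position}{self.to_residue}"


@dataclass
class OptimizationResult:
    peptide: str
    trace: list[MutationStep]
    initial_score: float
    final_score: float
    flags: list[str] = field(default_factory=list)


def _score(scorer: Callable[[str], float], seq: str) -> float:
    try:
        return float(scorer(seq))
    except Exception as exc:  # noqa: BLE001 - report the offending sequence
        raise OptimizationError(f"scorer failed on sequence {seq!r}: {exc}") from exc


def optimize(peptide: str, scorer: Callable[[str], float],
             config: OptimizationConfig = OptimizationConfig()) -> OptimizationResult:
    """Greedy serial substitution search outside the protected interval."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    n = len(peptide)
    protected = config.protected_interval
    if protected is not None and protected[1] > n:
        raise ValueError("protected_interval exceeds peptide bounds")

    free = [p for p in range(1, n + 1)
            if protected is None or not (protected[0] <= p <= protected[1])]
    current = peptide
    score = _score(scorer, current)
    result = OptimizationResult(current, [], score, score)
    if not free:
        if score < config.stop_threshold:
            result.flags.append("NO_FREE_POSITIONS")
        return result

    cap = (config.max_accepted_mutations if config.max_accepted_mutations is not None
           else len(free))
    base_charge = net_charge(peptide)

    while len(result.trace) < cap and score < config.stop_threshold:
        best = None  # (new_score, position, residue)
        for pos in free:
            old = current[pos - 1]
            for res in sorted(set(config.allowed_residues) - {old}):
                cand = current[:pos - 1] + res + current[pos:]
                if config.require_charge_preservation and net_charge(cand) != base_charge:
                    continue
                s = _score(scorer, cand)
                if s > score and (best is None or s > best[0]):
                    best = (s, pos, res)
        if best is None:
            break
        new_score, pos, res = best
        result.trace.append(MutationStep(pos, current[pos - 1], res, score, new_score))
        current = current[:pos - 1] + res + current[pos:]
        score = new_score

    result.peptide = current
    result.final_score = score
    return result


def apply_mutations(peptide: str, trace: list[MutationStep]) -> str:
    """Apply substitutions in order, verifying each source residue."""
    seq = list(peptide)
    for step in trace:
        if not 1 <= step.position <= len(seq):
            raise ValueError(f"position {step.position} out of bounds")
        if seq[step.position - 1] != step.from_residue:
            raise ValueError(
                f"integrity error at position {step.position}: expected "
                f"{step.from_residue!r}, found {seq[step.position - 1]!r}")
        seq[step.position - 1] = step.to_residue
    return "".join(seq)


def parse_mutation(text: str) -> tuple[int, str, str]:
    """Parse 'p.V32C' / 'V32C' into (position, from_residue, to_residue)."""
    t = text.removeprefix("p.")
    if len(t) < 3 or t[0] not in STANDARD_RESIDUES or t[-1] not in STANDARD_RESIDUES:
        raise ValueError(f"cannot parse mutation {text!r}")
    return int(t[1:-1]), t[0], t[-1]
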