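"""Synthetic inputs with planted ground truth for the mining pipeline.

Two generators:

* labelled peptide training sets -- each class is defined by a target
  amino-acid frequency vector; every peptide draws its own frequency vector
  from a Dirichlet centred on the target (concentration controls
  dispersion) and then samples residues i.i.d. The default ACP profile
  raises K, L, A, I by +0.05 and lowers D, E by -0.03 relative to uniform,
  emulating the cationic/hydrophobic character of anticancer peptides; the
  AMP-negative profile is cationic (K, R raised) but not hydrophobic.

* a synthetic metagenome -- background reads are i.i.d. uniform
  nucleotides; planted ACP-like peptides are reverse-translated (uniform
  synonymous codons) and embedded at recorded frames/coordinates, with
  reverse-strand plants embedded as the reverse complement. Per-base Phred
  qualities decay linearly toward the read ends. The emitted truth table
  matches the reads exactly before optional substitution-error injection.

Planted peptides are drawn from the ACP profile conditioned on a positive
net charge, since cationicity defines the class the screen is built to
recover. The default substitution error rate is 0: the generator emulates a
post-QC clean library, and error injection is an explicit robustness knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physchem import STANDARD_RESIDUES, net_charge
from .read_qc import RawRead
from .translate_scan import reverse_complement, translate_frame

__all__ = [
    "ClassProfile",
    "QualityModel",
    "SimulationConfig",
    "acp_profile",
    "amp_negative_profile",
    "random_profile",
    "profile_from_deltas",
    "simulate_training_sets",
    "reverse_translate",
    "simulate_metagenome",
    "truth_table_columns",
]

_AA = np.array(list(STANDARD_RESIDUES))
_AA_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}

# residue -> codons, deterministic order (standard code)
_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _cod = _b1 + _b2 + _b3
            _pep = translate_frame(_cod, 1)
            if _pep != "*":
                _CODONS.setdefault(_pep, []).append(_cod)


@dataclass(frozen=True)
class ClassProfile:
    """A peptide class: target composition + Dirichlet dispersion + lengths."""

    label: str  # ACP, AMP_NEG or RANDOM
    target_freqs: tuple[float, ...]  # 20 values, ACDEFGHIKLMNPQRSTVWY order
    concentration: float = 50.0
    length_range: tuple[int, int] = (5, 50)

    def __post_init__(self) -> None:
        f = np.asarray(self.target_freqs, dtype=float)
        if f.shape != (20,):
            raise ValueError("target_freqs must have 20 entries")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("target_freqs must be non-negative and sum to 1")
        lo, hi = self.length_range
        if not (5 <= lo <= hi <= 50):
            raise ValueError("length_range must lie within [5, 50]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        object.__setattr__(self, "target_freqs", tuple(float(x) for x in f))


def profile_from_deltas(label: str, deltas: dict[str, float], **kwargs) -> ClassProfile:
    """Uniform composition shifted by per-residue deltas, rebalanced on the rest."""
    f = np.full(20, 0.05)
    for res, d in deltas.items():
        f[_AA_INDEX[res]] += d
    excess = f.sum() - 1.0
    untouched = np.ones(20, dtype=bool)
    untouched[[_AA_INDEX[r] for r in deltas]] = False
    f[untouched] -= excess / untouched.sum()
    if np.any(f < 0):
        raise ValueError("deltas produce negative frequencies")
    return ClassProfile(label, tuple(f), **kwargs)


def acp_profile(**kwargs) -> ClassProfile:
    """Cationic/hydrophobic class: K, L, A, I +0.05; D, E -0.03."""
    return profile_from_deltas(
        "ACP", {"K": 0.05, "L": 0.05, "A": 0.05, "I": 0.05, "D": -0.03, "E": -0.03},
        **kwargs)


def amp_negative_profile(**kwargs) -> ClassProfile:
    """Cationic but non-hydrophobic contrast class: K, R +0.05; G +0.03; D, E -0.03."""
    return profile_from_deltas(
        "AMP_NEG", {"K": 0.05, "R": 0.05, "G": 0.03, "D": -0.03, "E": -0.03},
        **kwargs)


def random_profile(**kwargs) -> ClassProfile:
    """Uniform background class."""
    return ClassProfile("RANDOM", tuple(np.full(20, 0.05)), **kwargs)


def _sample_peptide(profile: ClassProfile, rng: np.random.Generator,
                    length: int | None = None) -> str:
    f = np.asarray(profile.target_freqs)
    pos = f > 0
    if pos.sum() == 1:
        freqs = f
    else:
        freqs = np.zeros(20)
        freqs[pos] = rng.dirichlet(profile.concentration * f[pos])
    if length is None:
        lo, hi = profile.length_range
        length = int(rng.integers(lo, hi + 1))
    return "".join(_AA[rng.choice(20, size=length, p=freqs)])


def simulate_training_sets(profiles: list[ClassProfile], n_per_class: int,
                           seed: int) -> dict[str, list[str]]:
    """n_per_class peptides per class, keyed by class label."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_per_class < 2:
        raise ValueError("need at least 2 peptides per class")
    rng = np.random.default_rng(seed)
    return {
        p.label: [_sample_peptide(p, rng) for _ in range(n_per_class)]
        for p in profiles
    }


def reverse_translate(peptide: str, seed: int | np.random.Generator = 0) -> str:
    """DNA encoding the peptide in frame +1, synonymous codons uniform."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        return "".join(_CODONS[r][rng.integers(len(_CODONS[r]))] for r in peptide)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class QualityModel:
    """Phred means: flat `mean` in the middle, linear decay of `end_decay`
    over the final `taper` bases at each end, plus N(0, jitter_sd) noise."""

    mean: float = 35.0
    end_decay: float = 10.0
    taper: int = 10
    jitter_sd: float = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_reads: int = 1000
    read_length_mean: float = 110.0
    read_length_sd: float = 10.0
    substitution_error_rate: float = 0.0
    quality_model: QualityModel = field(default_factory=QualityModel)
    n_planted: int = 5
    plant_length_range: tuple[int, int] = (20, 30)
    plant_profile: ClassProfile = field(default_factory=acp_profile)
    require_cationic_plants: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("substitution_error_rate must lie in [0, 1]")
        if self.n_planted > self.n_reads:
            raise ValueError("cannot plant more peptides than reads")
        if 3 * self.plant_length_range[1] > self.read_length_mean:
            raise ValueError(
                "reads too short on average to host the longest plant; raise "
                "read_length_mean or shorten plant_length_range")


truth_table_columns = (
    "peptide_id", "read_id", "frame", "read_start", "read_end", "peptide_sequence",
)


def _plant_peptide(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    lo, hi = cfg.plant_length_range
    for _ in range(1000):
        length = int(rng.integers(lo, hi + 1))
        pep = _sample_peptide(cfg.plant_profile, rng, length=length)
        if not cfg.require_cationic_plants or net_charge(pep) > 0:
            return pep
    raise RuntimeError("could not draw a cationic plant; profile too anionic")


def _qualities(length: int, qm: QualityModel, rng: np.random.Generator
               ) -> tuple[int, ...]:
    pos = np.arange(length)
    dist = np.minimum(pos, length - 1 - pos)
    mean = qm.mean - qm.end_decay * np.clip(1 - dist / max(qm.taper, 1), 0, 1)
    q = np.rint(mean + rng.normal(0, qm.jitter_sd, size=length))
    return tuple(int(x) for x in np.clip(q, 2, 41))


def simulate_metagenome(config: SimulationConfig
                        ) -> tuple[list[RawRead], pd.DataFrame]:
    """Reads plus a planted-truth table (coordinates before error injection)."""
    rng = np.random.default_rng(config.seed)
    lengths = np.clip(
        np.rint(rng.normal(config.read_length_mean, config.read_length_sd,
                           size=config.n_reads)).astype(int),
        10, None)
    plant_rows = []
    reads: list[RawRead] = []
    nt = np.array(list("ACGT"))
    for i in range(config.n_reads):
        read_id = f"read{i:05d}"
        L = int(lengths[i])
        if i < config.n_planted:
            pep = _plant_peptide(config, rng)
            coding = reverse_translate(pep, rng)
            # hosting reads are drawn long enough for the insert + any offset
            L = max(L, len(coding) + 3)
            bases = list(nt[rng.integers(0, 4, size=L)])
            frame = int(rng.choice([1, 2, 3, -1, -2, -3]))
            insert = coding if frame > 0 else reverse_complement(coding)
            offset = abs(frame) - 1
            # start positions congruent with the frame offset on the coding strand
            if frame > 0:
                starts = [s for s in range(offset, L - len(insert) + 1)
                          if (s - offset) % 3 == 0]
                s = int(starts[rng.integers(len(starts))])
                read_start, read_end = s + 1, s + len(insert)
            else:
                starts = [s for s in range(offset, L - len(insert) + 1)
                          if (s - offset) % 3 == 0]
                s_rc = int(starts[rng.integers(len(starts))])  # on the RC strand
                read_start = L - (s_rc + len(insert)) + 1
                read_end = L - s_rc
            bases[read_start - 1:read_end] = list(insert)
            plant_rows.append((f"plant{i:03d}", read_id, frame,
                               read_start, read_end, pep))
        else:
            bases = list(nt[rng.integers(0, 4, size=L)])
        seq = np.array(bases)
        if config.substitution_error_rate > 0:
            hit = rng.random(L) < config.substitution_error_rate
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                idx = {"A": 0, "C": 1, "G": 2, "T": 3}
                cur = np.array([idx[b] for b in seq[hit]])
                seq[hit] = nt[(cur + shift) % 4]
        reads.append(RawRead(read_id, "".join(seq),
                             _qualities(L, config.quality_model, rng)))
    truth = pd.DataFrame(plant_rows, columns=list(truth_table_columns))
    return reads, truth
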