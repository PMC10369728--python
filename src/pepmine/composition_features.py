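"""Amino-acid / dipeptide composition features and class-contrast selection.

The screen represents every peptide by 420 features: the 20 amino-acid
frequencies and the 400 overlapping-dipeptide frequencies. Features that
separate the ACP training class from the contrast class are selected by a
per-feature Welch t-test with a fixed Bonferroni correction over all 420
tests. Candidate peptides are then scored by their conformity to the ACP
class mean on the selected features (SE-standardised L1 distance; higher,
i.e. closer to zero, is more ACP-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .physchem import STANDARD_RESIDUES

__all__ = [
    "AA_FEATURES",
    "DIPEP_FEATURES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "aa_composition",
    "dipeptide_composition",
    "composition_vector",
    "FeatureStats",
    "select_features",
    "ConformityScore",
    "conformity_score",
]

AA_FEATURES: tuple[str, ...] = tuple(STANDARD_RESIDUES)
DIPEP_FEATURES: tuple[str, ...] = tuple(
    a + b for a in STANDARD_RESIDUES for b in STANDARD_RESIDUES
)
FEATURE_NAMES: tuple[str, ...] = AA_FEATURES + DIPEP_FEATURES
N_FEATURES = len(FEATURE_NAMES)  # 420

_AA_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


def _encode(peptide: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[r] for r in peptide], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in peptide") from None


def aa_composition(peptide: str) -> np.ndarray:
    """20 amino-acid frequencies (counts / length)."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    idx = _encode(peptide)
    return np.bincount(idx, minlength=20) / len(peptide)


def dipeptide_composition(peptide: str) -> np.ndarray:
    """400 overlapping-dipeptide frequencies (pair counts / (length - 1))."""
    if len(peptide) < 2:
        raise ValueError("dipeptide composition requires length >= 2")
    idx = _encode(peptide)
    pairs = idx[:-1] * 20 + idx[1:]
    return np.bincount(pairs, minlength=400) / (len(peptide) - 1)


def composition_vector(peptide: str) -> np.ndarray:
    """Concatenated 420-feature vector (20 aa + 400 dipeptide)."""
    return np.concatenate([aa_composition(peptide), dipeptide_composition(peptide)])


@dataclass
class FeatureStats:
    """Per-feature class statistics and Bonferroni-adjusted selection.

    ``mu_acp``/``se_acp`` are the ACP-class means and standard errors of the
    mean; the Bonferroni denominator is fixed at 420 regardless of constant
    features, for reproducibility.
    """

    mu_acp: np.ndarray
    mu_other: np.ndarray
    se_acp: np.ndarray
    se_other: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    selected: np.ndarray  # bool
    alpha: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "feature": FEATURE_NAMES,
            "mu_acp": self.mu_acp,
            "se_acp": self.se_acp,
            "mu_other": self.mu_other,
            "se_other": self.se_other,
            "t": self.t,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "selected": self.selected,
        })


def select_features(class_a, class_b, alpha: float = 0.05) -> FeatureStats:
    """Welch t-test per feature between two classes; Bonferroni over 420.

    ``class_a`` is the ACP class; both arguments are (n, 420) arrays or
    lists of 420-vectors with at least 2 samples each.
    """
    a = np.atleast_2d(np.asarray(class_a, dtype=float))
    b = np.atleast_2d(np.asarray(class_b, dtype=float))
    if a.shape[1] != N_FEATURES or b.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrices must have {N_FEATURES} columns")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per class")

    t, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
    # constant-on-both-sides features: no evidence either way
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)

    p_adj = np.minimum(1.0, p * N_FEATURES)
    return FeatureStats(
        mu_acp=a.mean(axis=0),
        mu_other=b.mean(axis=0),
        se_acp=a.std(axis=0, ddof=1) / np.sqrt(a.shape[0]),
        se_other=b.std(axis=0, ddof=1) / np.sqrt(b.shape[0]),
        t=t,
        p_raw=p,
        p_adj=p_adj,
        selected=p_adj < alpha,
        alpha=alpha,
    )


@dataclass(frozen=True)
class ConformityScore:
    """Conformity of one peptide to the ACP class mean on selected features."""

    score: float  # -sum |f - mu|/SE over selected features; 0 is maximal
    n_within_se: int
    n_selected: int
    passes: bool  # all selected features within k_se x SE


def conformity_score(pep_features: np.ndarray, stats: FeatureStats,
                     k_se: float = 1.0) -> ConformityScore:
    """SE-standardised L1 conformity to the ACP mean over selected features.

    The pre-filter passes only when every selected feature lies within
    ``k_se`` standard errors of the ACP class mean. A selected feature with
    SE = 0 contributes 0 when the peptide matches the mean exactly and
    otherwise fails the peptide outright (score -inf).
    """
    if stats.n_selected < 1:
        raise ValueError("no selected features; cannot score conformity")
    f = np.asarray(pep_features, dtype=float)[stats.selected]
    mu = stats.mu_acp[stats.selected]
    se = stats.se_acp[stats.selected]
    dev = np.abs(f - mu)

    zero_se = se == 0
    if np.any(zero_se & (dev > 0)):
        return ConformityScore(float("-inf"), 0, stats.n_selected, False)
    z = np.zeros_like(dev)
    nz = ~zero_se
    z[nz] = dev[nz] / se[nz]
    # tolerant comparison so an exactly-1-SE deviation passes at k_se = 1
    within = int(np.sum((z <= k_se * (1 + 1e-12)) | zero_se))
    return ConformityScore(
        score=float(-z.sum()),
        n_within_se=within,
        n_selected=stats.n_selected,
        passes=within == stats.n_selected,
    )
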