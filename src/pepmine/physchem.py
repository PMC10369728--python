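"""Physicochemical property calculators for candidate peptides.

Net formal charge, molecular weight and mean hydrophobicity-type scales are
the desk properties used to filter and characterise mined anticancer-peptide
(ACP) candidates: ACPs are short (5-50 aa), cationic and amphiphilic, so a
positive net charge is the first retention criterion of the screen.

Charge model: K and R count +1, D and E count -1, H counts 0 (no
pH-dependent pKa model). Molecular weight uses the standard average (or
monoisotopic) residue-mass table plus one water. The three named scales are
the conventional ones for each property: Eisenberg consensus hydrophobicity,
Kyte-Doolittle hydropathicity (GRAVY) and Hopp-Woods hydrophilicity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "STANDARD_RESIDUES",
    "HydroScale",
    "PropertyTable",
    "net_charge",
    "molecular_weight",
    "mean_scale",
    "is_cationic",
    "property_table",
    "get_scale",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")


def _load_json(name: str) -> dict:
    with resources.files("pepmine.data").joinpath(name).open() as fh:
        return json.load(fh)


_MASSES = _load_json("residue_masses.json")
_SCALES_RAW = _load_json("hydro_scales.json")["scales"]


@dataclass(frozen=True)
class HydroScale:
    """An immutable per-residue numeric scale (20 entries)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != _STANDARD_SET:
            raise ValueError(
                f"scale {self.name!r} must define exactly the 20 standard residues"
            )


_SCALES = {name: HydroScale(name, vals) for name, vals in _SCALES_RAW.items()}

EISENBERG_HYDROPHOBICITY = _SCALES["EISENBERG_HYDROPHOBICITY"]
KYTE_DOOLITTLE_HYDROPATHICITY = _SCALES["KYTE_DOOLITTLE_HYDROPATHICITY"]
HOPP_WOODS_HYDROPHILICITY = _SCALES["HOPP_WOODS_HYDROPHILICITY"]


def get_scale(name: str) -> HydroScale:
    """Return a named built-in scale."""
    try:
        return _SCALES[name]
    except KeyError:
        raise KeyError(f"unknown scale {name!r}; available: {sorted(_SCALES)}") from None


def _check_peptide(peptide: str) -> str:
    if not peptide:
        raise ValueError("peptide must be non-empty")
    bad = set(peptide) - _STANDARD_SET
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in peptide")
    return peptide


def net_charge(peptide: str) -> int:
    """Net formal charge: (#K + #R) - (#D + #E); H excluded."""
    _check_peptide(peptide)
    pos = sum(peptide.count(r) for r in _POSITIVE)
    neg = sum(peptide.count(r) for r in _NEGATIVE)
    return pos - neg


def is_cationic(peptide: str) -> bool:
    """True iff the net formal charge is strictly positive."""
    return net_charge(peptide) > 0


def molecular_weight(peptide: str, mass_set: str = "AVERAGE") -> float:
    """Peptide molecular weight in Da (residue masses + one water)."""
    _check_peptide(peptide)
    if mass_set not in ("AVERAGE", "MONOISOTOPIC"):
        raise ValueError("mass_set must be 'AVERAGE' or 'MONOISOTOPIC'")
    table = _MASSES[mass_set]
    return sum(table[r] for r in peptide) + _MASSES["water"][mass_set]


def mean_scale(peptide: str, scale: HydroScale) -> float:
    """Arithmetic mean of per-residue scale values."""
    _check_peptide(peptide)
    missing = set(peptide) - set(scale.values)
    if missing:
        raise ValueError(f"residue(s) {sorted(missing)} missing from scale {scale.name}")
    return sum(scale.values[r] for r in peptide) / len(peptide)


@dataclass(frozen=True)
class PropertyTable:
    """Desk properties of one peptide, as reported in candidate tables."""

    length: int
    net_charge: int
    molecular_weight: float
    hydrophobicity: float
    hydropathicity: float
    hydrophilicity: float


def property_table(peptide: str, mass_set: str = "AVERAGE") -> PropertyTable:
    """Compute the full property row for one peptide."""
    _check_peptide(peptide)
    return PropertyTable(
        length=len(peptide),
        net_charge=net_charge(peptide),
        molecular_weight=molecular_weight(peptide, mass_set),
        hydrophobicity=mean_scale(peptide, EISENBERG_HYDROPHOBICITY),
        hydropathicity=mean_scale(peptide, KYTE_DOOLITTLE_HYDROPATHICITY),
        hydrophilicity=mean_scale(peptide, HOPP_WOODS_HYDROPHILICITY),
    )
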