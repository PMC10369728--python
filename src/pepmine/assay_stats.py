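"""Assay calculators and dose-response fitting.

Implements the bench formulas used to characterise the mined peptide --
hemocytometer cell density, exponential-growth doubling time, scratch-assay
wound closure, erythrocyte hemolysis percentage and colony-forming units --
plus the "log(inhibitor) vs normalized response, variable slope" fit that
produces relative/absolute IC50, Hill coefficient and R^2 from MTT
viability data.

Dose-response model
-------------------
Responses are viability percentages normalised so that untreated = 100.
The *relative* IC50 comes from the plateau-constrained model

    y = 100 / (1 + (x / IC50_rel)^h)

fitted by least squares on log10 dose, jointly over all replicate wells.
The *absolute* IC50 is the dose at which an unconstrained four-parameter
logistic (free top/bottom plateaus) crosses y = 50; when the fitted curve
never brackets 50 the absolute IC50 is flagged undefined. The two IC50s
coincide exactly when the free plateaus come out at 100 and 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GrowthPair",
    "HemolysisTriple",
    "DoseResponseFit",
    "cells_per_ml",
    "doubling_time",
    "wound_closure_pct",
    "hemolysis_pct",
    "cfu_per_ml",
    "fit_dose_response",
]


# --------------------------------------------------------------------------
# closed-form bench formulas
# --------------------------------------------------------------------------

def cells_per_ml(count: float, dilution_factor: float, n_chambers: int) -> float:
    """Hemocytometer density: count x dilution_factor / n_chambers x 10,000."""
    if n_chambers <= 0:
        raise ValueError("number of chambers must be positive")
    if count < 0 or dilution_factor <= 0:
        raise ValueError("count must be >= 0 and dilution factor > 0")
    return count * dilution_factor / n_chambers * 10_000


@dataclass(frozen=True)
class GrowthPair:
    """Exponential-growth observation: T hours taking Xb cells to Xe cells."""

    T: float
    Xb: float
    Xe: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("growth interval T must be positive")
        if not (self.Xe > self.Xb > 0):
            raise ValueError("doubling time requires Xe > Xb > 0")


def doubling_time(g: GrowthPair) -> float:
    """DT = T ln2 / ln(Xe/Xb), hours."""
    return g.T * math.log(2) / math.log(g.Xe / g.Xb)


def wound_closure_pct(wc0: float, wcx: float) -> float:
    """Scratch-assay closure: (wc0 - wcx)/wc0 x 100.

    Negative values mean the wound widened (as seen for treated cells).
    """
    if wc0 <= 0:
        raise ValueError("initial wound measurement must be positive")
    return (wc0 - wcx) / wc0 * 100


@dataclass(frozen=True)
class HemolysisTriple:
    """Absorbances: Amax untreated RBCs, Amin fully hemolysed, At tested.

    The labelling follows the source formula as printed (Amax = untreated);
    pass ``labels="conventional"`` to :func:`hemolysis_pct` to swap the roles
    so that Amax means the full-lysis positive control.
    """

    Amax: float
    Amin: float
    At: float

    def __post_init__(self) -> None:
        if self.Amax == self.Amin:
            raise ValueError("Amax and Amin must differ")


def hemolysis_pct(h: HemolysisTriple, labels: str = "as_printed") -> float:
    """Hemolysis % = (Amax - At)/(Amax - Amin) x 100."""
    if labels == "as_printed":
        return (h.Amax - h.At) / (h.Amax - h.Amin) * 100
    if labels == "conventional":
        # Amax = fully hemolysed, Amin = untreated
        return (h.At - h.Amin) / (h.Amax - h.Amin) * 100
    raise ValueError("labels must be 'as_printed' or 'conventional'")


def cfu_per_ml(colonies: float, dilution_factor: float, plated_volume_ml: float) -> float:
    """CFU/ml = colonies x dilution factor / plated volume (ml)."""
    if plated_volume_ml <= 0:
        raise ValueError("plated volume must be positive")
    if colonies < 0 or dilution_factor <= 0:
        raise ValueError("colonies must be >= 0 and dilution factor > 0")
    return colonies * dilution_factor / plated_volume_ml


# --------------------------------------------------------------------------
# dose-response fitting
# --------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    relative_ic50: float | None
    absolute_ic50: float | None
    hill: float | None
    r2: float | None
    se: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    plateaus: tuple[float, float] | None = None  # (top, bottom) of the free fit


def _constrained(logx: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** ((logx - log_ic50) * hill))


def _free4pl(logx: np.ndarray, log_xmid: float, hill: float,
             top: float, bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logx - log_xmid) * hill))


def _multistart_fit(func, logx, y, starts, bounds):
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(func, logx, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((y - func(logx, *popt)) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    return best


def fit_dose_response(doses, responses, seed: int = 0) -> DoseResponseFit:
    """Fit the variable-slope dose-response model to viability data.

    Parameters
    ----------
    doses
        Positive concentrations, one per well (replicates repeat the dose).
    responses
        Viability percentages aligned with ``doses``; untreated = 100.
    seed
        Seeds the jittered multi-start initialisation; the fit is
        deterministic for fixed data and seed.
    """
    doses = np.asarray(doses, dtype=float).ravel()
    responses = np.asarray(responses, dtype=float).ravel()
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must be aligned")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (log scale)")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")

    logx = np.log10(doses)
    y = responses

    if float(np.ptp(y)) < 1e-9:
        return DoseResponseFit(None, None, None, None,
                               flags=["NO_RESPONSE"])

    rng = np.random.default_rng(seed)
    lo, hi = logx.min() - 2.0, logx.max() + 2.0
    base_p = float(np.median(logx))
    starts = [(p, h) for p in (base_p, logx.min(), logx.max())
              for h in (0.5, 1.0, 2.0, 4.0)]
    starts += [(float(rng.uniform(lo, hi)), float(rng.uniform(0.2, 6.0)))
               for _ in range(6)]

    fit_c = _multistart_fit(_constrained, logx, y, starts,
                            bounds=([lo, 0.01], [hi, 50.0]))
    if fit_c is None:
        return DoseResponseFit(None, None, None, None, flags=["FIT_FAILED"])

    (p_c, h_c), pcov_c, ss_res = fit_c
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rel_ic50 = 10.0 ** p_c

    perr = np.sqrt(np.diag(pcov_c)) if np.all(np.isfinite(pcov_c)) else [np.nan, np.nan]
    se = {
        "relative_ic50": math.log(10) * rel_ic50 * float(perr[0]),
        "hill": float(perr[1]),
    }

    # free-plateau variant defines the absolute IC50
    starts4 = [(p, h, 100.0, 0.0) for (p, h) in starts[:8]]
    starts4 += [(p_c, h_c, 100.0, 0.0)]
    fit_f = _multistart_fit(_free4pl, logx, y, starts4,
                            bounds=([lo, 0.01, 20.0, -50.0],
                                    [hi, 50.0, 200.0, 80.0]))
    flags: list[str] = []
    abs_ic50 = None
    plateaus = None
    if fit_f is not None:
        (p_f, h_f, top, bottom), _, _ = fit_f
        plateaus = (float(top), float(bottom))
        # solve bottom + (top-bottom)/(1 + (x/xmid)^h) = 50
        if top > 50.0 > bottom:
            ratio = (top - 50.0) / (50.0 - bottom)
            abs_ic50 = float(10.0 ** p_f * ratio ** (1.0 / h_f))
        else:
            flags.append("ABSOLUTE_IC50_UNDEFINED")
    else:
        flags.append("ABSOLUTE_IC50_UNDEFINED")

    return DoseResponseFit(
        relative_ic50=float(rel_ic50),
        absolute_ic50=abs_ic50,
        hill=float(h_c),
        r2=float(r2),
        se=se,
        flags=flags,
        plateaus=plateaus,
    )
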