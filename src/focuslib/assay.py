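"""Assay mathematics: normalization, 4PL fits, EC-fraction and Cheng-Prusoff.

The binding side normalizes raw radioligand counts to percent displacement
between the total-binding and nonspecific-binding windows; the functional
side normalizes to percent inhibition between agonist-stimulated and basal
signal. Dose-response data are fit with the four-parameter logistic
(variable-slope) model

    response = bottom + (top - bottom) / (1 + 10^((log10 IC50 - log10 c) * hill))

and displacement IC50s convert to inhibition constants with the
Cheng-Prusoff correction Ki = IC50 / (1 + [L]/KD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import ContractError, DegenerateWindowError, FitError
from .fixtures import four_pl


@dataclass(frozen=True)
class AssayConstants:
    """Study constants for the radioligand binding and functional assays."""

    radioligand_conc_nm: float = 6.0  # [3H]-radioligand concentration
    radioligand_kd_nm: float = 6.3  # its affinity for the receptor
    ec80_agonist_conc_nm: float = 5.15  # agonist challenge dose

    def __post_init__(self) -> None:
        if self.radioligand_kd_nm <= 0 or self.ec80_agonist_conc_nm <= 0:
            raise ContractError("assay concentrations must be positive")


def percent_displacement(total_counts: float, nsb_counts: float, sample_counts: float) -> float:
    """Percent of specific radioligand binding displaced by the sample.

    100 * (total - sample) / (total - NSB). Values outside [0, 100] are
    returned as-is (the caller sees the clamping flag via
    :func:`is_out_of_window`); a non-positive window is an error.
    """
    if total_counts <= nsb_counts:
        raise DegenerateWindowError("total binding must exceed nonspecific binding")
    return 100.0 * (total_counts - sample_counts) / (total_counts - nsb_counts)


def percent_inhibition(stimulated: float, basal: float, sample: float) -> float:
    """Percent inhibition of the agonist-stimulated signal."""
    if stimulated <= basal:
        raise DegenerateWindowError("stimulated signal must exceed basal")
    return 100.0 * (stimulated - sample) / (stimulated - basal)


def is_out_of_window(percent: float) -> bool:
    return not 0.0 <= percent <= 100.0


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    hill: float
    log_ic50: float  # log10 molar
    standard_errors: dict = field(default_factory=dict)
    n_points: int = 0

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50

    @property
    def pic50(self) -> float:
        return -self.log_ic50

    # alias names for agonist curves
    @property
    def log_ec50(self) -> float:
        return self.log_ic50

    @property
    def pec50(self) -> float:
        return self.pic50


def fit_4pl(concentrations_molar: Sequence[float], responses: Sequence[float],
            direction: str = "auto") -> DoseResponseFit:
    """Least-squares 4PL fit with a deterministic initialization rule.

    Initialization: bottom/top from the data extremes, log IC50 from the
    concentration nearest the half-maximal response, hill = +1 for
    increasing curves and -1 for decreasing ones (``direction`` can force
    either; ``auto`` infers it from the ends of the curve). The fit is
    reported in the orientation bottom <= top.
    """
    conc = np.asarray(concentrations_molar, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if len(conc) != len(resp):
        raise ContractError("concentrations and responses differ in length")
    if len(np.unique(conc)) < 4:
        raise ContractError("4PL fit needs at least 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ContractError("concentrations must be positive (molar)")

    order = np.argsort(conc)
    low_end, high_end = resp[order[:2]].mean(), resp[order[-2:]].mean()
    if direction == "auto":
        direction = "increasing" if high_end >= low_end else "decreasing"
    hill0 = 1.0 if direction == "increasing" else -1.0
    bottom0, top0 = float(resp.min()), float(resp.max())
    half = (bottom0 + top0) / 2.0
    log_ic50_0 = float(np.log10(conc[np.argmin(np.abs(resp - half))]))

    def model(c, bottom, top, hill, log_ic50):
        return four_pl(c, bottom, top, hill, log_ic50)

    try:
        popt, pcov = curve_fit(
            model, conc, resp,
            p0=[bottom0, top0, hill0, log_ic50_0],
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, hill, log_ic50 = (float(v) for v in popt)
    errors = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    se = dict(zip(("bottom", "top", "hill", "log_ic50"), (float(e) for e in errors)))
    if bottom > top:  # reorient: the two parameterizations are equivalent
        bottom, top, hill = top, bottom, -hill
        se["bottom"], se["top"] = se["top"], se["bottom"]
    if not math.isfinite(hill) or hill == 0:
        raise FitError("fit produced a degenerate Hill slope")
    return DoseResponseFit(bottom, top, hill, log_ic50, se, len(conc))


def cheng_prusoff_ki(ic50_molar: float, radioligand_conc_molar: float, kd_molar: float) -> float:
    """Ki = IC50 / (1 + [L]/KD); all concentrations in molar."""
    if ic50_molar <= 0:
        raise ContractError("IC50 must be positive")
    if kd_molar <= 0:
        raise ContractError("radioligand KD must be positive")
    if radioligand_conc_molar < 0:
        raise ContractError("radioligand concentration must be >= 0")
    return ic50_molar / (1.0 + radioligand_conc_molar / kd_molar)


def pki(ki_molar: float) -> float:
    return -math.log10(ki_molar)


def ic50_to_pic50(ic50_molar: float) -> float:
    if ic50_molar <= 0:
        raise ContractError("IC50 must be positive")
    return -math.log10(ic50_molar)


def ec_fraction(ec50_molar: float, hill: float, fraction: float) -> float:
    """Concentration producing the given fractional response (e.g. 0.8 -> EC80)."""
    if not 0.0 < fraction < 1.0:
        raise ContractError("fraction must be in (0, 1)")
    if hill == 0:
        raise ContractError("Hill slope must be nonzero")
    return ec50_molar * (fraction / (1.0 - fraction)) ** (1.0 / hill)


@dataclass(frozen=True)
class BindingResult:
    ic50_molar: float
    ki_molar: float

    @property
    def pki(self) -> float:
        return -math.log10(self.ki_molar)


def binding_result(ic50_molar: float, constants: Optional[AssayConstants] = None) -> BindingResult:
    """Convenience wrapper applying the study constants (explicit overridable)."""
    constants = constants or AssayConstants()
    ki = cheng_prusoff_ki(
        ic50_molar,
        constants.radioligand_conc_nm * 1e-9,
        constants.radioligand_kd_nm * 1e-9,
    )
    return BindingResult(ic50_molar, ki)
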