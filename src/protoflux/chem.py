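"""Acid-base speciation, buffer capacity, electrochemical potentials and
fluorescent-probe response models.

This is the computational kernel shared by the vesicle simulator, the trace
analysis and the synthetic-data generator.  Everything here is closed-form.

Conventions
-----------
* ``delta_psi = psi_in - psi_out`` (mV).
* :func:`pmf` returns the electrochemical free energy (kcal/mol) of moving one
  proton from the vesicle *interior* to the *exterior*; negative values mean
  proton efflux is downhill.
* Probe calibration follows the ratiometric pyranine relation
  ``pH = a * log10(I404/I454) + b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import F_KCAL_PER_V, LN10, R_KCAL, T_DEFAULT, rt

__all__ = [
    "AcidBaseSpecies",
    "IonSpecies",
    "ProbeCalibration",
    "AcmaResponse",
    "speciate",
    "deprotonated_fraction",
    "buffer_capacity",
    "nernst_potential",
    "pmf",
    "pyranine_pH",
    "pyranine_intensities",
    "acma_quench",
    "DEFAULT_PKA",
]

# default pKa set; only acetate's value is anchored experimentally, the others
# are standard literature values exposed for override in configs
DEFAULT_PKA = {
    "acetate": 4.8,
    "mops": 7.20,
    "pyranine": 7.30,
    "methylamine": 10.6,
    "hepes": 7.50,
    "bicine": 8.35,
}


@dataclass(frozen=True)
class AcidBaseSpecies:
    """A monoprotic acid-base species.

    Parameters
    ----------
    name : str
    pKa : float
        Acid dissociation constant at the reference temperature.
    total_conc : float
        Total concentration (both protonation forms), mM.
    charge_deprotonated : int
        Charge of the deprotonated form in elementary charges (the protonated
        form carries ``charge_deprotonated + 1``).
    permeant_form : {"protonated", "deprotonated", "none"}
        Which protonation form crosses the lipid bilayer: the neutral acid for
        acetate-like species, the neutral amine for methylamine-like species.
    """

    name: str
    pKa: float
    total_conc: float
    charge_deprotonated: int = -1
    permeant_form: Literal["protonated", "deprotonated", "none"] = "none"

    def __post_init__(self) -> None:
        if not math.isfinite(self.pKa):
            raise ValueError(f"{self.name}: pKa must be finite")
        if self.total_conc < 0:
            raise ValueError(f"{self.name}: total_conc must be >= 0")

    def with_conc(self, total_conc: float) -> "AcidBaseSpecies":
        return AcidBaseSpecies(
            self.name, self.pKa, total_conc, self.charge_deprotonated, self.permeant_form
        )


@dataclass(frozen=True)
class IonSpecies:
    """A (non-titratable) ion in a compartment."""

    name: str
    charge: int
    conc: float  # mM

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"{self.name}: conc must be >= 0")


@dataclass(frozen=True)
class ProbeCalibration:
    """Ratiometric pyranine calibration ``pH = a log10(I404/I454) + b``."""

    slope_a: float = 1.1684
    intercept_b: float = 7.721

    def __post_init__(self) -> None:
        if not self.slope_a > 0:
            raise ValueError("slope_a must be > 0")


@dataclass(frozen=True)
class AcmaResponse:
    """Hill-type mapping of the transmembrane pH difference to ACMA quench.

    ``Q(dpH) = q_max * dpH**h / (half_sat**h + dpH**h)``.

    ACMA quenching in vesicles is a saturable monotone reporter of interior
    acidification; the Hill form is a phenomenological response law whose
    parameters are calibrated against the observed quench plateaus.
    """

    q_max: float = 0.95
    half_sat: float = 0.938  # pH units
    hill: float = 2.73

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must be in (0, 1]")
        if not self.half_sat > 0:
            raise ValueError("half_sat must be > 0")
        if self.hill < 1:
            raise ValueError("hill must be >= 1")


def deprotonated_fraction(pH, pKa):
    """Fraction of a monoprotic species in the deprotonated (base) form."""
    return 1.0 / (1.0 + np.power(10.0, pKa - np.asarray(pH, dtype=float)))


def speciate(pH: float, sp: AcidBaseSpecies) -> tuple[float, float]:
    """Henderson-Hasselbalch split of a species at the given pH.

    Returns ``(protonated, deprotonated)`` concentrations in mM; they sum to
    ``sp.total_conc`` exactly and obey ``deprot/prot = 10**(pH - pKa)``.
    """
    pH = float(pH)
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    alpha = float(deprotonated_fraction(pH, sp.pKa))
    deprot = sp.total_conc * alpha
    return sp.total_conc - deprot, deprot


def buffer_capacity(pH: float, species_list: Sequence[AcidBaseSpecies]) -> float:
    """Buffer capacity beta = ln(10) * sum_i C_i * alpha_i * (1 - alpha_i).

    Units: mM per pH unit.  Equals -d(total bound protons)/d(pH); the free
    proton term is excluded (negligible at the mM buffer concentrations and
    near-neutral pH of the assays, and accounted for separately where needed).
    """
    if len(species_list) == 0:
        raise ValueError("species_list must be non-empty")
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    beta = 0.0
    for sp in species_list:
        a = float(deprotonated_fraction(pH, sp.pKa))
        beta += sp.total_conc * a * (1.0 - a)
    return LN10 * beta


def nernst_potential(charge: int, c_out: float, c_in: float, T: float = T_DEFAULT) -> float:
    """Nernst equilibrium potential in mV, sign convention psi_in - psi_out.

    ``E = (RT / zF) ln(c_out / c_in)``.
    """
    if charge == 0:
        raise ValueError("charge must be nonzero")
    if not (c_out > 0 and c_in > 0):
        raise ValueError("concentrations must be > 0")
    return 1000.0 * (R_KCAL * T) / (charge * F_KCAL_PER_V) * math.log(c_out / c_in)


def pmf(pH_in: float, pH_out: float, delta_psi: float, T: float = T_DEFAULT) -> float:
    """Proton electrochemical free energy for one proton moving in -> out.

    ``pmf = -F*delta_psi - 2.303 RT (pH_out - pH_in)`` in kcal/mol, with
    ``delta_psi = psi_in - psi_out`` in mV.  Negative when efflux is downhill
    (acidic interior and/or interior-positive potential).
    """
    for v in (pH_in, pH_out, delta_psi):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    return -F_KCAL_PER_V * (delta_psi / 1000.0) - LN10 * rt(T) * (pH_out - pH_in)


def pyranine_pH(I404, I454, cal: ProbeCalibration = ProbeCalibration()):
    """Convert the 404/454 nm excitation intensity pair to pH.

    Accepts scalars or arrays; raises on non-positive intensities.
    """
    I404 = np.asarray(I404, dtype=float)
    I454 = np.asarray(I454, dtype=float)
    if np.any(I404 <= 0) or np.any(I454 <= 0):
        raise ValueError("intensities must be > 0")
    out = cal.slope_a * np.log10(I404 / I454) + cal.intercept_b
    return float(out) if out.ndim == 0 else out


def pyranine_intensities(pH, cal: ProbeCalibration = ProbeCalibration(), total_scale: float = 100.0):
    """Inverse of :func:`pyranine_pH`: render an intensity pair for a pH.

    The two channels share ``total_scale`` (I404 + I454 = total_scale); only
    their ratio is pH-determined, so any positive split works, and the
    recovered pH is invariant to ``total_scale``.
    """
    if not total_scale > 0:
        raise ValueError("total_scale must be > 0")
    pH = np.asarray(pH, dtype=float)
    ratio = np.power(10.0, (pH - cal.intercept_b) / cal.slope_a)
    I404 = total_scale * ratio / (1.0 + ratio)
    I454 = total_scale / (1.0 + ratio)
    if pH.ndim == 0:
        return float(I404), float(I454)
    return I404, I454


def acma_quench(delta_pH, resp: AcmaResponse = AcmaResponse()):
    """ACMA quench fraction for an interior-acidic pH difference >= 0."""
    dpH = np.asarray(delta_pH, dtype=float)
    if np.any(dpH < 0):
        raise ValueError("delta_pH must be >= 0")
    num = np.power(dpH, resp.hill)
    out = resp.q_max * num / (resp.half_sat**resp.hill + num)
    return float(out) if out.ndim == 0 else out
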