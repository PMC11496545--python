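"""Event-driven ODE model of a proteoliposome proton-conduction assay.

A single representative vesicle is simulated.  The interior is a closed
compartment whose total titratable proton content, weak-acid/base totals,
K+ content and membrane potential evolve in time; the exterior is an infinite
clamped reservoir (the cuvette).  Interior pH is resolved algebraically at
every step from the proton content (instantaneous acid-base equilibrium).

Processes (all fluxes in mM of interior volume per second):

* neutral-form permeation of the weak acid/base (acetic acid, methylamine),
* antiporter proton flux through a symmetric Eyring barrier,
  ``J = N k 2 sinh(pmf / 2RT)`` (electrogenic),
* a small non-specific background proton leak of the same form,
* valinomycin K+ current relaxing the potential toward the K+ Nernst value,
* nigericin electroneutral H+/K+ exchange,
* optional ATP-synthase pumping with a linear stall law,
* membrane potential integrated from net charge flux over the capacitance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import chem
from .chem import AcidBaseSpecies, AcmaResponse, IonSpecies, ProbeCalibration
from .barrier import eyring_rate
from .constants import F_KCAL_PER_V, LN10, N_AVOGADRO, T_DEFAULT, rt

__all__ = [
    "CompartmentState",
    "Vesicle",
    "ConstructPreset",
    "PumpATPase",
    "Ionophore",
    "Event",
    "EventSchedule",
    "ProtonFluxAssay",
    "AssayResult",
    "load_presets",
    "get_preset",
    "acetate_assay",
    "methylamine_assay",
    "atp_competition_assay",
]


# --------------------------------------------------------------------------
# compartments and vesicle geometry
# --------------------------------------------------------------------------

@dataclass
class CompartmentState:
    """Chemical state of one side of the membrane."""

    pH: float
    buffers: list[AcidBaseSpecies] = field(default_factory=list)
    ions: list[IonSpecies] = field(default_factory=list)
    is_reservoir: bool = False

    def ion_conc(self, name: str) -> float:
        for ion in self.ions:
            if ion.name == name:
                return ion.conc
        return 0.0

    def implicit_counter_charge(self) -> float:
        """Charge (mM of monovalent equivalents) of the implicit counter-ion
        that balances the explicit species at initialisation."""
        q = 0.0
        for ion in self.ions:
            q += ion.charge * ion.conc
        for sp in self.buffers:
            prot, deprot = chem.speciate(self.pH, sp)
            q += prot * (sp.charge_deprotonated + 1) + deprot * sp.charge_deprotonated
        return -q


@dataclass
class Vesicle:
    """Vesicle geometry and electrical properties (single representative)."""

    diameter_nm: float
    bilayer_thickness_nm: float = 4.0
    capacitance_uF_cm2: float = 1.0
    interior: CompartmentState = None
    exterior: CompartmentState = None

    def __post_init__(self) -> None:
        if not self.diameter_nm > 2 * self.bilayer_thickness_nm:
            raise ValueError("diameter must exceed twice the bilayer thickness")

    @property
    def volume_L(self) -> float:
        d_cm = self.diameter_nm * 1e-7
        return math.pi / 6.0 * d_cm**3 * 1e-3  # cm^3 -> L

    @property
    def area_cm2(self) -> float:
        d_cm = self.diameter_nm * 1e-7
        return math.pi * d_cm**2

    @property
    def area_over_volume_cm(self) -> float:
        """Surface-to-volume ratio, cm^-1 (= 6/d for a sphere)."""
        return self.area_cm2 / (self.volume_L * 1e3)

    @property
    def per_proton_mM(self) -> float:
        """Interior concentration increment of a single molecule, mM."""
        return 1.0 / (N_AVOGADRO * self.volume_L) * 1e3

    @property
    def capacitance_mM_per_mV(self) -> float:
        """Specific charge of the membrane capacitor in mM per mV."""
        cap_F = self.capacitance_uF_cm2 * 1e-6 * self.area_cm2
        mol_per_mV = cap_F * 1e-3 / 96485.332
        return mol_per_mV / self.volume_L * 1e3


# --------------------------------------------------------------------------
# presets, pump, ionophores, schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstructPreset:
    """Per-construct channel parameters.

    ``barrier_dg`` is the lateral proton-transfer barrier (kcal/mol) of the
    construct's resting ion-pair state; ``blocked`` marks proton-wire
    substitutions (K235M, E377Q, K385I) that abolish conduction.  ``driving_dg``
    stores the QM/MM thermodynamic driving force, used only for direction
    sanity checks, never in the rate law.
    """

    name: str
    barrier_dg: float = 14.0
    copies_per_vesicle: int = 1
    electrogenic: bool = True
    orientation_n_in: float = 0.75
    blocked: bool = False
    driving_dg: float = 0.0

    def __post_init__(self) -> None:
        if self.copies_per_vesicle < 0:
            raise ValueError("copies_per_vesicle must be >= 0")
        if not (0.0 <= self.orientation_n_in <= 1.0):
            raise ValueError("orientation_n_in must be in [0, 1]")

    def rate_constant(self, attempt: float, cap: float, T: float = T_DEFAULT) -> float:
        """Effective per-channel rate constant (s^-1): attempt-probability x
        Eyring rate, capped by a delivery-limited maximum turnover."""
        if self.blocked or self.copies_per_vesicle == 0:
            return 0.0
        return min(attempt * eyring_rate(self.barrier_dg, T), cap)


@dataclass(frozen=True)
class PumpATPase:
    """F1Fo ATP synthase operating in hydrolysis (pumping) mode.

    Flux = ``copies * turnover_max * max(0, 1 - load/stall_pmf)`` with the
    load the proton electrochemical gradient opposing pumping (out -> in).
    """

    turnover_max: float = 2400.0  # H+ s^-1 per complex
    reference_potential_mV: float = 120.0
    stall_pmf: float = 4.0  # kcal/mol
    copies: int = 1

    def __post_init__(self) -> None:
        if not self.turnover_max > 0:
            raise ValueError("turnover_max must be > 0")

    def flux(self, load: float) -> float:
        """Pumping rate in H+ s^-1 per vesicle at the given load (kcal/mol)."""
        return self.copies * self.turnover_max * max(0.0, 1.0 - load / self.stall_pmf)


@dataclass(frozen=True)
class Ionophore:
    kind: str  # "valinomycin" | "nigericin"
    rate_coeff: float = 1.0
    active_from: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("valinomycin", "nigericin"):
            raise ValueError(f"unknown ionophore {self.kind!r}")
        if self.rate_coeff < 0:
            raise ValueError("rate_coeff must be >= 0")


ACTIONS = ("add_acetate", "add_methylamine", "add_atp", "add_nigericin", "add_valinomycin")


@dataclass(frozen=True)
class Event:
    time: float
    action: str
    amount: float = 0.0

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")


@dataclass
class EventSchedule:
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")

    def first_time(self, action: str) -> Optional[float]:
        for e in self.events:
            if e.action == action:
                return e.time
        return None


# --------------------------------------------------------------------------
# preset library (shipped JSON resource)
# --------------------------------------------------------------------------

_ALIASES = {
    "WT-Nqo12ΔTH": "WT-Nqo12dTH",
    "Empty": "empty",
    "EL": "empty",
}


def load_presets() -> dict:
    """Load the versioned preset library shipped with the package."""
    with resources.files("protoflux.data").joinpath("presets.json").open() as fh:
        return json.load(fh)


def get_preset(name: str, library: Optional[dict] = None) -> ConstructPreset:
    lib = library or load_presets()
    key = _ALIASES.get(name, name)
    entry = lib["constructs"].get(key)
    if entry is None:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(lib['constructs'])}"
        )
    return ConstructPreset(
        name=key,
        barrier_dg=entry["barrier_dg"],
        copies_per_vesicle=entry["copies_per_vesicle"],
        electrogenic=entry["electrogenic"],
        orientation_n_in=entry.get("orientation_n_in", 0.75),
        blocked=entry.get("blocked", False),
        driving_dg=entry.get("driving_dg", 0.0),
    )


# --------------------------------------------------------------------------
# the assay model
# --------------------------------------------------------------------------

# state vector indices
_IH, _IA, _IM, _IK, _IPSI = 0, 1, 2, 3, 4
_ICUM = 5  # cumulative flux diagnostics start here
_CUM_NAMES = ("cum_acid_in", "cum_base_in", "cum_channel_in", "cum_leak_in",
              "cum_pump_in", "cum_nigericin_out")
_NSTATE = _ICUM + len(_CUM_NAMES)


class ProtonFluxAssay:
    """Forward model of one proteoliposome assay.

    Parameters
    ----------
    vesicle : Vesicle
        Geometry plus interior/exterior compartment recipes.
    preset : ConstructPreset
        Antiporter construct reconstituted in the membrane.
    schedule : EventSchedule
        Timed additions (weak acid/base, ATP, ionophores).
    pump : PumpATPase, optional
        Co-reconstituted ATP synthase (activated by the ``add_atp`` event).
    ionophores : sequence of Ionophore
        Valinomycin/nigericin already present at t=0; scheduled
        ``add_valinomycin``/``add_nigericin`` events activate them later.
    channel_attempt, channel_cap : float
        Effective-rate parameters handed to the preset (see presets file).
    leak_rate : float
        Background proton-leak rate constant, s^-1 per vesicle.
    """

    def __init__(
        self,
        vesicle: Vesicle,
        preset: ConstructPreset,
        schedule: EventSchedule,
        pump: Optional[PumpATPase] = None,
        ionophores: Sequence[Ionophore] = (),
        channel_attempt: float = 1.0,
        channel_cap: float = 1.0e3,
        leak_rate: float = 0.2,
        permeability_acid: float = 6e-3,  # cm/s, acetic acid
        permeability_base: float = 1e-3,  # cm/s, methylamine
        nigericin_rate: float = 1.0,      # mM/s per ln-unit of driving
        valinomycin_tau: float = 0.05,    # s
        temperature: float = T_DEFAULT,
        pKa: Optional[dict] = None,
    ):
        self.vesicle = vesicle
        self.preset = preset
        self.schedule = schedule
        self.pump = pump
        self.ionophores = list(ionophores)
        self.leak_rate = leak_rate
        self.P_acid = permeability_acid
        self.P_base = permeability_base
        self.k_nig = nigericin_rate
        self.tau_val = valinomycin_tau
        self.T = temperature
        self.pKa = dict(chem.DEFAULT_PKA)
        if pKa:
            self.pKa.update(pKa)

        # per-vesicle effective channel rate (s^-1); both membrane orientations
        # conduct identically through the symmetric barrier, so the 75%/25%
        # orientation split enters as a sum of weights (= 1 here), kept
        # explicit for generality
        k1 = preset.rate_constant(channel_attempt, channel_cap, temperature)
        w = preset.orientation_n_in + (1.0 - preset.orientation_n_in)
        self.k_channel = preset.copies_per_vesicle * k1 * w

        self._sa_over_v = vesicle.area_over_volume_cm
        self._per_proton = vesicle.per_proton_mM
        self._cap = vesicle.capacitance_mM_per_mV
        self._rt = rt(temperature)

    # -- interior acid-base bookkeeping ---------------------------------
    def _interior_species(self, a_tot: float, m_tot: float) -> list[AcidBaseSpecies]:
        out = list(self.vesicle.interior.buffers)
        out.append(AcidBaseSpecies("acetate", self.pKa["acetate"], a_tot, -1, "protonated"))
        out.append(AcidBaseSpecies("methylamine", self.pKa["methylamine"], m_tot, 0, "deprotonated"))
        return out

    @staticmethod
    def _h_total(pH: float, species: Sequence[AcidBaseSpecies]) -> float:
        """Total titratable protons (mM): free H+ - OH- + bound to species."""
        h = 10.0 ** (3.0 - pH) - 10.0 ** (pH - 11.0)
        for sp in species:
            h += sp.total_conc * (1.0 - float(chem.deprotonated_fraction(pH, sp.pKa)))
        return h

    def _solve_pH(self, h_tot: float, species: Sequence[AcidBaseSpecies], guess: float) -> float:
        """Invert _h_total for pH (Newton with analytic slope, brentq fallback)."""
        pH = min(max(guess, 1.0), 13.0)
        for _ in range(30):
            f = self._h_total(pH, species) - h_tot
            beta = chem.buffer_capacity(pH, species) if species else 0.0
            slope = -LN10 * (10.0 ** (3.0 - pH) + 10.0 ** (pH - 11.0)) - beta
            step = f / slope
            new = pH - step
            if not (0.0 < new < 14.0):
                break
            pH = new
            if abs(step) < 1e-13:
                return pH
        return brentq(lambda x: self._h_total(x, species) - h_tot, 0.0, 14.0, xtol=1e-13)

    # -- right-hand side -------------------------------------------------
    def _fluxes(self, y: np.ndarray, ext: dict, active: dict) -> dict:
        """All fluxes (mM/s, positive into the interior unless noted)."""
        h_tot, a_tot, m_tot, k_in = y[_IH], y[_IA], y[_IM], max(y[_IK], 1e-9)
        psi = y[_IPSI]
        species = self._interior_species(max(a_tot, 0.0), max(m_tot, 0.0))
        pH_in = self._solve_pH(h_tot, species, guess=self._pH_guess)
        self._pH_guess = pH_in

        pH_out = ext["pH"]
        # neutral-form partitioning
        ha_in = max(a_tot, 0.0) * (1.0 - float(chem.deprotonated_fraction(pH_in, self.pKa["acetate"])))
        ha_out = ext["acetate"] * (1.0 - float(chem.deprotonated_fraction(pH_out, self.pKa["acetate"])))
        b_in = max(m_tot, 0.0) * float(chem.deprotonated_fraction(pH_in, self.pKa["methylamine"]))
        b_out = ext["methylamine"] * float(chem.deprotonated_fraction(pH_out, self.pKa["methylamine"]))

        j_acid = self.P_acid * self._sa_over_v * (ha_out - ha_in)
        j_base = self.P_base * self._sa_over_v * (b_out - b_in)

        mu = chem.pmf(pH_in, pH_out, psi, self.T)  # kcal/mol, in -> out
        x = mu / (2.0 * self._rt)
        sinh_term = 2.0 * math.sinh(max(min(x, 50.0), -50.0))
        j_channel = self._per_proton * self.k_channel * sinh_term
        j_leak = self._per_proton * self.leak_rate * sinh_term

        j_pump = 0.0
        if self.pump is not None and active["pump"]:
            j_pump = self._per_proton * self.pump.flux(-mu)

        j_val_K = 0.0
        if active["valinomycin"]:
            k_out = max(ext["K"], 1e-9)
            e_k = chem.nernst_potential(1, k_out, k_in, self.T)
            j_val_K = self._cap * (e_k - psi) / self.tau_val

        j_nig = 0.0
        if active["nigericin"]:
            # H+ out / K+ in, positive when interior is acid-rich vs K ratio
            arg = LN10 * (pH_out - pH_in) + math.log(max(ext["K"], 1e-9) / k_in)
            j_nig = self.k_nig * arg

        return {
            "pH_in": pH_in,
            "j_acid": j_acid,
            "j_base": j_base,
            "j_channel": j_channel,
            "j_leak": j_leak,
            "j_pump": j_pump,
            "j_val_K": j_val_K,
            "j_nig": j_nig,
        }

    def _rhs(self, t: float, y: np.ndarray, ext: dict, active: dict) -> np.ndarray:
        fl = self._fluxes(y, ext, active)
        dy = np.zeros(_NSTATE)
        dy[_IH] = fl["j_acid"] + fl["j_channel"] + fl["j_leak"] + fl["j_pump"] - fl["j_nig"]
        dy[_IA] = fl["j_acid"]
        dy[_IM] = fl["j_base"]
        dy[_IK] = fl["j_val_K"] + fl["j_nig"]
        charge = fl["j_val_K"] + fl["j_pump"] + fl["j_leak"]
        if self.preset.electrogenic:
            charge += fl["j_channel"]
        dy[_IPSI] = charge / self._cap
        dy[_ICUM + 0] = fl["j_acid"]
        dy[_ICUM + 1] = fl["j_base"]
        dy[_ICUM + 2] = fl["j_channel"]
        dy[_ICUM + 3] = fl["j_leak"]
        dy[_ICUM + 4] = fl["j_pump"]
        dy[_ICUM + 5] = fl["j_nig"]
        return dy

    # -- public API ------------------------------------------------------
    def run(
        self,
        t_end: float,
        dt_out: float = 0.6,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        probe: str = "pyranine",
        calibration: ProbeCalibration = ProbeCalibration(),
        acma: AcmaResponse = AcmaResponse(),
    ) -> "AssayResult":
        """Integrate the assay and return an :class:`AssayResult`.

        ``probe`` selects which fluorescence channels are rendered
        ("pyranine" or "acma").
        """
        interior = self.vesicle.interior
        exterior = self.vesicle.exterior
        if not exterior.is_reservoir:
            raise ValueError("exterior compartment must be flagged as a reservoir")
        for ev in self.schedule.events:
            if not (0.0 <= ev.time <= t_end):
                raise ValueError("schedule events must lie within [0, t_end]")

        ext = {
            "pH": exterior.pH,
            "K": exterior.ion_conc("K"),
            "acetate": 0.0,
            "methylamine": 0.0,
        }
        for sp in exterior.buffers:
            if sp.name == "acetate":
                ext["acetate"] = sp.total_conc
            if sp.name == "methylamine":
                ext["methylamine"] = sp.total_conc

        active = {"pump": False, "valinomycin": False, "nigericin": False}
        for iono in self.ionophores:
            if iono.active_from <= 0.0:
                active[iono.kind] = True
        if not any(i.kind == "valinomycin" for i in self.ionophores):
            self.ionophores.append(Ionophore("valinomycin", active_from=math.inf))
        if not any(i.kind == "nigericin" for i in self.ionophores):
            self.ionophores.append(Ionophore("nigericin", active_from=math.inf))
        for iono in self.ionophores:
            if 0.0 < iono.active_from <= 0.0:  # pragma: no cover
                active[iono.kind] = True

        # initial state
        a0 = sum(sp.total_conc for sp in interior.buffers if sp.name == "acetate")
        m0 = sum(sp.total_conc for sp in interior.buffers if sp.name == "methylamine")
        fixed = [sp for sp in interior.buffers if sp.name not in ("acetate", "methylamine")]
        self.vesicle.interior = replace(interior, buffers=fixed)
        species0 = self._interior_species(a0, m0)
        y0 = np.zeros(_NSTATE)
        y0[_IH] = self._h_total(interior.pH, species0)
        y0[_IA] = a0
        y0[_IM] = m0
        y0[_IK] = interior.ion_conc("K")
        y0[_IPSI] = 0.0
        self._pH_guess = interior.pH

        # breakpoints: event times + ionophore activations
        breaks = sorted(
            {0.0, t_end}
            | {ev.time for ev in self.schedule.events}
            | {i.active_from for i in self.ionophores if 0.0 < i.active_from < t_end}
        )
        times, states = [], []
        t_prev = 0.0
        y = y0.copy()
        for tb in breaks:
            if tb > t_prev:
                n = max(2, int(round((tb - t_prev) / dt_out)) + 1)
                t_eval = np.linspace(t_prev, tb, n)
                sol = solve_ivp(
                    self._rhs, (t_prev, tb), y, method="BDF",
                    t_eval=t_eval, rtol=rtol, atol=atol, args=(ext, active),
                )
                if not sol.success:
                    raise RuntimeError(
                        f"integration failed in [{t_prev}, {tb}]: {sol.message}; "
                        f"state={y.tolist()}"
                    )
                keep = slice(None) if not times else slice(1, None)
                times.append(sol.t[keep])
                states.append(sol.y[:, keep])
                y = sol.y[:, -1].copy()
                t_prev = tb
            # apply whatever fires at tb
            for ev in self.schedule.events:
                if ev.time == tb:
                    if ev.action == "add_acetate":
                        ext["acetate"] += ev.amount
                    elif ev.action == "add_methylamine":
                        ext["methylamine"] += ev.amount
                    elif ev.action == "add_atp":
                        active["pump"] = True
                    elif ev.action == "add_nigericin":
                        active["nigericin"] = True
                    elif ev.action == "add_valinomycin":
                        active["valinomycin"] = True
            for iono in self.ionophores:
                if iono.active_from == tb:
                    active[iono.kind] = True

        t = np.concatenate(times)
        ys = np.concatenate(states, axis=1)

        # reconstruct pH and neutral-form series
        pH_in = np.empty_like(t)
        guess = interior.pH
        for i in range(len(t)):
            sp = self._interior_species(max(ys[_IA, i], 0.0), max(ys[_IM, i], 0.0))
            guess = self._solve_pH(ys[_IH, i], sp, guess)
            pH_in[i] = guess

        ha_in = np.maximum(ys[_IA], 0.0) * (
            1.0 - chem.deprotonated_fraction(pH_in, self.pKa["acetate"])
        )
        species = {
            "acetate_total_mM": ys[_IA],
            "acetic_acid_mM": ha_in,
            "methylamine_total_mM": ys[_IM],
            "K_mM": ys[_IK],
        }
        cum = {name: ys[_ICUM + i] for i, name in enumerate(_CUM_NAMES)}

        i404, i454 = chem.pyranine_intensities(pH_in, calibration)
        dpH = np.maximum(0.0, exterior.pH - pH_in)
        f_acma = 1.0 - chem.acma_quench(dpH, acma)

        return AssayResult(
            time=t, pH_in=pH_in, delta_psi=ys[_IPSI], species=species,
            cumulative_flux=cum, pyranine_I404=i404, pyranine_I454=i454,
            acma_F=f_acma, schedule=self.schedule, pH_out=exterior.pH,
            probe=probe, assay=self,
        )


@dataclass
class AssayResult:
    """Trajectory of a simulated assay plus probe read-outs."""

    time: np.ndarray
    pH_in: np.ndarray
    delta_psi: np.ndarray
    species: dict
    cumulative_flux: dict
    pyranine_I404: np.ndarray
    pyranine_I454: np.ndarray
    acma_F: np.ndarray
    schedule: EventSchedule
    pH_out: float
    probe: str = "pyranine"
    assay: Optional[ProtonFluxAssay] = None

    def to_frame(self, tidy: bool = False) -> pd.DataFrame:
        cols = {
            "time_s": self.time,
            "pH_in": self.pH_in,
            "dpsi_mV": self.delta_psi,
            "I404": self.pyranine_I404,
            "I454": self.pyranine_I454,
            "F_acma": self.acma_F,
        }
        cols.update(self.species)
        df = pd.DataFrame(cols)
        if tidy:
            df = df.melt(id_vars="time_s", var_name="variable", value_name="value")
        return df

    def window_mean(self, t0: float, t1: float, series: str = "pH_in") -> float:
        mask = (self.time >= t0) & (self.time <= t1)
        values = getattr(self, series) if hasattr(self, series) else self.species[series]
        return float(np.mean(values[mask]))

    def summary(self) -> str:
        lines = [
            f"Proteoliposome assay ({self.probe} read-out)",
            f"  duration          {self.time[-1]:8.1f} s  ({len(self.time)} samples)",
            f"  initial pH_in     {self.pH_in[0]:8.3f}",
            f"  final pH_in       {self.pH_in[-1]:8.3f}",
            f"  min / max pH_in   {self.pH_in.min():8.3f} / {self.pH_in.max():8.3f}",
            f"  final dpsi        {self.delta_psi[-1]:8.2f} mV",
        ]
        if self.probe == "acma":
            lines.append(f"  max ACMA quench   {100 * (1 - self.acma_F.min()):8.1f} %")
        for ev in self.schedule.events:
            lines.append(f"  event t={ev.time:7.1f} s  {ev.action}  {ev.amount} mM")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.probe == "acma":
            ax.plot(self.time, self.acma_F)
            ax.set_ylabel("relative ACMA fluorescence")
        else:
            ax.plot(self.time, self.pH_in)
            ax.set_ylabel("interior pH")
        ax.set_xlabel("time (s)")
        for ev in self.schedule.events:
            ax.axvline(ev.time, ls=":", lw=0.8, color="grey")
        return ax


# --------------------------------------------------------------------------
# assay recipes (published default buffer compositions)
# --------------------------------------------------------------------------

def _residual_buffer(lib: dict) -> AcidBaseSpecies:
    rb = lib["residual_buffer"]
    return AcidBaseSpecies("residual", rb["pKa"], rb["conc_mM"], -1, "none")


def _acetate_vesicle(lib: dict) -> Vesicle:
    interior = CompartmentState(
        pH=7.2,
        buffers=[
            AcidBaseSpecies("mops", chem.DEFAULT_PKA["mops"], 2.0, -1, "none"),
            AcidBaseSpecies("pyranine", chem.DEFAULT_PKA["pyranine"], 5.0, -4, "none"),
            _residual_buffer(lib),
        ],
        ions=[IonSpecies("K", 1, 50.0), IonSpecies("Cl", -1, 50.0)],
    )
    exterior = CompartmentState(
        pH=7.2,
        buffers=[AcidBaseSpecies("mops", chem.DEFAULT_PKA["mops"], 2.0, -1, "none")],
        ions=[IonSpecies("K", 1, 50.0), IonSpecies("Cl", -1, 50.0)],
        is_reservoir=True,
    )
    return Vesicle(diameter_nm=60.0, interior=interior, exterior=exterior)


def _atp_vesicle(lib: dict) -> Vesicle:
    interior = CompartmentState(
        pH=7.5,
        buffers=[
            AcidBaseSpecies("hepes", chem.DEFAULT_PKA["hepes"], 10.0, -1, "none"),
            _residual_buffer(lib),
        ],
        ions=[IonSpecies("K", 1, 100.0), IonSpecies("Cl", -1, 110.0),
              IonSpecies("Mg", 2, 5.0)],
    )
    exterior = CompartmentState(
        pH=7.5,
        buffers=[AcidBaseSpecies("hepes", chem.DEFAULT_PKA["hepes"], 10.0, -1, "none")],
        ions=[IonSpecies("K", 1, 100.0), IonSpecies("Cl", -1, 110.0),
              IonSpecies("Mg", 2, 5.0)],
        is_reservoir=True,
    )
    return Vesicle(diameter_nm=200.0, interior=interior, exterior=exterior)


def _weak_acid_assay(
    preset, action: str, amount: float, t_add: float, t_nig: float, t_end: float,
    library: Optional[dict] = None,
) -> ProtonFluxAssay:
    lib = library or load_presets()
    if isinstance(preset, str):
        preset = get_preset(preset, lib)
    schedule = EventSchedule([
        Event(t_add, action, amount),
        Event(t_nig, "add_nigericin"),
    ])
    return ProtonFluxAssay(
        vesicle=_acetate_vesicle(lib),
        preset=preset,
        schedule=schedule,
        ionophores=[Ionophore("valinomycin", active_from=0.0)],
        channel_attempt=lib["acetate_attempt"],
        channel_cap=lib["rate_cap_s"],
        leak_rate=lib["leak_rate_s"],
    )


def acetate_assay(preset, amount: float = 10.0, t_add: float = 60.0,
                  t_nig: float = 540.0, t_end: float = 600.0,
                  library: Optional[dict] = None, **run_kwargs) -> AssayResult:
    """Acid-driven pyranine assay (10 mM potassium acetate, 60 nm vesicle)."""
    assay = _weak_acid_assay(preset, "add_acetate", amount, t_add, t_nig, t_end, library)
    return assay.run(t_end, dt_out=0.6, probe="pyranine", **run_kwargs)


def methylamine_assay(preset, amount: float = 10.0, t_add: float = 60.0,
                      t_nig: float = 540.0, t_end: float = 600.0,
                      library: Optional[dict] = None, **run_kwargs) -> AssayResult:
    """Base-driven pyranine assay; transport direction is reversed."""
    assay = _weak_acid_assay(preset, "add_methylamine", amount, t_add, t_nig, t_end, library)
    return assay.run(t_end, dt_out=0.6, probe="pyranine", **run_kwargs)


def atp_competition_assay(preset, pump: Optional[PumpATPase] = None,
                          t_atp: float = 60.0, t_nig: float = 340.0,
                          t_end: float = 400.0,
                          library: Optional[dict] = None, **run_kwargs) -> AssayResult:
    """ATPase-driven ACMA assay (200 nm vesicle, 0.2 mM ATP)."""
    lib = library or load_presets()
    if isinstance(preset, str):
        preset = get_preset(preset, lib)
    if pump is None:
        p = lib["pump"]
        pump = PumpATPase(
            turnover_max=p["turnover_max"], stall_pmf=p["stall_pmf_kcal"],
            reference_potential_mV=p["reference_potential_mV"], copies=p["copies"],
        )
    schedule = EventSchedule([
        Event(t_atp, "add_atp", 0.2),
        Event(t_nig, "add_nigericin"),
    ])
    assay = ProtonFluxAssay(
        vesicle=_atp_vesicle(lib),
        preset=preset,
        schedule=schedule,
        pump=pump,
        ionophores=[Ionophore("valinomycin", active_from=0.0)],
        channel_attempt=lib["atp_attempt"],
        channel_cap=lib["rate_cap_s"],
        leak_rate=lib["leak_rate_s"],
    )
    acma = AcmaResponse(**lib["acma"])
    return assay.run(t_end, dt_out=0.1, probe="acma", acma=acma, **run_kwargs)
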