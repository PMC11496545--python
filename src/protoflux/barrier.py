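"""Electric-field tuning of the lateral proton-transfer barrier.

A buried Glu-Lys ion-pair sits a distance ``R`` (the *pathway distance*) from
the midpoint of the lateral proton pathway in each antiporter-like module.
Opening of the ion-pair (increasing the charge-charge separation ``d``)
changes the Coulomb field it projects along the pathway; a Stark-like linear
coupling then shifts the proton-transfer barrier:

    dG(d) = dG_closed - q_dx * [E_par(d) - E_par(d_closed)]

with ``q_dx`` an effective (transferred charge x displacement) coupling in
e*A and ``E_par`` the field component along the pathway direction.  The model
is calibrated against pairs of barrier anchors (closed/open states) and can
be transferred between modules using the point-dipole far-field 1/R^3 decay.

Rates follow transition-state theory: ``k = (k_B T / h) exp(-dG / RT)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np

from .constants import (
    COULOMB_KCAL_A,
    KB_OVER_H,
    KCAL_PER_MOL_E_A_IN_MV_CM,
    T_DEFAULT,
    rt,
)

__all__ = [
    "IonPairGeometry",
    "FieldEstimate",
    "BarrierTuningModel",
    "BarrierTuningResults",
    "pathway_field",
    "eyring_rate",
    "load_anchor_table",
]


@dataclass(frozen=True)
class IonPairGeometry:
    """Geometry of a buried ion-pair relative to a proton pathway.

    The pathway midpoint is the origin and the pathway runs along x.  The
    ion-pair midpoint sits at distance ``pathway_distance_R`` perpendicular to
    the pathway (along y); the pair axis makes an angle with the pathway
    direction whose cosine is ``orientation_cos``.  The axis points from the
    positive (lysine) to the negative (glutamate) charge, so a positive
    ``orientation_cos`` orients the stabilising field along +x.

    Units: angstrom.
    """

    separation_d: float
    pathway_distance_R: float
    orientation_cos: float = 1.0

    def __post_init__(self) -> None:
        if self.separation_d < 0:
            raise ValueError("separation_d must be >= 0")
        if not self.pathway_distance_R > self.separation_d / 2:
            raise ValueError("pathway_distance_R must exceed separation_d/2")
        if abs(self.orientation_cos) > 1:
            raise ValueError("|orientation_cos| must be <= 1")

    def charge_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian positions (A) of the +e and -e charges."""
        c = self.orientation_cos
        s = math.sqrt(max(0.0, 1.0 - c * c))
        axis = np.array([c, s, 0.0])
        mid = np.array([0.0, self.pathway_distance_R, 0.0])
        half = 0.5 * self.separation_d * axis
        return mid - half, mid + half  # (+e, -e)


@dataclass(frozen=True)
class FieldEstimate:
    """Electric-field component along the pathway direction, MV/cm."""

    e_parallel: float


def pathway_field(geom: IonPairGeometry, eps: float = 4.0) -> FieldEstimate:
    """Exact two-point-charge Coulomb field at the pathway midpoint.

    The field of the +e/-e pair is evaluated at the origin, projected on the
    pathway direction (x) and screened by the effective dielectric ``eps``.
    For ``R >> d`` this reduces to the point-dipole far-field
    ``E_par = k q d cos(theta) / (eps R^3)``.
    """
    if eps < 1:
        raise ValueError("eps must be >= 1")
    pos_p, pos_m = geom.charge_positions()
    ex = 0.0
    for q, pos in ((+1.0, pos_p), (-1.0, pos_m)):
        r = -pos  # vector from charge to the evaluation point (origin)
        rn = float(np.linalg.norm(r))
        ex += q * r[0] / rn**3
    # kcal/(mol e A) -> MV/cm
    e_par = COULOMB_KCAL_A * ex / eps * KCAL_PER_MOL_E_A_IN_MV_CM
    return FieldEstimate(e_parallel=e_par)


def dipole_far_field(geom: IonPairGeometry, eps: float = 4.0) -> float:
    """Point-dipole approximation of :func:`pathway_field` (MV/cm)."""
    p = geom.separation_d * geom.orientation_cos  # e*A along x
    return (
        COULOMB_KCAL_A * p / (eps * geom.pathway_distance_R**3) * KCAL_PER_MOL_E_A_IN_MV_CM
    )


def eyring_rate(dg: float, T: float = T_DEFAULT) -> float:
    """Transition-state-theory rate constant (s^-1) for a barrier in kcal/mol."""
    return KB_OVER_H * T * math.exp(-dg / rt(T))


class BarrierTuningModel:
    """Two-parameter Stark model of barrier modulation, fit to anchors.

    Parameters
    ----------
    anchors : sequence of (separation_d, barrier)
        Ion-pair separations (A) and QM/MM barrier anchors (kcal/mol).  The
        smallest-separation anchor pins the closed-state reference barrier.
    pathway_distance_R : float
        Ion-pair-to-pathway distance (A).
    orientation_cos : float
        Ion-pair axis orientation relative to the pathway.

    ``fit()`` performs a least-squares fit of the coupling ``q_dx`` (e*A) and
    the effective dielectric ``eps`` (bounded to [2, 20]) to the non-reference
    anchors and returns :class:`BarrierTuningResults`.
    """

    def __init__(
        self,
        anchors: Sequence[tuple[float, float]],
        pathway_distance_R: float = 14.0,
        orientation_cos: float = 1.0,
    ):
        anchors = sorted((float(d), float(g)) for d, g in anchors)
        if len(anchors) < 2:
            raise ValueError("need at least 2 anchors")
        seps = [d for d, _ in anchors]
        if len(set(seps)) < len(seps):
            raise ValueError("anchor separations must be distinct")
        self.anchors = anchors
        self.R = float(pathway_distance_R)
        self.orientation_cos = float(orientation_cos)
        self.d_closed, self.dg_closed = anchors[0]

    def _geom(self, d: float) -> IonPairGeometry:
        return IonPairGeometry(d, self.R, self.orientation_cos)

    def _field_mv(self, d: float, eps: float) -> float:
        return pathway_field(self._geom(d), eps).e_parallel

    def barrier(self, d: float, q_dx: float, eps: float) -> float:
        """dG(d) in kcal/mol for given coupling/dielectric parameters."""
        dE = self._field_mv(d, eps) - self._field_mv(self.d_closed, eps)
        # MV/cm -> kcal/(mol e A), then times q_dx (e A)
        return self.dg_closed - q_dx * dE / KCAL_PER_MOL_E_A_IN_MV_CM

    def fit(self, q_dx0: float = 1.0, eps0: float = 4.0) -> "BarrierTuningResults":
        ds = np.array([d for d, _ in self.anchors[1:]])
        gs = np.array([g for _, g in self.anchors[1:]])

        params = lmfit.Parameters()
        params.add("q_dx", value=q_dx0, min=0.0)
        params.add("eps", value=eps0, min=2.0, max=20.0)

        def residual(p):
            return np.array(
                [self.barrier(d, p["q_dx"].value, p["eps"].value) - g for d, g in zip(ds, gs)]
            )

        import warnings

        with warnings.catch_warnings():
            # exactly-determined two-anchor fits have a singular covariance
            warnings.simplefilter("ignore", RuntimeWarning)
            out = lmfit.minimize(residual, params, method="least_squares")
        return BarrierTuningResults(self, out)


class BarrierTuningResults:
    """Fitted barrier-tuning model: predictions, rates, transfer, summary."""

    def __init__(self, model: BarrierTuningModel, minimizer_result):
        self.model = model
        self.minimizer_result = minimizer_result
        self.q_dx = float(minimizer_result.params["q_dx"].value)
        self.eps = float(minimizer_result.params["eps"].value)
        self.residuals = np.array(
            [self.predict(d) - g for d, g in model.anchors]
        )

    # -- predictions ----------------------------------------------------
    def predict(self, separation_d) -> float | np.ndarray:
        """Barrier dG(d) in kcal/mol at the fitted parameters."""
        d = np.asarray(separation_d, dtype=float)
        out = np.vectorize(lambda x: self.model.barrier(x, self.q_dx, self.eps))(d)
        return float(out) if out.ndim == 0 else out

    def rate(self, separation_d: float, T: float = T_DEFAULT) -> float:
        """Eyring rate constant (s^-1) at separation d."""
        return eyring_rate(self.predict(separation_d), T)

    @property
    def open_drop(self) -> float:
        """Barrier drop (kcal/mol) between the closed and largest-d anchor."""
        d_open = self.model.anchors[-1][0]
        return self.model.dg_closed - float(self.predict(d_open))

    def transfer_anchored_prediction(self, R2: float, dg_closed_2: float) -> float:
        """Predict the open-state barrier of a second module.

        The fitted barrier drop is rescaled by the point-dipole far-field
        ratio ``(R1/R2)**3`` and subtracted from the second module's
        closed-state anchor.
        """
        if not R2 > 0:
            raise ValueError("R2 must be > 0")
        scaled = self.open_drop * (self.model.R / R2) ** 3
        return dg_closed_2 - scaled

    # -- io / reporting -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "q_dx_eA": self.q_dx,
            "eps": self.eps,
            "dg_closed_kcal_mol": self.model.dg_closed,
            "d_closed_A": self.model.d_closed,
            "pathway_distance_A": self.model.R,
            "orientation_cos": self.model.orientation_cos,
            "anchors": self.model.anchors,
            "residuals_kcal_mol": self.residuals.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        lines = [
            "Barrier tuning model (Stark coupling to ion-pair Coulomb field)",
            f"  pathway distance R      {self.model.R:8.2f} A",
            f"  closed-state anchor     {self.model.dg_closed:8.2f} kcal/mol at d={self.model.d_closed:.2f} A",
            f"  coupling q*dx           {self.q_dx:8.3f} e*A",
            f"  effective dielectric    {self.eps:8.3f}",
            f"  open-state barrier drop {self.open_drop:8.2f} kcal/mol",
            "  anchors (d, dG, fit, resid):",
        ]
        for (d, g), r in zip(self.model.anchors, self.residuals):
            lines.append(f"    {d:6.2f} A  {g:6.2f}  {g + r:6.2f}  {r:+8.4f}")
        return "\n".join(lines)


def load_anchor_table(path: str | Path):
    """Read the shipped anchor CSV (construct, state, separation, R, barrier)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"construct", "state", "separation_A", "pathway_distance_A", "barrier_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"anchor table missing columns: {sorted(missing)}")
    return df


def fit_anchors_for_construct(df, construct: str) -> BarrierTuningResults:
    """Fit the tuning model to the anchor rows of one construct."""
    sub = df[df["construct"] == construct]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 anchors for {construct!r}")
    R = float(sub["pathway_distance_A"].iloc[0])
    anchors = list(zip(sub["separation_A"], sub["barrier_kcal_mol"]))
    return BarrierTuningModel(anchors, pathway_distance_R=R).fit()
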