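"""Desk-scale free-energy estimation on 1-D surrogate proton-wire potentials.

The lateral proton-transfer coordinate is replaced by a 1-D model potential
(double well with an optional linear field tilt from the barrier-tuning
model).  Umbrella windows are sampled with a Metropolis walker under a
harmonic bias; the unbiased potential of mean force (PMF) is recovered with
the weighted histogram analysis method (WHAM) and, independently, with the
multistate Bennett acceptance ratio estimator (MBAR).  Both estimators are
validated against the analytic potential.

For umbrella windows the unbiased part of the reduced potential is common to
every state and cancels from the MBAR equations, so only the harmonic biases
enter; :func:`solve_mbar` also accepts arbitrary reduced-potential matrices
for general multistate problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import T_DEFAULT, rt

__all__ = [
    "ModelPotential",
    "UmbrellaWindow",
    "PMFEstimate",
    "sample_window",
    "WHAMEstimator",
    "MBAREstimator",
    "solve_mbar",
    "default_windows",
]

DEFAULT_FORCE_CONSTANT = 100.0  # kcal mol^-1 A^-2, harmonic umbrella restraint


@dataclass(frozen=True)
class ModelPotential:
    """Analytic 1-D model potential U(x) in kcal/mol, x in A.

    kinds
    -----
    ``double_well`` : ``B ((x/a)^2 - 1)^2 - tilt * x`` with ``a`` half the
        well separation and ``B`` the untilted barrier height;
    ``harmonic``    : ``0.5 * k x^2`` with k = barrier_height (per A^2);
    ``flat``        : 0 everywhere;
    ``piecewise``   : V-shaped ``B * |x| / a``.

    ``field_tilt`` (kcal/mol per A) is the linear term produced by coupling
    the ion-pair electric field to the transferred charge; a positive tilt
    stabilises the product side and lowers the forward barrier.
    """

    kind: str = "double_well"
    barrier_height: float = 5.0
    well_separation: float = 2.0
    field_tilt: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("double_well", "harmonic", "flat", "piecewise"):
            raise ValueError(f"unknown potential kind {self.kind!r}")

    @property
    def half_sep(self) -> float:
        return self.well_separation / 2.0

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "flat":
            u = np.zeros_like(x)
        elif self.kind == "harmonic":
            u = 0.5 * self.barrier_height * x**2
        elif self.kind == "piecewise":
            u = self.barrier_height * np.abs(x) / self.half_sep
        else:
            u = self.barrier_height * ((x / self.half_sep) ** 2 - 1.0) ** 2
        u = u - self.field_tilt * x
        return float(u) if u.ndim == 0 else u

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "flat":
            du = np.zeros_like(x)
        elif self.kind == "harmonic":
            du = self.barrier_height * x
        elif self.kind == "piecewise":
            du = self.barrier_height * np.sign(x) / self.half_sep
        else:
            a = self.half_sep
            du = 4.0 * self.barrier_height * x * ((x / a) ** 2 - 1.0) / a**2
        du = du - self.field_tilt
        return float(du) if du.ndim == 0 else du

    def analytic_forward_barrier(self, x_range: tuple = None, n: int = 20001) -> float:
        """Barrier from the reactant-side minimum to the saddle between the
        two wells (kcal/mol), on a dense grid of the analytic potential."""
        a = self.half_sep
        lo, hi = x_range if x_range else (-2.5 * a, 2.5 * a)
        x = np.linspace(lo, hi, n)
        return _forward_barrier(self.energy(x))


def _forward_barrier(u: np.ndarray) -> float:
    """Saddle height between the left- and right-half minima of a profile."""
    n = len(u)
    mid = n // 2
    if mid == 0:
        return 0.0
    i_left = int(np.argmin(u[:mid]))
    i_right = mid + int(np.argmin(u[mid:]))
    top = float(u[i_left : i_right + 1].max())
    return top - float(u[i_left])


@dataclass(frozen=True)
class UmbrellaWindow:
    """A harmonically restrained sampling window."""

    center: float
    force_constant: float = DEFAULT_FORCE_CONSTANT  # kcal mol^-1 A^-2
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.force_constant > 0:
            raise ValueError("force_constant must be > 0")

    def bias(self, x):
        return 0.5 * self.force_constant * (np.asarray(x, dtype=float) - self.center) ** 2


def default_windows(
    lo: float, hi: float, n_windows: int = 24,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
    n_samples: int = 2000, seed: int = 0,
) -> list[UmbrellaWindow]:
    centers = np.linspace(lo, hi, n_windows)
    return [
        UmbrellaWindow(c, force_constant, n_samples, seed + i)
        for i, c in enumerate(centers)
    ]


def sample_window(
    potential: ModelPotential,
    window: UmbrellaWindow,
    T: float = T_DEFAULT,
    n_burn: int = 500,
    thin: int = 10,
) -> np.ndarray:
    """Metropolis sampling of ``exp(-(U + bias)/RT)``.

    The step size is auto-tuned during burn-in toward 40-60% acceptance, and
    the chain is thinned by ``thin`` steps per recorded sample to suppress
    autocorrelation.  Deterministic for a fixed window seed.
    """
    beta = 1.0 / rt(T)
    rng = np.random.default_rng(window.seed)
    x = window.center
    step = math.sqrt(rt(T) / window.force_constant)  # ~ bias standard deviation

    def e(xx):
        return potential.energy(xx) + float(window.bias(xx))

    ex = e(x)
    out = np.empty(window.n_samples)
    accepted = 0
    tried = 0
    total = n_burn + window.n_samples * thin
    for i in range(total):
        prop = x + step * rng.standard_normal()
        ep = e(prop)
        if ep <= ex or rng.random() < math.exp(-beta * (ep - ex)):
            x, ex = prop, ep
            accepted += 1
        tried += 1
        if i < n_burn:
            if tried == 50:  # crude Robbins-Monro tuning
                rate = accepted / tried
                if rate < 0.4:
                    step *= 0.8
                elif rate > 0.6:
                    step *= 1.25
                accepted = tried = 0
        elif (i - n_burn) % thin == thin - 1:
            out[(i - n_burn) // thin] = x
    return out


@dataclass
class PMFEstimate:
    """A free-energy profile on a 1-D grid (kcal/mol, min-shifted to 0)."""

    grid: np.ndarray
    values: np.ndarray
    window_offsets: np.ndarray
    stat_uncertainty: np.ndarray
    estimator: str = "wham"

    def __post_init__(self) -> None:
        shift = np.nanmin(self.values)
        self.values = self.values - shift

    def value_at(self, x: float) -> float:
        return float(np.interp(x, self.grid, self.values))

    def barrier(self) -> float:
        """Forward barrier: saddle between the two outer minima, relative to
        the reactant (left) minimum."""
        finite = np.isfinite(self.values)
        return _forward_barrier(self.values[finite])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_A": self.grid, "pmf_kcal_mol": self.values,
             "uncertainty_kcal_mol": self.stat_uncertainty}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_overlap(windows, samples, min_frac: float = 0.01) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order, order[1:]):
        lo = min(samples[a].max(), samples[b].max())
        hi = max(samples[a].min(), samples[b].min())
        frac_a = np.mean(samples[a] >= samples[b].min())
        frac_b = np.mean(samples[b] <= samples[a].max())
        if min(frac_a, frac_b) < min_frac:
            ca, cb = windows[a].center, windows[b].center
            raise ValueError(
                f"insufficient histogram overlap between windows at {ca:.3f} and "
                f"{cb:.3f} A (gap in sampled coordinate); add windows or soften "
                f"the restraints"
            )


class WHAMEstimator:
    """Weighted histogram analysis of umbrella-sampled windows."""

    def __init__(
        self,
        windows: Sequence[UmbrellaWindow],
        samples: Sequence[np.ndarray],
        T: float = T_DEFAULT,
        n_bins: int = 80,
    ):
        if len(windows) != len(samples):
            raise ValueError("windows and samples length mismatch")
        self.windows = list(windows)
        self.samples = [np.asarray(s, dtype=float) for s in samples]
        _check_overlap(self.windows, self.samples)
        self.T = T
        self.n_bins = n_bins

    def fit(self, tol: float = 1e-8, max_iter: int = 50000) -> PMFEstimate:
        kT = rt(self.T)
        allx = np.concatenate(self.samples)
        edges = np.linspace(allx.min(), allx.max(), self.n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        H = np.array([np.histogram(s, bins=edges)[0] for s in self.samples], dtype=float)
        N = np.array([len(s) for s in self.samples], dtype=float)
        Hsum = H.sum(axis=0)

        # bias energy of each window at each bin centre
        B = np.array([w.bias(centers) for w in self.windows])  # (K, M)
        expB = np.exp(-B / kT)

        f = np.zeros(len(self.windows))
        for it in range(max_iter):
            denom = (N[:, None] * np.exp(f[:, None] / kT) * expB).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                P = np.where(denom > 0, Hsum / denom, 0.0)
            z = expB @ P
            f_new = -kT * np.log(np.where(z > 0, z, np.nan))
            f_new = f_new - f_new[0]
            delta = np.nanmax(np.abs(f_new - f))
            f = f_new
            if delta < tol:
                break
        else:
            raise RuntimeError(f"WHAM did not converge in {max_iter} iterations")

        with np.errstate(divide="ignore"):
            G = -kT * np.log(np.where(P > 0, P, np.nan))
        # Poisson counting error on the per-bin weight: dG ~ kT / sqrt(n_bin)
        sig = np.where(Hsum > 0, kT / np.sqrt(np.maximum(Hsum, 1.0)), np.nan)
        return PMFEstimate(centers, G, window_offsets=f, stat_uncertainty=sig,
                           estimator="wham")


def solve_mbar(
    u_kn: np.ndarray, N_k: np.ndarray, tol: float = 1e-10, max_iter: int = 10000
) -> np.ndarray:
    """MBAR free energies (units of kT) for K states.

    ``u_kn[k, n]`` is the reduced potential of sample n evaluated in state k;
    samples from all states are concatenated along n.  The convex MBAR
    objective is minimised (BFGS with analytic gradient), followed by
    self-consistent sweeps down to ``tol``.  Returns ``f_k`` with ``f_0 = 0``.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp

    u_kn = np.asarray(u_kn, dtype=float)
    N_k = np.asarray(N_k, dtype=float)
    K, _ = u_kn.shape
    logN = np.log(N_k)

    def objective(theta):
        f = np.concatenate(([0.0], theta))
        a = logN[:, None] + f[:, None] - u_kn
        logD = logsumexp(a, axis=0)
        val = logD.sum() - float(N_k @ f)
        p = np.exp(a - logD[None, :])  # (K, n)
        grad = p.sum(axis=1) - N_k
        return val, grad[1:]

    res = minimize(objective, np.zeros(K - 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-7})
    f = np.concatenate(([0.0], res.x))

    # Newton polish on the estimating equations (quadratic convergence;
    # the Hessian is tiny: K x K)
    for _ in range(100):
        a = logN[:, None] + f[:, None] - u_kn
        logD = logsumexp(a, axis=0)
        p = np.exp(a - logD[None, :])  # (K, n)
        grad = p.sum(axis=1) - N_k
        H = np.diag(p.sum(axis=1)) - p @ p.T
        try:
            step = np.linalg.solve(H[1:, 1:], grad[1:])
        except np.linalg.LinAlgError:  # pragma: no cover
            step = np.linalg.lstsq(H[1:, 1:], grad[1:], rcond=None)[0]
        f = f - np.concatenate(([0.0], step))
        f = f - f[0]
        # convergence: one self-consistent sweep moves f by < tol
        logD = logsumexp(logN[:, None] + f[:, None] - u_kn, axis=0)
        f_sc = -logsumexp(-u_kn - logD[None, :], axis=1)
        f_sc = f_sc - f_sc[0]
        if np.max(np.abs(f_sc - f)) < tol:
            return f
    raise RuntimeError("MBAR did not converge")


class MBAREstimator:
    """MBAR analysis of umbrella-sampled windows.

    The common unbiased potential cancels between states, so the reduced
    potentials are the harmonic biases alone; unbiased per-sample weights
    then yield the PMF on the same grid convention as WHAM.
    """

    def __init__(
        self,
        windows: Sequence[UmbrellaWindow],
        samples: Sequence[np.ndarray],
        T: float = T_DEFAULT,
        n_bins: int = 80,
    ):
        if len(windows) != len(samples):
            raise ValueError("windows and samples length mismatch")
        self.windows = list(windows)
        self.samples = [np.asarray(s, dtype=float) for s in samples]
        _check_overlap(self.windows, self.samples)
        self.T = T
        self.n_bins = n_bins

    def fit(self, tol: float = 1e-10, max_iter: int = 50000) -> PMFEstimate:
        kT = rt(self.T)
        x = np.concatenate(self.samples)
        N_k = np.array([len(s) for s in self.samples], dtype=float)
        u_kn = np.array([w.bias(x) / kT for w in self.windows])
        f = solve_mbar(u_kn, N_k, tol=tol, max_iter=max_iter)
        self.f_k = f * kT  # window offsets, kcal/mol

        # unbiased weights
        a = np.log(N_k)[:, None] + f[:, None] - u_kn
        amax = a.max(axis=0)
        logw = -(amax + np.log(np.exp(a - amax).sum(axis=0)))

        edges = np.linspace(x.min(), x.max(), self.n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        idx = np.clip(np.digitize(x, edges) - 1, 0, self.n_bins - 1)
        G = np.full(self.n_bins, np.nan)
        neff = np.zeros(self.n_bins)
        for b in range(self.n_bins):
            m = idx == b
            if m.any():
                lb = logw[m]
                mx = lb.max()
                G[b] = -kT * (mx + math.log(np.exp(lb - mx).sum()))
                neff[b] = m.sum()
        sig = np.where(neff > 0, kT / np.sqrt(np.maximum(neff, 1.0)), np.nan)
        return PMFEstimate(centers, G, window_offsets=self.f_k,
                           stat_uncertainty=sig, estimator="mbar")

    def free_energy_differences(self) -> np.ndarray:
        """Pairwise window free-energy differences (kcal/mol), after fit()."""
        if not hasattr(self, "f_k"):
            self.fit()
        return self.f_k[None, :] - self.f_k[:, None]
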