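"""Synthetic fluorescence-trace generation.

Emulates the experimental design of the proteoliposome assays: the vesicle
simulator provides the noiseless physical trajectory, the probe models render
the fluorescence channels (pyranine intensity pair at 600 ms sampling, ACMA
single channel at 100 ms), and additive Gaussian noise is applied per
replicate with a deterministic seed ladder (base seed + replicate index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import vesicle as vs
from .chem import AcmaResponse, ProbeCalibration
from .traces import Trace

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "generate",
    "generate_linear_acma_traces",
    "fixture_suite",
    "DEFAULT_DESIGNS",
]

ASSAYS = ("acetate", "methylamine", "atp")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, sigma relative to the channel baseline."""

    sigma_rel: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """One (construct preset x assay) synthetic experiment."""

    preset: str
    assay: str = "acetate"
    n_replicates: int = 6
    sampling_dt: Optional[float] = None  # 0.6 s pyranine / 0.1 s ACMA default

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def dt(self) -> float:
        return self.sampling_dt or (0.1 if self.assay == "atp" else 0.6)


def _simulate(design: ExperimentDesign, library=None) -> vs.AssayResult:
    if design.assay == "acetate":
        return vs.acetate_assay(design.preset, library=library)
    if design.assay == "methylamine":
        return vs.methylamine_assay(design.preset, library=library)
    return vs.atp_competition_assay(design.preset, library=library)


def generate(
    design: ExperimentDesign,
    noise: NoiseModel = NoiseModel(),
    library: Optional[dict] = None,
    result: Optional[vs.AssayResult] = None,
) -> list[Trace]:
    """Render noisy replicate traces for one design.

    The simulation runs once; each replicate gets independent additive
    Gaussian noise seeded with ``noise.seed + replicate_index``, so output is
    fully deterministic for fixed seeds.  Pass ``result`` to reuse a
    previously computed simulation.
    """
    res = result if result is not None else _simulate(design, library)
    t = res.time
    traces = []
    for i in range(design.n_replicates):
        rng = np.random.default_rng(noise.seed + i)
        channels = {}
        if design.assay == "atp":
            f = res.acma_F
            sigma = noise.sigma_rel * abs(float(f[0]))
            channels["F_acma"] = f + sigma * rng.standard_normal(len(f))
        else:
            for name, ch in (("I404", res.pyranine_I404), ("I454", res.pyranine_I454)):
                sigma = noise.sigma_rel * abs(float(ch[0]))
                channels[name] = ch + sigma * rng.standard_normal(len(ch))
        traces.append(
            Trace(time=t.copy(), channels=channels, events=res.schedule,
                  replicate_id=f"{design.preset}_{design.assay}_r{i}",
                  sampling_dt=design.dt)
        )
    return traces


def generate_linear_acma_traces(
    k1_per_min: float,
    n_replicates: int = 6,
    sigma_rel: float = 0.01,
    seed: int = 0,
    t_event: float = 60.0,
    linear_span: float = 30.0,
    t_end: float = 120.0,
    dt: float = 0.1,
) -> list[Trace]:
    """Synthetic ACMA traces with a prescribed true initial decay rate.

    Unit baseline for ``t_event`` seconds, then a linear decay of slope
    ``-k1_per_min`` (per minute) over ``linear_span`` seconds, then a flat
    plateau; Gaussian noise of ``sigma_rel`` x baseline per replicate.
    Used for rate-estimator recovery studies.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    f = np.ones_like(t)
    lin = (t >= t_event) & (t <= t_event + linear_span)
    f[lin] = 1.0 - k1_per_min / 60.0 * (t[lin] - t_event)
    f[t > t_event + linear_span] = f[lin][-1] if lin.any() else 1.0
    schedule = vs.EventSchedule([vs.Event(t_event, "add_atp", 0.2)])
    out = []
    for i in range(n_replicates):
        rng = np.random.default_rng(seed + i)
        noisy = f + sigma_rel * rng.standard_normal(len(f))
        out.append(Trace(time=t.copy(), channels={"F_acma": noisy},
                         events=schedule, replicate_id=f"lin_r{i}", sampling_dt=dt))
    return out


DEFAULT_DESIGNS = (
    ExperimentDesign("WT-Nqo13", "acetate"),
    ExperimentDesign("E123Q-Nqo13", "acetate"),
    ExperimentDesign("empty", "acetate"),
    ExperimentDesign("F1Fo-only", "atp"),
    ExperimentDesign("WT-Nqo13", "atp"),
)


def fixture_suite(
    out_dir,
    designs: Sequence[ExperimentDesign] = DEFAULT_DESIGNS,
    base_seed: int = 1234,
    sigma_rel: float = 0.01,
    library: Optional[dict] = None,
) -> dict:
    """Write one CSV per (design x replicate) plus a manifest JSON.

    Regeneration with the same seed is idempotent (bitwise-identical files).
    Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"base_seed": base_seed, "sigma_rel": sigma_rel, "designs": []}
    for j, design in enumerate(designs):
        noise = NoiseModel(sigma_rel=sigma_rel, seed=base_seed + 1000 * j)
        traces = generate(design, noise, library=library)
        files = []
        for tr in traces:
            fname = f"{tr.replicate_id}.csv"
            tr.to_csv(out_dir / fname)
            files.append(fname)
        manifest["designs"].append(
            {
                "preset": design.preset,
                "assay": design.assay,
                "n_replicates": design.n_replicates,
                "sampling_dt_s": design.dt,
                "noise_seed": noise.seed,
                "files": files,
                "events": [
                    {"time_s": e.time, "action": e.action, "amount_mM": e.amount}
                    for e in traces[0].events.events
                ],
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
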