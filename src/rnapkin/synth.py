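"""Synthetic single-turnover quench-flow data and EC-stability decay curves.

The generator emulates the statistical structure of chemical quench-flow
transcription assays: a log-spaced observation grid starting at the
instrument dead time (5 ms) and running to 10 s, at least three replicates
per condition, a per-replicate multiplicative amplitude (radiolabel decays
between experiment days, so each replicate's overall signal scale differs),
and additive Gaussian noise on the normalized species fractions, clipped to
[0, 1].  Noise-free generation reproduces the forward model exactly, and a
fixed seed makes every output bit-reproducible.

Defaults: fraction noise SD 0.03 and amplitudes drawn from [0.85, 1.05] —
consistent with the replicate scatter and amplitude variation typical of
phosphorimage-quantified band intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TimeCourse
from .schemes import RateParameters, build_scheme1, build_scheme2, simulate

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "generate_single_nt",
    "generate_multi_nt",
    "generate_stability",
    "default_time_grid",
]

#: Earliest attainable quench-flow time point (s) — the instrument dead time.
DEAD_TIME_S = 5e-3


def default_time_grid(n: int = 25, t_min: float = DEAD_TIME_S, t_max: float = 10.0) -> np.ndarray:
    """Log-spaced observation grid from the dead time to 10 s."""
    return np.geomspace(t_min, t_max, n)


@dataclass(frozen=True)
class NoiseModel:
    """Additive fraction noise + per-replicate amplitude scaling."""

    fraction_sd: float = 0.03
    amplitude_range: tuple[float, float] = (0.85, 1.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_sd < 0:
            raise ValueError("fraction_sd must be >= 0")
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi <= 1.2):
            raise ValueError("amplitude_range must lie within (0, 1.2]")


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of a quench-flow titration."""

    time_grid: np.ndarray = field(default_factory=default_time_grid)
    concentrations_uM: tuple[float, ...] = (10.0, 50.0, 250.0, 1000.0)
    replicates: int = 3
    temperature: str = "25C"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        if t[0] < DEAD_TIME_S - 1e-12:
            raise ValueError(f"first time point must be >= the {DEAD_TIME_S*1e3:.0f} ms dead time")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time_grid", t)
        if self.replicates < 3:
            raise ValueError("at least three replicates per condition")


def _noise_pipeline(
    clean: dict[str, np.ndarray],
    rng: np.random.Generator,
    noise: NoiseModel,
    clip_log: list[int],
) -> tuple[dict[str, np.ndarray], float]:
    """Scale by one replicate amplitude, add Gaussian noise, clip to [0, 1]."""
    lo, hi = noise.amplitude_range
    amp = float(rng.uniform(lo, hi))
    out: dict[str, np.ndarray] = {}
    for name, y in clean.items():
        noisy = amp * y + rng.normal(0.0, noise.fraction_sd, size=y.shape)
        clipped = np.clip(noisy, 0.0, 1.0)
        clip_log.append(int(np.sum(noisy != clipped)))
        out[name] = clipped
    return out, amp


def generate_single_nt(
    design: ExperimentDesign, params: RateParameters, noise: NoiseModel
) -> list[TimeCourse]:
    """Simulate single-nucleotide-addition time courses (product-species fraction).

    For each ATP concentration x replicate the reversible-binding scheme is
    integrated from all mass in the unbound complex, the product (EC11)
    fraction is sampled on the design grid, and the noise pipeline is
    applied.  Metadata records the seed, generating parameters and the
    replicate amplitude.
    """
    rng = np.random.default_rng(noise.seed)
    scheme = build_scheme1()
    out: list[TimeCourse] = []
    clips: list[int] = []
    for conc in design.concentrations_uM:
        traj = simulate(scheme, params, conc, design.time_grid, temperature=design.temperature)
        clean = {"EC11": traj.species("EC11")}
        for rep in range(design.replicates):
            noisy, amp = _noise_pipeline(clean, rng, noise, clips)
            out.append(
                TimeCourse(
                    design.time_grid.copy(), noisy, replicate=rep, conc_uM=conc,
                    temperature=design.temperature,
                    metadata={
                        "seed": noise.seed, "scheme": scheme.name, "amplitude": amp,
                        "Kd_uM": params.Kd, "k3": params.k3, "k1": params.k1,
                        "n_clipped": clips[-1],
                    },
                )
            )
    return out


def generate_multi_nt(
    design: ExperimentDesign,
    params: RateParameters,
    noise: NoiseModel,
    reversible: bool = True,
) -> list[TimeCourse]:
    """Simulate multi-nucleotide-addition time courses (M11, M12, M13plus).

    Integrates the linear chain (reversible or irreversible variant) and
    records the three gel-observable species with the shared noise pipeline.
    The chain is phenomenological: NTP concentration enters only through the
    per-condition rate values, so the same ``params`` are used at every
    listed concentration.
    """
    rng = np.random.default_rng(noise.seed)
    scheme = build_scheme2(reversible=reversible)
    observed = ("M11", "M12", "M13plus")
    out: list[TimeCourse] = []
    clips: list[int] = []
    for conc in design.concentrations_uM:
        traj = simulate(scheme, params, conc, design.time_grid, temperature=design.temperature)
        clean = {name: traj.species(name) for name in observed}
        for rep in range(design.replicates):
            noisy, amp = _noise_pipeline(clean, rng, noise, clips)
            out.append(
                TimeCourse(
                    design.time_grid.copy(), noisy, replicate=rep, conc_uM=conc,
                    temperature=design.temperature,
                    metadata={
                        "seed": noise.seed, "scheme": scheme.name, "amplitude": amp,
                        "kobs": dict(params.kobs), "n_clipped": clips[-1],
                    },
                )
            )
    return out


def generate_stability(
    decay_rate_per_h: float,
    horizon_h: float,
    noise: NoiseModel,
    n_points: int = 9,
    replicates: int = 3,
    temperature: str = "25C",
) -> list[TimeCourse]:
    """Simulate EC-stability decay: intact fraction exp(-rate * t) over hours.

    Emulates the RNase-protection stability assay sampled from t=0 out to
    ``horizon_h`` (up to 96 h in practice); each replicate is noised and then
    re-normalized to its own t=0 value, matching how stability curves are
    normalized to starting material.  A decay rate of 0 reproduces the flat,
    ">96 h stable" behaviour.
    """
    if decay_rate_per_h < 0:
        raise ValueError("decay_rate_per_h must be >= 0")
    if horizon_h <= 0 or horizon_h > 200:
        raise ValueError("horizon must be in (0, 200] hours")
    rng = np.random.default_rng(noise.seed)
    t = np.linspace(0.0, horizon_h, n_points)
    clean = np.exp(-decay_rate_per_h * t)
    out: list[TimeCourse] = []
    for rep in range(replicates):
        noisy = clean + rng.normal(0.0, noise.fraction_sd, size=t.shape)
        noisy[0] = clean[0]  # the t=0 reference defines the normalization
        noisy = np.clip(noisy / noisy[0], 0.0, 1.2 - 1e-9)
        out.append(
            TimeCourse(
                t.copy(), {"intact": noisy}, replicate=rep, conc_uM=0.0,
                temperature=temperature,
                metadata={"seed": noise.seed, "decay_rate_per_h": decay_rate_per_h,
                          "time_unit": "h"},
            )
        )
    return out
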