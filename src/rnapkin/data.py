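"""Observed time-course records — the universal data container for fits.

A :class:`TimeCourse` holds one replicate of one experimental condition:
sampled species fractions over time plus the metadata (replicate id, NTP
concentration, temperature label) the fitting layers group on.  Unlike the
model :class:`~rnapkin.schemes.Trajectory`, observed fractions need not sum
to 1 — gels resolve only a subset of species, and amplitudes vary with the
radiolabel's freshness — so validation is looser: values in [0, 1.2] with a
warning above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeCourse", "TimeCourseError", "average_replicates"]


class TimeCourseError(ValueError):
    """Malformed time-course data."""


@dataclass
class TimeCourse:
    """One condition x replicate of sampled species fractions over time."""

    times: np.ndarray
    fractions: dict[str, np.ndarray]
    replicate: int = 0
    conc_uM: float = 0.0
    temperature: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise TimeCourseError("times must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise TimeCourseError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        for name, y in self.fractions.items():
            y = np.asarray(y, dtype=float)
            if y.shape != t.shape:
                raise TimeCourseError(f"fractions for {name} do not match the time grid")
            if np.any(y < 0) or np.any(y > 1.2):
                raise TimeCourseError(f"fractions for {name} outside [0, 1.2]")
            if np.any(y > 1.0):
                warnings.warn(f"fractions for {name} exceed 1", stacklevel=2)
            self.fractions[name] = y

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(self.fractions)

    def species(self, name: str) -> np.ndarray:
        if name not in self.fractions:
            raise TimeCourseError(f"species {name!r} not present in this time course")
        return self.fractions[name]

    @property
    def n_points(self) -> int:
        return len(self.times)


def average_replicates(tcs: list[TimeCourse]) -> tuple[TimeCourse, dict[str, np.ndarray]]:
    """Average replicates of one condition point-wise.

    Returns the mean time course (replicate id -1) and the per-point sample
    standard deviations (ddof=1) per species, the weights the
    model-independent fits use by default.  All inputs must share the time
    grid, species set and condition metadata.
    """
    if not tcs:
        raise TimeCourseError("no time courses to average")
    ref = tcs[0]
    for tc in tcs[1:]:
        if not np.allclose(tc.times, ref.times):
            raise TimeCourseError("replicates are on different time grids")
        if tc.species_names != ref.species_names:
            raise TimeCourseError("replicates record different species")
        if (tc.conc_uM, tc.temperature) != (ref.conc_uM, ref.temperature):
            raise TimeCourseError("replicates come from different conditions")
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for name in ref.species_names:
        stack = np.vstack([tc.species(name) for tc in tcs])
        mean[name] = stack.mean(axis=0)
        sd[name] = stack.std(axis=0, ddof=1) if len(tcs) > 1 else np.zeros(ref.n_points)
    out = TimeCourse(
        ref.times.copy(), mean, replicate=-1, conc_uM=ref.conc_uM,
        temperature=ref.temperature, metadata={"n_replicates": len(tcs)},
    )
    return out, sd
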