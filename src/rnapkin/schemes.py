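"""Kinetic schemes for single- and multi-nucleotide addition, as data + ODEs.

Two mechanisms are modeled, both under single-turnover conditions (a heparin
trap sequesters free polymerase, so there is no enzyme recycling):

* **Scheme 1** (single-nucleotide addition): reversible NTP binding followed
  by irreversible bond formation,

  ``EC10 + ATP <=> EC10.ATP -> EC11``

  with association rate ``k1`` (fixed at the diffusion limit, 1e8 M-1 s-1),
  dissociation ``k_-1 = Kd * k1`` and catalytic rate ``k3``.  Pyrophosphate
  release is too fast to detect and is folded into the catalytic step.

* **Scheme 2** (multi-nucleotide addition): a linear chain of observed RNA
  species ``M10 -> M11 -> M12 -> M13plus`` with phenomenological rate
  constants ``kobs1..kobs6`` — odd indices forward along the chain, even
  indices the corresponding reverses.  ``M13plus`` lumps every product of at
  least 13 nt.  Dropping the reverse rates gives the irreversible variant
  (scheme "A"), a nested special case used for model comparison.

Because the bimolecular step is folded to pseudo-first-order at a fixed
ligand concentration, every scheme reduces to a linear ODE system
``dy/dt = K y`` with a constant rate matrix, which :func:`simulate`
integrates with a stiff solver.  :func:`propagate_linear` offers the exact
matrix-exponential solution of the same system (used by the fitting layer,
where speed matters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
import scipy.linalg

__all__ = [
    "Transition",
    "KineticScheme",
    "RateParameters",
    "Trajectory",
    "SchemeError",
    "IntegratorError",
    "NoPeakError",
    "build_scheme1",
    "build_scheme2",
    "rate_matrix",
    "simulate",
    "propagate_linear",
    "pseudo_first_order_kobs",
    "intermediate_half_life",
    "SCHEME1_SPECIES",
    "SCHEME2_SPECIES",
]

SCHEME1_SPECIES = ("EC10", "EC10.ATP", "EC11")
SCHEME2_SPECIES = ("M10", "M11", "M12", "M13plus")


class SchemeError(ValueError):
    """Invalid scheme, parameter, or trajectory input."""


class IntegratorError(RuntimeError):
    """The ODE solver failed; the message carries solver diagnostics."""


class NoPeakError(ValueError):
    """The species has no interior maximum, so no half-life is defined."""


@dataclass(frozen=True)
class Transition:
    """One elementary (or observed) step between two declared species.

    ``order`` is ``"unimolecular"`` or ``"bimolecular"``; bimolecular steps
    carry a ``ligand`` tag (the NTP pool whose concentration multiplies the
    rate constant).
    """

    source: str
    target: str
    rate_symbol: str
    order: str = "unimolecular"
    ligand: str | None = None

    def __post_init__(self) -> None:
        if self.order not in ("unimolecular", "bimolecular"):
            raise SchemeError(f"unknown order {self.order!r}")
        if self.order == "bimolecular" and not self.ligand:
            raise SchemeError(f"bimolecular transition {self.rate_symbol} needs a ligand tag")


@dataclass(frozen=True)
class KineticScheme:
    """Ordered species and the transitions connecting them."""

    name: str
    species: tuple[str, ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        declared = set(self.species)
        for t in self.transitions:
            if t.source not in declared or t.target not in declared:
                raise SchemeError(
                    f"transition {t.rate_symbol}: {t.source}->{t.target} references "
                    f"undeclared species"
                )

    @property
    def rate_symbols(self) -> tuple[str, ...]:
        return tuple(t.rate_symbol for t in self.transitions)

    def index(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise SchemeError(f"species {species!r} not in scheme {self.name}") from None


@dataclass
class RateParameters:
    """Rate constants for the schemes, in the units of the published tables.

    ``k1`` is the bimolecular association rate in M-1 s-1, fixed by default
    to the diffusion limit 1e8; ``Kd`` is in uM, so the derived dissociation
    rate is ``k_minus1 = Kd * 1e-6 * k1`` s-1.  ``kobs`` maps the observed
    chain rate index (1..6) to its value in s-1.
    """

    k1: float = 1.0e8
    Kd: float | None = None
    k3: float | None = None
    kobs: dict[int, float] = field(default_factory=dict)
    k1_fixed: bool = True

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise SchemeError("k1 must be >= 0")
        if self.Kd is not None and self.Kd <= 0:
            raise SchemeError("Kd must be > 0")
        if self.k3 is not None and self.k3 < 0:
            raise SchemeError("k3 must be >= 0")
        for i, v in self.kobs.items():
            if v < 0:
                raise SchemeError(f"kobs{i} must be >= 0")

    @property
    def k_minus1(self) -> float:
        """Dissociation rate Kd*k1 in s-1 (Kd converted from uM to M)."""
        if self.Kd is None:
            raise SchemeError("Kd is not set")
        return self.Kd * 1e-6 * self.k1

    def value(self, symbol: str, ligand_conc_uM: float = 0.0) -> float:
        """Pseudo-first-order value (s-1) of a rate symbol at a ligand concentration."""
        if symbol == "k1":
            return self.k1 * ligand_conc_uM * 1e-6
        if symbol == "k_minus1":
            return self.k_minus1
        if symbol == "k3":
            if self.k3 is None:
                raise SchemeError("k3 is not set")
            return self.k3
        if symbol.startswith("kobs"):
            i = int(symbol[4:])
            if i not in self.kobs:
                raise SchemeError(f"{symbol} is not set")
            return self.kobs[i]
        raise SchemeError(f"unknown rate symbol {symbol!r}")


@dataclass(frozen=True)
class Trajectory:
    """Species fractions over time for one condition (closed system).

    Fractions at every time sum to 1 within 1e-6 and lie in [0, 1 + 1e-9].
    """

    times: np.ndarray
    fractions: dict[str, np.ndarray]
    ligand_conc_uM: float = 0.0
    temperature: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise SchemeError("times must be 1-D and strictly increasing")
        object.__setattr__(self, "times", t)
        total = np.zeros_like(t)
        for name, y in self.fractions.items():
            y = np.asarray(y, dtype=float)
            if y.shape != t.shape:
                raise SchemeError(f"fraction array for {name} has wrong shape")
            if np.any(y < -1e-9) or np.any(y > 1 + 1e-9):
                raise SchemeError(f"fractions for {name} outside [0, 1]")
            self.fractions[name] = y
            total += y
        if np.any(np.abs(total - 1.0) > 1e-6):
            raise SchemeError("species fractions do not sum to 1 (closed system)")

    def species(self, name: str) -> np.ndarray:
        return self.fractions[name]


def build_scheme1() -> KineticScheme:
    """Reversible ATP binding followed by irreversible bond formation."""
    return KineticScheme(
        name="scheme1",
        species=SCHEME1_SPECIES,
        transitions=(
            Transition("EC10", "EC10.ATP", "k1", order="bimolecular", ligand="ATP"),
            Transition("EC10.ATP", "EC10", "k_minus1"),
            Transition("EC10.ATP", "EC11", "k3"),
        ),
    )


def build_scheme2(reversible: bool = True) -> KineticScheme:
    """Linear 4-state chain M10 -> M11 -> M12 -> M13plus.

    Rate-symbol mapping (isolated here so it can be flipped wholesale): odd
    indices run forward along the chain (kobs1: M10->M11, kobs3: M11->M12,
    kobs5: M12->M13plus, the bond-formation step feeding higher oligomers)
    and even indices are the matching reverses.  With ``reversible=False``
    only the three forward rates remain (the irreversible "scheme A").
    """
    chain = list(zip(SCHEME2_SPECIES[:-1], SCHEME2_SPECIES[1:]))
    transitions: list[Transition] = []
    for step, (a, b) in enumerate(chain):
        fwd = 2 * step + 1
        transitions.append(Transition(a, b, f"kobs{fwd}"))
        if reversible:
            transitions.append(Transition(b, a, f"kobs{fwd + 1}"))
    return KineticScheme(
        name="scheme2" if reversible else "schemeA",
        species=SCHEME2_SPECIES,
        transitions=tuple(transitions),
    )


def rate_matrix(
    scheme: KineticScheme, params: RateParameters, ligand_conc_uM: float = 0.0
) -> np.ndarray:
    """Constant rate matrix K of the folded first-order system dy/dt = K y.

    Bimolecular steps are converted to pseudo-first-order using the ligand
    concentration (uM -> M where multiplied by k1); columns sum to zero, so
    total probability is conserved.
    """
    n = len(scheme.species)
    K = np.zeros((n, n))
    for t in scheme.transitions:
        conc = ligand_conc_uM if t.order == "bimolecular" else 0.0
        k = params.value(t.rate_symbol, conc)
        if k < 0:
            raise SchemeError(f"negative rate for {t.rate_symbol}")
        i, j = scheme.index(t.source), scheme.index(t.target)
        K[j, i] += k
        K[i, i] -= k
    return K


def simulate(
    scheme: KineticScheme,
    params: RateParameters,
    ligand_conc_uM: float,
    times: np.ndarray,
    initial: dict[str, float] | None = None,
    temperature: str = "",
) -> Trajectory:
    """Integrate the scheme's mass-action ODEs and return a :class:`Trajectory`.

    Uses LSODA with rtol 1e-8 / atol 1e-10 — the observed rates span roughly
    0.02 to 8500 s-1, a stiff range.  The initial state defaults to all mass
    in the first species; it must sum to 1.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise SchemeError("times must be 1-D and strictly increasing")
    y0 = np.zeros(len(scheme.species))
    if initial is None:
        y0[0] = 1.0
    else:
        for name, v in initial.items():
            y0[scheme.index(name)] = v
    if abs(y0.sum() - 1.0) > 1e-9:
        raise SchemeError("initial fractions must sum to 1")
    K = rate_matrix(scheme, params, ligand_conc_uM)

    t0 = min(0.0, times[0])
    sol = solve_ivp(
        lambda _t, y: K @ y,
        (t0, times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        jac=lambda _t, _y: K,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise IntegratorError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, 1.0)
    y /= y.sum(axis=0, keepdims=True)
    fractions = {name: y[i] for i, name in enumerate(scheme.species)}
    return Trajectory(times, fractions, ligand_conc_uM, temperature)


def propagate_linear(K: np.ndarray, y0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Exact solution y(t) = expm(K t) y0 of the constant-coefficient system.

    Solved by eigendecomposition when K is diagonalizable (the usual case for
    these chains), falling back to a matrix exponential per time point.
    Returns an array of shape ``(n_species, n_times)``.
    """
    times = np.asarray(times, dtype=float)
    try:
        w, V = np.linalg.eig(K)
        c = np.linalg.solve(V, y0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign overflow for huge -w*t
            y = (V * c) @ np.exp(np.outer(w, times))
        y = np.real_if_close(y, tol=1e6).real
        if not np.all(np.isfinite(y)):
            raise np.linalg.LinAlgError
        return y
    except np.linalg.LinAlgError:
        return np.column_stack([scipy.linalg.expm(K * t) @ y0 for t in times])


def pseudo_first_order_kobs(Kd_uM: float, k3: float, ligand_uM: float) -> float:
    """Rapid-equilibrium observed rate: k3 * [L] / ([L] + Kd).

    Valid when binding equilibrates much faster than catalysis
    (k1*[L] + k_-1 >> k3); saturates at k3 and halves at [L] = Kd.
    """
    if Kd_uM <= 0:
        raise SchemeError("Kd must be > 0")
    return k3 * ligand_uM / (ligand_uM + Kd_uM)


def intermediate_half_life(traj: Trajectory, species: str, n_dense: int = 100_000) -> float:
    """Half-life of a transient species' decay phase.

    Convention: the time from the species' peak until it first relaxes
    halfway from the peak toward its end-of-window level.  For species that
    decay to zero this is the ordinary peak-to-half-peak time (ln2/k for a
    one-step decay measured from its t=0 maximum); for reversible chains,
    where intermediates settle at a nonzero quasi-equilibrium, it measures
    the relaxation of the transient excess instead — a species whose plateau
    is close to its peak still has a well-defined decay half-life.

    The trajectory is interpolated with a monotonicity-preserving cubic
    (PCHIP) on a dense grid.  Raises :class:`NoPeakError` for species still
    rising at the last time point (e.g. the terminal accumulator).
    """
    y = traj.species(species)
    t = traj.times
    imax = int(np.argmax(y))
    if imax == len(y) - 1:
        raise NoPeakError(f"{species} is still rising at the last time point")
    if y[imax] <= 0:
        raise NoPeakError(f"{species} never rises above zero")
    interp = PchipInterpolator(t, y)
    tt = np.linspace(t[imax], t[-1], n_dense)
    yy = interp(tt)
    jpeak = int(np.argmax(yy))
    half = yy[-1] + (yy[jpeak] - yy[-1]) / 2.0
    # a genuine transient must overshoot its final level by more than solver noise
    if yy[jpeak] - yy[-1] <= 1e-3 * yy[jpeak]:
        raise NoPeakError(f"{species} does not decay within the observed window")
    below = np.nonzero(yy[jpeak:] <= half)[0]
    if below.size == 0:
        raise NoPeakError(f"{species} does not reach its half-relaxation level in the window")
    j = jpeak + below[0]
    # linear refinement between the bracketing dense-grid points
    t_lo, t_hi = tt[j - 1], tt[j]
    y_lo, y_hi = yy[j - 1], yy[j]
    t_half = t_lo + (y_lo - half) / (y_lo - y_hi) * (t_hi - t_lo) if y_lo != y_hi else t_hi
    return float(t_half - tt[jpeak])
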