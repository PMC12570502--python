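"""Model-dependent global fitting: hybrid GA + NLLS optimizer and profile CIs.

The fitting strategy mirrors multi-start evolutionary/NLLS hybrids used for
transient-kinetics schemes: a genetic algorithm explores log10 parameter
space inside box bounds (observed rates span five decades, so the search is
always in logs), each generation's elite individuals are polished by a
derivative-based local optimizer, and several independently seeded starts
guard against local minima.  The best point ever seen, not merely the last
generation's, is returned together with a monotone best-so-far trace.

Confidence bounds come from grid-search profiling: one parameter is stepped
over a log-spaced grid, all others re-optimized at each node, and the 68%
interval is read off where the profiled chi-square crosses
``chi2_min * (1 + F(1, N - p; 0.68) / (N - p))``.

Time courses are fit globally: one shared kinetic parameter set against all
conditions, with one multiplicative amplitude floated per replicate
(radiolabel freshness scales whole lanes).  Amplitudes are profiled out
analytically (variable projection), so the stochastic search only ever sees
the kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import TimeCourse
from .schemes import (
    KineticScheme,
    RateParameters,
    Trajectory,
    build_scheme1,
    build_scheme2,
    propagate_linear,
    rate_matrix,
)

__all__ = [
    "OptimizerConfig",
    "GlobalFitResult",
    "GlobalFitError",
    "InsufficientConditionsError",
    "MissingSpeciesError",
    "GridMismatchError",
    "chi_square",
    "hybrid_optimize",
    "global_fit_scheme1",
    "fit_scheme2",
    "grid_search_ci",
]


class GlobalFitError(RuntimeError):
    """Global fit failure (non-finite objective everywhere, etc.)."""


class InsufficientConditionsError(ValueError):
    """Scheme-1 global fits need at least two ligand concentrations."""


class MissingSpeciesError(ValueError):
    """A required observed species is absent from the data."""


class GridMismatchError(ValueError):
    """Model and data are not on the same time grid / conditions."""


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the hybrid optimizer.

    Defaults (population 48, 60 generations, elite fraction 0.15, 8 starts)
    solve the quench-flow-scale problems here in well under a minute; tests
    and profiling use lighter settings.  ``mutation_scale`` is in log10
    units.  The seed feeds every stochastic element and is recorded in the
    result provenance.
    """

    population: int = 48
    generations: int = 60
    elite_frac: float = 0.15
    mutation_scale: float = 0.25
    n_starts: int = 8
    polish_tol: float = 1e-10
    polish_elites: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 8:
            raise ValueError("population must be >= 8")
        if self.generations < 10:
            raise ValueError("generations must be >= 10")
        if not 0 < self.elite_frac < 1:
            raise ValueError("elite_frac must be in (0, 1)")


@dataclass
class GlobalFitResult:
    """Estimates, fixed parameters, objective and provenance of a global fit."""

    scheme: str
    estimates: dict[str, float]
    fixed: dict[str, float]
    chi_square: float
    bounds68: dict[str, tuple[float, float]] = field(default_factory=dict)
    amplitudes: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    trace: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)
    n_data: int = 0
    n_params: int = 0

    def __post_init__(self) -> None:
        if self.chi_square < 0:
            raise GlobalFitError("chi_square must be >= 0")
        for name, (lo, hi) in self.bounds68.items():
            est = self.estimates[name]
            if not (lo <= est <= hi):
                raise GlobalFitError(f"68% bounds for {name} do not bracket the estimate")


# ---------------------------------------------------------------------------
# objective


def chi_square(
    model: list[Trajectory],
    data: list[TimeCourse],
    weights: dict[str, np.ndarray] | None = None,
) -> float:
    """Sum of squared residuals between model trajectories and observed data.

    Model trajectories are matched to time courses by (concentration,
    temperature); every observed species must exist in the matched
    trajectory, on an identical time grid.  With *weights* (per-species
    1/sd arrays) the residuals are variance-weighted; the default is
    unweighted on the fraction scale.
    """
    index = {(m.ligand_conc_uM, m.temperature): m for m in model}
    total = 0.0
    for tc in data:
        key = (tc.conc_uM, tc.temperature)
        if key not in index:
            raise GridMismatchError(f"no model trajectory for condition {key}")
        m = index[key]
        if len(m.times) != len(tc.times) or not np.allclose(m.times, tc.times):
            raise GridMismatchError(f"time grids differ for condition {key}")
        for name in tc.species_names:
            if name not in m.fractions:
                raise GridMismatchError(f"model lacks species {name!r} for condition {key}")
            r = tc.species(name) - m.species(name)
            if weights is not None and name in weights:
                r = r * weights[name]
            total += float(np.sum(r * r))
    return total


# ---------------------------------------------------------------------------
# hybrid optimizer


def _polish(objective, x, lo, hi, tol):
    res = optimize.minimize(
        objective, np.clip(x, lo, hi), method="L-BFGS-B",
        bounds=list(zip(lo, hi)), options={"ftol": tol, "gtol": 1e-12, "maxiter": 200},
    )
    return res.x, float(res.fun)


def _ga_run(objective, lo, hi, cfg: OptimizerConfig, rng: np.random.Generator):
    dim = len(lo)
    span = hi - lo
    pop = lo + rng.random((cfg.population, dim)) * span
    fit = np.array([objective(x) for x in pop])
    n_elite = max(1, int(round(cfg.elite_frac * cfg.population)))
    best_x, best_f = pop[np.argmin(fit)].copy(), float(np.min(fit))
    trace = [best_f]
    for _gen in range(cfg.generations):
        order = np.argsort(fit)
        pop, fit = pop[order], fit[order]
        # NLLS polish of the top elites (the "hybrid" step)
        for j in range(min(cfg.polish_elites, n_elite)):
            px, pf = _polish(objective, pop[j], lo, hi, cfg.polish_tol)
            if pf < fit[j]:
                pop[j], fit[j] = px, pf
        if fit[0] < best_f:
            best_x, best_f = pop[0].copy(), float(fit[0])
        # next generation: elites survive, offspring from tournament parents
        children = [pop[j].copy() for j in range(n_elite)]
        while len(children) < cfg.population:
            i1, i2 = rng.integers(0, cfg.population, 2)
            p1 = pop[i1] if fit[i1] < fit[i2] else pop[i2]
            i3, i4 = rng.integers(0, cfg.population, 2)
            p2 = pop[i3] if fit[i3] < fit[i4] else pop[i4]
            alpha = rng.random(dim)
            child = alpha * p1 + (1 - alpha) * p2
            child += rng.normal(0.0, cfg.mutation_scale, dim) * span * (rng.random(dim) < 0.5)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fit = np.array([objective(x) for x in pop])
        trace.append(min(best_f, float(np.min(fit))))
    # final polish of the champion
    px, pf = _polish(objective, best_x, lo, hi, cfg.polish_tol)
    if pf < best_f:
        best_x, best_f = px, pf
    trace.append(best_f)
    return best_x, best_f, np.minimum.accumulate(np.array(trace))


def hybrid_optimize(
    objective,
    bounds: list[tuple[float, float]],
    config: OptimizerConfig,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize a scalar objective on a box by multi-start GA + local polish.

    *bounds* are in the same (typically log10) space the objective consumes.
    Returns ``(x_best, f_best, trace)`` where *trace* is the non-increasing
    best-so-far objective across generations of the best start.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy lo < hi")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_starts)
    best = None
    for ss in seeds:
        x, f, trace = _ga_run(objective, lo, hi, config, np.random.default_rng(ss))
        if best is None or f < best[1]:
            best = (x, f, trace)
    if best is None or not np.isfinite(best[1]):
        raise GlobalFitError("objective was non-finite everywhere in the search box")
    return best


# ---------------------------------------------------------------------------
# scheme-fit problems (amplitudes profiled analytically)


class _SchemeProblem:
    """Chi-square of a kinetic scheme against grouped time courses.

    Groups replicates by condition, computes one model trajectory per
    condition via the analytic propagator, and profiles one non-negative
    amplitude per replicate (shared across that replicate's species) by
    linear least squares before summing squared residuals.
    """

    def __init__(
        self,
        scheme: KineticScheme,
        data: list[TimeCourse],
        param_names: list[str],
        make_params,
        observed_species: list[str],
        bounds_log10: list[tuple[float, float]],
    ):
        self.scheme = scheme
        self.param_names = param_names
        self.make_params = make_params
        self.observed = observed_species
        self.bounds_log10 = bounds_log10
        self.groups: dict[tuple[float, str], list[TimeCourse]] = {}
        for tc in data:
            self.groups.setdefault((tc.conc_uM, tc.temperature), []).append(tc)
        self.n_data = sum(len(tc.times) * len(self.observed) for tc in data)
        self._y0 = np.zeros(len(scheme.species))
        self._y0[0] = 1.0

    def model_curves(self, theta_nat: np.ndarray, key) -> np.ndarray:
        params: RateParameters = self.make_params(theta_nat)
        K = rate_matrix(self.scheme, params, key[0])
        y = propagate_linear(K, self._y0, self.groups[key][0].times)
        idx = [self.scheme.index(s) for s in self.observed]
        return np.clip(y[idx], 0.0, 1.0)  # (n_obs_species, n_times)

    def chi2_and_amplitudes(self, theta_nat: np.ndarray):
        total = 0.0
        amps: dict[tuple[float, str, int], float] = {}
        for key, tcs in self.groups.items():
            m = self.model_curves(theta_nat, key)
            mm = float(np.sum(m * m))
            for tc in tcs:
                yobs = np.vstack([tc.species(s) for s in self.observed])
                a = float(np.sum(m * yobs) / mm) if mm > 0 else 0.0
                a = min(max(a, 0.0), 1.5)
                r = yobs - a * m
                total += float(np.sum(r * r))
                amps[(key[0], key[1], tc.replicate)] = a
        return total, amps

    def objective_log10(self, x: np.ndarray) -> float:
        chi2, _ = self.chi2_and_amplitudes(10.0 ** np.asarray(x, dtype=float))
        return chi2 if np.isfinite(chi2) else 1e30


def _solve(problem: _SchemeProblem, config: OptimizerConfig, fixed_names: dict[str, float],
           scheme_label: str) -> GlobalFitResult:
    x, f, trace = hybrid_optimize(problem.objective_log10, problem.bounds_log10, config)
    theta = 10.0 ** x
    chi2, amps = problem.chi2_and_amplitudes(theta)
    return GlobalFitResult(
        scheme=scheme_label,
        estimates={n: float(v) for n, v in zip(problem.param_names, theta)},
        fixed=dict(fixed_names),
        chi_square=chi2,
        amplitudes={f"{k[0]:g}uM/{k[1]}/rep{k[2]}": a for k, a in amps.items()},
        provenance={
            "seed": config.seed, "n_starts": config.n_starts,
            "population": config.population, "generations": config.generations,
            "weighting": "unweighted fraction scale",
        },
        trace=trace,
        n_data=problem.n_data,
        n_params=len(problem.param_names),
    )


_RATE_BOUNDS_LOG10 = (-4.0, 5.0)  # s-1
_KD_BOUNDS_LOG10 = (-3.0, 4.0)  # uM


def _scheme1_problem(data: list[TimeCourse]) -> _SchemeProblem:
    def make_params(theta: np.ndarray) -> RateParameters:
        return RateParameters(Kd=float(theta[0]), k3=float(theta[1]))

    return _SchemeProblem(
        build_scheme1(), data, ["Kd", "k3"], make_params, ["EC11"],
        [_KD_BOUNDS_LOG10, _RATE_BOUNDS_LOG10],
    )


def global_fit_scheme1(data: list[TimeCourse], config: OptimizerConfig) -> GlobalFitResult:
    """Globally fit (Kd, k3) of the single-nucleotide-addition scheme.

    One shared (Kd, k3) pair is fit simultaneously against the product
    time courses at *all* ligand concentrations (the concentration
    dependence is what separates binding from catalysis, hence the
    requirement for at least two concentrations); k1 stays fixed at the
    diffusion limit.
    """
    concs = {tc.conc_uM for tc in data}
    if len(concs) < 2:
        raise InsufficientConditionsError(
            "global Scheme-1 fits need time courses at >= 2 ligand concentrations"
        )
    for tc in data:
        if "EC11" not in tc.fractions:
            raise MissingSpeciesError("each time course must record the EC11 fraction")
    problem = _scheme1_problem(data)
    return _solve(problem, config, {"k1": 1.0e8}, "scheme1")


def _scheme2_problem(data: list[TimeCourse], reversible: bool) -> _SchemeProblem:
    indices = (1, 2, 3, 4, 5, 6) if reversible else (1, 3, 5)
    names = [f"kobs{i}" for i in indices]

    def make_params(theta: np.ndarray) -> RateParameters:
        return RateParameters(kobs=dict(zip(indices, map(float, theta))))

    return _SchemeProblem(
        build_scheme2(reversible), data, names, make_params,
        ["M11", "M12", "M13plus"], [_RATE_BOUNDS_LOG10] * len(names),
    )


def fit_scheme2(
    data: list[TimeCourse],
    reversible: bool,
    config: OptimizerConfig,
    allow_multiple_concentrations: bool = False,
) -> GlobalFitResult:
    """Fit the multi-nucleotide chain rates at one NTP concentration.

    Fits the six observed rate constants (three for the irreversible
    variant) jointly against the M11, M12 and M13plus curves of every
    replicate at that concentration.  The chain is phenomenological — NTP
    concentration enters only through the fitted rate values — so fits are
    per-concentration by default; ``allow_multiple_concentrations=True``
    pools several conditions under one shared rate set (useful when the
    rates are known or assumed concentration-independent).
    """
    concs = {tc.conc_uM for tc in data}
    if len(concs) != 1 and not allow_multiple_concentrations:
        raise ValueError("fit_scheme2 expects time courses at a single concentration")
    for tc in data:
        for s in ("M11", "M12", "M13plus"):
            if s not in tc.fractions:
                raise MissingSpeciesError(f"time course lacks the {s} series")
    problem = _scheme2_problem(data, reversible)
    return _solve(problem, config, {}, "scheme2" if reversible else "schemeA")


# ---------------------------------------------------------------------------
# grid-search confidence bounds


def _reoptimize_others(problem: _SchemeProblem, x_best: np.ndarray, i_fixed: int,
                       value_log10: float, tol: float) -> float:
    """Profiled chi-square: parameter i fixed, all others re-optimized."""
    free = [j for j in range(len(x_best)) if j != i_fixed]
    if not free:
        x = x_best.copy()
        x[i_fixed] = value_log10
        return problem.objective_log10(x)

    def obj(xf):
        x = x_best.copy()
        x[i_fixed] = value_log10
        x[free] = xf
        return problem.objective_log10(x)

    bounds = [problem.bounds_log10[j] for j in free]
    res = optimize.minimize(
        obj, x_best[free], method="L-BFGS-B", bounds=bounds,
        options={"ftol": tol, "gtol": 1e-12, "maxiter": 200},
    )
    return float(res.fun)


def _refine_crossing(profile, g1: float, g2: float, thresh: float) -> float:
    """Root-find the grid value where the profiled chi-square crosses *thresh*.

    ``profile(g)`` is below the threshold at g1 and at/above it at g2."""
    try:
        return float(optimize.brentq(lambda g: profile(g) - thresh, g1, g2, xtol=1e-4))
    except ValueError:  # numerically flat bracket
        return g2


def grid_search_ci(
    fit: GlobalFitResult,
    data: list[TimeCourse],
    param: str,
    level: float = 0.68,
    n_grid: int = 13,
    span_decades: float = 1.0,
    max_expand: int = 6,
) -> tuple[float, float]:
    """Grid-search confidence interval for one floated parameter.

    Profiles *param* over a log-spaced grid centred on the estimate,
    re-optimizing every other parameter at each node, and brackets where the
    profiled chi-square crosses ``chi2_min * (1 + F(1, N-p; level)/(N-p))``
    (the F-statistic threshold conventional for grid-search analysis).  The
    grid half-width starts at ``span_decades`` and expands (up to
    ``max_expand`` times) until both crossings are bracketed; an interval
    truncated at the parameter's box bound is flagged in ``fit.warnings``.
    The bounds are stored in ``fit.bounds68`` and returned in natural units.
    """
    if fit.scheme == "scheme1":
        problem = _scheme1_problem(data)
    elif fit.scheme in ("scheme2", "schemeA"):
        problem = _scheme2_problem(data, fit.scheme == "scheme2")
    else:
        raise ValueError(f"unknown scheme {fit.scheme!r}")
    if param not in fit.estimates:
        raise ValueError(f"{param!r} was not floated in this fit")
    names = problem.param_names
    i = names.index(param)
    x_best = np.log10(np.array([fit.estimates[n] for n in names]))
    chi2_min = fit.chi_square
    dof = fit.n_data - fit.n_params
    if dof <= 0:
        raise GlobalFitError("no residual degrees of freedom for a CI")
    thresh = chi2_min * (1.0 + stats.f.ppf(level, 1, dof) / dof)
    tol = 1e-12

    box_lo, box_hi = problem.bounds_log10[i]
    center = x_best[i]

    def profile(g: float) -> float:
        return _reoptimize_others(problem, x_best, i, g, tol)

    def profile_side(direction: int) -> tuple[float, bool]:
        """Walk outward; return (bound_log10, truncated?)."""
        span = span_decades
        prev_g = center
        for _ in range(max_expand):
            edge = center + direction * span
            hit_box = edge <= box_lo or edge >= box_hi
            edge = min(max(edge, box_lo), box_hi)
            if abs(edge - prev_g) < 1e-12:
                return prev_g, True
            grid = np.linspace(prev_g, edge, max(3, n_grid // 2 + 1))[1:]
            for g in grid:
                if profile(g) >= thresh:
                    return _refine_crossing(profile, prev_g, g, thresh), False
                prev_g = g
            if hit_box:
                return prev_g, True
            span *= 2.0
        return prev_g, True

    lo_log, lo_trunc = profile_side(-1)
    hi_log, hi_trunc = profile_side(+1)
    if lo_trunc:
        fit.warnings.append(f"lower {level:.0%} bound for {param} truncated at grid/box edge")
    if hi_trunc:
        fit.warnings.append(f"upper {level:.0%} bound for {param} truncated at grid/box edge")
    lo, hi = float(10.0 ** lo_log), float(10.0 ** hi_log)
    lo = min(lo, fit.estimates[param])
    hi = max(hi, fit.estimates[param])
    fit.bounds68[param] = (lo, hi)
    return lo, hi
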