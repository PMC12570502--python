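"""Model-independent exponential analysis of quench-flow time courses.

Product formation under single-turnover conditions is summarized by rising
exponentials:

* single:  ``f(t) = A * (1 - exp(-kobs * t))``
* double:  ``f(t) = A_fast * (1 - exp(-k_fast * t)) + A_slow * (1 - exp(-k_slow * t))``

Amplitudes are always floated (never pinned to 1) because the absolute
signal scale tracks the radiolabel's freshness, not the kinetics.  Model
order is chosen per condition by an F-test on the nested pair (the
configurable stand-in for "not described well by a single exponential"),
with small-sample AIC reported alongside.

At high temperature the chemistry outruns the 5 ms instrument dead time:
when the first observed point already sits at the fitted plateau, the rate
is reported as a *lower limit*, not an estimate (``lower_limit_flag``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .data import TimeCourse

__all__ = [
    "ExpFitResult",
    "FitError",
    "DegenerateDataError",
    "fit_single_exponential",
    "fit_double_exponential",
    "compare_exponential_models",
    "estimate_lower_limit",
]


class FitError(RuntimeError):
    """Fit failed to converge; the message carries the final residual."""


class DegenerateDataError(ValueError):
    """The response carries no kinetic information (e.g. all values equal)."""


@dataclass
class ExpFitResult:
    """Parameters and diagnostics of a single- or double-exponential fit.

    For ``model_order == 2`` the fast phase is stored first
    (``rates[0] >= rates[1]``, amplitudes permuted to match).
    """

    model_order: int
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]
    sse: float
    n_points: int
    lower_limit_flag: bool = False
    identifiability_warning: bool = False
    stderr: tuple[float | None, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return 2 * self.model_order

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, k in zip(self.amplitudes, self.rates):
            out += a * (1.0 - np.exp(-k * t))
        return out


def _prepare(tc: TimeCourse, species: str | None) -> tuple[np.ndarray, np.ndarray]:
    if species is None:
        if len(tc.fractions) != 1:
            raise ValueError("time course has several species; name the one to fit")
        species = tc.species_names[0]
    return tc.times, tc.species(species)


def _initial_rate(t: np.ndarray, y: np.ndarray, plateau: float) -> float:
    """Deterministic rate start from a log-linear regression on the rise.

    Fits ln(1 - y/plateau) ~ -k t over the points still short of the plateau;
    falls back to 1/median(t) when fewer than two usable points exist.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        z = 1.0 - y / plateau
        mask = z > 0.02
        if mask.sum() >= 2:
            slope = np.polyfit(t[mask], np.log(z[mask]), 1)[0]
            if slope < 0:
                return float(-slope)
    return float(1.0 / np.median(t))


def fit_single_exponential(
    tc: TimeCourse,
    species: str | None = None,
    weights: np.ndarray | None = None,
) -> ExpFitResult:
    """Least-squares fit of ``A * (1 - exp(-kobs t))`` with positivity bounds.

    Initialization is deterministic: the amplitude starts at the late-time
    plateau and the rate from a log-linear regression on the rising phase.
    Optional *weights* (1/sd per point) are applied to the residuals.
    """
    t, y = _prepare(tc, species)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.ptp(y) < 1e-12:
        raise DegenerateDataError("all response values are equal")

    plateau = max(float(np.mean(y[-max(2, len(y) // 4):])), 1e-6)
    k0 = _initial_rate(t, y, plateau)
    model = lmfit.Model(lambda t, A, k: A * (1.0 - np.exp(-k * t)), independent_vars=["t"])
    params = model.make_params(
        A={"value": plateau, "min": 0.0, "max": 1.5},
        k={"value": k0, "min": 1e-8, "max": 1e7},
    )
    res = model.fit(y, params, t=t, weights=weights)
    if not res.success:
        raise FitError(f"single-exponential fit did not converge (residual {res.chisqr:.3g})")
    sse = float(np.sum((res.best_fit - y) ** 2))
    return ExpFitResult(
        model_order=1,
        amplitudes=(float(res.params["A"].value),),
        rates=(float(res.params["k"].value),),
        sse=sse,
        n_points=len(t),
        stderr=(res.params["A"].stderr, res.params["k"].stderr),
        metadata={"redchi": float(res.redchi), "init_k": k0},
    )


def fit_double_exponential(
    tc: TimeCourse,
    species: str | None = None,
    weights: np.ndarray | None = None,
    rate_ratio_warn: float = 1.5,
) -> ExpFitResult:
    """Least-squares fit of a sum of two rising exponentials.

    Multi-start: the single-exponential solution seeds starts with rate pairs
    ``(k/3, 3k)``, ``(k/10, 10k)`` and ``(k, k*1.01)``, amplitudes split
    evenly; the lowest-SSE converged start wins, and the fast phase is stored
    first.  Fits with ``k_fast/k_slow < rate_ratio_warn`` set
    ``identifiability_warning`` — the two phases are not distinguishable.
    """
    t, y = _prepare(tc, species)
    if len(t) < 6:
        raise ValueError("need at least 6 time points")
    if np.ptp(y) < 1e-12:
        raise DegenerateDataError("all response values are equal")

    single = fit_single_exponential(tc, species, weights)
    k1 = single.rates[0]
    amp = single.amplitudes[0]
    model = lmfit.Model(
        lambda t, Af, kf, As, ks: Af * (1.0 - np.exp(-kf * t)) + As * (1.0 - np.exp(-ks * t)),
        independent_vars=["t"],
    )
    best = None
    for kf0, ks0 in ((3 * k1, k1 / 3), (10 * k1, k1 / 10), (1.01 * k1, k1)):
        params = model.make_params(
            Af={"value": amp / 2, "min": 0.0, "max": 1.5},
            kf={"value": kf0, "min": 1e-8, "max": 1e7},
            As={"value": amp / 2, "min": 0.0, "max": 1.5},
            ks={"value": ks0, "min": 1e-8, "max": 1e7},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(y, params, t=t, weights=weights)
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitError("no double-exponential start converged")

    pairs = sorted(
        [
            (float(best.params["kf"].value), float(best.params["Af"].value),
             best.params["kf"].stderr, best.params["Af"].stderr),
            (float(best.params["ks"].value), float(best.params["As"].value),
             best.params["ks"].stderr, best.params["As"].stderr),
        ],
        reverse=True,
    )
    (kf, af, kf_se, af_se), (ks, a_s, ks_se, as_se) = pairs
    sse = float(np.sum((best.best_fit - y) ** 2))
    warn = kf / max(ks, 1e-300) < rate_ratio_warn
    return ExpFitResult(
        model_order=2,
        amplitudes=(af, a_s),
        rates=(kf, ks),
        sse=sse,
        n_points=len(t),
        identifiability_warning=warn,
        stderr=(af_se, as_se, kf_se, ks_se),
        metadata={"redchi": float(best.redchi)},
    )


def compare_exponential_models(
    fit1: ExpFitResult, fit2: ExpFitResult, n_points: int | None = None, alpha: float = 0.05
) -> dict:
    """Choose between the nested single/double fits by F-test (df 2).

    Returns a dict with the preferred order, the F statistic and p-value, and
    small-sample AIC (AICc) for both models.  Equal SSEs prefer order 1
    (parsimony).  Both fits must come from the same data.
    """
    if fit1.model_order != 1 or fit2.model_order != 2:
        raise ValueError("pass the order-1 fit first and the order-2 fit second")
    n = n_points if n_points is not None else fit1.n_points
    if fit1.n_points != fit2.n_points:
        raise ValueError("fits are on different data (point counts differ)")
    df_extra = fit2.n_params - fit1.n_params
    df_denom = n - fit2.n_params
    if df_denom <= 0:
        raise ValueError("too few points for the F-test")
    if fit2.sse <= 0 or fit1.sse <= fit2.sse * (1 + 1e-12):
        # perfect order-2 fit or tie: fall back on parsimony unless the
        # improvement is genuinely infinite
        F = np.inf if fit2.sse == 0 and fit1.sse > 0 else 0.0
    else:
        F = ((fit1.sse - fit2.sse) / df_extra) / (fit2.sse / df_denom)
    p = float(stats.f.sf(F, df_extra, df_denom)) if np.isfinite(F) else 0.0

    def _aicc(fit: ExpFitResult) -> float:
        k = fit.n_params + 1  # + residual variance
        aic = n * np.log(max(fit.sse, 1e-300) / n) + 2 * k
        corr = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
        return float(aic + corr)

    preferred = 2 if p < alpha else 1
    return {
        "preferred_order": preferred,
        "F": float(F),
        "p_value": p,
        "alpha": alpha,
        "aicc_order1": _aicc(fit1),
        "aicc_order2": _aicc(fit2),
    }


def estimate_lower_limit(
    tc: TimeCourse,
    dead_time_s: float = 5e-3,
    species: str | None = None,
    plateau_threshold: float = 0.95,
) -> ExpFitResult:
    """Single-exponential fit with dead-time awareness.

    If the first observed point already sits at the fitted plateau (within
    noise), the reaction finished inside the instrument dead time and only a
    lower bound on the rate is identifiable: the fit is returned with
    ``lower_limit_flag`` set and the fitted rate is to be read as "at least
    this fast".  The flagging threshold is ``plateau_threshold`` softened by
    three estimated noise SDs so a single unlucky first-point draw cannot
    suppress the flag; the reported bound is capped at
    ``-ln(1 - plateau_threshold)/dead_time`` — the fastest rate the first
    observable point can actually attest to — so it never exceeds the true
    rate of a reaction complete inside the dead time.
    """
    if dead_time_s <= 0:
        raise ValueError("dead_time_s must be > 0")
    t, y = _prepare(tc, species)
    fit = fit_single_exponential(tc, species)
    plateau = fit.amplitudes[0]
    first_frac = float(y[0] / plateau) if plateau > 0 else 0.0
    noise_rel = float(np.sqrt(fit.sse / max(fit.n_points - 2, 1)) / plateau) if plateau > 0 else 0.0
    flagged = first_frac >= plateau_threshold - 3.0 * noise_rel
    if flagged:
        # cap the reported bound at what the dead time can actually resolve
        q = min(first_frac, plateau_threshold, 1 - 1e-9)
        k_cap = -np.log1p(-q) / t[0]
        k_bound = min(fit.rates[0], k_cap)
        fit = ExpFitResult(
            model_order=1,
            amplitudes=fit.amplitudes,
            rates=(float(k_bound),),
            sse=fit.sse,
            n_points=fit.n_points,
            lower_limit_flag=True,
            stderr=fit.stderr,
            metadata={**fit.metadata, "dead_time_s": dead_time_s,
                      "first_point_fraction_of_plateau": first_frac},
        )
    else:
        fit.metadata.update(
            {"dead_time_s": dead_time_s, "first_point_fraction_of_plateau": first_frac}
        )
    return fit
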