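"""Published fitted rate constants for *T. kodakarensis* RNAP, as inputs.

These are the parameter values reported for the single-nucleotide-addition
scheme at 25 C and for the multi-nucleotide chain at 25 C and 65 C.  The raw
quench-flow time courses behind them are not deposited, so throughout this
package the tables serve as *generating truths* for synthetic data and as
printed inputs for summary arithmetic — not as values the fits are tuned
toward.

All rates are s-1; Kd is uM; k1 is M-1 s-1.  Chain-rate columns are keyed by
the equimolar ATP+GTP concentration in uM; odd indices are forward rates
along M10 -> M11 -> M12 -> M13plus, even indices the reverses.
"""

from __future__ import annotations

from .schemes import RateParameters

__all__ = [
    "SCHEME1_25C",
    "CHAIN_RATES_25C",
    "CHAIN_RATES_65C",
    "scheme1_params",
    "chain_params",
    "kobs5_summary",
]

#: Single-nucleotide addition at 25 C: fixed k1, fitted Kd and k3.
SCHEME1_25C = {"k1": 1.0e8, "Kd_uM": 2.985, "k3": 1.001}

#: Multi-nucleotide chain rates (s-1) at 25 C, by NTP concentration (uM).
CHAIN_RATES_25C: dict[float, dict[int, float]] = {
    10.0: {1: 0.786, 2: 1.174, 3: 0.356, 4: 0.715, 5: 0.145, 6: 0.262},
    50.0: {1: 1.351, 2: 2.656, 3: 0.772, 4: 1.064, 5: 0.167, 6: 0.337},
    250.0: {1: 1.448, 2: 0.733, 3: 0.585, 4: 0.863, 5: 0.063, 6: 0.019},
    1000.0: {1: 0.558, 2: 2.674, 3: 0.683, 4: 1.037, 5: 0.299, 6: 0.429},
}

#: Multi-nucleotide chain rates (s-1) at 65 C, by NTP concentration (uM).
CHAIN_RATES_65C: dict[float, dict[int, float]] = {
    10.0: {1: 62.95, 2: 793.9, 3: 72.98, 4: 109.7, 5: 24.2, 6: 9.05},
    50.0: {1: 2185.5, 2: 8484.7, 3: 287.7, 4: 313.2, 5: 141.3, 6: 17.7},
    250.0: {1: 5910.8, 2: 6069.3, 3: 4614.4, 4: 54.51, 5: 135.2, 6: 7.65},
    1000.0: {1: 373.1, 2: 1029.8, 3: 384.2, 4: 382.6, 5: 107.8, 6: 13.96},
}


def scheme1_params() -> RateParameters:
    """The published single-nucleotide-addition parameter set at 25 C."""
    return RateParameters(
        k1=SCHEME1_25C["k1"], Kd=SCHEME1_25C["Kd_uM"], k3=SCHEME1_25C["k3"]
    )


def chain_params(conc_uM: float, temperature: str = "65C") -> RateParameters:
    """Chain rates for one published condition as a parameter set."""
    table = CHAIN_RATES_65C if temperature == "65C" else CHAIN_RATES_25C
    if conc_uM not in table:
        raise KeyError(f"no published column at {conc_uM} uM ({temperature})")
    return RateParameters(kobs=dict(table[conc_uM]))


def kobs5_summary(temperature: str = "65C") -> tuple[float, float]:
    """Mean and population SD of the bond-formation rate kobs5 across the
    four NTP concentrations at one temperature."""
    import numpy as np

    table = CHAIN_RATES_65C if temperature == "65C" else CHAIN_RATES_25C
    vals = np.array([col[5] for col in table.values()])
    return float(vals.mean()), float(vals.std(ddof=0))
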