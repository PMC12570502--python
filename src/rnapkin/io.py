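"""File I/O: long-format time-course CSV, FASTA strands, JSON fit reports.

The CSV schema is long format with columns ``time_s, species, fraction,
replicate, conc_uM, temperature`` — one row per (time, species) sample —
round-tripping losslessly through :class:`~rnapkin.data.TimeCourse`.
Artifact files embed the seed and a config hash so every number can be
traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data import TimeCourse, TimeCourseError
from .globalfit import GlobalFitResult
from .scaffold import NucleicStrand

__all__ = [
    "SchemaError",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_fasta_strand",
    "write_fasta_strand",
    "write_fit_report",
    "read_fit_report",
    "config_hash",
]

CSV_COLUMNS = ["time_s", "species", "fraction", "replicate", "conc_uM", "temperature"]


class SchemaError(ValueError):
    """The file does not match the expected schema; names the missing parts."""


def write_timecourse_csv(tcs: list[TimeCourse], path: str | Path) -> None:
    """Write time courses as one long-format CSV."""
    rows = []
    for tc in tcs:
        for species in tc.species_names:
            y = tc.species(species)
            for t, v in zip(tc.times, y):
                rows.append((t, species, v, tc.replicate, tc.conc_uM, tc.temperature))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_timecourse_csv(path: str | Path) -> list[TimeCourse]:
    """Read a long-format CSV back into per-(condition, replicate) records.

    Validates the header (a :class:`SchemaError` lists any missing columns)
    and the fraction range ([0, 1.2]; values above 1 warn inside
    :class:`TimeCourse`).
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    bad = df[(df["fraction"] < 0) | (df["fraction"] > 1.2)]
    if not bad.empty:
        line = int(bad.index[0]) + 2  # header + 1-based
        raise TimeCourseError(
            f"fraction {bad.iloc[0]['fraction']} outside [0, 1.2] at {path} line {line}"
        )
    out: list[TimeCourse] = []
    for (conc, temp, rep), grp in df.groupby(["conc_uM", "temperature", "replicate"], sort=True):
        fractions = {}
        times = None
        for species, sgrp in grp.groupby("species", sort=True):
            sgrp = sgrp.sort_values("time_s")
            t = sgrp["time_s"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif len(t) != len(times) or not np.allclose(t, times):
                raise SchemaError(
                    f"species {species!r} of condition ({conc}, {temp}, rep {rep}) "
                    f"is on a different time grid"
                )
            fractions[species] = sgrp["fraction"].to_numpy(dtype=float)
        out.append(
            TimeCourse(times, fractions, replicate=int(rep), conc_uM=float(conc),
                       temperature=str(temp))
        )
    return out


def read_fasta_strand(path: str | Path, alphabet: str | None = None) -> NucleicStrand:
    """Read a single-record FASTA into a strand; infers RNA from any U."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise SchemaError(f"{path} must contain exactly one FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    if alphabet is None:
        alphabet = "RNA" if "U" in seq else "DNA"
    return NucleicStrand(seq, alphabet, name=records[0].id)


def write_fasta_strand(strand: NucleicStrand, path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(strand.sequence), id=strand.name or "strand", description="")],
        str(path),
        "fasta",
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_fit_report(fit: GlobalFitResult, path: str | Path, config: dict | None = None) -> None:
    """Serialize a global-fit result (estimates, bounds, chi-square, provenance)."""
    payload = {
        "scheme": fit.scheme,
        "estimates": fit.estimates,
        "fixed": fit.fixed,
        "chi_square": fit.chi_square,
        "bounds68": {k: list(v) for k, v in fit.bounds68.items()},
        "amplitudes": fit.amplitudes,
        "provenance": fit.provenance,
        "warnings": fit.warnings,
        "n_data": fit.n_data,
        "n_params": fit.n_params,
    }
    if config is not None:
        payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def read_fit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
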