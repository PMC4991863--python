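"""Energy-table I/O and best-effort QM engine output parsers.

The canonical exchange format is a comma-separated table, one row per
conformer, with the bit-exact header::

    molecule_id,state,conformer_id,method,solvent_model,units,delta_hf,g_rrho,dg_solv,n_imaginary,convergence_tier

Energies are stored in the unit named by each row's ``units`` column
(``kcal/mol`` or ``hartree``) and are always kcal/mol after loading; an
empty ``g_rrho`` cell means the RRHO term is absent for that conformer.

The engine parsers are deliberately marker-line based and tolerant of
surrounding noise.  They target a fixed dialect (the marker strings in
``MOPAC_HOF_RE`` / ``GAMESS_*_RE`` below are the configuration points)
rather than every historical output variant:

* MOPAC-style output yields the final heat of formation; a COSMO run's
  heat of formation already contains the solvation term, so the solvation
  free energy is derived by the caller as (solvated − gas) from a pair of
  runs (:func:`derive_dg_solv`).
* GAMESS-style logs yield the heat of formation, the SMD solvation free
  energy, and the count of imaginary vibrational modes from the FREQUENCY
  lines of a Hessian section (imaginary modes carry a trailing ``I``).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .constants import HARTREE_TO_KCAL
from .errors import EnergyTableError, EngineOutputError
from .thermo import (
    ConvergenceTier,
    EnergyRecord,
    Method,
    SolventModel,
    State,
    mark_exclusions,
)

CANONICAL_COLUMNS = [
    "molecule_id",
    "state",
    "conformer_id",
    "method",
    "solvent_model",
    "units",
    "delta_hf",
    "g_rrho",
    "dg_solv",
    "n_imaginary",
    "convergence_tier",
]

_UNIT_FACTORS = {"kcal/mol": 1.0, "hartree": HARTREE_TO_KCAL}


class ParserWarning(UserWarning):
    """Recoverable oddity in engine output (duplicate markers, missing
    Hessian section)."""


@dataclass
class EnergyTable:
    """In-memory canonical energy table."""

    rows: list[EnergyRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rows:
            key = (r.molecule_id, r.state, r.conformer_id, r.method, r.solvent_model)
            if key in seen:
                raise EnergyTableError(
                    f"duplicate record key {tuple(k.value if hasattr(k, 'value') else k for k in key)}"
                )
            seen.add(key)


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise EnergyTableError(
            f"non-numeric value {raw!r} in column {column!r}, data row {row}"
        ) from None


def read_energy_table(path) -> EnergyTable:
    """Load a canonical energy table, converting all energies to kcal/mol."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise EnergyTableError(f"missing mandatory column(s): {missing} in {path}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        units = row["units"] or "kcal/mol"
        if units not in _UNIT_FACTORS:
            raise EnergyTableError(
                f"unknown unit {units!r} in data row {i} (column 'units')"
            )
        factor = _UNIT_FACTORS[units]
        g_rrho_raw = row["g_rrho"].strip()
        n_imag_raw = row["n_imaginary"].strip()
        tier_raw = row["convergence_tier"].strip()
        try:
            records.append(
                EnergyRecord(
                    molecule_id=row["molecule_id"],
                    state=State(row["state"]),
                    conformer_id=row["conformer_id"],
                    method=Method(row["method"]),
                    solvent_model=SolventModel(row["solvent_model"]),
                    delta_hf=_parse_float(row["delta_hf"], i, "delta_hf") * factor,
                    dg_solv=_parse_float(row["dg_solv"], i, "dg_solv") * factor,
                    g_rrho=(
                        _parse_float(g_rrho_raw, i, "g_rrho") * factor
                        if g_rrho_raw
                        else None
                    ),
                    n_imaginary=int(n_imag_raw) if n_imag_raw else 0,
                    convergence_tier=(
                        ConvergenceTier(tier_raw)
                        if tier_raw
                        else ConvergenceTier.DEFAULT
                    ),
                )
            )
        except ValueError as exc:
            raise EnergyTableError(f"data row {i}: {exc}") from None
    records = mark_exclusions(records)
    return EnergyTable(
        rows=records,
        metadata={"source": str(path), "units": "kcal/mol"},
    )


def write_energy_table(table: EnergyTable, path) -> None:
    """Write the canonical CSV (kcal/mol); read∘write is field-exact."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for r in table.rows:
            writer.writerow(
                [
                    r.molecule_id,
                    r.state.value,
                    r.conformer_id,
                    r.method.value,
                    r.solvent_model.value,
                    "kcal/mol",
                    repr(r.delta_hf),
                    "" if r.g_rrho is None else repr(r.g_rrho),
                    repr(r.dg_solv),
                    r.n_imaginary,
                    r.convergence_tier.value,
                ]
            )


# ---------------------------------------------------------------------------
# Engine output parsers

MOPAC_HOF_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/MOL"
)
GAMESS_HOF_RE = re.compile(r"HEAT OF FORMATION IS\s+(-?\d+(?:\.\d+)?)\s*KCAL/MOL")
GAMESS_SOLV_RE = re.compile(
    r"FREE ENERGY OF SOLVATION[^=]*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/MOL"
)
GAMESS_FREQ_LINE_RE = re.compile(r"^\s*FREQUENCY:\s*(.*)$", re.MULTILINE)
_FREQ_TOKEN_RE = re.compile(r"(-?\d+(?:\.\d+)?)(\s*I)?")


def parse_mopac_output(text: str) -> dict:
    """Extract the final heat of formation from MOPAC-style output.

    Returns ``{"delta_hf": kcal/mol}``.  For a COSMO run this value is the
    solvated heat of formation; combine with a gas-phase run via
    :func:`derive_dg_solv`.  Multiple marker lines → last one wins with a
    warning.
    """
    matches = MOPAC_HOF_RE.findall(text)
    if not matches:
        raise EngineOutputError(
            "no 'FINAL HEAT OF FORMATION' marker found in MOPAC-style output"
        )
    if len(matches) > 1:
        warnings.warn(
            f"{len(matches)} heat-of-formation markers found; using the last",
            ParserWarning,
            stacklevel=2,
        )
    return {"delta_hf": float(matches[-1])}


def derive_dg_solv(gas_hof: float, solvated_hof: float) -> float:
    """ΔG°_solv as solvated-minus-gas heat of formation from paired runs."""
    return solvated_hof - gas_hof


def parse_gamess_log(text: str) -> dict:
    """Extract energies and imaginary-mode count from a GAMESS-style log.

    Returns a dict with ``delta_hf`` (required), ``dg_solv`` (present for
    SMD runs) and ``n_imaginary`` (``None`` with a warning when no Hessian
    section exists).
    """
    hof = GAMESS_HOF_RE.findall(text)
    if not hof:
        raise EngineOutputError(
            "no recognizable energy block ('HEAT OF FORMATION IS') in "
            "GAMESS-style log"
        )
    out: dict = {"delta_hf": float(hof[-1])}
    solv = GAMESS_SOLV_RE.findall(text)
    if solv:
        out["dg_solv"] = float(solv[-1])
    freq_lines = GAMESS_FREQ_LINE_RE.findall(text)
    if not freq_lines:
        out["n_imaginary"] = None
        warnings.warn(
            "no Hessian/FREQUENCY section: imaginary-mode count unknown",
            ParserWarning,
            stacklevel=2,
        )
    else:
        n_imag = 0
        for line in freq_lines:
            for m in _FREQ_TOKEN_RE.finditer(line):
                if m.group(2):
                    n_imag += 1
        out["n_imaginary"] = n_imag
    return out


# ---------------------------------------------------------------------------
# Fixture generator

_MOPAC_TEMPLATE = """\
 *******************************************************************************
 ** MOPAC-style fixture — synthetic output for parser testing                 **
 *******************************************************************************
          GEOMETRY OPTIMISED USING EIGENVECTOR FOLLOWING (EF).
          SCF FIELD WAS ACHIEVED

          FINAL HEAT OF FORMATION = {hof:>15.5f} KCAL/MOL

          COSMO AREA              =         99.99 SQUARE ANGSTROMS
          IONIZATION POTENTIAL    =          9.999 EV
"""

_GAMESS_HEADER = """\
          *** GAMESS-style fixture — synthetic output for parser testing ***
 ...... END OF GEOMETRY SEARCH ......
     HEAT OF FORMATION IS {hof:>12.5f} KCAL/MOL
"""

_GAMESS_SOLV = """\
     SMD SOLVATION SUMMARY
     FREE ENERGY OF SOLVATION (DELTA-G-S) = {dg_solv:>10.5f} KCAL/MOL
"""

_GAMESS_FREQ_HEADER = """\
     NORMAL COORDINATE ANALYSIS IN THE HARMONIC APPROXIMATION
"""


def generate_fixture(spec: dict) -> str:
    """Emit synthetic engine-style text embedding the given values.

    ``spec`` keys: ``engine`` ("mopac" or "gamess"), ``hof`` (kcal/mol);
    for GAMESS additionally ``dg_solv``, ``n_imaginary`` and ``n_real``
    (real-frequency count, default 5; set both counts absent to omit the
    Hessian section).  parse∘generate is the identity on every named field.
    """
    engine = spec.get("engine")
    if engine == "mopac":
        return _MOPAC_TEMPLATE.format(hof=float(spec["hof"]))
    if engine == "gamess":
        text = _GAMESS_HEADER.format(hof=float(spec["hof"]))
        if "dg_solv" in spec:
            text += _GAMESS_SOLV.format(dg_solv=float(spec["dg_solv"]))
        if "n_imaginary" in spec or "n_real" in spec:
            n_imag = int(spec.get("n_imaginary", 0))
            n_real = int(spec.get("n_real", 5))
            freqs = [f"{120.0 + 7.0 * k:>10.2f} I" for k in range(n_imag)]
            freqs += [f"{400.0 + 90.0 * k:>10.2f}  " for k in range(n_real)]
            text += _GAMESS_FREQ_HEADER
            for start in range(0, len(freqs), 5):
                text += "   FREQUENCY:" + "".join(freqs[start : start + 5]) + "\n"
        return text
    raise EngineOutputError(f"unknown engine label {engine!r} (mopac|gamess)")


def records_to_table(records: Sequence[EnergyRecord], metadata: Optional[dict] = None) -> EnergyTable:
    """Convenience constructor applying the exclusion rule."""
    return EnergyTable(rows=mark_exclusions(records), metadata=metadata or {})
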