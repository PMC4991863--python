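"""Isodesmic-reaction pKa prediction and the reference-molecule library.

The pKa of an ionizable site is anchored to a structurally similar
reference molecule of known experimental pKa through the proton-exchange
(isodesmic) reaction

    AH + B_ref  ⇌  A⁻ + B_ref H        (acids; for bases AH is BH⁺)

whose standard free-energy change ΔG° is assembled from decomposed
per-species free energies.  The prediction is then

    pKa = pKa_ref + ΔG° / (R T ln 10)

Because the reaction conserves bond types, systematic errors in the
underlying electronic-structure and solvation energies largely cancel,
which is what makes semiempirical heats of formation usable at all for
this purpose.  An optional one-parameter-per-class additive correction
(+2 pH units for tertiary amines by default) compensates the remaining
systematic underestimation for amine classes, and an optional two-parameter
linear calibration pKa = A·ΔG°/(RT ln 10) + B can replace the fixed-slope
form when a training set is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from math import isfinite
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats as _scipy_stats

from .constants import STANDARD_TEMPERATURE, rt_ln10
from .errors import (
    CalibrationError,
    InconsistentVariantError,
    InferredReferenceError,
    ReferenceLookupError,
)

logger = logging.getLogger(__name__)


class SiteClass(str, Enum):
    """Functional-group class of an ionizable site."""

    PYRIDINE = "pyridine"
    ALCOHOL = "alcohol"
    PHENOL = "phenol"
    BENZOIC_ACID = "benzoic_acid"
    CARBOXYLIC_ACID = "carboxylic_acid"
    PRIMARY_AMINE = "primary_amine"
    SECONDARY_AMINE = "secondary_amine"
    TERTIARY_AMINE = "tertiary_amine"


@dataclass(frozen=True)
class ReferenceEntry:
    """A reference molecule anchoring predictions for one site class."""

    name: str
    site_class: SiteClass
    pka_ref: float
    provenance: str = ""
    is_default: bool = False

    def __post_init__(self) -> None:
        if not isfinite(self.pka_ref):
            raise ValueError("pka_ref must be finite")

    @property
    def inferred(self) -> bool:
        return "inferred" in self.provenance


@dataclass(frozen=True)
class PkaPrediction:
    """One predicted pKa with its provenance.

    Invariant: ``pka == reference.pka_ref + delta_g/(RT ln10) +
    correction_applied`` to 1e-9.
    """

    molecule_id: str
    site_class: SiteClass
    reference: ReferenceEntry
    delta_g: float
    pka: float
    model_label: str = ""
    correction_applied: float = 0.0
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        expected = (
            self.reference.pka_ref
            + self.delta_g / rt_ln10(self.temperature)
            + self.correction_applied
        )
        if abs(self.pka - expected) > 1e-9:
            raise ValueError(
                f"inconsistent prediction: pka={self.pka} but "
                f"pka_ref + dG/(RT ln10) + correction = {expected}"
            )


@dataclass(frozen=True)
class CalibrationModel:
    """Linear recalibration pKa = A·ΔG°/(RT ln10) + B."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (isfinite(self.slope) and isfinite(self.intercept)):
            raise ValueError("calibration parameters must be finite")


def isodesmic_delta_g(
    g_acid_target: float,
    g_base_target: float,
    g_acid_ref: float,
    g_base_ref: float,
) -> float:
    """ΔG° of the proton-exchange reaction, kcal/mol.

    With the target's acid form on the left,

        ΔG° = [G°(base_target) + G°(acid_ref)] − [G°(acid_target) + G°(base_ref)]

    All four energies must come from the same method/solvent variant; a
    constant shift applied to every species cancels exactly.
    """
    vals = (g_acid_target, g_base_target, g_acid_ref, g_base_ref)
    if not all(isfinite(v) for v in vals):
        raise ValueError(f"all four free energies must be finite, got {vals}")
    return (g_base_target + g_acid_ref) - (g_acid_target + g_base_ref)


def check_variant_consistency(labels: Iterable[str]) -> None:
    """Raise if the free energies entering one reaction mix method variants."""
    distinct = {lbl for lbl in labels if lbl}
    if len(distinct) > 1:
        raise InconsistentVariantError(
            f"inconsistent method variant: energies mix {sorted(distinct)}"
        )


def predict_pka(
    delta_g: float,
    reference: ReferenceEntry,
    *,
    molecule_id: str = "",
    temperature: float = STANDARD_TEMPERATURE,
    model_label: str = "",
) -> PkaPrediction:
    """pKa = pKa_ref + ΔG°/(RT ln 10), with RT ln10 = 1.3643 kcal/mol at
    298.15 K."""
    pka = reference.pka_ref + delta_g / rt_ln10(temperature)
    return PkaPrediction(
        molecule_id=molecule_id,
        site_class=reference.site_class,
        reference=reference,
        delta_g=delta_g,
        pka=pka,
        model_label=model_label,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# Reference library


def load_reference_library(path=None) -> list[ReferenceEntry]:
    """Load the reference-molecule library (packaged copy by default).

    The packaged library carries the benchmark anchors: pyridine (5.2),
    ethanol (15.9), acetic acid (4.8), diethylamine (11.1), triethylamine
    (10.7), plus the alternative tertiary-amine anchors quinuclidine (11.0),
    benzylpyrrolidene (8.9) and heliotridane (11.4).  Entries whose
    provenance is marked "inferred" are refused by :func:`select_reference`
    unless explicitly confirmed.
    """
    if path is None:
        with resources.files("isopka.data").joinpath("references.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    entries = [
        ReferenceEntry(
            name=row["name"],
            site_class=SiteClass(row["site_class"]),
            pka_ref=float(row["pka_ref"]),
            provenance=str(row["provenance"]),
            is_default=bool(int(row["is_default"])),
        )
        for _, row in df.iterrows()
    ]
    per_class = {}
    for e in entries:
        if e.is_default:
            if e.site_class in per_class:
                raise ValueError(
                    f"multiple default references for class {e.site_class.value}"
                )
            per_class[e.site_class] = e
    return entries


def select_reference(
    site_class: SiteClass | str,
    library: Sequence[ReferenceEntry],
    override: Optional[str] = None,
    allow_inferred: bool = False,
) -> ReferenceEntry:
    """Pick the reference molecule for a site class.

    By default the library's default entry for the class is returned; a
    named ``override`` (e.g. quinuclidine instead of triethylamine for a
    bicyclic tertiary amine) is honored regardless of class defaults.
    """
    if override is not None:
        for e in library:
            if e.name.lower() == override.lower():
                return e
        raise ReferenceLookupError(
            f"no reference named {override!r}; available: "
            f"{sorted(e.name for e in library)}"
        )
    try:
        site_class = SiteClass(site_class)
    except ValueError:
        raise ReferenceLookupError(
            f"unknown site class {site_class!r}; available classes: "
            f"{sorted(c.value for c in SiteClass)}"
        ) from None
    defaults = [e for e in library if e.site_class is site_class and e.is_default]
    if not defaults:
        raise ReferenceLookupError(
            f"no reference for class {site_class.value!r}; classes present: "
            f"{sorted({e.site_class.value for e in library})}"
        )
    entry = defaults[0]
    if entry.inferred and not allow_inferred:
        raise InferredReferenceError(
            f"default reference {entry.name!r} for {site_class.value} has "
            f"inferred provenance ({entry.provenance!r}); pass "
            "allow_inferred=True to use it"
        )
    if entry.inferred:
        logger.warning(
            "using reference %s (%s) with inferred provenance: %s",
            entry.name,
            site_class.value,
            entry.provenance,
        )
    return entry


# ---------------------------------------------------------------------------
# Corrections and calibration

#: Additive class corrections applied after the isodesmic prediction.  Only
#: the tertiary-amine +2 pH unit offset is active by default; a +1 offset
#: for secondary amines is a documented option left off.
DEFAULT_CORRECTIONS: dict[SiteClass, float] = {SiteClass.TERTIARY_AMINE: 2.0}


def apply_class_correction(
    prediction: PkaPrediction, offsets: Mapping[SiteClass | str, float]
) -> PkaPrediction:
    """Shift a prediction by its class offset (identity if class absent)."""
    normalized = {SiteClass(k): v for k, v in offsets.items()}
    offset = normalized.get(prediction.site_class, 0.0)
    if offset == 0.0:
        return prediction
    return replace(
        prediction,
        pka=prediction.pka + offset,
        correction_applied=prediction.correction_applied + offset,
    )


def fit_calibration(
    delta_gs: Sequence[float],
    exp_pkas: Sequence[float],
    temperature: float = STANDARD_TEMPERATURE,
) -> CalibrationModel:
    """Least-squares fit of experimental pKa against ΔG°/(RT ln10)."""
    if len(delta_gs) != len(exp_pkas):
        raise CalibrationError("delta_gs and exp_pkas must have equal length")
    if len(delta_gs) < 2:
        raise CalibrationError("calibration needs at least 2 points")
    scale = rt_ln10(temperature)
    x = [dg / scale for dg in delta_gs]
    if max(x) == min(x):
        raise CalibrationError("degenerate fit: all delta_g values identical")
    res = _scipy_stats.linregress(x, list(exp_pkas))
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept))


def apply_calibration(
    delta_g: float,
    model: CalibrationModel,
    temperature: float = STANDARD_TEMPERATURE,
) -> float:
    """pKa = A·ΔG°/(RT ln10) + B."""
    return model.slope * delta_g / rt_ln10(temperature) + model.intercept


def round_display(value: float, ndigits: int = 1) -> float:
    """Round half-away-from-zero for display (full precision is kept
    internally everywhere)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
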