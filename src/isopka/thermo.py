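"""Free-energy bookkeeping for conformer ensembles.

The standard free energy of a solvated species X is assembled from three
decomposed terms, all in kcal/mol::

    G°(X) = ΔH_f(X) + G°_RRHO(X) + ΔG°_solv(X)

where ΔH_f is the semiempirical heat of formation (PM6 or PM6-D3H+),
G°_RRHO the rigid-rotor/harmonic-oscillator free-energy correction from a
gas-phase frequency calculation, and ΔG°_solv the continuum solvation free
energy (SMD or COSMO).  The RRHO term is optional; a method label carries a
trailing ``*`` exactly when it is dropped (e.g. ``PM6/COSMO*``).

The 1 M standard-state correction to G°_RRHO is never applied here: in an
isodesmic reaction the correction appears once on each side and cancels.

Conformer handling follows a lowest-free-energy selection rule: within an
ensemble of conformers of one (molecule, protonation state), the
representative is the non-excluded record with the smallest G°(X).
Records with imaginary vibrational modes surviving the tightest geometry
convergence tier (5e-5 au) are excluded outright; imaginary modes at looser
tiers are retained with a warning, since in the original workflow such
structures are re-optimized at a tighter criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

from .constants import STANDARD_TEMPERATURE
from .errors import NoValidConformerError, RRHOUnavailableError

logger = logging.getLogger(__name__)


class State(str, Enum):
    """Protonation state of a species: acid form (HA / BH+) or base form."""

    ACID = "acid"
    BASE = "base"


class Method(str, Enum):
    """Semiempirical electronic-structure method for the heat of formation."""

    PM6 = "PM6"
    PM6_D3HP = "PM6-D3H+"


class SolventModel(str, Enum):
    """Continuum solvation model supplying ΔG°_solv."""

    SMD = "SMD"
    COSMO = "COSMO"


class ConvergenceTier(str, Enum):
    """Geometry-optimization gradient convergence criterion (au).

    The workflow starts at 5e-4 and tightens to 1e-4 and then 5e-5 whenever
    imaginary frequencies appear; only structures still carrying imaginary
    modes at the tightest tier are discarded.
    """

    DEFAULT = "default_5e-4"
    TIGHT = "tight_1e-4"
    TIGHTEST = "tightest_5e-5"


@dataclass(frozen=True)
class EnergyRecord:
    """Decomposed energy terms for one conformer of one protonation state.

    Parameters
    ----------
    delta_hf : float
        Semiempirical heat of formation, kcal/mol.
    dg_solv : float
        Continuum solvation free energy, kcal/mol.
    g_rrho : float, optional
        RRHO free-energy correction, kcal/mol.  May be absent; a model with
        ``include_rrho=True`` then refuses the record.
    n_imaginary : int
        Number of imaginary vibrational modes found for this geometry.
    """

    molecule_id: str
    state: State
    conformer_id: str
    method: Method
    solvent_model: SolventModel
    delta_hf: float
    dg_solv: float
    g_rrho: Optional[float] = None
    n_imaginary: int = 0
    convergence_tier: ConvergenceTier = ConvergenceTier.DEFAULT
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.n_imaginary < 0:
            raise ValueError(
                f"n_imaginary must be non-negative, got {self.n_imaginary}"
            )


@dataclass(frozen=True)
class FreeEnergyModel:
    """A method variant: which terms enter G°(X) and at what temperature.

    The label convention is ``<method>/<solvent>`` with a trailing ``*``
    if and only if the RRHO term is neglected.
    """

    include_rrho: bool
    temperature: float = STANDARD_TEMPERATURE
    label: str = ""

    def __post_init__(self) -> None:
        if self.label:
            starred = self.label.endswith("*")
            if starred == self.include_rrho:
                raise ValueError(
                    f"label {self.label!r} inconsistent with "
                    f"include_rrho={self.include_rrho}: a trailing '*' marks "
                    "a model without the RRHO term"
                )

    @classmethod
    def from_parts(
        cls,
        method: Method,
        solvent_model: SolventModel,
        include_rrho: bool,
        temperature: float = STANDARD_TEMPERATURE,
    ) -> "FreeEnergyModel":
        label = f"{method.value}/{solvent_model.value}" + ("" if include_rrho else "*")
        return cls(include_rrho=include_rrho, temperature=temperature, label=label)


@dataclass(frozen=True)
class ConformerEnsemble:
    """All conformer records of one (molecule, state) under one variant."""

    molecule_id: str
    state: State
    records: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise ValueError("ensemble must be non-empty")
        first = records[0]
        for r in records:
            if (
                r.molecule_id != self.molecule_id
                or r.state != self.state
                or r.method != first.method
                or r.solvent_model != first.solvent_model
            ):
                raise ValueError(
                    "all ensemble records must share molecule_id, state, "
                    "method and solvent_model"
                )
        ids = [r.conformer_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("conformer_id must be unique within an ensemble")


def standard_free_energy(record: EnergyRecord, model: FreeEnergyModel) -> float:
    """Assemble G°(X) = ΔH_f + [G°_RRHO] + ΔG°_solv for one conformer.

    Raises
    ------
    RRHOUnavailableError
        If the model includes the RRHO term but the record lacks it.  The
        term is never silently dropped.
    """
    g = record.delta_hf + record.dg_solv
    if model.include_rrho:
        if record.g_rrho is None:
            raise RRHOUnavailableError(
                f"RRHO term unavailable for {record.molecule_id}/"
                f"{record.state.value}/{record.conformer_id} but the model "
                f"{model.label or '(unlabelled)'} requires it"
            )
        g += record.g_rrho
    return g


def select_conformer(
    ensemble: ConformerEnsemble, model: FreeEnergyModel
) -> EnergyRecord:
    """Pick the representative conformer: lowest G°(X) among non-excluded
    records, ties broken by lexicographic conformer_id."""
    candidates = [r for r in ensemble.records if not r.excluded]
    if not candidates:
        raise NoValidConformerError(
            f"no valid conformer for {ensemble.molecule_id}/"
            f"{ensemble.state.value}: all records excluded"
        )
    return min(
        candidates,
        key=lambda r: (standard_free_energy(r, model), r.conformer_id),
    )


def mark_exclusions(records: Sequence[EnergyRecord]) -> list[EnergyRecord]:
    """Apply the imaginary-frequency exclusion rule.

    A record is excluded exactly when it still has imaginary modes at the
    tightest convergence tier.  Imaginary modes at looser tiers are retained
    (re-optimization at a tighter criterion is expected upstream) with a
    logged warning; all other records pass through untouched.
    """
    out = []
    for r in records:
        if r.n_imaginary > 0 and r.convergence_tier is ConvergenceTier.TIGHTEST:
            out.append(replace(r, excluded=True))
        else:
            if r.n_imaginary > 0:
                logger.warning(
                    "record %s/%s/%s has %d imaginary mode(s) at tier %s; "
                    "retained — expect re-optimization at a tighter criterion",
                    r.molecule_id,
                    r.state.value,
                    r.conformer_id,
                    r.n_imaginary,
                    r.convergence_tier.value,
                )
            out.append(r)
    return out
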