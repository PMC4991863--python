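"""End-to-end prediction from an energy table.

Given a canonical energy table holding both protonation forms of the
target(s) and of the reference molecule under one method variant, pick the
lowest-free-energy conformer of each (molecule, form), assemble the
isodesmic reaction free energy and convert it to a pKa.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Mapping, Optional, Sequence

from .constants import STANDARD_TEMPERATURE
from .errors import MissingSpeciesError
from .isodesmic import (
    PkaPrediction,
    ReferenceEntry,
    apply_class_correction,
    isodesmic_delta_g,
    predict_pka,
)
from .qmio import EnergyTable
from .thermo import (
    ConformerEnsemble,
    FreeEnergyModel,
    Method,
    SolventModel,
    State,
    select_conformer,
    standard_free_energy,
)

logger = logging.getLogger(__name__)


def species_free_energies(
    table: EnergyTable,
    method: Method,
    solvent_model: SolventModel,
    model: FreeEnergyModel,
) -> dict[tuple[str, State], float]:
    """Lowest-conformer G°(X) for every (molecule, form) under one variant."""
    grouped: dict[tuple[str, State], list] = defaultdict(list)
    for r in table.rows:
        if r.method is method and r.solvent_model is solvent_model:
            grouped[(r.molecule_id, r.state)].append(r)
    out = {}
    for (mol, state), records in grouped.items():
        ensemble = ConformerEnsemble(molecule_id=mol, state=state, records=tuple(records))
        best = select_conformer(ensemble, model)
        logger.info(
            "selected conformer %s for %s/%s (%s)",
            best.conformer_id,
            mol,
            state.value,
            model.label,
        )
        out[(mol, state)] = standard_free_energy(best, model)
    return out


def predict_from_table(
    table: EnergyTable,
    *,
    method: Method,
    solvent_model: SolventModel,
    include_rrho: bool,
    reference: ReferenceEntry,
    targets: Optional[Sequence[str]] = None,
    corrections: Optional[Mapping] = None,
    temperature: float = STANDARD_TEMPERATURE,
) -> list[PkaPrediction]:
    """Predict pKa for each target molecule against one reference.

    The reference molecule's energies are looked up in the table under
    ``reference.name`` as molecule_id.  With no explicit target list, every
    other molecule in the table (under the requested variant) is predicted.
    """
    model = FreeEnergyModel.from_parts(
        method, solvent_model, include_rrho, temperature=temperature
    )
    energies = species_free_energies(table, method, solvent_model, model)

    def _energy(mol: str, state: State) -> float:
        try:
            return energies[(mol, state)]
        except KeyError:
            raise MissingSpeciesError(mol, state.value) from None

    g_acid_ref = _energy(reference.name, State.ACID)
    g_base_ref = _energy(reference.name, State.BASE)
    if targets is None:
        targets = sorted(
            {mol for (mol, _s) in energies if mol != reference.name}
        ) or [reference.name]
    predictions = []
    for mol in targets:
        dg = isodesmic_delta_g(
            _energy(mol, State.ACID),
            _energy(mol, State.BASE),
            g_acid_ref,
            g_base_ref,
        )
        pred = predict_pka(
            dg,
            reference,
            molecule_id=mol,
            temperature=temperature,
            model_label=model.label,
        )
        if corrections:
            pred = apply_class_correction(pred, corrections)
        logger.info(
            "%s: dG=%+.4f kcal/mol, reference %s (%.1f) -> pKa %.2f",
            mol,
            dg,
            reference.name,
            reference.pka_ref,
            pred.pka,
        )
        predictions.append(pred)
    return predictions
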