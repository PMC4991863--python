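"""Exception hierarchy."""


class IsopkaError(Exception):
    """Base class for all package errors."""


class RRHOUnavailableError(IsopkaError):
    """RRHO term unavailable: a free-energy model requiring the RRHO
    correction was applied to a record whose g_rrho field is absent."""


class NoValidConformerError(IsopkaError):
    """Every conformer in the ensemble is excluded (imaginary modes at the
    tightest convergence tier); no valid representative exists."""


class InconsistentVariantError(IsopkaError):
    """Isodesmic reaction assembled from energies computed under different
    method/solvent model variants."""


class ReferenceLookupError(IsopkaError, KeyError):
    """Requested reference molecule or site class not in the library."""


class InferredReferenceError(ReferenceLookupError):
    """Default reference for this class has inferred provenance and was not
    explicitly confirmed (pass allow_inferred=True)."""


class CalibrationError(IsopkaError):
    """Linear calibration cannot be fit (too few points or degenerate
    predictor variance)."""


class SmilesParseError(IsopkaError):
    """Input SMILES string could not be parsed."""


class EnergyTableError(IsopkaError):
    """Malformed canonical energy table (missing column, duplicate key,
    non-numeric energy, unknown unit)."""


class EngineOutputError(IsopkaError):
    """QM engine output text lacks the expected marker lines."""


class MissingSpeciesError(IsopkaError):
    """Energy table lacks a required (molecule, protonation state) pair."""

    def __init__(self, molecule_id: str, state: str):
        self.molecule_id = molecule_id
        self.state = state
        super().__init__(
            f"energy table has no records for molecule {molecule_id!r} "
            f"in state {state!r}"
        )


class StatisticsError(IsopkaError):
    """Benchmark statistic cannot be computed (length mismatch, too few
    points, degenerate variance)."""
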