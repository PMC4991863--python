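"""Ionizable-site classification and manual start-state enumeration.

Generic conformer searchers treat C–NH2 and C–OH single bonds as
non-rotatable and never invert pyramidal nitrogens, so the corresponding
start geometries must be enumerated explicitly before any conformer search:

* three staggered torsions for every terminal C–NH2 (primary amines, both
  protonation forms) and C–OH bond (alcohols, phenols and carboxylic acids
  in the neutral acid form);
* nitrogen inversion ("up"/"down") for deprotonated secondary amines and
  for tertiary amines in both protonation forms — the combinations where
  the inverted pyramid is a genuinely distinct start state.

Classification works on the molecular graph (RDKit) with simple
deterministic rules: sp3 nitrogens with 1/2/3 heavy neighbours and no
adjacent carbonyl are primary/secondary/tertiary amines; two-coordinate
aromatic ring nitrogens are pyridine-type; O–H groups are phenols on
aromatic carbons, carboxylic acids on carbonyl carbons (benzoic acids when
that carbon bears an aryl substituent) and alcohols otherwise.  Amides and
everything else are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem

from .errors import SmilesParseError
from .isodesmic import SiteClass
from .thermo import State

#: Site classes whose acid form is a cation (proton on nitrogen).
BASIC_CLASSES = frozenset(
    {
        SiteClass.PYRIDINE,
        SiteClass.PRIMARY_AMINE,
        SiteClass.SECONDARY_AMINE,
        SiteClass.TERTIARY_AMINE,
    }
)

#: (class, form) pairs requiring nitrogen-inversion start states.
INVERSION_CASES = frozenset(
    {
        (SiteClass.SECONDARY_AMINE, State.BASE),
        (SiteClass.TERTIARY_AMINE, State.ACID),
        (SiteClass.TERTIARY_AMINE, State.BASE),
    }
)

#: O–H classes whose hydroxyl torsion needs manual start states (acid form).
_OH_ROTOR_CLASSES = frozenset(
    {SiteClass.ALCOHOL, SiteClass.PHENOL, SiteClass.CARBOXYLIC_ACID, SiteClass.BENZOIC_ACID}
)

ROTOR_VARIANTS = ("anti", "gauche+", "gauche-")
INVERSION_VARIANTS = ("up", "down")


class StartStateKind(str, Enum):
    ROTOR = "rotor"
    INVERSION = "inversion"


@dataclass(frozen=True)
class IonizableSite:
    """One ionizable site: an atom of the molecular graph plus its class.

    ``atom_index`` is 0-based over the canonical atom order of the parsed
    molecule (inputs are re-canonicalized, so equivalent SMILES give
    identical indices).
    """

    molecule_id: str
    atom_index: int
    site_class: SiteClass
    acid_form_charge: int
    base_form_charge: int

    def __post_init__(self) -> None:
        if self.acid_form_charge != self.base_form_charge + 1:
            raise ValueError(
                "acid form must carry exactly one more positive charge "
                "than the base form"
            )


@dataclass(frozen=True)
class StartStateDescriptor:
    """One manually prepared start geometry variant.

    For rotors ``atom_indices`` holds the site heteroatom; the rotated bond
    is the one to its unique heavy neighbour.  For inversions it holds the
    nitrogen centre.
    """

    kind: StartStateKind
    atom_indices: tuple[int, ...]
    variant_label: str

    def __post_init__(self) -> None:
        if len(self.atom_indices) != 1:
            raise ValueError(
                "descriptor must name a single rotatable-bond heteroatom "
                "or a single inversion centre"
            )


def _canonical_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    # round-trip through canonical SMILES so atom indices are input-order
    # independent
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def _has_adjacent_carbonyl(atom: Chem.Atom) -> bool:
    for nbr in atom.GetNeighbors():
        if nbr.GetSymbol() != "C":
            continue
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if (
                bond.GetBondType() == Chem.BondType.DOUBLE
                and other.GetSymbol() == "O"
            ):
                return True
    return False


def _classify_nitrogen(atom: Chem.Atom) -> Optional[SiteClass]:
    if atom.GetFormalCharge() != 0:
        return None
    if atom.GetIsAromatic():
        ring_bonds = sum(1 for b in atom.GetBonds() if b.IsInRing())
        if ring_bonds == 2 and atom.GetDegree() == 2 and atom.GetTotalNumHs() == 0:
            return SiteClass.PYRIDINE
        return None
    if atom.GetHybridization() != Chem.HybridizationType.SP3:
        return None
    if _has_adjacent_carbonyl(atom):
        return None  # amide-like, not basic
    heavy = atom.GetDegree()
    return {
        1: SiteClass.PRIMARY_AMINE,
        2: SiteClass.SECONDARY_AMINE,
        3: SiteClass.TERTIARY_AMINE,
    }.get(heavy)


def _classify_hydroxyl(atom: Chem.Atom) -> Optional[SiteClass]:
    if (
        atom.GetFormalCharge() != 0
        or atom.GetTotalNumHs() < 1
        or atom.GetDegree() != 1
    ):
        return None
    carbon = atom.GetNeighbors()[0]
    if carbon.GetSymbol() != "C":
        return None
    if carbon.GetIsAromatic():
        return SiteClass.PHENOL
    carbonyl = any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(carbon).GetSymbol() == "O"
        for b in carbon.GetBonds()
    )
    if carbonyl:
        aryl = any(n.GetIsAromatic() for n in carbon.GetNeighbors())
        return SiteClass.BENZOIC_ACID if aryl else SiteClass.CARBOXYLIC_ACID
    return SiteClass.ALCOHOL


def classify_sites(smiles: str, molecule_id: str = "") -> list[IonizableSite]:
    """Classify every recognizable ionizable site of a molecule.

    Returns sites in ascending canonical atom index; unrecognized groups
    (amides, ethers, thiols, ...) are silently skipped.
    """
    mol = _canonical_mol(smiles)
    molecule_id = molecule_id or Chem.MolToSmiles(mol)
    sites = []
    for atom in mol.GetAtoms():
        cls: Optional[SiteClass] = None
        if atom.GetSymbol() == "N":
            cls = _classify_nitrogen(atom)
        elif atom.GetSymbol() == "O":
            cls = _classify_hydroxyl(atom)
        if cls is None:
            continue
        if cls in BASIC_CLASSES:
            acid_q, base_q = 1, 0
        else:
            acid_q, base_q = 0, -1
        sites.append(
            IonizableSite(
                molecule_id=molecule_id,
                atom_index=atom.GetIdx(),
                site_class=cls,
                acid_form_charge=acid_q,
                base_form_charge=base_q,
            )
        )
    return sites


def required_start_states(
    site: IonizableSite, form: State
) -> list[StartStateDescriptor]:
    """Manual start states needed for one (site, protonation form).

    Inversion descriptors appear exactly for deprotonated secondary amines
    and protonated/deprotonated tertiary amines; three staggered rotor
    variants appear for every C–NH2 bond (primary amines, both forms — the
    protonated form is torsionally near-symmetric but is enumerated
    uniformly) and for C–OH bonds in the neutral acid form.
    """
    out: list[StartStateDescriptor] = []
    if site.site_class is SiteClass.PRIMARY_AMINE or (
        site.site_class in _OH_ROTOR_CLASSES and form is State.ACID
    ):
        out.extend(
            StartStateDescriptor(StartStateKind.ROTOR, (site.atom_index,), lbl)
            for lbl in ROTOR_VARIANTS
        )
    if (site.site_class, form) in INVERSION_CASES:
        out.extend(
            StartStateDescriptor(StartStateKind.INVERSION, (site.atom_index,), lbl)
            for lbl in INVERSION_VARIANTS
        )
    return out


def job_manifest(
    sites: Sequence[IonizableSite],
    forms: Iterable[State] = (State.ACID, State.BASE),
    include_defaults: bool = True,
) -> pd.DataFrame:
    """Work list for an external conformer generator / QM engine.

    One row per required start state of each (site, form).  A (site, form)
    with no manual variants contributes a single ``default`` row when
    ``include_defaults`` is true, and nothing otherwise (useful to list
    only the geometries that must be hand-prepared).  Ordering is
    deterministic: molecule, atom index, acid before base, emission order
    of variants.
    """
    forms = tuple(forms)
    rows = []
    for site in sorted(sites, key=lambda s: (s.molecule_id, s.atom_index)):
        for form in sorted(forms, key=lambda f: f.value):
            descriptors = required_start_states(site, form)
            if not descriptors and include_defaults:
                rows.append(
                    (site.molecule_id, site.atom_index, site.site_class.value,
                     form.value, "default", "default")
                )
            for d in descriptors:
                rows.append(
                    (site.molecule_id, site.atom_index, site.site_class.value,
                     form.value, d.kind.value, d.variant_label)
                )
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "atom_index", "site_class", "state", "kind",
                 "variant_label"],
    )


def protonation_smiles(smiles: str, site: IonizableSite, form: State) -> str:
    """SMILES of the molecule with the site set to the requested form.

    The edit is a formal charge / explicit H-count change at the site atom
    only; stereo descriptors elsewhere are preserved.
    """
    mol = Chem.RWMol(_canonical_mol(smiles))
    atom = mol.GetAtomWithIdx(site.atom_index)
    target_charge = site.acid_form_charge if form is State.ACID else site.base_form_charge
    delta_h = target_charge - atom.GetFormalCharge()
    atom.SetFormalCharge(target_charge)
    atom.SetNumExplicitHs(max(0, atom.GetTotalNumHs() + delta_h))
    atom.SetNoImplicit(True)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)
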