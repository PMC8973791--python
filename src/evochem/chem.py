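"""Shared low-level chemistry helpers built on RDKit."""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

# RDKit is chatty about kekulization/valence during speculative product
# sanitization; failures are handled explicitly where they matter.
RDLogger.DisableLog("rdApp.*")


class ChemistryError(ValueError):
    """Raised when a SMILES/SMARTS input cannot be interpreted."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`ChemistryError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles_or_mol, strip_stereo: bool = True) -> str:
    """Canonical SMILES of a molecule or SMILES string.

    Stereo descriptors are stripped by default: generated structures are
    deduplicated on constitution only, and stereo enumeration is deferred to
    downstream 3D preparation.
    """
    if isinstance(smiles_or_mol, Chem.Mol):
        mol = smiles_or_mol
    else:
        mol = mol_from_smiles(smiles_or_mol)
    if strip_stereo:
        mol = Chem.Mol(mol)
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    return mol_from_smiles(smiles).GetNumHeavyAtoms()


def sanitize_product(mol: Chem.Mol) -> tuple[str, int] | None:
    """Sanitize a raw reaction product; return (canonical SMILES, n_heavy) or None.

    Products with broken valences (a routine outcome of speculative SMARTS
    application) are silently rejected.
    """
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    smi = Chem.MolToSmiles(mol)
    # round-trip: RunReactants can emit mols whose SMILES re-parse fails
    rt = Chem.MolFromSmiles(smi)
    if rt is None:
        return None
    Chem.RemoveStereochemistry(rt)
    return Chem.MolToSmiles(rt), rt.GetNumHeavyAtoms()


def aromatic_ring_count(mol: Chem.Mol) -> int:
    ri = mol.GetRingInfo()
    n = 0
    for ring in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n += 1
    return n


def hba_count(mol: Chem.Mol) -> int:
    return rdMolDescriptors.CalcNumHBA(mol)
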