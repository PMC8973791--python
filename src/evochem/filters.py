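"""Property, ring-system, and substructure filters gating generated molecules.

Default bounds (the shipped configuration): MW in [81, 450] Da, LogP in
[0, 5], HBD <= 5, HBA <= 10, rotatable bonds <= 4 (by a custom SMARTS that
excludes bonds between two pi systems, which tend to lock into conjugated
rotamers), TPSA <= 200 A^2; ring systems <= 4, <= 3 rings per polycyclic
system, ring size <= 7, fused <= 3, bridged <= 1, spiro <= 1.  Substructure
gates reject sulfur/phosphorus and a small structure-alert set, cap
carboxylic acids and alkynes at one each, and apply the published PAINS
catalogue.  Filters are deliberately project-tunable; these defaults target
fragment-to-lead growing campaigns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from evochem.chem import mol_from_smiles

# Custom rotatable-bond SMARTS: first atom must be a non-terminal sp3 carbon
# (not CF3); the partner must not be halogen, a methyl-like H3 atom, terminal,
# triple-bonded, or CF3-like.  Strictly more restrictive than the classic
# definition on the first atom.
ROTATABLE_BOND_SMARTS = (
    "[C^3!D1;!$(C(F)(F)F)]-!@"
    "[!Br!F!Cl!I!H3&!$(*#*)!D1;!$([!Br!F!Cl!I](F)(F)F)]"
)
_ROT_PATTERN = Chem.MolFromSmarts(ROTATABLE_BOND_SMARTS)


@dataclass
class PropertyFilterConfig:
    mw_min: float = 81.0
    mw_max: float = 450.0
    logp_min: float = 0.0
    logp_max: float = 5.0
    hbd_max: int = 5
    hba_max: int = 10
    rb_max: int = 4
    tpsa_max: float = 200.0

    def __post_init__(self):
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if not self.logp_min < self.logp_max:
            raise ValueError("logp_min must be < logp_max")
        for name in ("hbd_max", "hba_max", "rb_max", "tpsa_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RingFilterConfig:
    max_ring_systems: int = 4
    max_rings_per_system: int = 3
    max_ring_size: int = 7
    max_fused: int = 3
    max_bridged: int = 1
    max_spiro: int = 1

    def __post_init__(self):
        for f_ in self.__dataclass_fields__:
            if getattr(self, f_) < 0:
                raise ValueError(f"{f_} must be >= 0")


#: Identity patterns: a single match rejects the molecule.
DEFAULT_IDENTITY_PATTERNS = [
    ("sulfur", "[#16]"),
    ("phosphorus", "[#15]"),
    ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    ("aldehyde", "[CX3H1]=O"),
    ("michael_acceptor", "[CX3]=[CX3][CX3]=[OX1]"),
]

#: Count patterns: more than max_count matches rejects.
DEFAULT_COUNT_PATTERNS = [
    ("carboxylic_acid", "[CX3](=O)[OX2H1]", 1),
    ("alkyne", "[CX2]#[CX2]", 1),
]


@dataclass
class SubstructureFilterConfig:
    identity_patterns: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_IDENTITY_PATTERNS)
    )
    count_patterns: list[tuple[str, str, int]] = field(
        default_factory=lambda: list(DEFAULT_COUNT_PATTERNS)
    )
    pains_enabled: bool = True

    def __post_init__(self):
        for name, smarts in self.identity_patterns:
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"identity pattern {name!r} does not parse")
        for name, smarts, _ in self.count_patterns:
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"count pattern {name!r} does not parse")


@dataclass
class FilterConfig:
    """The full filter cascade configuration."""

    properties: PropertyFilterConfig = field(default_factory=PropertyFilterConfig)
    rings: RingFilterConfig = field(default_factory=RingFilterConfig)
    substructures: SubstructureFilterConfig = field(
        default_factory=SubstructureFilterConfig
    )


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed iff reasons empty")


class PropertyVector(NamedTuple):
    mw: float
    logp: float
    hbd: int
    hba: int
    rb_custom: int
    tpsa: float
    fsp3: float


def count_rotatable_bonds_custom(smiles: str) -> int:
    """Rotatable bonds by the custom pi-system-aware SMARTS definition.

    Symmetric duplicate matches of the same bond are counted once.
    """
    mol = mol_from_smiles(smiles)
    bonds = {
        tuple(sorted(match))
        for match in mol.GetSubstructMatches(_ROT_PATTERN, uniquify=False)
    }
    return len(bonds)


def compute_properties(smiles: str) -> PropertyVector:
    """Descriptor vector: MW (Da), LogP, HBD, HBA, custom RB, TPSA (A^2), Fsp3."""
    mol = mol_from_smiles(smiles)
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rb_custom=count_rotatable_bonds_custom(smiles),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        fsp3=rdMolDescriptors.CalcFractionCSP3(mol),
    )


class RingSystemStats(NamedTuple):
    n_ring_systems: int
    max_rings_in_system: int
    max_ring_size: int
    n_fused_rings: int
    n_bridged: int
    n_spiro: int


def ring_system_stats(smiles: str) -> RingSystemStats:
    """Ring bookkeeping on the smallest set of smallest rings.

    A ring system is a connected component of the ring-bond graph (rings
    sharing at least one atom merge; biphenyl's rings stay separate).  The
    fused count is the number of rings in the largest system sharing an edge
    with another ring of that system.  Bridged systems are counted as
    bridgehead-atom pairs; spiro as spiro atoms.
    """
    mol = mol_from_smiles(smiles)
    ri = mol.GetRingInfo()
    atom_rings = [frozenset(r) for r in ri.AtomRings()]
    bond_rings = [frozenset(r) for r in ri.BondRings()]
    if not atom_rings:
        return RingSystemStats(0, 0, 0, 0, 0, 0)

    # union-find over rings sharing atoms
    parent = list(range(len(atom_rings)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(atom_rings)):
        for j in range(i + 1, len(atom_rings)):
            if atom_rings[i] & atom_rings[j]:
                parent[find(i)] = find(j)

    systems: dict[int, list[int]] = {}
    for i in range(len(atom_rings)):
        systems.setdefault(find(i), []).append(i)

    sizes = [len(members) for members in systems.values()]
    largest = max(systems.values(), key=len)
    fused = sum(
        1
        for i in largest
        if any(bond_rings[i] & bond_rings[j] for j in largest if j != i)
    )
    return RingSystemStats(
        n_ring_systems=len(systems),
        max_rings_in_system=max(sizes),
        max_ring_size=max(len(r) for r in atom_rings),
        n_fused_rings=fused,
        n_bridged=rdMolDescriptors.CalcNumBridgeheadAtoms(mol) // 2,
        n_spiro=rdMolDescriptors.CalcNumSpiroAtoms(mol),
    )


@lru_cache(maxsize=512)
def _compiled(smarts: str):
    return Chem.MolFromSmarts(smarts)


_PAINS_CATALOG = None


def _pains_catalog():
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog(params)
    return _PAINS_CATALOG


_VERDICT_CACHE: dict[tuple[str, str], FilterVerdict] = {}


def passes_filters(smiles: str, config: FilterConfig | None = None) -> FilterVerdict:
    """Run the full cascade; every violated bound is reported (no short-circuit).

    Verdicts are memoized on (canonical input string, config repr): the
    cascade is a pure function of both.
    """
    if config is None:
        config = FilterConfig()
    cache_key = (smiles, repr(config))
    cached = _VERDICT_CACHE.get(cache_key)
    if cached is not None:
        return cached
    mol = mol_from_smiles(smiles)
    reasons: list[str] = []

    p = compute_properties(smiles)
    pc = config.properties
    if p.mw < pc.mw_min:
        reasons.append("MW_LOW")
    if p.mw > pc.mw_max:
        reasons.append("MW_HIGH")
    if p.logp < pc.logp_min:
        reasons.append("LOGP_LOW")
    if p.logp > pc.logp_max:
        reasons.append("LOGP_HIGH")
    if p.hbd > pc.hbd_max:
        reasons.append("HBD_HIGH")
    if p.hba > pc.hba_max:
        reasons.append("HBA_HIGH")
    if p.rb_custom > pc.rb_max:
        reasons.append("RB_HIGH")
    if p.tpsa > pc.tpsa_max:
        reasons.append("TPSA_HIGH")

    r = ring_system_stats(smiles)
    rc = config.rings
    if r.n_ring_systems > rc.max_ring_systems:
        reasons.append("RINGSYS_HIGH")
    if r.max_rings_in_system > rc.max_rings_per_system:
        reasons.append("RINGS_PER_SYS_HIGH")
    if r.max_ring_size > rc.max_ring_size:
        reasons.append("RINGSIZE_HIGH")
    if r.n_fused_rings > rc.max_fused:
        reasons.append("FUSED_HIGH")
    if r.n_bridged > rc.max_bridged:
        reasons.append("BRIDGED_HIGH")
    if r.n_spiro > rc.max_spiro:
        reasons.append("SPIRO_HIGH")

    sc = config.substructures
    for name, smarts in sc.identity_patterns:
        if mol.HasSubstructMatch(_compiled(smarts)):
            reasons.append(f"IDENTITY:{name}")
    for name, smarts, max_count in sc.count_patterns:
        n = len(mol.GetSubstructMatches(_compiled(smarts)))
        if n > max_count:
            reasons.append(f"COUNT:{name}")
    if sc.pains_enabled:
        entry = _pains_catalog().GetFirstMatch(mol)
        if entry is not None:
            reasons.append(f"PAINS:{entry.GetDescription()}")

    verdict = FilterVerdict(passed=not reasons, reasons=tuple(reasons))
    if len(_VERDICT_CACHE) < 500_000:
        _VERDICT_CACHE[cache_key] = verdict
    return verdict
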