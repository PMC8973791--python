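"""Transformation rules and the rule-based molecular generator.

Rules are reaction-like SMARTS records in four categories:

* ``grow`` — a replaceable hydrogen position (expressed as a heavy-atom
  environment with an H-count constraint) gains a new atom, group, or ring;
* ``mutate`` — atom replacement, insertion/deletion, ring edits,
  aromatic/aliphatic exchange;
* ``bioisostere`` — classical isosteric group swaps;
* ``reaction`` — a virtual one-step organic reaction between the seed and a
  commercial building block (two reactant templates).

Applying an enabled rule to a seed enumerates every symmetry-distinct site,
sanitizes the products, and deduplicates them on stereo-stripped canonical
SMILES.  Lineage (parent id + rule id) is recorded on every child.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

from evochem.chem import (
    ChemistryError,
    canonical_smiles,
    mol_from_smiles,
    sanitize_product,
)

logger = logging.getLogger(__name__)

RULE_CATEGORIES = ("grow", "mutate", "bioisostere", "reaction")

#: Hard cap on products per (seed, rule) application; reaction rules crossed
#: with large building-block libraries explode combinatorially.
MAX_PRODUCTS_PER_RULE = 1000


class RuleError(ValueError):
    """Raised for fatally malformed rule inputs."""


@dataclass(frozen=True)
class TransformationRule:
    """One reaction-like SMARTS transformation.

    The pattern must parse as reaction SMARTS with >= 1 reactant template and
    exactly one product template; category ``reaction`` iff it declares two
    reactant templates (seed + building block).
    """

    rule_id: str
    category: str
    pattern: str
    description: str = ""
    enabled: bool = True

    def __post_init__(self):
        if self.category not in RULE_CATEGORIES:
            raise RuleError(
                f"rule {self.rule_id}: unknown category {self.category!r}"
            )
        rxn = _parse_reaction(self.pattern)
        if rxn is None:
            raise RuleError(f"rule {self.rule_id}: unparsable SMARTS {self.pattern!r}")
        n_react = rxn.GetNumReactantTemplates()
        if rxn.GetNumProductTemplates() != 1 or n_react < 1:
            raise RuleError(
                f"rule {self.rule_id}: need >=1 reactant and exactly 1 product "
                f"template, got {n_react}>>{rxn.GetNumProductTemplates()}"
            )
        if (self.category == "reaction") != (n_react == 2):
            raise RuleError(
                f"rule {self.rule_id}: category 'reaction' requires exactly 2 "
                f"reactant templates (found {n_react})"
            )

    @property
    def reaction(self) -> AllChem.ChemicalReaction:
        return _parse_reaction(self.pattern)


def _parse_reaction(pattern: str):
    # "⌃" is a typographic variant of the caret hybridization primitive
    pattern = pattern.replace("⌃", "^")
    try:
        rxn = AllChem.ReactionFromSmarts(pattern)
    except Exception:
        return None
    return rxn


@dataclass
class RuleSet:
    """An ordered rule collection plus the building blocks reaction rules use."""

    rules: list[TransformationRule] = field(default_factory=list)
    building_blocks: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise RuleError("duplicate rule_ids in RuleSet")
        self.building_blocks = [canonical_smiles(b) for b in self.building_blocks]

    def enabled_rules(self) -> list[TransformationRule]:
        return [r for r in self.rules if r.enabled]

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class MoleculeRecord:
    """A generated structure with lineage annotation.

    ``generation`` 0 marks campaign seeds (``parent_id`` is then None);
    children carry the id of the parent they grew from and the rule that
    produced them.  Naming follows ``GEN_<g>_M_<serial>``.
    """

    mol_id: str
    smiles: str
    generation: int
    parent_id: str | None = None
    rule_id: str | None = None
    n_heavy: int = 0

    def __post_init__(self):
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if (self.generation == 0) != (self.parent_id is None):
            raise ValueError("generation 0 iff parent_id is None")
        if self.n_heavy == 0:
            # normalize: canonicalize and count heavy atoms
            canon = canonical_smiles(self.smiles)
            if canon != self.smiles:
                object.__setattr__(self, "smiles", canon)
            object.__setattr__(
                self, "n_heavy", mol_from_smiles(self.smiles).GetNumHeavyAtoms()
            )
        # a caller supplying n_heavy asserts that smiles is already canonical
        # and the count correct (the generator's sanitized-product fast path)


def make_record(
    smiles: str, generation: int, serial: int, parent_id=None, rule_id=None
) -> MoleculeRecord:
    """Build a MoleculeRecord with the GEN_<g>_M_<serial> naming convention."""
    return MoleculeRecord(
        mol_id=f"GEN_{generation}_M_{serial:06d}",
        smiles=canonical_smiles(smiles),
        generation=generation,
        parent_id=parent_id,
        rule_id=rule_id,
    )


# ---------------------------------------------------------------------------
# Loading


def _rows_from_tsv(path: Path):
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("rule_id", "category", "smarts"):
            if name not in idx:
                raise RuleError(f"{path}: missing column {name!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            yield {
                "rule_id": parts[idx["rule_id"]],
                "category": parts[idx["category"]],
                "smarts": parts[idx["smarts"]],
                "description": parts[idx["description"]]
                if "description" in idx and len(parts) > idx["description"]
                else "",
                "enabled": True,
            }


def _rows_from_sqlite(path: Path):
    con = sqlite3.connect(path)
    try:
        cur = con.execute(
            "SELECT rule_id, category, smarts, description, enabled FROM rules"
        )
        for rule_id, category, smarts, description, enabled in cur:
            yield {
                "rule_id": rule_id,
                "category": category,
                "smarts": smarts,
                "description": description or "",
                "enabled": bool(enabled),
            }
    finally:
        con.close()


def load_rules(
    source: str | Path, building_blocks: str | Path | Sequence[str] | None = None
) -> RuleSet:
    """Load a rule table from TSV or SQLite into a :class:`RuleSet`.

    Malformed rows are skipped with a warning naming the rule_id; a source
    with zero valid rules is fatal.  ``building_blocks`` may be a path to a
    SMILES list (one per line, optional tab-separated id) or an in-memory
    sequence of SMILES.
    """
    source = Path(source)
    if not source.exists():
        raise RuleError(f"rule source not found: {source}")
    rows = (
        _rows_from_sqlite(source)
        if source.suffix in (".db", ".sqlite", ".sqlite3")
        else _rows_from_tsv(source)
    )
    rules: list[TransformationRule] = []
    for row in rows:
        try:
            rules.append(
                TransformationRule(
                    rule_id=row["rule_id"],
                    category=row["category"],
                    pattern=row["smarts"],
                    description=row["description"],
                    enabled=row["enabled"],
                )
            )
        except RuleError as exc:
            logger.warning("skipping malformed rule %s: %s", row.get("rule_id"), exc)
    if not rules:
        raise RuleError(f"no valid rules in {source}")

    blocks: list[str] = []
    if building_blocks is not None:
        if isinstance(building_blocks, (str, Path)):
            with open(building_blocks, encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        blocks.append(line.split("\t")[0])
        else:
            blocks = list(building_blocks)
    return RuleSet(rules=rules, building_blocks=blocks)


def demo_rule_pack() -> RuleSet:
    """The bundled demonstration rule pack (~10 rules per category)."""
    data_dir = Path(__file__).parent / "data"
    return load_rules(data_dir / "demo_rules.tsv", data_dir / "building_blocks.smi")


# ---------------------------------------------------------------------------
# Application


def apply_rule(
    seed: MoleculeRecord | str,
    rule: TransformationRule,
    blocks: Iterable[str] = (),
) -> set[str]:
    """Apply one rule to one seed; return the deduplicated product SMILES set.

    Every symmetry-distinct application site is enumerated (symmetric sites
    collapse under canonicalization).  Products failing valence sanitization
    are dropped.  A rule whose template matches nothing yields an empty set.
    """
    return set(_apply_rule_counted(seed, rule, blocks))


def _apply_rule_counted(
    seed: MoleculeRecord | str,
    rule: TransformationRule,
    blocks: Iterable[str] = (),
) -> dict[str, int]:
    """apply_rule keeping each product's heavy-atom count (generator fast path)."""
    smiles = seed.smiles if isinstance(seed, MoleculeRecord) else seed
    mol = mol_from_smiles(smiles)
    rxn = rule.reaction

    if rule.category == "reaction":
        blocks = list(blocks)
        if not blocks:
            raise RuleError(
                f"rule {rule.rule_id} is a reaction rule but no building blocks given"
            )
        reactant_sets = []
        for b in blocks:
            bmol = Chem.MolFromSmiles(b)
            if bmol is not None:
                reactant_sets.append((mol, bmol))
    else:
        reactant_sets = [(mol,)]

    products: dict[str, int] = {}
    for reactants in reactant_sets:
        try:
            outcomes = rxn.RunReactants(reactants)
        except Exception:
            continue
        for outcome in outcomes:
            res = sanitize_product(outcome[0])
            if res is not None and res[0]:
                products[res[0]] = res[1]
            if len(products) >= MAX_PRODUCTS_PER_RULE:
                logger.warning(
                    "rule %s on %s truncated at %d products",
                    rule.rule_id,
                    smiles,
                    MAX_PRODUCTS_PER_RULE,
                )
                return products
    return products


def generate_children(
    seeds: Sequence[MoleculeRecord],
    ruleset: RuleSet,
    gen: int,
    known_smiles: set[str] | None = None,
) -> list[MoleculeRecord]:
    """One generation step: apply every enabled rule to every seed.

    Children are globally deduplicated by canonical SMILES with first-seen
    lineage retained; any child identical to a structure already in
    ``known_smiles`` (the campaign lineage store, including the seeds
    themselves) is dropped.
    """
    if gen < 1:
        raise ValueError("gen must be >= 1")
    if not seeds:
        raise ValueError("seeds must be non-empty")
    seen = set(known_smiles) if known_smiles is not None else set()
    seen.update(s.smiles for s in seeds)

    children: list[MoleculeRecord] = []
    serial = 1
    for seed in seeds:
        for rule in ruleset.enabled_rules():
            try:
                prods = _apply_rule_counted(seed, rule, ruleset.building_blocks)
            except (RuleError, ChemistryError):
                continue
            for smi in sorted(prods):
                if smi in seen:
                    continue
                seen.add(smi)
                children.append(
                    MoleculeRecord(
                        mol_id=f"GEN_{gen}_M_{serial:06d}",
                        smiles=smi,
                        generation=gen,
                        parent_id=seed.mol_id,
                        rule_id=rule.rule_id,
                        n_heavy=prods[smi],
                    )
                )
                serial += 1
    return children


# ---------------------------------------------------------------------------
# Input variant enumeration


def enumerate_variants(
    smiles: str, tautomers: bool = False, spiro: bool = False
) -> set[str]:
    """Enumerate input variants: tautomers and/or spiro-center configurations.

    Always contains at least the canonical input.  Tautomers come from the
    standard RDKit tautomer enumerator.  With ``spiro`` on, unassigned
    stereocenters sitting on spiro atoms are expanded into both
    configurations (other stereocenters are left untouched).
    """
    mol = mol_from_smiles(smiles)
    out = {canonical_smiles(mol, strip_stereo=False)}
    if tautomers:
        enumerator = rdMolStandardize.TautomerEnumerator()
        for taut in enumerator.Enumerate(mol):
            out.add(Chem.MolToSmiles(taut))
    if spiro:
        out |= _spiro_configurations(mol)
    return out


def _spiro_configurations(mol: Chem.Mol) -> set[str]:
    from rdkit.Chem import rdMolDescriptors
    from rdkit.Chem.EnumerateStereoisomers import (
        EnumerateStereoisomers,
        StereoEnumerationOptions,
    )

    if rdMolDescriptors.CalcNumSpiroAtoms(mol) == 0:
        return set()
    ri = mol.GetRingInfo()
    spiro_atoms = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if ri.NumAtomRings(a.GetIdx()) >= 2
        and sum(
            len(set(r1) & set(r2)) == 1
            for r1 in ri.AtomRings()
            for r2 in ri.AtomRings()
            if r1 != r2 and a.GetIdx() in r1 and a.GetIdx() in r2
        )
    }
    opts = StereoEnumerationOptions(onlyUnassigned=True, maxIsomers=32)
    out = set()
    for iso in EnumerateStereoisomers(mol, options=opts):
        # keep only configurations that differ at spiro atoms
        for a in iso.GetAtoms():
            if a.GetIdx() in spiro_atoms and a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
                out.add(Chem.MolToSmiles(iso))
                break
    return out
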