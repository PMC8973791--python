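"""Exhaustive enumeration of small fragments as campaign starting points.

The enumeration follows a string-pipeline strategy: a linear carbon chain of
each heavy-atom count is the starting point; the chain is rearranged and
ring-closed into the complete set of carbon skeletons (connected graphs,
degree <= 4); each skeleton is then transformed by unsaturation/aromatization
and heteroatom substitution over an element alphabet; finally the same filter
cascade used on generated molecules (with fragment MW bounds, default
[50, 210] Da) gates what is emitted to an SQLite fragment store.

Hyperstrained skeletons — two rings of size <= 4 sharing an atom (fused or
spiro cyclopropane/cyclobutane pairs, propellanes, tetrahedrane-like cages) —
are excluded as synthetically unreasonable fragment cores.

Counts are implementation-defined (they depend on the transform and validity
rules above); the published multi-hundred-million-fragment scale requires a
cluster run of the same pipeline and is intentionally out of desk scope.
"""

from __future__ import annotations

import itertools
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from rdkit import Chem
from rdkit.Chem import Descriptors

from evochem.chem import mol_from_smiles
from evochem.filters import FilterConfig, PropertyFilterConfig, passes_filters

#: Maximum valence per element in the fragment alphabet.
ELEMENT_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}


@dataclass
class FragmentEnumConfig:
    max_heavy_atoms: int = 12
    mw_min: float = 50.0
    mw_max: float = 210.0
    element_alphabet: tuple[str, ...] = ("C", "N", "O", "F")
    emit_db: str | Path | None = None

    def __post_init__(self):
        if not 1 <= self.max_heavy_atoms <= 12:
            raise ValueError("max_heavy_atoms must be in [1, 12]")
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        for el in self.element_alphabet:
            if el not in ELEMENT_VALENCE:
                raise ValueError(f"unsupported element {el!r}")

    def filter_config(self) -> FilterConfig:
        cfg = FilterConfig()
        cfg.properties = PropertyFilterConfig(mw_min=self.mw_min, mw_max=self.mw_max)
        return cfg


def carbon_chain(n: int) -> str:
    """Linear alkane SMILES of n carbons (the enumeration starting string)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return "C" * n


# ---------------------------------------------------------------------------
# Skeleton enumeration


def _mol_from_graph(n: int, edges, elements=None, orders=None) -> Chem.Mol | None:
    mol = Chem.RWMol()
    for i in range(n):
        mol.AddAtom(Chem.Atom(elements[i] if elements else "C"))
    bond_types = {
        1: Chem.BondType.SINGLE,
        2: Chem.BondType.DOUBLE,
        3: Chem.BondType.TRIPLE,
    }
    for k, (u, v) in enumerate(edges):
        mol.AddBond(u, v, bond_types[orders[k] if orders else 1])
    m = mol.GetMol()
    try:
        Chem.SanitizeMol(m)
    except Exception:
        return None
    return m


def _adjacency(mol: Chem.Mol):
    n = mol.GetNumAtoms()
    adj = [set() for _ in range(n)]
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
    return adj


def _small_cycles(adj) -> list[frozenset[int]]:
    """All simple cycles of length 3 or 4, as atom sets."""
    n = len(adj)
    cycles = set()
    for i in range(n):
        for j in adj[i]:
            for k in adj[j]:
                if k > i and k != i and i in adj[k] and j > i:
                    cycles.add(frozenset((i, j, k)))
    for i in range(n):
        for j in adj[i]:
            for k in adj[j]:
                if k == i:
                    continue
                for l_ in adj[k]:
                    if l_ != j and l_ != i and i in adj[l_]:
                        cyc = frozenset((i, j, k, l_))
                        if len(cyc) == 4:
                            cycles.add(cyc)
    return list(cycles)


def is_hyperstrained(adj) -> bool:
    """True when two distinct rings of size <= 4 share at least one atom."""
    cycles = _small_cycles(adj)
    for a, b in itertools.combinations(cycles, 2):
        if a & b:
            return True
    return False


def ring_closures(chain: str) -> set[str]:
    """All valid carbon skeletons on the chain's atom count.

    Closure of the linear chain under two string/graph rearrangement moves —
    re-attaching a terminal carbon elsewhere (branch rearrangement) and
    bonding two distant carbons (ring closing) — explored to fixpoint with
    canonical-SMILES deduplication.  Every connected carbon graph with
    degree <= 4 is reachable this way; hyperstrained skeletons are dropped.
    """
    start = mol_from_smiles(chain)
    if any(a.GetSymbol() != "C" for a in start.GetAtoms()):
        raise ValueError("chain must be a linear alkane")
    n = start.GetNumAtoms()
    if n == 1:
        return {"C"}

    def neighbors_key(mol):
        return Chem.MolToSmiles(mol)

    seen = {neighbors_key(start)}
    frontier = [start]
    out: set[str] = set()
    while frontier:
        mol = frontier.pop()
        adj = _adjacency(mol)
        if not is_hyperstrained(adj):
            out.add(Chem.MolToSmiles(mol))
        candidates = []
        # branch rearrangement: move a leaf atom to another attachment point
        for a in range(n):
            if len(adj[a]) != 1:
                continue
            (nb,) = adj[a]
            for b in range(n):
                if b in (a, nb) or len(adj[b]) >= 4:
                    continue
                rw = Chem.RWMol(mol)
                rw.RemoveBond(a, nb)
                rw.AddBond(a, b, Chem.BondType.SINGLE)
                candidates.append(rw.GetMol())
        # ring closing: bond two non-adjacent atoms with spare valence
        for a in range(n):
            for b in range(a + 1, n):
                if b in adj[a] or len(adj[a]) >= 4 or len(adj[b]) >= 4:
                    continue
                rw = Chem.RWMol(mol)
                rw.AddBond(a, b, Chem.BondType.SINGLE)
                candidates.append(rw.GetMol())
        for cand in candidates:
            try:
                Chem.SanitizeMol(cand)
            except Exception:
                continue
            key = neighbors_key(cand)
            if key not in seen:
                seen.add(key)
                # prune hyperstrained states: adding edges only adds cycles,
                # and leaf moves act on trees, so no valid skeleton is lost
                if not is_hyperstrained(_adjacency(cand)):
                    frontier.append(cand)
    return out


# ---------------------------------------------------------------------------
# Structure transforms


def _bond_order_assignments(n: int, edges, max_val=4) -> Iterator[tuple[int, ...]]:
    """All per-edge order assignments (1-3) keeping atom order sums <= max_val."""
    degree_sum = [0] * n

    def rec(k, acc):
        if k == len(edges):
            yield tuple(acc)
            return
        u, v = edges[k]
        for order in (1, 2, 3):
            if degree_sum[u] + order <= max_val and degree_sum[v] + order <= max_val:
                degree_sum[u] += order
                degree_sum[v] += order
                acc.append(order)
                yield from rec(k + 1, acc)
                acc.pop()
                degree_sum[u] -= order
                degree_sum[v] -= order

    yield from rec(0, [])


def skeleton_transforms(skeleton: str, config: FragmentEnumConfig) -> set[str]:
    """Unsaturation/aromatization then heteroatom substitution on one skeleton.

    Bond orders 1-3 are enumerated under valence constraints (aromatic rings
    emerge from alternating assignments at sanitization); every atom is then
    substituted over the element alphabet subject to each element's maximum
    valence.  Output is sanitized, canonical, and deduplicated; it always
    contains the saturated all-carbon input itself.
    """
    mol = mol_from_smiles(skeleton)
    n = mol.GetNumAtoms()
    edges = [
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    ]
    out: set[str] = set()
    alphabet = tuple(config.element_alphabet)
    for orders in _bond_order_assignments(n, edges):
        order_sum = [0] * n
        for k, (u, v) in enumerate(edges):
            order_sum[u] += orders[k]
            order_sum[v] += orders[k]
        allowed = [
            [el for el in alphabet if ELEMENT_VALENCE[el] >= order_sum[i]]
            for i in range(n)
        ]
        if any(not a for a in allowed):
            continue
        for elements in itertools.product(*allowed):
            m = _mol_from_graph(n, edges, elements=list(elements), orders=list(orders))
            if m is not None:
                out.add(Chem.MolToSmiles(m))
    return out


# ---------------------------------------------------------------------------
# Full enumeration


def iter_fragments(config: FragmentEnumConfig) -> Iterator[tuple[str, int, float]]:
    """Stream (smiles, n_heavy, mw) fragment records passing the filter cascade."""
    fcfg = config.filter_config()
    seen: set[str] = set()
    for n in range(1, config.max_heavy_atoms + 1):
        for skeleton in sorted(ring_closures(carbon_chain(n))):
            for smi in sorted(skeleton_transforms(skeleton, config)):
                if smi in seen:
                    continue
                seen.add(smi)
                if passes_filters(smi, fcfg).passed:
                    mol = mol_from_smiles(smi)
                    yield smi, mol.GetNumHeavyAtoms(), Descriptors.MolWt(mol)


def enumerate_fragments(config: FragmentEnumConfig) -> int:
    """Run the full pipeline; emit to SQLite when configured; return the count."""
    count = 0
    con = None
    if config.emit_db is not None:
        con = sqlite3.connect(config.emit_db)
        con.execute(
            "CREATE TABLE IF NOT EXISTS fragments ("
            "frag_id INTEGER PRIMARY KEY, smiles TEXT UNIQUE, "
            "n_heavy INTEGER, mw REAL)"
        )
    try:
        for smi, n_heavy, mw in iter_fragments(config):
            count += 1
            if con is not None:
                con.execute(
                    "INSERT OR IGNORE INTO fragments (smiles, n_heavy, mw) "
                    "VALUES (?, ?, ?)",
                    (smi, n_heavy, mw),
                )
        if con is not None:
            con.commit()
    finally:
        if con is not None:
            con.close()
    return count
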