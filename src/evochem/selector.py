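"""Genetic seed selector: binding-mode gating, diversity clustering, sampling,
and tournament selection.

The eligibility gate keeps a child when its inherited substructure stayed
put (pose RMSD to the parent below 2 A) OR its score improved by more than a
margin — consistent binding modes are maintained while clearly better ones
are not carved out.  Diversity is enforced by deterministic sphere-exclusion
(leader) clustering on fingerprint Tanimoto distance before sampling, and
next-generation seeds are drawn by tournament selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem, DataStructs

from evochem.chem import mol_from_smiles
from evochem.fitness import (
    UNDEFINED_RMSD,
    FitnessResult,
    shared_substructure_rmsd,
)

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    rmsd_threshold: float = 2.0          # A
    score_drop_margin: float = 1.0       # kcal/mol
    n_seeds: int = 100
    tournament_size: int = 4
    cluster_distance_cutoff: float = 0.15
    sample_size: int = 10000
    rng_seed: int = 0
    #: tournament ranking key: "ligand_efficiency" (default) or "raw_score"
    rank_by: str = "ligand_efficiency"

    def __post_init__(self):
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be > 0")
        if self.n_seeds < 1 or self.tournament_size < 1:
            raise ValueError("n_seeds and tournament_size must be >= 1")
        if not 0.0 <= self.cluster_distance_cutoff <= 1.0:
            raise ValueError("cluster_distance_cutoff must be in [0, 1]")


def _fitness_key(result: FitnessResult, rank_by: str, smiles: str = ""):
    primary = (
        result.ligand_efficiency if rank_by == "ligand_efficiency" else result.raw_score
    )
    # lower is better; full determinism via raw-score then SMILES tie-breaks
    return (primary, result.raw_score, smiles, result.mol_id)


def eligible_seeds(
    children: Sequence[FitnessResult],
    parents: Mapping[str, FitnessResult | None],
    config: SelectionConfig,
) -> list[FitnessResult]:
    """Gate children on binding-mode consistency or clear score improvement.

    ``parents`` maps child mol_id -> parent FitnessResult (None for
    generation-1 children, which are always eligible).  A child passes when
    its parent/child pose RMSD is below the threshold OR its raw score
    improved on the parent's by at least the margin.  Children without poses
    (mock/similarity modes) satisfy the RMSD clause vacuously.
    """
    keep: list[FitnessResult] = []
    for child in children:
        parent = parents.get(child.mol_id)
        if parent is None:
            keep.append(child)
            continue
        if child.pose is None or parent.pose is None:
            keep.append(child)  # no poses: RMSD clause vacuously true
            continue
        rmsd = shared_substructure_rmsd(parent.pose, child.pose)
        if rmsd < config.rmsd_threshold and rmsd != UNDEFINED_RMSD:
            keep.append(child)
        elif child.raw_score <= parent.raw_score - config.score_drop_margin:
            keep.append(child)
    return keep


# ---------------------------------------------------------------------------
# Diversity clustering


@lru_cache(maxsize=200_000)
def _rdkit_fp(smiles: str):
    return Chem.RDKFingerprint(mol_from_smiles(smiles))


def cluster_population(
    mols: Sequence[str],
    cutoff: float = 0.15,
    fitness: Sequence[float] | None = None,
) -> list[int]:
    """Sphere-exclusion (leader) partition on Tanimoto distance.

    Molecules are visited best-fitness-first (ties broken by canonical
    SMILES, then input position); each joins the first existing cluster whose
    leader is within ``cutoff`` Tanimoto distance, else founds a new cluster.
    Returns a cluster id per input molecule; id order follows leader
    discovery order.
    """
    if not mols:
        raise ValueError("mols must be non-empty")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    n = len(mols)
    if fitness is None:
        order = sorted(range(n), key=lambda i: (mols[i], i))
    else:
        order = sorted(range(n), key=lambda i: (fitness[i], mols[i], i))
    fps = [_rdkit_fp(s) for s in mols]
    leaders: list[int] = []
    assignment = [-1] * n
    for i in order:
        placed = False
        if leaders:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], [fps[j] for j in leaders])
            for cid, sim in enumerate(sims):
                if 1.0 - sim <= cutoff:
                    assignment[i] = cid
                    placed = True
                    break
        if not placed:
            assignment[i] = len(leaders)
            leaders.append(i)
    return assignment


def sample_representatives(
    clusters: Sequence[int],
    members: Sequence[str],
    sample_size: int,
    fitness: Sequence[float] | None = None,
    rng_seed: int = 0,
) -> list[int]:
    """Pick indices representing every cluster, then round-robin to size.

    The best-fitness member of each cluster is taken first (clusters ordered
    by their best member's fitness), then additional members are allocated
    round-robin until ``sample_size`` is reached.  Fully deterministic; the
    rng_seed only matters if callers extend this with stochastic policies.
    """
    n = len(members)
    by_cluster: dict[int, list[int]] = {}
    for i, cid in enumerate(clusters):
        by_cluster.setdefault(cid, []).append(i)

    def member_key(i):
        return (fitness[i] if fitness is not None else 0.0, members[i], i)

    for cid in by_cluster:
        by_cluster[cid].sort(key=member_key)
    cluster_order = sorted(by_cluster, key=lambda c: member_key(by_cluster[c][0]))

    if sample_size < len(by_cluster):
        logger.warning(
            "sample_size %d < %d clusters; truncating one-per-cluster by fitness",
            sample_size,
            len(by_cluster),
        )
        return [by_cluster[c][0] for c in cluster_order[:sample_size]]

    picked: list[int] = []
    depth = 0
    while len(picked) < min(sample_size, n):
        advanced = False
        for cid in cluster_order:
            if depth < len(by_cluster[cid]):
                picked.append(by_cluster[cid][depth])
                advanced = True
                if len(picked) >= sample_size:
                    break
        if not advanced:
            break
        depth += 1
    return picked


# ---------------------------------------------------------------------------
# Tournament selection


def tournament_select(
    pop: Sequence[FitnessResult],
    k: int,
    n: int,
    rng_seed: int = 0,
    rank_by: str = "ligand_efficiency",
    smiles: Mapping[str, str] | None = None,
) -> list[FitnessResult]:
    """Select up to ``n`` distinct seeds by k-way tournaments.

    Each tournament draws k individuals uniformly without replacement and the
    best fitness wins (docking convention: lowest).  Tournaments repeat until
    n distinct winners are collected or the population is exhausted.
    Deterministic under a fixed seed.
    """
    if not pop:
        raise ValueError("population must be non-empty")
    if k < 1:
        raise ValueError("tournament size must be >= 1")
    rng = np.random.default_rng(rng_seed)
    smiles = smiles or {}
    k = min(k, len(pop))
    winners: list[FitnessResult] = []
    seen: set[str] = set()
    # only the best len(pop) - (k - 1) individuals under the total order can
    # ever win a k-way tournament; treat the rest as unreachable
    n_winnable = max(1, len({r.mol_id for r in pop}) - (k - 1))
    while len(winners) < n and len(seen) < n_winnable:
        idx = rng.choice(len(pop), size=k, replace=False)
        best = min(
            (pop[i] for i in idx),
            key=lambda r: _fitness_key(r, rank_by, smiles.get(r.mol_id, "")),
        )
        if best.mol_id not in seen:
            seen.add(best.mol_id)
            winners.append(best)
    return winners
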