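"""Fitness evaluation: ligand efficiency, similarity mode, pose RMSD, and a
deterministic mock pocket scorer.

The primary ranking quantity is ligand efficiency,

    LE = score / (1 + ln(N_heavy)),

which counteracts the size bias of raw docking-style scores and prevents
premature enrichment of large molecules before the molecular-weight ceiling
is reached.  Scores follow the docking convention: lower (more negative) is
better.

Three fitness modes share one contract:

* ``mock`` — a documented linear pocket surrogate, fully deterministic, used
  to exercise the evolutionary loop without an external docking engine;
* ``similarity`` — Tanimoto fingerprint similarity to reference ligands
  (ligand-based campaigns); higher is better, so the score is negated
  internally to keep the lower-is-better convention;
* ``docking`` — a shell-out adapter contract for an external engine
  (AutoDock Vina-compatible output parsing).
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, rdFMCS

from evochem.chem import (
    aromatic_ring_count,
    hba_count,
    mol_from_smiles,
)
from evochem.filters import count_rotatable_bonds_custom

#: Sentinel for an RMSD that cannot be computed (< 3 mappable atoms);
#: always compares as "binding mode changed".
UNDEFINED_RMSD = float("inf")


def ligand_efficiency(raw_score: float, n_heavy: int) -> float:
    """raw_score / (1 + ln(n_heavy)); sign-preserving."""
    if n_heavy < 1:
        raise ValueError("n_heavy must be >= 1")
    return raw_score / (1.0 + math.log(n_heavy))


@dataclass(frozen=True)
class Pose:
    """Heavy-atom coordinates of a scored binding pose in the receptor frame."""

    mol_id: str
    symbols: tuple[str, ...]
    coords: tuple[tuple[float, float, float], ...]
    score: float
    smiles: str | None = None

    def __post_init__(self):
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("coordinates must be finite")
        if len(self.symbols) != len(self.coords):
            raise ValueError("symbols and coords length mismatch")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class FitnessResult:
    mol_id: str
    raw_score: float
    n_heavy: int
    ligand_efficiency: float
    pose: Pose | None = None

    def __post_init__(self):
        if self.n_heavy < 1:
            raise ValueError("n_heavy must be >= 1")
        expected = ligand_efficiency(self.raw_score, self.n_heavy)
        if not math.isclose(self.ligand_efficiency, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("ligand_efficiency inconsistent with raw_score/n_heavy")


def make_fitness_result(
    mol_id: str, raw_score: float, n_heavy: int, pose: Pose | None = None
) -> FitnessResult:
    return FitnessResult(
        mol_id=mol_id,
        raw_score=raw_score,
        n_heavy=n_heavy,
        ligand_efficiency=ligand_efficiency(raw_score, n_heavy),
        pose=pose,
    )


# ---------------------------------------------------------------------------
# Similarity mode


def _fingerprint(mol: Chem.Mol, kind: str):
    if kind == "rdkit":
        return Chem.RDKFingerprint(mol)
    if kind == "morgan":
        return AllChem.GetMorganFingerprintAsBitVect(mol, 2, nBits=2048)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def similarity_fitness(
    smiles: str,
    refs: Sequence[str],
    fp_kind: str = "rdkit",
    aggregate: str = "max",
) -> float:
    """Tanimoto similarity of ``smiles`` to reference ligands, in [0, 1]."""
    if not refs:
        raise ValueError("reference set must be non-empty")
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")
    fp = _fingerprint(mol_from_smiles(smiles), fp_kind)
    sims = [
        DataStructs.TanimotoSimilarity(fp, _fingerprint(mol_from_smiles(r), fp_kind))
        for r in refs
    ]
    return max(sims) if aggregate == "max" else float(np.mean(sims))


# ---------------------------------------------------------------------------
# Pose RMSD (binding-mode consistency)


def shared_substructure_rmsd(
    parent: Pose,
    child: Pose,
    mapping: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Coordinate RMSD over mapped parent/child atoms, without re-superposition.

    Poses live in a common receptor frame, so no alignment is performed: the
    quantity measures whether the inherited substructure kept its binding
    mode.  When ``mapping`` is None, a maximum common substructure match is
    computed from the poses' SMILES and all symmetry-equivalent atom mappings
    are evaluated; the minimum RMSD is returned.  Fewer than 3 mappable atoms
    yields the UNDEFINED_RMSD sentinel (treated as a changed binding mode).
    """
    if mapping is not None:
        mappings = [list(mapping)]
    else:
        if parent.smiles is None or child.smiles is None:
            raise ValueError("no mapping given and poses carry no SMILES")
        mappings = _mcs_mappings(parent.smiles, child.smiles)
    best = UNDEFINED_RMSD
    p_xyz, c_xyz = parent.xyz, child.xyz
    for m in mappings:
        if len(m) < 3:
            continue
        pi = [a for a, _ in m]
        ci = [b for _, b in m]
        diff = p_xyz[pi] - c_xyz[ci]
        rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
        best = min(best, rmsd)
    return best


def _mcs_mappings(parent_smiles: str, child_smiles: str):
    """All symmetry-equivalent MCS atom maps between parent and child.

    Heavy atoms only, bond-order-insensitive, with a 10 s timeout.
    """
    pmol = mol_from_smiles(parent_smiles)
    cmol = mol_from_smiles(child_smiles)
    res = rdFMCS.FindMCS(
        [pmol, cmol],
        bondCompare=rdFMCS.BondCompare.CompareAny,
        timeout=10,
    )
    if res.canceled or res.numAtoms < 3:
        return []
    query = Chem.MolFromSmarts(res.smartsString)
    p_matches = pmol.GetSubstructMatches(query, uniquify=False, maxMatches=5000)
    c_matches = cmol.GetSubstructMatches(query, uniquify=False, maxMatches=5000)
    return [
        list(zip(pm, cm))
        for pm in p_matches
        for cm in c_matches
    ]


# ---------------------------------------------------------------------------
# Mock pocket scorer

#: Linear mock-pocket coefficients (kcal/mol-like units): rewards hydrogen-bond
#: acceptors, aromatic ring stacking, and pocket occupancy (heavy atoms);
#: penalizes rotatable-bond entropy.
MOCK_COEFFS = {"hba": 0.35, "aromatic_ring": 0.55, "heavy_atom": 0.12, "rb": 0.20}


@lru_cache(maxsize=500_000)
def mock_pocket_score(smiles: str, seed: int = 0) -> float:
    """Deterministic docking-like score; lower is better.

    score = -(a*HBA + b*aromatic_rings + c*N_heavy - d*RB_custom).
    ``seed`` is accepted for interface uniformity with stochastic evaluators
    and ignored: the score is a pure function of the structure.
    """
    mol = mol_from_smiles(smiles)
    a, b, c, d = (
        MOCK_COEFFS["hba"],
        MOCK_COEFFS["aromatic_ring"],
        MOCK_COEFFS["heavy_atom"],
        MOCK_COEFFS["rb"],
    )
    return -(
        a * hba_count(mol)
        + b * aromatic_ring_count(mol)
        + c * mol.GetNumHeavyAtoms()
        - d * count_rotatable_bonds_custom(smiles)
    )


# ---------------------------------------------------------------------------
# 3D embedding


def embed_3d(smiles: str, seed: int = 0) -> str:
    """One ETKDG conformer as an SDF (V2000) block; deterministic under seed."""
    mol = mol_from_smiles(smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv2()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"3D embedding failed for {smiles!r}")
    mol = Chem.RemoveHs(mol)
    return Chem.MolToMolBlock(mol)


# ---------------------------------------------------------------------------
# External docking adapter (contract only)


class DockingConfigurationError(RuntimeError):
    """External docking engine missing or misconfigured."""


def parse_vina_output(text: str) -> tuple[float, list[tuple[str, float, float, float]]]:
    """Parse best-mode score and heavy-atom coordinates from Vina-style PDBQT text.

    The best mode is the first MODEL block; its score is read from the
    ``REMARK VINA RESULT`` line.
    """
    score = None
    atoms: list[tuple[str, float, float, float]] = []
    in_first_model = False
    saw_model = False
    for line in text.splitlines():
        if line.startswith("MODEL"):
            if saw_model:
                break
            saw_model = True
            in_first_model = True
        elif line.startswith("ENDMDL"):
            break
        elif line.startswith("REMARK VINA RESULT:") and score is None:
            score = float(line.split()[3])
        elif line.startswith(("ATOM", "HETATM")) and (in_first_model or not saw_model):
            name = line[12:16].strip()
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            if not name.startswith("H"):
                atoms.append((name, x, y, z))
    if score is None:
        raise ValueError("no 'REMARK VINA RESULT' line in docking output")
    return score, atoms


def dock_adapter(
    mol3d_sdf: str,
    receptor: str | Path,
    box_center: tuple[float, float, float],
    box_size: tuple[float, float, float],
    executable: str = "vina",
    workdir: str | Path = ".",
    mol_id: str = "ligand",
) -> tuple[Pose, float]:
    """Shell out to an external docking engine and parse the best mode.

    This is a contract implementation: it validates configuration, runs the
    engine, and parses its text output into a :class:`Pose`.  It is never
    exercised in desk-scale test campaigns.
    """
    exe = shutil.which(executable)
    if exe is None:
        raise DockingConfigurationError(
            f"docking executable {executable!r} not found on PATH"
        )
    receptor = Path(receptor)
    if not receptor.exists():
        raise FileNotFoundError(f"receptor file not found: {receptor}")
    workdir = Path(workdir)
    lig_in = workdir / f"{mol_id}.sdf"
    lig_out = workdir / f"{mol_id}_out.pdbqt"
    lig_in.write_text(mol3d_sdf)
    cmd = [
        exe,
        "--receptor", str(receptor),
        "--ligand", str(lig_in),
        "--center_x", str(box_center[0]),
        "--center_y", str(box_center[1]),
        "--center_z", str(box_center[2]),
        "--size_x", str(box_size[0]),
        "--size_y", str(box_size[1]),
        "--size_z", str(box_size[2]),
        "--out", str(lig_out),
    ]
    subprocess.run(cmd, check=True, capture_output=True)
    score, atoms = parse_vina_output(lig_out.read_text())
    pose = Pose(
        mol_id=mol_id,
        symbols=tuple(a[0] for a in atoms),
        coords=tuple((a[1], a[2], a[3]) for a in atoms),
        score=score,
    )
    return pose, score


def retrosynthesis_accessibility(smiles: str) -> str:
    """Interface stub for an external retrosynthesis service; always 'unknown'."""
    return "unknown"
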