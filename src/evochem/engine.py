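"""Campaign orchestration: the generate / filter / sample / evaluate / select
loop, archive persistence, and library profiling.

One cycle takes the current elite seeds, evolves them with every enabled
rule, gates the children through the filter cascade, clusters and samples
the survivors to the evaluation budget, scores the sample with the active
fitness mode, applies the binding-mode eligibility gate, and breeds the next
generation's seeds by tournament selection.  Generation 0 is the seed input
itself and is exempt from filtering (typical starting fragments such as
benzene sit below the MW floor on purpose).

Everything — molecules, lineage, filter verdicts, scores, per-generation
summaries — is persisted to an SQLite archive; mock and similarity campaigns
are bit-reproducible under a fixed RNG seed.
"""

from __future__ import annotations

import logging
import sqlite3
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors

from evochem.chem import canonical_smiles, mol_from_smiles
from evochem.filters import FilterConfig, PropertyFilterConfig, passes_filters
from evochem.fitness import (
    FitnessResult,
    make_fitness_result,
    mock_pocket_score,
    similarity_fitness,
)
from evochem.rules import MoleculeRecord, RuleSet, demo_rule_pack, generate_children, load_rules
from evochem.selector import (
    SelectionConfig,
    cluster_population,
    eligible_seeds,
    sample_representatives,
    tournament_select,
)
from evochem.surrogate import SurrogateConfig

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class CampaignConfig:
    seeds_file: str | Path | None = None
    seeds: list[tuple[str, str]] = field(default_factory=list)  # (smiles, id)
    mode: str = "mock"  # mock | similarity | docking
    n_generations: int = 5
    rules_file: str | Path | None = None
    blocks_file: str | Path | None = None
    reference_ligands: list[str] = field(default_factory=list)
    filters: FilterConfig = field(default_factory=FilterConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    workspace: str | Path | None = None
    rng_seed: int = 0
    mw_ceiling_override: float | None = None
    #: cap on children retained per generation before filtering (uniform
    #: seeded downsample); keeps desk-scale campaigns tractable, matching the
    #: practice of sampling from the full rule output under limited resources
    max_pool_per_generation: int = 2000

    def __post_init__(self):
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.mode not in ("mock", "similarity", "docking"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mw_ceiling_override is not None:
            self.filters.properties = replace(
                self.filters.properties, mw_max=float(self.mw_ceiling_override)
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "seeds_file", "mode", "n_generations", "rules_file", "blocks_file",
            "reference_ligands", "workspace", "rng_seed", "mw_ceiling_override",
            "max_pool_per_generation",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "filters" in raw:
            kwargs["filters"] = FilterConfig(
                properties=PropertyFilterConfig(**raw["filters"].get("properties", {}))
            )
        if "selection" in raw:
            kwargs["selection"] = SelectionConfig(**raw["selection"])
        if "surrogate" in raw:
            kwargs["surrogate"] = SurrogateConfig(**raw["surrogate"])
        return cls(**kwargs)


@dataclass
class GenerationState:
    index: int
    population: int
    sampled: int
    evaluated: int
    selected_ids: list[str]
    top100_mean: float
    top1000_mean: float
    halted: bool = False
    diagnostic: str = ""


class CampaignResult:
    """In-memory view of a finished campaign."""

    def __init__(self):
        self.states: list[GenerationState] = []
        self.molecules: dict[str, MoleculeRecord] = {}
        self.verdicts: dict[str, tuple[bool, tuple[str, ...]]] = {}
        self.scores: dict[str, FitnessResult] = {}
        self.generated_unevaluated: list[str] = []

    def evaluated_records(self) -> list[tuple[str, float]]:
        return [
            (self.molecules[mid].smiles, res.raw_score)
            for mid, res in self.scores.items()
            if mid in self.molecules
        ]


def load_seed_file(path: str | Path) -> list[tuple[str, str]]:
    """Seed structures from a tab-separated SMILES/ID file."""
    seeds = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smi = parts[0]
            sid = parts[1] if len(parts) > 1 else f"seed_{len(seeds)}"
            seeds.append((smi, sid))
    if not seeds:
        raise ValueError(f"no seeds in {path}")
    return seeds


def _evaluator(config: CampaignConfig):
    if config.mode == "mock":
        return lambda smi: mock_pocket_score(smi)
    if config.mode == "similarity":
        refs = config.reference_ligands
        if not refs:
            raise ValueError("similarity mode requires reference_ligands")
        # similarity is higher-better; negate into the lower-is-better convention
        return lambda smi: -similarity_fitness(smi, refs)
    raise NotImplementedError(
        "docking mode requires an external engine; configure the dock adapter "
        "and evaluate poses outside run_campaign"
    )


def run_campaign(config: CampaignConfig) -> CampaignResult:
    """Run the full evolutionary loop; persist an archive when a workspace is set."""
    seeds_in = list(config.seeds)
    if config.seeds_file:
        seeds_in = load_seed_file(config.seeds_file) + seeds_in
    if not seeds_in:
        raise ValueError("no seed structures configured")
    if config.rules_file:
        ruleset = load_rules(config.rules_file, config.blocks_file)
    else:
        ruleset = demo_rule_pack()

    evaluate = _evaluator(config)
    result = CampaignResult()

    current_seeds: list[MoleculeRecord] = []
    for smi, sid in seeds_in:
        rec = MoleculeRecord(
            mol_id=sid, smiles=canonical_smiles(smi), generation=0
        )
        current_seeds.append(rec)
        result.molecules[rec.mol_id] = rec
    lineage_store = {r.smiles for r in current_seeds}

    # generation 0: seeds are evaluated but not filtered
    for rec in current_seeds:
        score = evaluate(rec.smiles)
        result.scores[rec.mol_id] = make_fitness_result(
            rec.mol_id, score, rec.n_heavy
        )
    parent_scores: dict[str, FitnessResult] = dict(result.scores)

    for g in range(1, config.n_generations + 1):
        gen_rng = np.random.default_rng((config.rng_seed * 1009 + g) % (2**31))
        children = generate_children(current_seeds, ruleset, g, lineage_store)
        if not children:
            result.states.append(
                GenerationState(g, 0, 0, 0, [], float("nan"), float("nan"),
                                halted=True, diagnostic="no children generated")
            )
            break
        if len(children) > config.max_pool_per_generation:
            keep = sorted(
                gen_rng.choice(
                    len(children), size=config.max_pool_per_generation, replace=False
                )
            )
            pool = [children[i] for i in keep]
        else:
            pool = children
        lineage_store.update(c.smiles for c in children)
        for rec in pool:
            result.molecules[rec.mol_id] = rec

        survivors: list[MoleculeRecord] = []
        reason_counter: Counter[str] = Counter()
        for rec in pool:
            verdict = passes_filters(rec.smiles, config.filters)
            result.verdicts[rec.mol_id] = (verdict.passed, verdict.reasons)
            if verdict.passed:
                survivors.append(rec)
            else:
                reason_counter.update(verdict.reasons)
        if not survivors:
            dominant = reason_counter.most_common(1)[0][0] if reason_counter else "NONE"
            result.states.append(
                GenerationState(g, len(pool), 0, 0, [], float("nan"), float("nan"),
                                halted=True,
                                diagnostic=f"all children filtered out; dominant reason {dominant}")
            )
            logger.warning("generation %d halted: dominant filter reason %s", g, dominant)
            break

        smiles_list = [r.smiles for r in survivors]
        assignment = cluster_population(
            smiles_list, config.selection.cluster_distance_cutoff
        )
        sampled_idx = sample_representatives(
            assignment,
            smiles_list,
            min(config.selection.sample_size, len(survivors)),
            rng_seed=int(gen_rng.integers(2**31)),
        )
        sampled = [survivors[i] for i in sampled_idx]
        result.generated_unevaluated.extend(
            survivors[i].smiles
            for i in range(len(survivors))
            if i not in set(sampled_idx)
        )

        evaluated: list[FitnessResult] = []
        for rec in sampled:
            score = evaluate(rec.smiles)
            evaluated.append(make_fitness_result(rec.mol_id, score, rec.n_heavy))
        for res in evaluated:
            result.scores[res.mol_id] = res

        parents_map = {
            res.mol_id: parent_scores.get(result.molecules[res.mol_id].parent_id)
            for res in evaluated
        }
        eligible = eligible_seeds(evaluated, parents_map, config.selection)
        smiles_by_id = {r.mol_id: r.smiles for r in sampled}
        selected = tournament_select(
            eligible,
            config.selection.tournament_size,
            config.selection.n_seeds,
            rng_seed=int(gen_rng.integers(2**31)),
            rank_by=config.selection.rank_by,
            smiles=smiles_by_id,
        )

        raw_scores = sorted(res.raw_score for res in evaluated)
        state = GenerationState(
            index=g,
            population=len(pool),
            sampled=len(sampled),
            evaluated=len(evaluated),
            selected_ids=[r.mol_id for r in selected],
            top100_mean=float(np.mean(raw_scores[:100])),
            top1000_mean=float(np.mean(raw_scores[:1000])),
        )
        result.states.append(state)
        logger.info(
            "gen %d: pop=%d sampled=%d selected=%d top100=%.3f",
            g, state.population, state.sampled, len(selected), state.top100_mean,
        )

        current_seeds = [result.molecules[r.mol_id] for r in selected]
        parent_scores = {res.mol_id: res for res in evaluated}
        if not current_seeds:
            break

    if config.workspace is not None:
        write_archive(result, config)
    return result


# ---------------------------------------------------------------------------
# Persistence


def _archive_path(workspace: str | Path) -> Path:
    return Path(workspace) / "archive.db"


def write_archive(result: CampaignResult, config: CampaignConfig) -> Path:
    """Persist a campaign to an SQLite archive (plus per-generation TSVs)."""
    workspace = Path(config.workspace)
    workspace.mkdir(parents=True, exist_ok=True)
    path = _archive_path(workspace)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(
            """
            CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
            CREATE TABLE molecules (
                mol_id TEXT PRIMARY KEY, smiles TEXT, generation INTEGER,
                parent_id TEXT, rule_id TEXT, n_heavy INTEGER);
            CREATE TABLE verdicts (
                mol_id TEXT PRIMARY KEY, passed INTEGER, reasons TEXT);
            CREATE TABLE scores (
                mol_id TEXT PRIMARY KEY, raw_score REAL, le REAL);
            CREATE TABLE generations (
                idx INTEGER PRIMARY KEY, population INTEGER, sampled INTEGER,
                evaluated INTEGER, n_selected INTEGER,
                top100_mean REAL, top1000_mean REAL,
                halted INTEGER, diagnostic TEXT);
            CREATE TABLE selected (generation INTEGER, mol_id TEXT);
            """
        )
        con.execute("INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),))
        con.execute("INSERT INTO meta VALUES ('rng_seed', ?)", (str(config.rng_seed),))
        con.execute("INSERT INTO meta VALUES ('mode', ?)", (config.mode,))
        for mid in sorted(result.molecules):
            r = result.molecules[mid]
            con.execute(
                "INSERT INTO molecules VALUES (?,?,?,?,?,?)",
                (r.mol_id, r.smiles, r.generation, r.parent_id, r.rule_id, r.n_heavy),
            )
        for mid in sorted(result.verdicts):
            passed, reasons = result.verdicts[mid]
            con.execute(
                "INSERT INTO verdicts VALUES (?,?,?)", (mid, int(passed), ";".join(reasons))
            )
        for mid in sorted(result.scores):
            res = result.scores[mid]
            con.execute(
                "INSERT INTO scores VALUES (?,?,?)",
                (mid, res.raw_score, res.ligand_efficiency),
            )
        for st in result.states:
            con.execute(
                "INSERT INTO generations VALUES (?,?,?,?,?,?,?,?,?)",
                (st.index, st.population, st.sampled, st.evaluated,
                 len(st.selected_ids), st.top100_mean, st.top1000_mean,
                 int(st.halted), st.diagnostic),
            )
            for mid in st.selected_ids:
                con.execute("INSERT INTO selected VALUES (?,?)", (st.index, mid))
        con.commit()
    finally:
        con.close()

    for st in result.states:
        rows = []
        for mid, res in sorted(result.scores.items()):
            rec = result.molecules.get(mid)
            if rec is None or rec.generation != st.index:
                continue
            rows.append(
                {
                    "mol_id": mid,
                    "smiles": rec.smiles,
                    "score": res.raw_score,
                    "le": res.ligand_efficiency,
                    "parent_id": rec.parent_id,
                    "rule_id": rec.rule_id,
                    "selected": int(mid in st.selected_ids),
                }
            )
        pd.DataFrame(rows).to_csv(
            workspace / f"generation_{st.index}.tsv", sep="\t", index=False
        )
    return path


def read_archive(workspace: str | Path) -> dict[str, pd.DataFrame]:
    """Read a persisted campaign archive back into DataFrames."""
    path = _archive_path(workspace)
    if not path.exists():
        raise FileNotFoundError(f"no archive at {path}")
    con = sqlite3.connect(path)
    try:
        version = con.execute(
            "SELECT value FROM meta WHERE key='schema_version'"
        ).fetchone()
        if version is None or int(version[0]) != SCHEMA_VERSION:
            raise ValueError(
                f"archive schema version {version} != supported {SCHEMA_VERSION}"
            )
        out = {
            name: pd.read_sql(f"SELECT * FROM {name}", con)
            for name in ("molecules", "verdicts", "scores", "generations", "selected")
        }
    except sqlite3.DatabaseError as exc:
        raise ValueError(f"corrupt or non-archive file {path}: {exc}") from exc
    finally:
        con.close()
    return out


def top_n_summary(
    archive: dict[str, pd.DataFrame] | str | Path, n: int
) -> pd.DataFrame:
    """Per-generation mean of the n best (most negative) raw scores."""
    if not isinstance(archive, dict):
        archive = read_archive(archive)
    mols = archive["molecules"][["mol_id", "generation"]]
    scores = archive["scores"].merge(mols, on="mol_id")
    if scores.empty:
        raise ValueError("archive holds no scores")
    rows = []
    for g, grp in scores.groupby("generation"):
        vals = np.sort(grp["raw_score"].to_numpy())
        if n > len(vals):
            logger.warning("top_n_summary: n=%d > %d scores in gen %d", n, len(vals), g)
        rows.append({"generation": int(g), "mean_top_n": float(np.mean(vals[:n])),
                     "n_used": int(min(n, len(vals)))})
    return pd.DataFrame(rows).sort_values("generation").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Library profiling


def npr_from_coords(coords: np.ndarray, masses: np.ndarray | None = None) -> tuple[float, float]:
    """Normalized principal moments of inertia (I1/I3, I2/I3) from coordinates.

    Unit masses by default.  A linear rod gives (0, 1); a regular planar
    hexagon gives (0.5, 0.5); NPR1 + NPR2 >= 1 for any rigid body.
    """
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    r = coords - com
    inert = np.zeros((3, 3))
    for m, v in zip(masses, r):
        inert += m * (np.dot(v, v) * np.eye(3) - np.outer(v, v))
    moments = np.sort(np.linalg.eigvalsh(inert))
    i1, i2, i3 = moments
    if i3 <= 0:
        return (0.0, 0.0)  # single point
    return (float(i1 / i3), float(i2 / i3))


def profile_library(
    mols: Sequence[str],
    n_sample: int = 5000,
    rng_seed: int = 0,
    unit_masses: bool = True,
) -> dict:
    """Property distributions plus PMI shape ratios for a random sample.

    MW / LogP / Fsp3 are computed for every molecule; a seeded random sample
    is embedded in 3D (ETKDG), optimized with MMFF94, and reduced to
    normalized principal-moment ratios over heavy atoms.  Embedding failures
    are skipped and counted.
    """
    if not mols:
        raise ValueError("mols must be non-empty")
    props = {"mw": [], "logp": [], "fsp3": []}
    for smi in mols:
        m = mol_from_smiles(smi)
        props["mw"].append(Descriptors.MolWt(m))
        props["logp"].append(Crippen.MolLogP(m))
        props["fsp3"].append(rdMolDescriptors.CalcFractionCSP3(m))

    rng = np.random.default_rng(rng_seed)
    idx = (
        rng.choice(len(mols), size=n_sample, replace=False)
        if n_sample < len(mols)
        else np.arange(len(mols))
    )
    nprs: list[tuple[float, float]] = []
    failures = 0
    for i in idx:
        try:
            mol = Chem.AddHs(mol_from_smiles(mols[i]))
            params = AllChem.ETKDGv2()
            params.randomSeed = int(rng_seed)
            if AllChem.EmbedMolecule(mol, params) != 0:
                failures += 1
                continue
            AllChem.MMFFOptimizeMolecule(mol)
            mol = Chem.RemoveHs(mol)
            conf = mol.GetConformer()
            coords = np.array(
                [list(conf.GetAtomPosition(a)) for a in range(mol.GetNumAtoms())]
            )
            masses = (
                None
                if unit_masses
                else np.array([a.GetMass() for a in mol.GetAtoms()])
            )
            nprs.append(npr_from_coords(coords, masses))
        except Exception:
            failures += 1
    return {
        "mw": np.asarray(props["mw"]),
        "logp": np.asarray(props["logp"]),
        "fsp3": np.asarray(props["fsp3"]),
        "npr": nprs,
        "embed_failures": failures,
    }
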