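"""Rule loading, application, deduplication, and lineage semantics."""

import sqlite3

import networkx as nx
import pytest
from rdkit import Chem

from evochem.chem import canonical_smiles
from evochem.rules import (
    MoleculeRecord,
    RuleError,
    RuleSet,
    TransformationRule,
    apply_rule,
    demo_rule_pack,
    enumerate_variants,
    generate_children,
    load_rules,
    make_record,
)

BENZENE = "c1ccccc1"
TOLUENE = "Cc1ccccc1"
XYLENES = {"Cc1ccccc1C", "Cc1cccc(C)c1", "Cc1ccc(C)cc1"}


class TestLoading:
    def test_demo_pack_round_trip(self, demo_rules):
        assert len(demo_rules) >= 30
        categories = {r.category for r in demo_rules.rules}
        assert categories == {"grow", "mutate", "bioisostere", "reaction"}
        for cat in categories:
            assert sum(r.category == cat for r in demo_rules.rules) >= 5
        assert demo_rules.building_blocks  # reaction rules need them

    def test_sqlite_source(self, tmp_path, demo_rules):
        db = tmp_path / "rules.db"
        con = sqlite3.connect(db)
        con.execute(
            "CREATE TABLE rules (rule_id TEXT PRIMARY KEY, category TEXT,"
            " smarts TEXT, description TEXT, enabled INTEGER)"
        )
        for r in demo_rules.rules:
            con.execute(
                "INSERT INTO rules VALUES (?,?,?,?,1)",
                (r.rule_id, r.category, r.pattern, r.description),
            )
        con.commit()
        con.close()
        rs = load_rules(db)
        assert {r.rule_id for r in rs.rules} == {r.rule_id for r in demo_rules.rules}

    def test_malformed_smarts_skipped_with_warning(self, tmp_path, caplog):
        src = tmp_path / "rules.tsv"
        src.write_text(
            "rule_id\tcategory\tsmarts\tdescription\n"
            "OK1\tgrow\t[cH:1]>>[c:1]C\tfine\n"
            "BAD1\tgrow\t[C>>\tbroken\n"
        )
        with caplog.at_level("WARNING"):
            rs = load_rules(src)
        assert len(rs) == 1
        assert "BAD1" in caplog.text

    def test_empty_table_fatal(self, tmp_path):
        src = tmp_path / "rules.tsv"
        src.write_text("rule_id\tcategory\tsmarts\tdescription\n")
        with pytest.raises(RuleError):
            load_rules(src)

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(RuleError):
            load_rules(tmp_path / "nope.tsv")

    def test_reaction_category_requires_two_templates(self):
        with pytest.raises(RuleError):
            TransformationRule("X", "reaction", "[cH:1]>>[c:1]C")
        with pytest.raises(RuleError):
            TransformationRule("Y", "grow", "[cH:1].[NH2:2]>>[c:1][N:2]")


class TestApplyRule:
    def test_benzene_methylation_collapses_symmetry(self, grow_methyl_rule):
        assert apply_rule(BENZENE, grow_methyl_rule) == {TOLUENE}

    def test_toluene_methylation_gives_three_xylenes(self, grow_methyl_rule):
        assert apply_rule(TOLUENE, grow_methyl_rule) == XYLENES

    def test_benzene_aza_mutation_gives_pyridine(self):
        rule = TransformationRule("M01", "mutate", "[cH:1]>>[n:1]")
        assert apply_rule(BENZENE, rule) == {"c1ccncc1"}

    def test_nonmatching_template_yields_empty_set(self, grow_methyl_rule):
        assert apply_rule("C1CCCCC1", grow_methyl_rule) == set()

    def test_reaction_rule_requires_blocks(self, demo_rules):
        rule = next(r for r in demo_rules.rules if r.category == "reaction")
        with pytest.raises(RuleError):
            apply_rule(BENZENE, rule, blocks=[])


class TestGenerateChildren:
    def _ruleset(self, rule):
        return RuleSet(rules=[rule])

    def test_single_seed_single_rule(self, grow_methyl_rule):
        seed = make_record(BENZENE, 0, 1)
        children = generate_children([seed], self._ruleset(grow_methyl_rule), 1)
        assert len(children) == 1
        child = children[0]
        assert child.smiles == TOLUENE
        assert child.parent_id == seed.mol_id
        assert child.rule_id == "G01"
        assert child.generation == 1
        assert child.n_heavy == 7

    def test_seed_overlap_dedup(self, grow_methyl_rule):
        b = MoleculeRecord("b", BENZENE, 0)
        t = MoleculeRecord("t", TOLUENE, 0)
        children = generate_children([b, t], self._ruleset(grow_methyl_rule), 1)
        # toluene is already a seed, so benzene's product is dropped;
        # the three xylenes from toluene remain
        assert {c.smiles for c in children} == XYLENES
        assert len(children) == 3

    def test_empty_ruleset_yields_nothing(self):
        seed = make_record(BENZENE, 0, 1)
        assert generate_children([seed], RuleSet(rules=[]), 1) == []

    def test_lineage_forest_is_acyclic(self, demo_rules):
        seeds = [make_record(BENZENE, 0, 1)]
        store = {BENZENE}
        all_records = {seeds[0].mol_id: seeds[0]}
        g = nx.DiGraph()
        current = seeds
        for gen in (1, 2):
            children = generate_children(current, demo_rules, gen, store)[:150]
            store.update(c.smiles for c in children)
            for c in children:
                all_records[c.mol_id] = c
                g.add_edge(c.parent_id, c.mol_id)
            current = children[:20]
        assert nx.is_forest(nx.Graph(g))
        roots = [n for n in g if g.in_degree(n) == 0]
        assert roots == [seeds[0].mol_id]


class TestInvariants:
    def test_canonicalization_idempotent(self, fragment_pool):
        for smi in fragment_pool[:100]:
            assert canonical_smiles(canonical_smiles(smi)) == canonical_smiles(smi)

    def test_grow_rule_products_contain_seed_scaffold(self, demo_rules):
        """Growing only adds atoms: the seed is a substructure of every product."""
        import random

        rng = random.Random(7)
        grow_rules = [r for r in demo_rules.rules if r.category == "grow"]
        seeds = [BENZENE, TOLUENE, "c1ccncc1", "Oc1ccccc1", "Nc1ccccc1"]
        pairs = []
        for seed in seeds:
            for rule in grow_rules:
                for prod in apply_rule(seed, rule):
                    pairs.append((seed, prod))
        assert pairs
        for seed, prod in rng.sample(pairs, min(20, len(pairs))):
            assert Chem.MolFromSmiles(prod).HasSubstructMatch(
                Chem.MolFromSmiles(seed)
            ), (seed, prod)

    def test_dedup_matches_isomorphism_oracle(self, demo_rules, fragment_pool):
        """Canonical-SMILES dedup agrees with pairwise graph isomorphism."""
        from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

        def to_graph(smi):
            mol = Chem.MolFromSmiles(smi)
            g = nx.Graph()
            for a in mol.GetAtoms():
                g.add_node(a.GetIdx(), el=a.GetSymbol(), h=a.GetTotalNumHs())
            for b in mol.GetBonds():
                g.add_edge(
                    b.GetBeginAtomIdx(), b.GetEndAtomIdx(), o=str(b.GetBondType())
                )
            return g

        pop = fragment_pool[:120]
        canon_groups = {}
        for smi in pop:
            canon_groups.setdefault(canonical_smiles(smi), []).append(smi)
        graphs = {smi: to_graph(smi) for smi in pop}
        nm = categorical_node_match(["el", "h"], [None, None])

        def iso(a, b):
            return GraphMatcher(
                graphs[a], graphs[b], node_match=nm,
                edge_match=lambda x, y: x["o"] == y["o"],
            ).is_isomorphic()

        # brute-force union-find by pairwise isomorphism
        reps = []
        oracle_groups = []
        for smi in pop:
            for i, rep in enumerate(reps):
                if iso(smi, rep):
                    oracle_groups[i].append(smi)
                    break
            else:
                reps.append(smi)
                oracle_groups.append([smi])
        assert len(oracle_groups) == len(canon_groups)
        assert sorted(map(sorted, oracle_groups)) == sorted(
            sorted(v) for v in canon_groups.values()
        )


class TestEnumerateVariants:
    def test_benzene_has_no_variants(self):
        assert enumerate_variants(BENZENE, tautomers=True, spiro=True) == {BENZENE}

    def test_hydroxypyridine_tautomer_pair(self):
        out = enumerate_variants("Oc1ccccn1", tautomers=True)
        assert "Oc1ccccn1" in out
        assert "O=c1cccc[nH]1" in out  # 2-pyridone form

    def test_flags_off_identity(self):
        assert enumerate_variants("Oc1ccccn1") == {"Oc1ccccn1"}


class TestMoleculeRecord:
    def test_generation_parent_consistency(self):
        with pytest.raises(ValueError):
            MoleculeRecord("x", BENZENE, 0, parent_id="p")
        with pytest.raises(ValueError):
            MoleculeRecord("x", BENZENE, 1, parent_id=None)

    def test_smiles_normalized_and_counted(self):
        rec = MoleculeRecord("x", "C1=CC=CC=C1", 0)
        assert rec.smiles == BENZENE
        assert rec.n_heavy == 6
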