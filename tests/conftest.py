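import pytest

from evochem.fragments import FragmentEnumConfig, iter_fragments
from evochem.rules import RuleSet, TransformationRule, demo_rule_pack


@pytest.fixture(scope="session")
def demo_rules() -> RuleSet:
    return demo_rule_pack()


@pytest.fixture(scope="session")
def grow_methyl_rule() -> TransformationRule:
    """Aromatic-CH methylation: the canonical grow rule used in hand examples."""
    return TransformationRule(
        rule_id="G01", category="grow", pattern="[cH:1]>>[c:1]C"
    )


@pytest.fixture(scope="session")
def fragment_pool() -> list[str]:
    """A deterministic pool of small valid molecules (filtered fragments, <=5 heavy)."""
    cfg = FragmentEnumConfig(max_heavy_atoms=5)
    return [smi for smi, _, _ in iter_fragments(cfg)]


#: diverse drug-like probe molecules for filter property tests
PROBE_MOLECULES = [
    "Cc1ccccc1",
    "CCc1ccccc1",
    "Cc1ccc(C)cc1",
    "c1ccc2ccccc2c1",
    "Cc1ccncc1",
    "COc1ccccc1",
    "Nc1ccccc1",
    "Oc1ccc(Cl)cc1",
    "N#Cc1ccccc1",
    "O=C(N)c1ccccc1",
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc(N2CCOCC2)cc1",
    "CC(C)Cc1ccc(C)cc1C(=O)O",
    "OC(=O)c1ccccc1",
    "CN1CCN(c2ccccc2)CC1",
    "Clc1ccccc1Cl",
    "Fc1ccc(F)cc1",
    "O=C(Nc1ccccc1)C1CC1",
    "CC1CCC(C)CC1",
    "C1CCOC1",
    "c1ccc(Cn2ccnc2)cc1",
    "CC(=O)Nc1ccc(O)cc1",
    "O=C(O)c1ccc(N)cc1",
    "c1ccc(-c2ccncc2)cc1",
    "CC(C)(C)c1ccccc1",
    "FC(F)(F)c1ccccc1",
    "O=C(NC1CC1)c1ccccc1",
    "Cn1cnc2ccccc21",
    "c1ccc2[nH]ccc2c1",
    "CCOc1ccccc1",
]


@pytest.fixture(scope="session")
def probe_molecules() -> list[str]:
    return list(PROBE_MOLECULES)
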