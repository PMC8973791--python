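# evochem

Evolutionary chemical-space exploration for structure- and ligand-based hit
finding. `evochem` grows novel molecules from seed fragments by applying
curated reaction-SMARTS transformation rules, gates every generation through
medicinal-chemistry filters, scores candidates with a pluggable fitness
function ranked on **ligand efficiency**, and breeds the next generation of
seeds with a genetic selector. A fingerprint surrogate regressor screens the
large pool of generated-but-unevaluated molecules.

## Who this is for

Computational and medicinal chemists running fragment-growing campaigns:
starting from a small fragment (or an exhaustively enumerated fragment
library), the platform iterates *generate → filter → sample → score →
select* until the population converges on structures that fit the evaluation
model — an external docking engine in production, or the bundled
deterministic mock pocket scorer and Tanimoto-similarity mode for
development and ligand-based work.

## The model

- **Rules** come in four categories: *grow* (replace an eligible hydrogen
  with an atom, group, or ring), *mutate* (atom/ring edits), *bioisostere*
  (isosteric swaps), and *reaction* (virtual one-step reactions with a
  building-block library). Rules are reaction SMARTS; a demonstration pack
  of ~33 rules and 8 building blocks ships with the package.
- **Filters**: MW ∈ [81, 450] Da, LogP ∈ [0, 5], HBD ≤ 5, HBA ≤ 10,
  rotatable bonds ≤ 4 by a custom SMARTS that treats bonds between two
  π systems as non-rotatable, TPSA ≤ 200 Å²; ring-system bounds
  (≤4 systems, ≤3 rings/system, ring size ≤7, fused ≤3, bridged ≤1,
  spiro ≤1); substructure gates (no S/P, structure alerts, count caps,
  PAINS).
- **Fitness ranking** uses ligand efficiency,
  `LE = score / (1 + ln N_heavy)`, which prevents premature enrichment of
  large molecules under size-biased docking-style scores.
- **Selection**: a child stays eligible when its inherited substructure kept
  its binding mode (pose RMSD < 2 Å against the parent, no re-superposition)
  OR its score improved by ≥ 1 kcal/mol; survivors are clustered by
  sphere exclusion on fingerprint Tanimoto distance (cutoff 0.15), sampled,
  and bred by k-way tournament selection.
- **Surrogate**: Morgan-fingerprint ridge regression (80/10/10 split)
  predicting raw score or LE, usable per-generation (*combined* mode) or
  post-campaign (*clean* mode).

## Worked example

```python
from evochem import CampaignConfig, run_campaign
from evochem.selector import SelectionConfig

config = CampaignConfig(
    seeds=[("c1ccccc1", "benzene")],   # benzene, 78 Da
    mode="mock",
    n_generations=5,
    rng_seed=1,
    selection=SelectionConfig(n_seeds=100),
)
result = run_campaign(config)
for st in result.states:
    print(st.index, st.population, st.sampled, len(st.selected_ids),
          round(st.top100_mean, 3))
```

prints

```
1 13 12 9 -2.03
2 270 253 100 -3.548
3 2000 1873 100 -5.524
4 2000 1766 100 -6.671
5 2000 1581 100 -7.523
```

Each line is one generation: pool size after deduplication and the
per-generation cap, molecules sampled and evaluated, seeds selected, and the
mean of the 100 best mock-pocket scores (kcal/mol-like; lower is better).
The monotone decrease from −2.03 to −7.52 is the expected evolutionary
trajectory: each generation's elites grow into better-scoring children while
the filters keep the population drug-like. The same loop runs identically —
and bit-reproducibly under a fixed `rng_seed` — from the CLI:

```bash
evochem run --config campaign.yaml
evochem fragments --max-heavy 5 --out fragments.db
evochem profile --in workspace/
evochem surrogate --in workspace/ --threshold -6.0
```

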