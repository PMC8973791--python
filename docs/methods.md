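# Methods

## The evolutionary loop

`evochem` treats fragment growing as a genetic algorithm in which
rule application is the variation operator (no crossover: the chemistry of
recombining two arbitrary molecules is ill-defined, whereas curated
transformations preserve synthetic plausibility). One cycle:

1. **Generate.** Every enabled transformation rule is applied to every seed.
   Rules are reaction SMARTS with one product template; *grow*, *mutate*,
   and *bioisostere* rules take the seed alone, *reaction* rules take the
   seed plus each building block. Every symmetry-distinct application site
   is enumerated; products are sanitized and deduplicated on
   stereo-stripped canonical SMILES, first-seen lineage retained. Children
   identical to any earlier structure in the campaign are dropped, which
   makes the lineage graph a forest rooted at the generation-0 seeds.
2. **Filter.** Children (never generation-0 seeds — starting fragments such
   as benzene legitimately sit below the MW floor) pass the property,
   ring-system, and substructure cascade. All violations are reported, not
   just the first, so reason-code histograms stay informative.
3. **Cluster and sample.** Survivors are partitioned by deterministic
   sphere-exclusion (leader) clustering on RDKit-fingerprint Tanimoto
   distance, then sampled one-best-per-cluster followed by round-robin up to
   the evaluation budget. This enforces diversity before the expensive
   fitness call.
4. **Score.** The configured fitness mode evaluates the sample. Scores
   follow the docking convention (lower is better); ligand efficiency
   `LE = score / (1 + ln N_heavy)` is the primary ranking key.
5. **Select.** The binding-mode gate keeps children whose mapped-substructure
   pose RMSD to the parent is below threshold OR whose score improved by at
   least the drop margin; tournament selection then draws the next
   generation's seeds.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| MW window | [81, 450] | Da | fragment-to-lead growing range |
| LogP window | [0, 5] | — | permeability/solubility balance |
| HBD / HBA / RB / TPSA | 5 / 10 / 4 / 200 | counts, Å² | drug-likeness caps; RB by the custom π-aware SMARTS |
| ring bounds | 4 systems / 3 per system / size 7 / 3 fused / 1 bridged / 1 spiro | counts | architectural sanity |
| RMSD threshold | 2.0 | Å | binding-mode consistency between consecutive generations |
| score drop margin | 1.0 | kcal/mol | "clearly better" escape hatch for changed binding modes |
| cluster cutoff | 0.15 | Tanimoto distance | diversity radius before sampling |
| seeds per generation | 100 | count | population size of the genetic algorithm |
| tournament size k | 4 | count | moderate selection pressure; k=1 is uniform, k=N greedy |
| surrogate split | 80/10/10 | — | train/test/validation at molecule level |

The custom rotatable-bond SMARTS
`[C^3!D1;!$(C(F)(F)F)]-!@[!Br!F!Cl!I!H3&!$(*#*)!D1;!$([!Br!F!Cl!I](F)(F)F)]`
requires an sp3 carbon on one side: a single bond between two π systems
tends to lock into a small number of conjugated rotamers and is not counted.
Symmetric duplicate matches of one bond are counted once.

## Fitness modes

**Mock pocket scorer.** A documented linear form,
`score = −(0.35·HBA + 0.55·aromatic_rings + 0.12·N_heavy − 0.20·RB)`,
deterministic by construction (the `seed` argument exists only for evaluator
interface uniformity). It rewards acceptor count, aromatic stacking surface,
and pocket occupancy, and penalizes rotor entropy — enough structure for
the evolutionary loop, clustering, and surrogate to behave qualitatively
like a docking campaign, with none of a real pocket's shape specificity,
steric clashes, or pose multiplicity. Passing trend tests under the mock
scorer therefore demonstrates the machinery, not docking accuracy.

**Similarity mode.** Tanimoto similarity (RDKit path or Morgan fingerprints)
to reference ligands, aggregated by max or mean, negated into the
lower-is-better convention.

**Docking adapter.** A shell-out contract for an AutoDock-Vina-compatible
engine: configuration validation, box/receptor plumbing, and parsing of the
best mode's score and heavy-atom coordinates from the engine's text output.
No scoring function is implemented here, and desk-scale tests exercise only
the parser and error paths.

**Pose RMSD.** Parent/child pose agreement is measured over mapped heavy
atoms *without* re-superposition — both poses live in the receptor frame,
so translation of the inherited substructure is exactly what the gate must
detect. With no explicit atom map, a maximum common substructure (heavy
atoms, bond-order-insensitive, 10 s timeout) supplies candidate mappings and
the minimum RMSD over all symmetry-equivalent matches is used. Fewer than 3
mappable atoms returns an undefined-RMSD sentinel treated as "binding mode
changed". In poseless modes the RMSD clause of the gate is vacuously true.

## Fragment enumeration

The enumerator reconstructs a GDB-style exhaustive fragment space: linear
carbon chains → the complete set of carbon skeletons (closure of the chain
under leaf re-attachment and ring closing; connected graphs of degree ≤ 4)
→ unsaturation (bond orders 1–3 under valence caps; aromatic rings emerge
at sanitization) → heteroatom substitution over the alphabet {C, N, O, F}
(S and P are excluded by the identity filters; heavier halogens would breach
the MW ceiling at 12 heavy atoms) → the standard filter cascade with
fragment MW bounds [50, 210] Da.

Skeletons in which two rings of size ≤ 4 share an atom (fused or spiro
cyclopropane/cyclobutane pairs, propellanes, tetrahedrane-like cages) are
rejected as hyperstrained fragment cores. With this rule the skeleton sets
at 3 and 4 carbons are exactly {propane, cyclopropane} and {butane,
isobutane, cyclobutane, methylcyclopropane}.

Absolute fragment counts are implementation-defined — they depend on the
transform and validity rules above — so the tests assert *oracle
equivalence*: an independent brute-force enumerator (direct edge-subset
graph enumeration with isomorphism deduplication, independent cycle-based
strain checking, and independent decoration) must produce the identical
molecule set at ≤ 5 heavy atoms. Desk-scale runs cap at 7 heavy atoms; the
full 12-heavy-atom space is a cluster-scale run of the same pipeline.

## Surrogate regressor

The default backend is 2048-bit Morgan (radius 2) fingerprints into ridge
regression with internal leave-one-out selection of the regularization
strength over a fixed grid (10^-3 … 10^3). This one design choice covers
both regimes the tests demand — near-perfect fit on a realizable linear
target and near-zero (not spuriously positive) test R² on pure noise —
without per-dataset tuning, and is deterministic on CPU. The validation
partition is held out and reported but unused: ridge needs no early
stopping. An external graph-model backend (message-passing networks) can be
plugged in behind the same train/predict contract. *Combined* mode retrains
each generation after nominating top-predicted unsampled molecules for true
evaluation; *clean* mode trains once post-campaign and screens the archive
against a score threshold.

## Numerical and design choices

- **Determinism.** Every stochastic step (pool downsampling, sampling,
  tournaments, splits) uses a seeded NumPy generator; ties everywhere break
  by fitness, then canonical SMILES, then id. Mock/similarity campaigns with
  equal configs produce byte-identical SQLite archives.
- **Stereochemistry** is stripped before canonical deduplication; rules do
  not assign stereocenter configurations. Docking-oriented workflows
  re-enumerate stereo at 3D preparation.
- **Hydrogens** are implicit; grow rules target heavy-atom environments with
  H-count constraints rather than explicit H atoms.
- **Tournament termination.** Under k-way tournaments the k−1 worst
  individuals (in the deterministic total order) can never win; selection
  stops at n distinct winners or when all winnable individuals are
  collected.
- **Desk-scale problem sizes.** Campaign runs cap the per-generation child
  pool at 2000 by seeded uniform downsampling before filtering — the same
  sample-the-rule-output strategy a resource-bounded production campaign
  uses — with 100 seeds and 5 generations in the trend checks; fragment
  oracle equivalence is asserted at ≤ 5 heavy atoms; PMI profiling embeds
  tens of molecules per test.
- **Degenerate inputs.** Empty rule sets, non-matching templates, and empty
  generations halt cleanly; a generation whose children all fail the
  filters halts with the dominant reason code; unparseable molecules raise
  (or warn and yield sentinels in batch prediction paths).

## Known limitations

- The demo rule pack (~33 rules) demonstrates the four categories; a
  production campaign needs a curated database orders of magnitude larger.
  Rule-pack extensibility (TSV or SQLite) is the contract, not pack size.
- The mock scorer has no pose geometry, so binding-mode gating is only
  exercised end-to-end in docking mode; poseless modes pass the gate
  vacuously by design.
- LogP is the RDKit atom-contribution estimate; other estimators can shift
  values by a few tenths of a log unit near the filter boundaries.
- The structure-alert and count-filter defaults are a small illustrative
  set (acyl halides, aldehydes, Michael acceptors; ≤1 carboxylic acid, ≤1
  alkyne) and are fully configurable.
- Retrosynthetic accessibility scoring is an interface stub returning
  "unknown"; synthesis-aware triage requires an external service.
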