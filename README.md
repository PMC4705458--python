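# ctuscope

Candidate taxonomic unit (CTU) circumscription for marine SSU rRNA surveys.

`ctuscope` re-implements, as a tested pipeline, the delineation of candidate
taxa from environmental 16S sequences:

1. **Mining** (`ctuscope.mining`) — select marine water-column,
   environmental, quality-passing sequences from database-style records
   (keyword source classification, uncultivated-clone detection, Pintail /
   sequence-quality / alignment-quality / length filters) and apply the
   whole-clade inclusion rule (≥ 50% marine water-column members, no
   non-marine member).
2. **Clustering** (`ctuscope.clustering`) — 10% base-conservation column
   mask, pairwise percent identities over comparable columns, deterministic
   furthest-neighbor (complete-linkage) agglomeration, and nested OTU
   partitions cut at rank identity thresholds
   (Phylum 75, Class 78.5, Order 82, Family 86.5, Genus 94.5 %).
3. **Recognition** (`ctuscope.recognition`) — outgroup rooting, maximal
   monochromatic clades per rank (an OTU that is polyphyletic on the tree
   splits into hyphen-suffixed components, e.g. `Ctx.Order3-1` /
   `Ctx.Order3-2`), nested hierarchy construction, standardized naming, and
   known-clade masking from leaf annotations.
4. **Ecology** (`ctuscope.ecology`) — rank-level relative abundance
   aggregation, min–max scaled category summaries, one-sided permutation
   site-association tests (difference-of-means or IndVal statistic), and
   Spearman correlation screens against environmental variables with
   pairwise missing-value handling.
5. **Simulation** (`ctuscope.simulate`) — fully seed-deterministic fixture
   bundles with planted rank structure (ultrametric trees whose crown
   distances interleave the rank cutoffs), Jukes–Cantor sequence evolution,
   synthetic metadata exercising every filter branch, and clade×sample
   tables with planted category enrichments and monotone environmental
   links, plus ground-truth files.

All I/O is plain text (aligned FASTA + TSV metadata sidecar, Newick, TSV
tables) and byte-deterministic for fixed inputs and seeds.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: configuration
fidelity, brute-force clustering-oracle equivalence (200 random matrices),
CTU invariants on 100 random trees, planted-taxonomy recovery
(ARI = 1.0 on 50 fixtures), naming rules, ecology-statistics calibration
(type-I error and power), and end-to-end byte determinism.

## CLI

```sh
ctuscope simulate --preset smoke --seed 1 --out-dir fixture/
ctuscope run-all --fixture-dir fixture/ --seed 1 --out-dir out/
```

Individual stages are exposed as `ctuscope mine | cluster | recognize |
ecology` operating on the same file formats; `--config` takes a
`key=value` file. `run-all` writes `taxonomy.tsv`, `lineages.tsv`,
`partitions.tsv`, `distances.phylip`, `rooted_tree.nwk`,
`associations.tsv`, `correlations.tsv`, `scaled_summary.tsv`, and
`run_summary.json`.

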