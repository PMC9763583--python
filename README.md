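# micropod

Gut-microbiome case/control diagnostic modelling: candidate-OTU screening,
cross-validated random-forest feature-count selection, per-sample
probability-of-disease (POD) scoring with ROC/cut-off evaluation and
external-cohort validation, together with the diversity, ordination,
permutation and compositional-correlation statistics such studies use —
exercised end to end on synthetic Dirichlet-multinomial cohorts.

## Modules

| module | purpose |
|---|---|
| `micropod.otu_io` | OTU table (TSV / BIOM-JSON), taxonomy, metadata and newick tree I/O; relative abundance; taxon aggregation; Firmicutes/Bacteroidetes ratio |
| `micropod.diversity` | observed OTUs, ACE, Mann–Whitney / Kruskal–Wallis comparisons, Bray–Curtis, unweighted/weighted UniFrac, optional seeded rarefaction |
| `micropod.ordination` | PCoA, NMDS (Kruskal stress-1), ANOSIM permutation test |
| `micropod.matching` | propensity-score 1:1 case/control matching, 2:1 discovery/validation split |
| `micropod.screen` | three-criterion candidate-OTU screen (abundance > 0.5 % in ≥ 1 sample, rank-sum p < 0.01, forest mean-decrease-accuracy > 1e-4) |
| `micropod.rfcv` | CV error-vs-k curve with in-fold feature re-ranking, panel training, POD scoring (cross-validated and external), ROC / Youden cut-off |
| `micropod.sparcc` | SparCC compositional correlation with bootstrap pseudo-p-values; OTU × clinical-indicator block (Spearman fallback) |
| `micropod.synth` | synthetic cohort generator with planted differential OTUs, batch effects, phylogeny, clinical couplings, and ground truth |
| `micropod.pipeline` / `micropod.cli` | end-to-end orchestration from a YAML config |

## CLI

```sh
# synthetic cohort mirroring the 30-case/31-control discovery design
micropod simulate --preset paper-discovery --seed 1 --out data/

# alpha/beta diversity, PCoA/NMDS/ANOSIM
micropod diversity --table data/otu_table.tsv --metadata data/metadata.csv \
    --tree data/tree.nwk --distance unifrac-weighted --out div/

# candidate screen, model training, prediction, validation
micropod screen  --table data/otu_table.tsv --metadata data/metadata.csv \
    --seed 1 --out screen.csv
micropod train   --table data/otu_table.tsv --metadata data/metadata.csv \
    --seed 1 --out model/
micropod predict --model model/model.json --table new_cohort.tsv --out pod.csv
micropod validate --model model/model.json --table new_cohort.tsv \
    --metadata new_meta.csv --out summary.json

# OTU x clinical-indicator correlation
micropod sparcc --table panel.tsv --metadata meta.csv --seed 1 --out assoc.csv

# everything from one config
micropod run-all --config config.yaml
```

Example `config.yaml`:

```yaml
seed: 1
out_dir: out
distance: bray-curtis
synthetic:            # or `inputs: {otu_table: ..., metadata: ..., tree: ...}`
  n_case: 30
  n_control: 31
  n_otus: 200
  n_effect: 8
  fold_change: 4.0
  external_cohorts: 1
  batch_sigma: 0.5
screen: {n_trees: 200}
rfcv: {folds: 5, repeats: 2, n_trees: 100, rule: min}
sparcc: {n_inner: 8, n_boot: 40}
```

Exit codes: 0 success, 2 config/validation error, 3 stage failure.

Table orientation is always declared (`--orientation otus-as-rows`, the
default, or `samples-as-rows`) — never guessed.

## Notes

- POD is defined as the fraction of forest trees voting the disease class,
  averaged over CV repeats in cross-validated mode; cross-validated scores
  come only from forests whose training folds excluded the sample.
- Feature ranking is re-derived inside every CV training fold to avoid
  selection leakage (`legacy_leaky=True` reproduces the naive protocol for
  comparison).
- Models persist as plain-text JSON sidecars carrying the panel, forest
  parameters, seed, and training data; loading refits the forest
  deterministically.
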