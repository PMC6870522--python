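# neutralcomm

Community-assembly analysis for sample-by-OTU count tables: OTU-retention
filtering, alpha/beta diversity, permutation statistics (PERMANOVA, CAP
ordination, rank tests), and the Sloan neutral-assembly model that
classifies each OTU as neutrally distributed or under positive/negative
host selection. A synthetic neutral-community generator makes every stage
testable without external data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: generator/
predictor closure, migration-rate recovery, CI calibration, AIC model
selection, and exact oracle equivalence for the diversity and permutation
statistics. The tests that reproduce published headline numbers require the
deposited OTU tables (an optional download, see below) and are skipped when
those are absent.

## Library overview

| module | contents |
|---|---|
| `neutralcomm.core_io` | `CountTable`, `TaxonomyMap`, `SampleMetadata`, `Tree`; classic-TSV and BIOM-JSON readers/writers, metadata TSV/CSV, Newick |
| `neutralcomm.filtering` | `filter_pruned` (0.005% global), `filter_dominant` (5% in one sample), `filter_min_reads` (20 reads), `remove_host_otu`, near-zero-variance screening |
| `neutralcomm.diversity` | Shannon, richness, Whittaker beta, Aitchison, Bray-Curtis, exact rarefaction, Faith's PD, rarefaction curves |
| `neutralcomm.community_stats` | sequential PERMANOVA, PCoA, CAP (PCoA + LDA with leave-one-out success), Kruskal-Wallis, Conover post hoc, shared-OTU counts, taxonomy aggregation |
| `neutralcomm.neutral_model` | occurrence-abundance summary, beta-CDF occurrence predictor, binomial null, least-squares migration-rate fit, Wilson/prediction-band OTU classification, AIC comparison, per-group fits, taxonomic distinctness |
| `neutralcomm.synthetic_data` | metacommunity sampler, stationary-beta neutral table generator, discrete Hubbell chain cross-check, selected-OTU spiking, diet-table generator |

A minimal analysis:

```python
from neutralcomm import read_count_table, read_metadata
from neutralcomm.filtering import filter_pruned
from neutralcomm.neutral_model import fit_per_group

table, taxonomy = read_count_table("table.tsv")
meta = read_metadata("metadata.tsv")
table, meta, _ = meta.align(table)
pruned, report = filter_pruned(table)
fits, summary = fit_per_group(pruned, meta, "location", level=99)
print(summary["mean_neutral_fraction"])
```

## Command line

```bash
neutralcomm simulate --seed 1 --out sim.tsv --meta sim_meta.tsv
neutralcomm filter --mode pruned --in table.tsv --out pruned.tsv --report report.json
neutralcomm diversity --metric braycurtis --in pruned.tsv --out bc.tsv
neutralcomm permanova --in pruned.tsv --metadata meta.tsv \
    --design "species+location+species:location" --nperm 10000 --seed 1 --out permanova.tsv
neutralcomm cap --in pruned.tsv --metadata meta.tsv --group species --out cap.json
neutralcomm neutral-fit --in pruned.tsv --metadata meta.tsv \
    --group-by location --ci 99 --out fit/
neutralcomm pipeline --config pipeline.yaml
```

Exit codes: 0 ok, 1 validation error, 2 runtime error.

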