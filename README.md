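# episom

Integrative SOM portraying of paired DNA-methylation and gene-expression
cohorts. Gene × sample matrices (methylation beta values in [0, 1] or
log2 expression intensities) are clustered with a batch self-organizing
map in which genes are the observations and samples the dimensions; each
grid unit's prototype is a "metagene" profile, and reshaping one
sample's metagene components onto the grid yields its molecular
*portrait*. On top of the trained maps the package provides:

- **cohort statistics** — differential methylation vs a reference class,
  integral hyper/hypomethylation, per-sample variance, beta-value
  histograms with Sarle's bimodality coefficient;
- **portraits & spot modules** — class-mean portraits, variance maps,
  overview spot masks (union of per-sample extreme-tail units) and
  8-connected spot-module segmentation with gene lists and profiles;
- **GSZ enrichment** — finite-population-corrected z-scores of gene-set
  means, per-class profiles with high/moderate/low stratification, and
  hypergeometric spot-vs-set overlap tables (BH-adjusted);
- **sample networks** — Pearson similarity of metagene landscapes,
  thresholded edges (strictly r > 0.5 by default) and connected-component
  cluster composition;
- **integration** — class-level methylation-expression coupling of gene
  groups across *unmatched* cohorts (class labels are the join key),
  classified into positive / negative / methylation-only /
  expression-only / silent patterns;
- **synthetic cohorts** — a generator of paired cohorts with bimodal
  beta mixtures, planted gene modules and known coupling signs, plus the
  ground-truth tables used by the recovery tests.

Three SOM variants are supported: **MetSOM** (raw beta values),
**DmetSOM** (per-gene centralized beta values) and **DexSOM**
(centralized log-expression).

## CLI

The `episom` entry point exposes one subcommand per pipeline stage.
Global options: `--config` (flat key-value YAML of option defaults),
`--seed`, `--out-dir`, `--log-level`. Every run writes a
`run_metadata.json` with parameters, seed and library versions.

```sh
# synthetic paired cohort with ground truth (768 genes, 133 + 133 samples)
episom --seed 0 simulate --out-dir out/sim

# train a SOM on centralized beta values (20x20 grid; default is 50x50)
episom --seed 11 train --matrix out/sim/methylation.tsv --modality dmet \
    --rows 20 --cols 20 --out-dir out/model

# class-mean portraits and variance map
episom portray --model out/model \
    --annotation out/sim/methylation_annotation.tsv --out-dir out/portraits

# spot-module detection (per-sample 98th-percentile tail, min 4 units)
episom spots --model out/model --out-dir out/spots

# gene-set overlap + GSZ class profiles
episom enrich --gmt out/sim/modules.gmt --spots-dir out/spots \
    --matrix out/sim/methylation.tsv \
    --annotation out/sim/methylation_annotation.tsv --out-dir out/enrich

# sample similarity network (edges strictly r > 0.5)
episom network --model out/model \
    --annotation out/sim/methylation_annotation.tsv --out-dir out/net

# per-class methylation summary statistics
episom stats --matrix out/sim/methylation.tsv \
    --annotation out/sim/methylation_annotation.tsv --reference B \
    --out-dir out/stats

# methylation-expression coupling of gene groups (unmatched cohorts)
episom integrate --met-matrix out/sim/methylation.tsv \
    --exp-matrix out/sim/expression.tsv \
    --met-annotation out/sim/methylation_annotation.tsv \
    --exp-annotation out/sim/expression_annotation.tsv \
    --groups out/sim/modules.gmt --ref-class GCB --target-class DLBCL \
    --out-dir out/integration

# aggregate run metadata
episom report --run-dirs out/sim --run-dirs out/model --out-dir out/report
```

## File formats

- **Matrices**: TSV, first column gene symbols, header row sample ids,
  `NA` for missing values.
- **Annotations**: two-column TSV `sample_id<TAB>class` with header.
- **Gene sets**: standard GMT (name, description, tab-separated
  symbols); symbols are matched case-insensitively.
- **SOM models**: a directory of `codebook.tsv`, `bmu.tsv`, `data.tsv`
  and `model.json`.

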