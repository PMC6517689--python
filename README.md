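# frigg

Resistance-gene-directed prioritization of predicted secondary-metabolite
gene clusters across multiple fungal genomes.

Many bioactive metabolites inhibit an essential enzyme of their own producer,
which survives by keeping a second, resistant copy of the target gene inside
the biosynthetic cluster. `frigg` mines multi-genome inputs for exactly that
signature: clusters containing one gene with a single extra genomic copy of
an otherwise single-copy, broadly conserved protein family.

## What it does

Inputs are plain TSV tables (plus optional FASTA):

| table | columns |
|---|---|
| proteins | `organism_id  protein_id  length_aa  section  interpro_ids` |
| clusters | `cluster_id  organism_id  member_rank  protein_id  is_backbone` |
| families | `family_id  organism_id  protein_id` (optional — can be built from BLAST hits) |

The pipeline:

1. **Homology counts** — for every cluster gene, count its protein-family
   members in the same organism, and how many of those sit in predicted
   clusters.
2. **Cluster selection** — *strict*: exactly one member has exactly one
   extra copy, located outside all predicted clusters; every other member is
   single-copy. *Alternative*: families larger than `X × n_organisms`
   members are exempt from the copy constraint (and ineligible as resistance
   genes), letting clusters with common tailoring enzymes through.
3. **Recurrence filter** (optional) — keep candidates whose resistance family
   recurs in ≥ 2 candidate clusters.
4. **Essentiality filter** — keep candidates whose resistance family has
   members in ≥ N% (typically 90–98%) of all organisms.
5. **Single-copy majority filter** (optional) — drop families that are
   multi-copy in more than 50% of the genomes.

When no family table is given, families are built by single-linkage
clustering of bidirectional BLASTp hits (identity ≥ 50%, query + subject
coverage sum ≥ 130%).

Outputs: per-step candidate tables, a step-count summary over the standard
12-setting grid (strict / alternative X=2 / X=3 × step 3 on/off ×
essentiality 90/98%), a family × setting presence matrix, context-label
tables, and per-family FASTA exports whose headers encode
`organism|section|protein|copies|label` with labels `StrictClust` (designated
resistance gene), `Clust` (in a predicted cluster), `outsideSC` (free-standing
homolog of a resistance gene, the putative target) and `0` (elsewhere).

## CLI

```bash
# generate a synthetic dataset with planted scenarios and a truth manifest
frigg synth --out data/ --n-organisms 8 --seed 7 --emit-hits

# build families from BLAST tabular hits (if you have no family table)
frigg families --proteins data/proteins.tsv --clusters data/clusters.tsv \
    --hits data/hits.tsv --out data/families.tsv

# one run
frigg run --proteins data/proteins.tsv --clusters data/clusters.tsv \
    --families data/families.tsv --fasta data/proteins.faa \
    --pattern alternative --x 2 --essential-pct 90 --out out/

# the 12-setting grid + presence matrix + step-count summary
frigg grid --proteins data/proteins.tsv --clusters data/clusters.tsv \
    --families data/families.tsv --out gridout/

# just the step-count summary table
frigg counts --proteins data/proteins.tsv --clusters data/clusters.tsv \
    --families data/families.tsv
```

`frigg run` also accepts `--config cfg.yaml` (YAML mirroring the
`PipelineConfig` fields); explicit CLI flags override file values.

## Synthetic data and planted scenarios

`frigg.synth.generate_dataset` produces deterministic datasets with
background content (essential single-copy families, private singletons,
clusters of 4–19 singleton-family genes) plus planted architectures, each
with a fixed expected fate recorded in a truth manifest:

| scenario kind | fate |
|---|---|
| `true_resistance_recurrent` | final in every setting |
| `fellutamide_like_singleton` | final iff step 3 is skipped |
| `mpa_like_step2_decoy` | eliminated at step 2 under both patterns |
| `nonessential_dup_step4_decoy` | eliminated at step 4 |
| `multicopy_step5_decoy` | eliminated at step 5 |
| `tailoring_large_family` | final under the alternative pattern only |

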