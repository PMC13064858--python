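# defcore

Core-defensome analysis pipeline for bacterial genomes. Given per-genome
defense/counter-defense system annotations, gene coordinate tables, protein
sequences, and MGE interval annotations, `defcore`:

- applies genome QC (completeness ≥ 90%, contamination ≤ 5%) and species-size
  (≥ 10 genomes) filters;
- builds reciprocal-best-hit (RBH) protein orthology within each species
  (identity ≥ 95%, coverage ≥ 80% on both sequences, e-value ≤ 1e-4) and lifts
  it to a system-level conservation relation (all components matched, same
  family);
- groups linked system instances into blocks (connected components) and
  classifies them as **core** (100% presence), **quasi-core** (90–99%), or
  accessory — core + quasi-core blocks are the highly conserved systems;
- detects **defense islands** (clusters of defense genes separated by ≤ 10
  intervening genes, ≥ 5 defense genes from ≥ 3 families, with circular
  wrap-around) and tests conserved-block membership in them;
- resolves overlapping MGE annotations (both members of an intersecting pair
  are excluded), assigns each system a genomic context (chromosome vs MGE
  class, requiring whole-system containment), and computes per-Mb densities;
- runs the associated statistics (two-sided Mann–Whitney–Wilcoxon with an
  exact small-sample branch, Fisher-exact family enrichment with
  Benjamini–Hochberg adjustment, Spearman density-vs-size correlation);
- clusters viral contigs into vOTUs by greedy centroid ANI clustering
  (min ANI 95, member coverage ≥ 0.85) and calls highly conserved
  counter-defense blocks per vOTU (≥ 10 members);
- ships a deterministic synthetic pangenome / phage-contig generator with
  planted ground truth, used as the recovery oracle for every stage.

## CLI

```bash
# generate a synthetic dataset (default: 5 species x 20 genomes) + truth
defcore simulate --out demo_in --seed 1
# optionally: --config sim.yaml with SimConfig fields (YAML)

# run the full analysis
defcore run --input demo_in --output demo_out
# options: --config cfg.yaml (PipelineConfig fields), --seed, --species SP00,
#          --external-hits hits.tsv (precomputed all-vs-all protein hit table)

# inspect the run report
defcore report --output demo_out

# vOTU clustering + conserved counter-defense calling
defcore votu --contigs contigs.fna --external-ani ani.tsv \
             --systems phage_systems.tsv --proteins phage_proteins.faa \
             --output votu_out
```

Input dialects (all plain text) are documented in `src/defcore/io.py`:
`manifest.tsv`, per-genome GFF3 gene tables under `genes/`, `systems.tsv`,
`mges.tsv`, `proteins.faa`. Outputs: `hcads_blocks.tsv`, `islands.tsv`,
`context.tsv`, `densities.tsv`, `removed_mges.tsv`, `stats.tsv`,
`species_summary.tsv`, `votus.tsv`, `hccds.tsv`, and `run_report.json`.

The built-in protein aligner (Smith–Waterman, BLOSUM62, gap 11/1) and the
built-in ANI backend are desk-scale conveniences; full-scale runs should feed
precomputed hit/ANI tables via the `--external-*` options. The RBH and
clustering logic is always defcore's own.

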