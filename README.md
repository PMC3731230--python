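# haplogwas

Association mapping of a binary trait in haploid populations: per-SNP
Fisher exact co-inheritance tests, permutation-calibrated expected hit
counts and experiment-wise false discovery rates, regional linkage
disequilibrium (r²), and a synthetic-data generator so the whole pipeline
is testable end to end without external data.

The pipeline stages are:

1. **genotype filtering** — haploid biallelic SNP matrices (TSV dialect or
   haploid VCF), filtered to sites where the minor allele is carried by
   strictly more than a chosen fraction of strains (default > 25%).
2. **phenotype binarization** — replicate fusion-assay counts are averaged
   per strain (each replicate × timepoint weighted equally); a strain is
   classed *low* iff its mean is more than one standard deviation below the
   grand mean across strains, *high* otherwise.
3. **association** — Fisher's exact test of allele × class per site,
   memoized so permutation scans cost one evaluation per distinct 2×2 table.
4. **permutation FDR** — the class vector is shuffled among strains
   (1000 permutations by default, or exhaustively for small panels); the
   expected hit count at a p-value threshold, FDR = expected/observed, the
   true-positive fraction, and expected-count-calibrated thresholds (e.g.
   "the p at which 0.1 hits are expected by chance") are derived from it.
5. **LD profiling** — pairwise haploid r² within a region, long-format
   heatmap table.

## CLI

Every stage is a subcommand of `haplogwas`; `run` composes them.

```sh
# synthetic dataset: genotype TSV + phenotype CSV + truth JSON
haplogwas simulate --out-dir sim --causal-site 250 --seed 1

# stage by stage
haplogwas filter    --in sim/genotypes.tsv --out filtered.tsv --min-maf 0.25
haplogwas phenotype --in sim/phenotypes.csv --out classes.tsv --bins-out bins.tsv
haplogwas assoc     --genotype filtered.tsv --phenotype sim/phenotypes.csv --out assoc.tsv
haplogwas permute   --genotype filtered.tsv --phenotype sim/phenotypes.csv \
                    --out thresholds.tsv --n-perms 1000 --seed 1 \
                    --thresholds 5.6e-6,0.015 --target-expected 0.1
haplogwas ld        --in filtered.tsv --out ld.tsv --region IV:3500000-3700000

# whole pipeline with a manifest
haplogwas run --genotype sim/genotypes.tsv --phenotype sim/phenotypes.csv \
              --out-dir out --seed 1 --n-perms 1000
```

`run` also accepts `--config cfg.yaml` (flat keys mirroring `RunConfig`;
flags override the file). Exit codes: 0 success, 2 validation error,
3 I/O error.

### File formats

* **Genotype TSV** — header `site<TAB>strain…`; one row per SNP with key
  `CHROM:POS` and single-nucleotide cells, `.` = missing. Coordinates are
  1-based; regions are closed intervals.
* **Haploid VCF** — read-only convenience; single-allele GT fields,
  multi-allelic records skipped, diploid GTs rejected.
* **Phenotype CSV** — columns `strain,replicate,timepoint,fused,total`.

## Library use

```python
import haplogwas as h

spec = h.SimSpec(causal_site=120, seed=1)
gm, pt, truth = h.gen_dataset(spec)
gm = h.filter_maf(h.filter_biallelic(gm))
bp = h.binarize(pt)
results = h.scan(gm, bp)
plan = h.PermutationPlan(n_permutations=1000, seed=1)
null = h.build_null(gm, bp, plan)
t01 = h.threshold_for_expected(gm, bp, plan, 0.1, null=null)
```
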