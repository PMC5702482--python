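# assortpca

Ancestry-based assortative-mating analysis of SNP genotype data.

The pipeline quantifies how genetically similar spouses are along the top
axes of ancestry variation:

1. **Genotype QC** — per-SNP call-rate filter (strict `> 0.95`), minor
   allele frequency filter (strict `> 0.05`), then greedy windowed LD
   pruning (50-SNP window, 5-SNP step, removing the later SNP of any kept
   pair with dosage r² > 0.30).
2. **PCA** — Patterson normalization (center by 2p̂, scale by
   √(p̂(1−p̂)), mean-impute missing as 0) and eigendecomposition of the
   sample–sample covariance; sign orientation against an anchor group so
   PC1/PC2 quadrant rules are reproducible.
3. **Spouse pairs** — identified from a pedigree by in-common children,
   with deterministic remarriage resolution and per-reason exclusion
   counts; PC1/PC2 quadrant ethnicity labels (East: PC1 < 0 & PC2 < 0;
   North: PC1 > 0 & PC2 < 0).
4. **Correlation tables** — per-stratum, per-PC Pearson correlations with
   Fisher-z 95% confidence intervals and t-distribution p-values,
   including generation strata and an exclude-site variant.
5. **Random-pairing null** — repeated random heterosexual within-ethnicity
   matchings (default 1000 replicates), summarized by the mean and
   empirical 95% quantile interval of each PC's correlation, compared
   against the observed values.
6. **Synthetic cohorts** — a Balding–Nichols forward simulator of a
   two-generation, multi-subpopulation cohort with a tunable endogamy
   probability per generation, Mendelian offspring at unlinked SNPs,
   optional missingness, and full ground truth, so every stage is testable
   without controlled-access data.

Formats: PLINK text PED/MAP (MAP optionally extended with two allele
columns), a FAM-style pedigree TSV with generation/site/subpop metadata
columns, minimal VCF 4.2 (GT-only, biallelic; read via cyvcf2), and a
PC-score TSV with an eigenvalue header line.

## CLI

Every stage is a subcommand of `assortpca` (add `-v` for stage logs):

```sh
assortpca simulate --n-subpops 3 --couples-per-pop 100 --n-snps 2000 \
    --fst 0.02 --endogamy-founder 0.9 --endogamy-offspring 0.4 \
    --seed 1 --out-prefix work/cohort
assortpca qc  --ped work/cohort.ped --map work/cohort.map --out work/kept.tsv
assortpca pca --ped work/cohort.ped --map work/cohort.map \
    --keep-snps work/kept.tsv --k 8 --fam work/cohort.fam.tsv \
    --anchor-group pop0 --out-scores work/scores.tsv --out-scree work/scree.tsv
assortpca pairs --fam work/cohort.fam.tsv --scores work/scores.tsv \
    --out work/pairs.tsv
assortpca correlate --pairs work/pairs.tsv --scores work/scores.tsv \
    --pcs 1,2,3,4,5,6 --out work/correlations.tsv
assortpca nulldist --fam work/cohort.fam.tsv --scores work/scores.tsv \
    --replicates 1000 --seed 2 --observed work/correlations.tsv \
    --out work/null.tsv
assortpca report --correlations work/correlations.tsv --out work/table.tsv
```

`assortpca run --config pipeline.yaml` executes everything end to end from
a single YAML file (simulate mode or PED/MAP+FAM input mode), writing a
manifest with a config hash and derived per-stage seeds; a fixed master
seed reproduces every output byte-identically.

## Layout

- `src/assortpca/simulate.py` — synthetic cohort simulator
- `src/assortpca/io.py` — PED/MAP, FAM TSV, VCF, score TSV readers/writers
- `src/assortpca/qc.py` — call-rate/MAF filters, LD pruning
- `src/assortpca/pca.py` — normalization, PCA, sign orientation, scree
- `src/assortpca/pairs.py` — spouse pairs, quadrant labels, stratification
- `src/assortpca/stats.py` — correlations, Fisher CIs, p-values
- `src/assortpca/nulldist.py` — random-pairing null and comparison
- `src/assortpca/pipeline.py`, `cli.py` — orchestration and CLI
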