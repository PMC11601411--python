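# epicqtl

QTL mapping and chromosome-level epistasis detection from pooled
sequencing of a two-parent yeast cross with one fixed chromosome.

Bulk segregant analysis (BSA) finds trait loci by comparing pooled allele
frequencies between selected and unselected segregant pools, but averaging
over pools hides genetic interactions. When every segregant instead carries
the *same* parental copy of one chromosome — and the experiment is repeated
with the other parent's copy — loci whose selection response depends on
that chromosome's parent of origin reveal themselves as
selection-by-background interactions, detected with the full power of
pooled sequencing. `epicqtl` implements the complete analysis for such
four-bulk designs, plus a forward simulator of the whole experiment.

At each position (after Gaussian smoothing of parental read counts along
the chromosome) the Wine-allele odds are fit by a binomial GLM

    log(odds_Wine) = β0 + β1·selection + β2·background + β3·(selection × background)

with selection coded 0/1 and background coded ∓0.5 (Wine/Oak). β1 measures
the additive QTL effect and β3 epistasis with the fixed chromosome.
Per-effect significance thresholds at a 5% false discovery rate come from a
permutation null built by position-shuffling the unselected bulks; peaks
are the per-segment maxima of |z| between local minima of the slope-
segmented trace; and each interaction peak is classified as **sign**
epistasis (selection shifts the allele frequency in opposite directions in
the two backgrounds) or **magnitude** epistasis (same direction, different
size). See `docs/methods.md` for the full model description.

## Worked example

Simulate an experiment with chromosome VIII fixed and a locus on VII whose
selection effect is three times stronger in the Oak background (magnitude
epistasis), then analyze it:

```python
from epicqtl import synthetic_data as sim
from epicqtl.pipeline import RunConfig, run_epicqtl

config, model = sim.magnitude_scenario(seed=7)     # a=1.5, gamma=1.5 at VII:30000
table, truth, genome = sim.generate_experiment(config, model)

result = run_epicqtl(
    RunConfig(fixed_chrom="VIII", n_perm=100, exclude=(), seed=7,
              out_dir="epicqtl_out"),
    variant_table=table)

print(result.interaction_peaks[["chrom", "pos", "zscore"]])
print(result.calls[["chrom", "pos", "classification", "crossing",
                    "additive_distance", "within_6kb"]])
```

which prints (the interaction peak lands 400 bp = 2 SNPs from the planted
locus at VII:30000, 600 bp from the additive peak, and the call is
magnitude, not sign):

```
  chrom    pos   zscore
0   VII  29600  2.54002
  chrom    pos classification  crossing  additive_distance  within_6kb
0   VII  29600      magnitude     False              600.0        True
```

The run also writes `epicqtl_out/`: a per-SNP z-score table
(`s1_zscores.tsv` with columns label/chr/CHROM/POS/zscore/q5), additive and
interaction peak tables (`s2_…`, `s3_…` with CSS/CHROM/POS/zscore),
epistasis calls, and a JSON manifest echoing every parameter, threshold and
count needed to reproduce the run.

The same stages are available as a CLI (`epicqtl simulate | load | smooth |
scan | fdr | peaks | classify | run | validate-s1`); `epicqtl validate-s1`
re-calls peaks directly from any per-SNP z-score table with q5 thresholds,
bypassing smoothing and the GLM.

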