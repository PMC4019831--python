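# rhizotax

Polyphasic taxonomy of rhizobial isolates, as a reusable Python pipeline.
The motivating problem: nitrogen-fixing root-nodule bacteria isolated from a
wild legume must be placed in a genus using three independent lines of
evidence — numerical taxonomy of phenotypic traits, restriction typing of the
PCR-amplified 16S rRNA gene (ARDRA / 16S rDNA-RFLP), and comparative 16S
sequence analysis. `rhizotax` implements all three tracks, plus synthetic-data
generators with known ground truth so every step can be validated.

## The methods at the core

**Numerical taxonomy.** Strains scored for binary characters are compared
with the simple matching coefficient SM = (a + d)/(a + b + c + d), where
a, b, c, d count the 1/1, 1/0, 0/1 and 0/0 character pairs (missing scores
use pairwise deletion). Strains are clustered by UPGMA on d = 1 − SM, and
phena are read off the phenogram by cutting it at a similarity level (a
cluster formed at cophenetic distance d sits at similarity 1 − d).

**In silico PCR-RFLP.** The near-full-length 16S rDNA amplicon is extracted
between the universal primers fD1/rD1, digested with a panel of seven
4-cutters (AluI, MboI, RsaI, Hin6I, TaqI, MspI, HinfI; IUPAC-degenerate
recognition sites supported), and passed through a gel model (detection
limit + co-migration merging). Identical band patterns per enzyme share a
letter (A, B, …); the combined seven-letter tuple is the strain's 16S
rDNA genotype (Roman numerals). Band sharing between strains is measured
with the Nei–Li (Dice) coefficient 2·n_xy/(n_x + n_y) and clustered by UPGMA.

**16S sequence phylogeny.** From an externally computed alignment:
pairwise percent identity (pairwise gap deletion; N never matches), the
Kimura two-parameter distance
d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)
with transition/transversion proportions P and Q, neighbor-joining trees,
column-resampling bootstrap supports, and the "gold standard" genus rule:
a query is assigned the genus of its best reference at ≥95% identity.

## Worked example

The package ships a 41-strain per-enzyme pattern-letter table (28 isolates,
13 reference *Mesorhizobium* strains). Recompute the combined genotypes:

```sh
python analysis/02_table3_genotypes.py
```

prints

```
25 distinct genotypes among 41 strains
15 distinct among 28 isolates; 12 distinct among 13 references
9 genotypes carried by a single isolate
2 isolate genotypes identical to a reference genotype
```

i.e. combining the seven enzyme patterns resolves the panel into 25
genotypes; two isolates are indistinguishable from named reference species
(*M. septentrionale*, *M. tianshanense*) at this resolution, and nine
genotypes are private to a single isolate. The other drivers follow the
same pattern:

* `analysis/01_phenotypic_taxonomy.py` — SM + UPGMA on a synthetic
  62 × 86 trait matrix; cuts the phenogram at the 75% similarity level and
  checks the phena against the planted clusters.
* `analysis/03_insilico_rflp.py` — plants five genotype groups in a 1.5 kb
  amplicon family by destroying restriction sites, genotypes them with the
  full pipeline, and builds the Nei–Li/UPGMA dendrogram.
* `analysis/04_16s_phylogeny.py` — identity matrix, 95% genus calls, and a
  bootstrapped NJ tree for a simulated two-genus 1,239 bp alignment.

All drivers take `--seed` and write their tables under `results/`.

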