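# Methods

This note records the models and procedures implemented in `rhizotax`, the
conventions chosen where the underlying methods admit several, and what the
synthetic-data validation does and does not establish.

## Numerical taxonomy track

Binary trait vectors are compared with the simple matching coefficient
SM = (a + d)/(a + b + c + d) over the positions scored in both strains
(a/b/c/d = counts of 1/1, 1/0, 0/1, 0/0 pairs). Missing scores use
**pairwise deletion** per strain pair, not listwise removal of characters:
this preserves information and is the common numerical-taxonomy default; a
pair with no jointly scored position is an error, never a silent value.

UPGMA is implemented directly (average linkage with size-weighted distance
updates, which equals the plain mean over all cross-cluster member pairs).
Conventions:

* merge heights are stored on the distance scale d = 1 − SM; leaf-to-node
  branch lengths are half the merge distance, so cophenetic distances equal
  merge distances and the tree is exactly ultrametric;
* ties in the minimum inter-cluster distance are broken toward the
  lexicographically smallest index pair in the current cluster ordering, so
  results are deterministic across platforms and orderings;
* `cut_at_similarity(tree, L)` removes merges whose **merge distance**
  (cophenetic value, i.e. twice the node-to-tip height) exceeds 1 − L, with
  a 1e-9 tolerance so exact-boundary merges are kept. Raising L only
  refines the partition.

scipy's average-linkage clustering is used in the test suite as an
independent cross-check (equal cophenetic matrices), never as the
implementation, because the cut semantics and tie-break rule above are part
of the contract.

## In silico PCR-RFLP track

Amplicon extraction finds the best (fewest-mismatch, bounded by
`max_mismatches`) occurrence of the forward primer and of the reverse
primer's reverse complement on a linear template; the product includes both
primer sites. Multiple equally good matches that imply different products
are an ambiguity error (coordinates listed), not a silent choice.

Digestion scans the amplicon for every (possibly overlapping) IUPAC match
of the recognition site; cut positions are match start + cut offset, and
fragments are the distances between consecutive interior cuts and the
sequence ends, so fragment lengths always sum to the amplicon length. All
seven default enzymes (AluI AG^CT, MboI ^GATC, RsaI GT^AC, Hin6I G^CGC,
TaqI T^CGA, MspI C^CGG, HinfI G^ANTC — sites from standard enzyme
catalogues, as the panel's sources list only the enzyme names) are
palindromic, so one strand suffices; non-palindromic patterns are also
scanned on the reverse complement unless disabled.

The gel model has two parameters: a **detection limit** (default 50 bp) and
a **co-migration tolerance** (default 5% of the larger size). Neither is
dictated by the underlying protocol (3% agarose); the defaults are
plausible for small-fragment agarose work and are configurable via
`RunConfig`. Merging proceeds left-to-right on sorted sizes and is iterated
to stability; merged bands sit at the group mean. Pattern identity for
letter typing is decided on gel-visible band lists (post-merge), not raw
fragment multisets — matching what a gel can actually distinguish. Letters
(A, B, …) and combined-genotype Roman numerals are issued in order of first
appearance in input order, reproducing the labelling convention of
published typing tables.

For band-sharing similarity, each enzyme's band sizes are pooled across
strains and binned with the same co-migration rule, so the same true band
maps to one (enzyme, size-bin) column even when per-strain merged means
differ slightly. Nei–Li similarity is Dice on these band sets; the RFLP
dendrogram is UPGMA on 1 − similarity.

The packaged 41-strain letter table is transcribed as printed, including
its one internal inconsistency: two isolates (AG8/AG9) carry the same
letter tuple as two others (AG2/AG3) yet a different printed group label.
All genotype statistics are therefore **recomputed from the letter tuples**
(25 distinct genotypes among 41 strains; 15 — not the published 13 — among
the 28 isolates; 12 among 13 references; 9 single-isolate genotypes; 2
isolate genotypes identical to reference genotypes), and the printed labels
are preserved alongside for comparison.

## 16S sequence track

Alignments are consumed, not computed (multiple sequence alignment is
standard external tooling). Gap handling is pairwise deletion for both
percent identity and K2P; N is never comparable. The K2P distance is the
closed form d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q); a non-positive log
argument is a saturation error naming the pair.

Neighbor joining follows the Saitou–Nei Q-criterion with standard branch
lengths; ties break toward the first minimal pair in scan order. Negative
branch-length estimates (possible for non-additive inputs) are clamped to
zero with the deficit moved to the sibling edge, preserving the pair's
summed length. The returned tree is unrooted, represented with a degree-3
root. On exactly additive inputs the tree reproduces the input path-length
matrix to 1e-9 and the generating topology (property-tested against random
additive trees; dendropy's NJ serves as an independent implementation in
the tests).

Bootstrap resamples alignment columns with replacement, recomputes K2P+NJ
per replicate, and scores every internal bipartition of the full-data tree
by the percentage of replicate trees containing it (computed over completed
replicates; replicates with saturated pairs are skipped, and more than 50%
skips is an error). Supports are rounded percentages stored on the nodes
and emitted as internal Newick labels. "100 permutations of the data sets"
is read as 100 column-resampling bootstrap replicates, the standard usage.

Genus assignment uses the 95%-identity rule: a query takes the genus of its
best-identity reference if that identity meets the threshold; below
threshold it is unassigned, and an exact best-identity tie across genera is
reported as ambiguous rather than resolved arbitrarily.

Maximum-likelihood inference and substitution-model selection are out of
scope; the NJ track is the implemented counterpart (the two agreed in the
motivating study).

## Synthetic-data generators

The generators exist to give every track inputs with known ground truth;
their defaults are the study conditions.

**Sequences** (`simulate_alignment`): a two-level tree (genus ancestors,
then leaves) with leaf branches drawn uniformly from half the within-genus
divergence range and genus branches sized so the expected between-genus
leaf-to-leaf path equals the between divergence. Evolution is per-site
independent: each site substitutes with probability 1 − exp(−t) per branch
of length t, a substitution being a transition with probability
κ/(κ + 2) (default κ = 2). This is deliberately simpler than full
rate-matrix exponentiation; realized divergences are validated empirically
in the tests (mean within 20% of target at L = 1200). Defaults: 1,239 bp
(the study's sequenced length), within-genus divergence 1–5%, between 10%.
No indels, no rate heterogeneity, no secondary-structure constraints — so
recovery results on these data bound what the pipeline can do on clean
alignments, not on hard real-world ones.

**Traits** (`simulate_traits`): cluster consensus vectors plus independent
per-character copy noise. The agreement parameters are the **expected pairwise
simple-matching similarities** within (a_w) and between (a_b) clusters —
the scale the phenogram is cut on. Internally the copy probability is
p = (1 + sqrt(2·a_w − 1))/2 and the consensus agreement is
(a_b − (1 − a_w))/(2·a_w − 1); a_w ≤ 0.5 is unattainable by independent
copies, hence the (0.5, 1] bound. Defaults 28 strains (14 + 14), 86
characters, a_w = 0.9, a_b = 0.5.

**RFLP families** (`plant_rflp_groups`): each planted group destroys a
group-specific set of the base amplicon's restriction sites by single-base
edits that provably (i) remove exactly the targeted occurrence, (ii) leave
every other panel enzyme's site set unchanged, and (iii) never touch the
primer regions. The construction is verified by genotyping the family and
re-drawing candidate sites on collision (e.g. when a gel-level merge masks
an edit), so recovery of the planted partition is guaranteed by
construction, not assumed.

The ten-sequence "isolate set" used for the identity-band analysis is a
synthetic stand-in generated by `simulate_alignment` in single-genus mode
with within-divergence drawn from 2.4–3.6% — centred inside the 1–5%
divergence regime of the real isolates so that sampled identities stay
within the 95–99% band with margin at L = 1,239. The real deposited
sequences require a network download and are not redistributed here.

## Problem sizes and numerical choices

Analyses and checks run at desk scale: 100-seed Monte Carlo for phenon
recovery (28 × 86 matrices), 1,000 random 200–2,000 bp sequences × 7
enzymes for the digest oracle, 4–8-taxon matrices for the tree oracles,
100 bootstrap replicates at L = 1,200 for the clade-support analysis.
Symmetry is validated to 1e-12, ultrametricity and additive-tree recovery
to 1e-9. Degenerate inputs fail loudly by design: empty band sets, no
jointly scored characters, saturated pairs, ambiguous amplicons.

## Known limitations

* The published phenogram and RFLP-dendrogram heights (67%/75%/76%
  similarity levels) rest on matrices that were never published; they are
  covered by structural properties (ultrametricity, nested cuts,
  determinism) rather than numeric reproduction.
* The gel model is deliberately coarse (hard detection limit, relative
  co-migration window); it does not model band intensity, smiling, or
  partial digestion.
* The substitution simulator ignores multiple-hit bookkeeping within a
  branch (one draw per site per branch), which slightly deflates realized
  divergence at large branch lengths; calibration tests bound the effect.
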