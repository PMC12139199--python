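# Methods

`riceshift` implements the computational core of a rice phylogenomics and
heterosis analysis: where did bursts of gene duplication happen on the
*Oryza* species tree, do the duplicate topologies at the cultivated-rice
ancestor look like independent divergence of *indica* and *japonica* or
like hybridization, how old are the duplicates on the synonymous-substitution
clock, what genomic context (tandem arrays, transposable elements) produced
them, which variants in an F1 super-hybrid are inherited, shared or de novo,
and how is F1 gene expression placed relative to its parents.  This note
records the models, parameter choices and numerical conventions, and what
the synthetic data do and do not establish.

## Gene-duplication calling by reconciliation

Gene trees are reconciled against a rooted species tree by LCA mapping:
each gene-tree node maps to the lowest species-tree node containing all
species below it.  Species sets are bitmasks over the species-tree leaves,
so one reconciliation is linear in tree size with O(depth) LCA queries.

**Rooting.**  Input gene trees are unrooted in practice (maximum-likelihood
inference does not root them), so every branch is tried and the rooting
minimizing duplications + losses under LCA reconciliation is kept.  Losses
use the standard depth formula: an edge whose mapping jumps *d* levels
contributes *d* − 1 losses below a speciation node and *d* below a
duplication.  Ties are resolved deterministically: fewer duplications,
then the deeper species-tree span of the smaller root clade, then the
lexicographically smallest leaf label on that side.  Bootstrap supports
are attributes of *edges*, and follow the edge when the tree is re-rooted.

**Detection thresholds.**  A node is a duplication event when its two
child clades share ≥ `min_shared_species` (default 2) genomes, the node's
support is ≥ `bp` (default 70) and both child supports are ≥ `sub_bp`
(default 70), on a 0–100 scale.  A missing support is treated as
uninformative and passes — our simulated trees carry full supports, but
user trees may not, and absence of evidence is not evidence against a
node.  The event is placed at the LCA of the union of the child species
sets.

**Duplicate-topology typing.**  At a focal ancestor whose two descendant
lineage sets are labelled A and B (e.g. the *indica* and *japonica*
clades below the *O. sativa* ancestor), an event whose two copies both
retain A and B descendants is ABAB; a copy reduced to only-A makes it
ABAX, to only-B makes it ABXB.  ABAB events are expected when A and B
diverged independently *after* the duplication; an excess of reduced
topologies would suggest the focal ancestor was a hybrid of the two
lineages.  Taxa outside A ∪ B are ignored by intersection; degenerate
configurations (neither copy retaining both lineages) are reported as
OTHER rather than forced into a class.

## NG86 Ka/Ks

Synonymous/nonsynonymous *sites* per codon are counted as the fraction of
the nine single-nucleotide neighbours that preserve the amino acid, with
changes into stop codons counted nonsynonymous; S is averaged between the
two sequences, and S + N = 3 × retained codons exactly.  *Differences*
for codons differing at k positions are averaged over the k! orderings of
single steps; orderings that pass through a stop codon are excluded (if
every ordering does, all are used — a standard implementation choice the
original description leaves open).  Codon columns containing gaps,
ambiguity codes or stop codons in either sequence are dropped entirely.
Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with
Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (reported as
`saturated`, never an abort).  Ka/Ks is undefined when Ks is 0 or
saturated.  The standard nuclear code is the default; the code table is
injectable for testing.

Ks distributions are summarized by a Gaussian KDE over finite values
(saturated pairs excluded but counted), with the modal Ks read off a
512-point grid over [0, max] and all local maxima reported — the shape
used to compare divergence ages between subspecies pairs.  The
molecular-clock gene filter retains CDSs of 900–1200 bp inclusive with
optional taxa-coverage floors.

## Tandem and TE context

Tandem duplication: both genes of a pair on one chromosome with at most
10 intervening genes, counted on the dense ordinal ranking of *all*
annotated genes on that chromosome (the gene universe is not restricted
to duplicates; the criterion text does not specify it).  TE association:
any TE interval sharing ≥ 1 base with the gene body extended 2 kb both
ways (1-based inclusive coordinates, clamped at position 1, gene-body
boundaries rather than TSS).  The duplicated × TE-associated 2×2 table is
tested with the Pearson chi-square (df = 1), Yates correction off by
default since the source analysis names only "chi-square test".  Note
that on tables with small expected counts the asymptotic p-value can
differ visibly from the exact conditional one; the test suite checks the
asymptotic p against a hypergeometric permutation oracle only in the
regime where the approximation is valid.

## Trio variants

Hard filtering fails a site when any *present* annotation violates
QD < 10, FS > 60, MQ < 40, SOR > 3, MQRankSum < −12.5 or
ReadPosRankSum < −8 (absent fields pass, the GATK VariantFiltration
convention).  The depth band fails a sample strictly below mean/3 or
strictly above 3 × mean, applied to all three trio members.  Inheritance
classification is full-genotype multiset equality: F1 equal to both
parents → shared, to exactly one → inherited from it, to neither → de
novo; any missing genotype → unclassified.  This is deliberately *not*
Mendelian-transmission consistency — a het F1 from hom-ref × hom-alt
parents is de novo under this rule although Mendelian-consistent; such
sites carry a `mendelian_consistent` flag for transparency.  Multiallelic
records are decomposed per alternate allele, folding other alternates
onto the reference.  Allele-frequency spectra use right-closed bins and
report the fraction of sites with AF > 0.9; the M/S ratio is
missense-class over synonymous-class counts from the annotation field,
undefined (reported, not raised) without synonymous sites.

## Expression inheritance modes

With LP/HP the lower/higher parental means and MP = (P1 + P2)/2, three
directional calls (F1 vs HP, LP, MP) yield the seven modes: POD (above
HP), NOD (below LP), PD (above MP, at HP), ND (below MP, at LP), PPD
(between MP and HP), NPD (between LP and MP), A (at MP, between the
parents), else NC.  Overdominance is evaluated first, so a POD gene that
is also above MP is not shadowed by PD.  The significance test is a Welch
two-sided t-test on log2(TPM + 1) at α = 0.05 (the upstream study does
not name its test; this is a documented stand-in and configurable).  The
MP comparison uses the pseudo-sample of per-replicate-index parental
averages; with unequal replicate counts the longer parent is truncated to
the common count, keeping the procedure deterministic.  Genes below 1
mean TPM in all groups are left NC (noise floor).  The DE-retention
filter keeps genes significant against at least one parent after
Benjamini–Hochberg adjustment within each comparison and a 2-fold
change on the (mean + 1) scale.  HP/LP/MP are label-free, so swapping P1
and P2 cannot change a call.

## Synthetic data

The generators plant known truth for every stage and are byte-identical
given (parameters, seed).  Class counts use deterministic
largest-remainder allocation, not multinomial draws, so planted
compositions are exact.

- **Gene trees**: each family starts as a copy of the species tree; a
  planted duplication copies the subtree at the chosen node, pruning the
  second copy per the requested class.  Lineage loss (optional) removes
  leaves *inside duplicate clades only*, keeping the backbone intact so
  truth replay is exact: each event's survival (copies still sharing ≥ 2
  species), realized class and realized placement are recomputed from the
  loss draws and written into the truth record.  Supports are 100 unless
  explicitly degraded.
- **Codon pairs**: at most one substitution per codon and no stops
  created, so planted synonymous/nonsynonymous counts are exactly what
  pathway counting must return; multi-hit pathway averaging is exercised
  separately by randomized multi-hit pairs against a brute-force
  enumerator.
- **Trios**: biallelic sites with genotype patterns realizing each class,
  Poisson(mean depth) per-sample depths, INFO fields inside the filter
  pass region, optional genotype masking replayed into the truth.
- **Expression**: parents separated by a fold factor (high parent
  randomized), F1 mean placed per mode (POD/NOD a further fold beyond
  HP/LP; PPD/NPD halfway between MP and HP/LP), mean-preserving lognormal
  replicate noise at a given coefficient of variation.

What this does not emulate: real gene trees have estimation error and
incomplete lineage sorting, real variant data have genotyping error
correlated with depth, and real expression counts have gene-length and
library-composition effects plus non-lognormal dispersion.  Passing the
planted-recovery tests therefore demonstrates correctness of the
*classifiers and counting machinery*, not robustness to inference noise
in real data.

## Problem sizes and verification

The test suite verifies the reconciliation pipeline against a brute-force
oracle that enumerates every rooting: exhaustively over all unrooted
topologies *and* species assignments up to 5 leaves on a 4-taxon species
tree (16,128 trees), and over every 6- and 7-leaf topology with seeded
random assignments; the NG86 engine is checked against an independent
pathway enumerator on 500 random pairs (tolerance 1e-9) and
cross-checked against Biopython's NG86 on single-hit pairs.  The
acceptance script (`scripts/acceptance.py`) replants the study-condition
topology mix (96.46/2.89/0.65% over 1383 one-event families), a
10,000-site trio at composition 0.4/0.3/0.2/0.1, and a 2,000-gene
expression panel with 25% additive genes at fold 4, 6 replicates, 10% cv,
and reports the recovered quantities.

## Known limitations

- The min-(duplication + loss) rooting is a principled stand-in for the
  undocumented rooting mode of the reference duplication-calling tool;
  rootings on real trees may differ where several branches tie.
- Gap/stop handling in other Ka/Ks implementations varies; small numeric
  differences against them are expected and only the pathway-enumeration
  oracle is treated as ground truth.
- The chi-square test is asymptotic; use larger windows or pooled tables
  rather than trusting it on tables with expected counts below ~5.
- No attempt is made to infer gene trees, call variants from reads or
  quantify expression; those stages are consumed as inputs.
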