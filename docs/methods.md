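# Methods

## The inference problem

Two tandem paralogs (an inhibitory/activating receptor pair such as
Siglec-11/Siglec-16) that arose by duplication before the radiation of the
species under study will, absent gene conversion, produce a *locus-wise*
phylogeny: all copies of locus 1 form a clade, all copies of locus 2 form a
clade, and the paralog pair of any one species is separated by twice the
duplication age.  A gene-conversion event copies a tract from one locus
onto the other, resetting the pair's divergence inside the tract to zero at
the event time.  Everything this package computes follows from that
contrast: high sequence identity inside the tract, within-species paralog
clades in trees built from it, and a tract divergence `d` that dates the
event as `T = d / (2 lambda)`.

## Substitution model and distances

All distance work uses Jukes–Cantor (JC69): equal base frequencies, a
single rate, `d = -(3/4) ln(1 - 4p/3)` with sampling variance
`p(1-p) / (L (1 - 4p/3)^2)`, where `p` is the mismatch proportion over the
`L` columns comparable after pairwise deletion (columns with a gap or N in
either sequence are dropped for that pair).  Distances with `p >= 0.75` are
reported as saturated and refused.  Kimura two-parameter distances are
available by flag; p-distances likewise.  JC69 is deliberately the default:
the analyses operate on closely related sequences (within-genus to
within-superfamily divergences of a few percent) where multiple-hit
correction is mild and model choice immaterial.

## Neighbor joining and bootstrap

NJ follows Saitou & Nei: join the pair minimizing
`Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`; branch lengths from
the standard rate-corrected formulas; the last three clusters close an
unrooted trifurcation by the three-point formulas.  Ties in Q are broken by
the lexicographically smallest (minimum member name) cluster pair, making
the output deterministic under taxon reordering.  Negative branch-length
estimates are clamped to zero with the deficit transferred to the sister
branch (disable with `clamp_negative=False`).  On additive matrices NJ
returns the generating tree with exact lengths; the test suite verifies
this exhaustively for all 15 five-taxon topologies.

Bootstrap supports resample alignment columns with replacement (multinomial
weights), rebuild the NJ tree per replicate, and annotate each internal
bipartition of the point-estimate tree with its replicate frequency x 100.
Replicates producing a saturated distance are dropped and counted; a
warning fires when more than 10% drop.  Default 1000 replicates.

## Conversion calls

For each species with both loci, the two paralog leaves are tested as an
unrooted bipartition of (a) the candidate-region tree and (b) the
control-region tree.  `converted = clade in (a) and not clade in (b)`; the
decisive bipartition's bootstrap support is reported.  Species with a
single locus (the duplication postdates their split, or one copy was lost)
are reported not-applicable.  No outgroup rooting is needed; the test is
purely on bipartitions.

## Dating

`T = d / (2 lambda)` with `lambda = (1.4 +/- 0.1) x 10^-9`
substitutions/site/year by default (the neutral rate of the genomic
neighborhood of these loci; configurable).  The standard error combines the
JC distance variance and the rate uncertainty to first order:
`T_se^2 = var(d) / (4 lambda^2) + d^2 se(lambda)^2 / (4 lambda^4)`;
both components are reported separately since conventions for the second
term vary.  Rate constancy between the two paralogs is checked first with
Tajima's 1D relative-rate test against an outgroup: `m1` = sites where only
sequence A differs, `m2` = sites where only B differs,
`chi2 = (m1-m2)^2/(m1+m2)` with 1 df; sites where all three sequences
differ are uninformative.  With `m1 + m2 = 0` the test is undefined and
reported as "no informative sites".  Dating uses the noncoding part of the
converted tract so that selection on the exons cannot bias `d`.

## Relaxed-constraint analysis

Site classes: coding codon positions 1–2 are treated as the nonsynonymous
class and position 3 as the synonymous class; everything outside coding
intervals is intronic/noncoding.  This per-site-class approximation matches
the simulator's rate model (below) and the distance-based character of the
whole analysis; `classify_sites` additionally produces exact Nei–Gojobori
fractional S/N site counts per sequence pair (f/3-weighted site counting
averaged over the two sequences, multi-hit codons averaged over minimal
pathways, pathways through stops excluded, changes to stops counted
nonsynonymous) for descriptive dN/dS-style reporting.

Per class, a JC distance matrix feeds an unweighted OLS fit of branch
lengths on the fixed reference topology (in practice the intron tree, per
the region's own data, or a user-supplied Newick): `min ||Xb - d||^2`
where `X` is the 0/1 path-incidence matrix over the unrooted edges (a
rooted binary input topology has its two root edges merged into the single
unrooted edge they represent).  Negative estimates are retained but
flagged.  Weighted LS (1/variance) is available by flag.

The neutral expectation per branch is the unweighted mean of the synonymous
and intronic OLS lengths (a site-count-weighted mean is available by flag).
The test statistic per branch is `b_nonsyn - b_neutral`; its SE comes from
a nonparametric bootstrap over columns within each of the three partitions
(default 1000 resamples, seeded), giving `Z` and a two-sided normal
p-value.  The nonsyn/neutral ratio is reported descriptively alongside.
Calibration on null simulations (all classes neutral) puts the per-branch
rejection rate at the nominal 0.02 level, and a 3x rate increase on one
branch (2-kb coding + 1-kb intron) is detected in well over 80% of
replicates.

## Glycan-array clustering

Binding matrices (rows = Siglec-Fc samples, columns = glycans, values =
background-subtracted RFU) are normalized per row by the root mean square
(`x / sqrt(mean(x^2))`), so each sample's profile shape rather than its
magnitude drives clustering; the axis is a flag since either convention is
defensible.  Clustering is agglomerative complete linkage on Euclidean
distances via scipy (`hclust`-equivalent); merge heights are monotone
nondecreasing by construction and asserted on every run.  Determinism
follows from the input order; ties (exactly equal inter-cluster distances)
are resolved by the library's fixed scan order.  `comembership_check` asks
whether a named group (e.g. the six Siglec-11/16 samples) appears as an
exact cluster of the merge sequence and returns the size of the smallest
containing cluster.

## The simulator

`simulate_history` evolves one ancestral sequence (i.i.d. uniform bases)
that duplicates into two loci at `duplication_time` and then descends a
dated species tree (Newick, branch lengths in years; default a five-species
catarrhine tree with splits at 6.5, 9, 18 and 30 MYA and duplication at 40
MYA).  Substitutions are Jukes–Cantor events drawn as Poisson counts per
branch segment and site class, at rate `lambda` for noncoding and
synonymous-class sites and `lambda x omega(branch, locus)` for
nonsynonymous-class sites; multiple hits per site are allowed.  Each
conversion event instantaneously copies the donor tract onto the acceptor
at its time on its branch (complete, no repair mosaics — fragmented
conversion is represented as several short tracts).  Output is gap-free;
indels and within-species polymorphism are out of scope, as is GC-biased
conversion.  Everything is deterministic given the seed, and the
`TruthRecord` carries realized event counts per branch/locus/class, the
applied conversions and the per-species paralog divergence time implied by
the most recent conversion on its lineage.

Default study conditions used by the simulation studies (and hence the
acceptance script): 2-kb conversion tracts, ~800-bp noncoding dating
regions, 2-kb coding + 1-kb intron constraint regions,
`lambda = 1.4e-9/site/year`, conversion ages of a few MYR against a 40-MYR
duplication.  What passing these studies shows — and what it does not —
follows from the generator: real data add alignment gaps, rate
heterogeneity among sites, base-composition bias, polymorphism and
fragmented tracts, none of which are simulated; the studies validate the
estimators' algebra and calibration under the stated model, not robustness
to all of those complications.

## Numerical and design choices

- Coordinates are 0-based half-open internally, 1-based inclusive in
  reports.
- Identity scan: columns gapped in either sequence are stripped before
  windowing (gaps-as-mismatch available by flag); segmentation merges
  high-identity runs separated by less than one window and drops runs
  shorter than `min_len` (default threshold 0.97, min_len 500 bp, both
  settable — tract boundaries in real data are judgment calls).
- NJ tie-break and negative-branch policy are stated above; no claim of
  bit-level agreement with any particular desktop phylogenetics tool is
  made.
- Bootstrap SE in the constraint test uses 200 resamples inside the
  large replicate-count calibration studies (a runtime/precision tradeoff;
  the user-facing default stays at 1000).
- Degenerate inputs fail loudly: saturated distances, empty partitions,
  all-zero RFU vectors, rank-deficient incidence matrices, windows longer
  than the usable sequence.
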