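# Methods

`mitonuc` implements a complete mitonuclear-coevolution analysis: lineage
rate estimation on a fixed species topology, background-normalized
evolutionary rate covariation (ERC), NG86 dN/dS group comparisons,
structure-derived mitonuclear contact pairs, and a substitution-ordering
test of the nuclear compensation hypothesis. A synthetic-data generator
with fully logged ground truth exercises every stage.

## The generative model

Sequences evolve down a rooted tree. Per-branch rate scalars are
log-normal: the log scalars of the mitochondrial (mt) and
nuclear-mt-targeted (N-mt) gene sets are bivariate normal with mean 0,
per-margin standard deviation `scalar_sd` (default 0.5, giving
several-fold rate differences between the fastest and slowest lineages,
in line with the spread reported for mammalian mt proteins) and
correlation `rate_coupling_rho` (default 0.9) — the coevolution signal
ERC is meant to detect. Background "random ortholog" sets are modeled as
concatenations of `n_background_genes` (default 15) genes with
independent lineage effects, so their effective per-branch scalar is an
average with correspondingly smaller spread.

The amino-acid process is the 20-state equal-exchangeability (Poisson)
model, chosen over an empirical matrix because it is analytically
checkable: `P(same | t) = 1/20 + (19/20) e^{-20t/19}` with branch length
`t` in expected substitutions per site. A symmetric 20x20 exchangeability
hook is provided for users wanting LG/mtART-like behavior. The codon
process is GY-style with uniform codon frequencies, transition/
transversion ratio `kappa` (default 2) and per-gene-set `omega`
(defaults: mt 0.1, N-mt 0.2 — purifying selection, weaker on N-mt),
rescaled to unit expected substitutions per codon site; proposals to stop
codons are excluded. Every simulated substitution is logged with its
branch, so tip sequences are exactly reproducible by replaying the event
log, and all randomness derives from one integer seed through named
sub-streams.

`base_rate` defaults to 0.02 expected substitutions per site per unit
branch length. On the default 30–60-taxon pure-birth trees this gives
roughly 0.3–0.6 changes per site across the whole tree — the sparse,
low-homoplasy regime in which conserved-protein alignments live and in
which parsimony-based substitution mapping is reliable. At several-fold
higher rates, compensatory changes occur in parallel in sibling subtrees
and parsimony merges them onto the parent branch, degrading ordering
classification; we verified that the classifier reproduces the true
labels exactly when given the true events, so that degradation is purely
a reconstruction property.

Compensatory contact pairs: each pair is one mt column and one N-mt
column. The designated trigger site substitutes at the baseline rate;
once it has substituted on a lineage, the partner's rate on descendant
branches is multiplied by `compensation_boost_beta` (default 20) until
the partner substitutes. The boost starts on descendant branches rather
than within the triggering branch, and it is a rate boost rather than a
deterministic fix, so both mt-first and N-mt-first outcomes occur and
classifier error behavior is testable. True pair labels are computed
from the event log with the same path-majority rule the classifier uses
(plus an `unresolved` value when no root-to-tip path carries events at
both sites or the vote ties).

## Rate estimation and ERC

Branch lengths are estimated on the fixed topology by maximizing the
pruning likelihood under Poisson (optionally +Γ4: four equal-probability
discrete-gamma categories at quantile midpoints, rescaled to mean 1) via
per-branch bounded Brent search in rounds (start 0.1, bounds [0, 10]
substitutions/site, convergence when a round improves log-likelihood by
less than `tol`, default 1e-6). Gaps and ambiguity codes are missing
data. Fitted lengths below 1e-5 are reported as 0. Per-taxon rates are
root-to-tip path sums. Concatenation pads missing taxa with gaps and
drops taxa padded beyond a configurable fraction (default 50%). An
outgroup may root the tree and be dropped (`Phylogeny.drop_tip`) before
correlation.

ERC divides each target's root-to-tip rates by a background set's rates,
taxon-wise. The random orthologs are split by seeded shuffle into two
halves; Nrand1 normalizes mt and Nrand2 normalizes every nuclear target,
so the two sides of a correlation never share their background.
Correlation is Spearman with average ranks. Differences between two
correlations are tested by resampling taxa jointly with replacement
(10,000 replicates by default) and forming a BCa interval (bias
correction from the fraction of replicates below the point estimate;
acceleration from a leave-one-taxon-out jackknife); replicates with
constant ranks are dropped and counted, with more than 10% dropped
treated as an error. A difference is called robust when the 95% interval
excludes zero. Lineage-restricted ERC (`lineage_subset_erc`) applies a
taxon filter before correlating and refuses subsets below 5 taxa.

Calibration caveat: the null/alternative calibration of ERC (|r_s| <=
0.3 under no coupling, r_s >= 0.5 under strong coupling, in >=90% of
100 seeded 60-taxon runs) is defined on the star phylogeny, i.e. under
exchangeable lineages, which is the regime where the Spearman null
sampling distribution applies. On deep pure-birth trees shared ancestry
inflates the null spread of r_s roughly twofold (about 12 effective
lineages out of 60 in our measurements) — exactly the concern that
motivates the phylogenetically corrected correlation. That correction is
provided as Felsenstein independent contrasts with a through-origin
Pearson correlation; it is this package's own definition of a
phylogenetic ERC, a documented substitution for less fully specified
phylogenetic correlation tests. Passing calibration on the star design
therefore demonstrates the statistics are correct under exchangeability,
not that deep-tree autocorrelation is harmless; users of real data
should consult the PIC variant.

## dN/dS

Per-gene dN/dS uses Nei–Gojobori (1986) counting: fractional
synonymous/nonsynonymous site counts over each codon's nine
single-nucleotide neighbors (mutations to stops excluded from the
per-position denominator, so syn + nonsyn = 3 per codon), differences
averaged over minimal mutational pathways with stop-passing pathways
excluded, and Jukes–Cantor correction `d = -(3/4) ln(1 - 4p/3)`.
Proportions at or beyond 3/4 are saturated: the pair is excluded and
counted, never truncated. A gene's dN and dS are means over unordered
taxon pairs and omega is the ratio of those means (more stable than a
mean of per-pair ratios when per-pair dS is small). mt genes use the
vertebrate mitochondrial code, nuclear genes the standard code. This
counting estimator is a deliberate stand-in for ML codon fitting; it is
self-contained and oracle-checkable, and simulations show it recovers
omega within about +-0.05 at 1,000 codons and 20 taxa when the generator
matches its no-ts/tv-bias assumption (kappa = 1), with the expected mild
downward bias but preserved ordering at kappa = 2. Group contrasts are
one-way ANOVA with Tukey HSD adjusted pairwise comparisons; the
contact-fraction trend is ordinary least squares of omega on the
per-gene fraction of contact residues. An optional branch-wise mode
(`branchwise_dnds`) sums NG86 differences over reconstructed
ancestor→descendant changes instead of taxon pairs; it is approximate
(parsimony undercounts multiple hits) and intended for saturation-prone
data, recovering the selective regime rather than the exact omega.

## Contacts

Contact pairs come from a PDB structure with a user-supplied chain→gene
and gene→genome map. The primary criterion is minimum heavy-atom
Euclidean distance <= 5.0 Å, boundary inclusive; an optional
van-der-Waals mode computes `overlap = r_i + r_j - d` with a bundled
radius table for users wanting the overlap >= -1 Å convention (a 1 Å gap
allowance). Hydrogens are ignored and the highest-occupancy altloc
conformer is kept. Only inter-genome pairs are reported. Residues map to
alignment columns through a global pairwise alignment (match 1, mismatch
-1, gap -2) of the chain sequence against the reference taxon's ungapped
row; below 50% identity the mapping refuses, since that indicates a
wrong chain/gene pairing. Author residue numbering and 1-based columns
are used in all outputs.

## Ordering

Ancestral states default to two-pass Fitch parsimony with a
deterministic tie-break (keep the parent's chosen state when it is in
the node's optimal set, else the lexicographically smallest member;
root: lexicographically smallest). Determinism is required for
reproducibility; marginal ML under the Poisson model is available as a
sensitivity option. A substitution is an event on the branch where
parent and child states differ, both non-missing. For each contact pair,
every root-to-tip path carrying at least one event at each partner site
votes by comparing the shallowest event per side (branch depth counts
edges from the root); the majority wins, equal depths on one branch give
`same_branch`, and ties or no qualifying path give `unresolved`. Branch
separation is the depth difference (adjacent = 1); a classified pair is
`close` at separation 1 or 2 — on a shared path the deeper branch
necessarily lies in the clade subtended by the shallower one, so the
monophyly condition is implied. `same_branch` pairs are tabulated
separately and excluded from the ordering chi-square. Lineage-restricted
analyses filter the voting paths to a named tip set.

The equal-ordering test is a one-degree-of-freedom goodness-of-fit
chi-square of the (mt-first, N-mt-first) counts against 50:50.
Enrichment of mt-first ordering in a restricted versus broader dataset
uses Fisher's exact test with the conditional-MLE odds ratio and its
exact confidence interval; with a zero margin the odds ratio is reported
as undefined.

## Selection and functional nodal mutations

Site-level positive selection is a counting (SLAC-like) test:
substitutions at a codon site are replayed over the reconstruction
(optionally restricted to a foreground set of subtrees), split into
synonymous/nonsynonymous (pathway-averaged for multi-nucleotide codon
changes), and compared against the neutral expectation from the site's
branch-length-weighted NG86 opportunities by a one-sided binomial tail
(continuous in the fractional counts via the regularized incomplete
beta). Two reporting tiers: `selected` at alpha = 0.05 and `stringent`
at 0.01, both configurable. The binomial needs several changes at a site
before it can reject at all, so meaningful power requires either large
trees or high per-site divergence; this is an inherent property of
counting tests and is documented rather than hidden. No categorical
agreement with likelihood branch-site site lists is claimed.

The functional-nodal-mutation flag is reduced to the frequency component
of predictive deleteriousness models — an event is "frequency-FNM" when
its derived residue occurs below a threshold proportion (default 0.05)
among the non-gap residues of its column. The structural-stability
component would require per-species structures and is out of scope.

## What the synthetic data does and does not show

The generator emulates correlated lineage rates, gene-set-specific
omega, and triggered compensation with known ordering truth. It does not
simulate indels, among-site rate variation beyond gene-set scalars,
realistic base/amino-acid composition, or structure-linked site effects.
Passing tests therefore demonstrate that each stage measures what it
claims under the stated model — not that the biological conclusions of
any particular real dataset follow.

## Problem sizes and numerical choices

Test and acceptance runs use 16–60 taxa, 100–1,000 sites or codons,
2,000–10,000 bootstrap replicates, and 5–200 seeded repetitions per
property — sizes at which every Monte-Carlo band in the suite is stable.
Ties in Spearman use average ranks; degenerate inputs (constant ranks,
zero backgrounds, all-gap columns, saturated pairs, zero-margin tables)
are reported explicitly rather than coerced; zero-length branches are
floored at 1e-8 only inside independent contrasts, with a warning. The
pipeline is a pure function of (inputs, config, seed): reruns are
diff-identical, and every report number is re-derivable from the stage
TSVs written next to it.
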