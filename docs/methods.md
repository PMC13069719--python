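# Methods

`methvar` catalogues CpG probes on EPIC-like methylation arrays whose beta
values (methylated fraction, in [0, 1]) are unusually variable (VMPs) or
unusually stable (SMPs) across individuals in whole blood, and then asks
*why*: cell composition, genetic control (mQTLs) and 3D genome context,
bimodal epiallele structure, and coupling to gene-expression variability.
This note documents the models, the conventions the implementation fixes
where the procedure is underdetermined, what the synthetic data do and do
not emulate, and known limitations.

## Variability calling

For each cohort (discovery, validation) and each of `n_repeats = 10`
repeats, `floor(0.10 * n_samples)` individuals are removed uniformly at
random, the per-probe sample SD (ddof = 1, beta scale) is computed on the
remainder, and the `floor(q * P)` probes of highest SD (`q = 0.10`) are
selected as variable, the same number of lowest SD as stable. A probe is a
VMP/SMP only if selected in **all** repeats of **both** cohorts. The
repeated downsampling suppresses selections driven by outlier individuals;
the two-cohort intersection suppresses cohort-specific artefacts.

Conventions fixed here (the procedure is silent on them):

* `floor()` for both the drop count and the selection size;
* the SD threshold is recomputed within every downsampled replicate;
* ties at the selection boundary are broken towards the lexicographically
  smaller probe id, and the stable set is drawn from the non-variable
  remainder so the two sets are disjoint even under exact ties;
* downsampling draws are keyed to *sorted sample ids* with per-repeat seed
  `rng_seed + repeat`, so results are invariant to column order;
* probes with more than 5% missing betas are dropped up front; SDs are
  otherwise computed over available samples (arrays preprocessed upstream
  are normally complete).

SD is computed on the beta scale, not M-values: the screens and the
epiallele window are defined on betas.

## Cell-composition correction

Whole blood is a cell mixture; six estimated cell-type proportions (CD8T,
CD4T, NK, B, Mono, Gran) sum to ~1, so only five are linearly independent.
Each probe is regressed by OLS on an intercept plus five proportions, with
NK — the smallest fraction — excluded as the dependent remainder (the
excluded type is configurable). The corrected value is
`intercept + residual`, which keeps corrected data on a beta-like scale
but is deliberately **not clipped** to [0, 1]; the out-of-range rate is
logged. Because the intercept is the extrapolation to zero proportions of
the included types, the corrected mean does not exactly equal the raw mean;
with population-scale sample sizes the shift is negligible, and the exact
identities that do hold (zero residual for an exactly linear probe,
residual orthogonality to every included proportion, corrected variance
<= raw variance) are enforced by tests. The corrected catalogue reuses the
raw catalogue's seeds so differences reflect correction, not resampling.

## Genomic-context enrichment

For a probe set against the array background (all analyzable probes in the
manifest), enrichment per annotation is `log2((n_in_set/n_set) /
(n_in_bg/n_bg))`, reported as undefined (NaN) when either fraction is zero.
Significance is a two-sided Fisher exact test whose background column
*excludes* the test set (disjoint columns). Island relation (island, shore,
shelf, open sea) is exclusive; feature annotations (promoter, exon, intron,
5'UTR, 3'UTR, enhancer, intergenic, TE) can overlap, and a probe counts
once in every feature it carries. The imprinted-region overlap additionally
gets a permutation p-value: `n_reps = 1000` random same-size draws from the
background, `p = (1 + #{overlap >= observed}) / (n_reps + 1)`. Draws are
unconstrained (chromosome composition is not preserved). Note the add-one
permutation p on a discrete overlap count is conservative and only
near-uniform under the null; calibration checks use configurations where
the overlap lattice is fine.

Housekeeping labelling: a gene is housekeeping iff its within-tissue
percentile rank (average ranks on ties) is in the top 40% in *every*
tissue of a genes x tissues expression matrix; all others are
tissue-specific. A constant tissue column ties all genes at the average
rank, which passes that tissue.

## mQTL linkage and 3D co-occupancy

A SNP-CpG pair is **cis** iff both are on the same chromosome and
`|snp_pos - cpg_pos| <= 500` bp — a deliberately small, nucleosome-scale
window aimed at effects of sequence variation in or immediately flanking
the probe — and **trans** otherwise (including different chromosomes,
where distance is undefined). CpGs with both kinds of partner are reported
as a separate cis-and-trans class rather than folded into either margin.

Positions are 1-based; TADs (BED) and loop anchors (BEDPE) are 0-based
half-open, so a position exactly at a TAD start is inside and at the end is
outside. TADs must be non-overlapping per chromosome (validated). A pair is
*same-TAD* iff one TAD contains both positions, and *loop-connected* iff
some loop has the SNP inside one anchor and the CpG inside the other (both
in the same single anchor does not count). Co-occupancy enrichment of a
pair set is a two-sided Fisher test against the background of all trans
mQTL pairs.

## Epiallele screen and the dip statistic

Candidates are VMPs with pooled (discovery + validation) mean beta in
[0.40, 0.60], inclusive at both ends. Each candidate's betas across
individuals are tested for unimodality with Hartigan's dip statistic: the
smallest sup-norm distance between the empirical CDF and any unimodal CDF
(nondecreasing, convex up to a mode, concave after, at most one atom at the
mode). The dip lies in [1/(2n), 0.25]; the maximum is attained by two equal
point masses.

The implementation is from scratch: bisection on the band half-width with a
feasibility test that reduces the convex/concave fit to conditions on one
extremal line per data block (max-slope line from the block's post-step
count to the convex hull of earlier pre-step counts, and its mirror image),
plus a cross condition that couples the two sides through the mode and is
minimised over the mode position as a convex piecewise-linear function.
Prefix checks use a Li Chao max-of-lines tree; the numerical core is
numba-compiled with a pure-Python fallback. The test suite verifies exact
(1e-10) agreement with an independent brute-force minimiser over unimodal
CDFs on exhaustive small-sample batteries, plus closed-form anchors and
permutation/location/scale invariance. The dip is **not** invariant under
non-affine monotone transforms — it depends on the spacings of the data,
not only their ranks (e.g. [0, .5, 1, 10, 10.5, 11] has dip 0.225 while its
monotone image [1..6] has dip 1/12).

P-values are Monte Carlo against the uniform null — the asymptotically
least favourable unimodal distribution, making the test conservative for
other unimodal nulls: `B = 2000` uniform samples of the same size,
`p = (1 + #{null dip >= observed}) / (B + 1)`. Null tables are cached per
(n, B, seed). A probe is a putative epiallele iff it is a candidate and
`p < 0.05` (no multiplicity correction, mirroring the screening intent); a
Benjamini-Hochberg column is emitted alongside for users who want it.
Constant candidates are reported as degenerate with the minimal dip, never
flagged. Whether the mean window uses pooled or per-cohort samples is a
free choice; pooling is the default and per-cohort screening is available
by passing a single matrix.

## Expression integration

*Variation vs variation* (cohorts need not share samples): per probe-gene
pair, the probe's methylation SD against the target gene's expression CV
(sample SD / mean; genes with non-positive mean are excluded and counted),
correlated with Pearson r and the standard t-based two-sided p, stratified
by feature group. *Level vs level* (matched samples): per pair, Pearson r
of methylation and expression across shared samples (>= 3 required),
summarised per feature group by the mean pair r. Probes map to the
manifest's gene link; multi-gene entries take the first listed; unmapped
probes are dropped and counted. Pairs with fewer than 3 observations or a
degenerate axis report r as undefined.

## Synthetic data

The generator emulates the structure the pipeline must detect, with
defaults chosen as a plausible population whole-blood operating point:

* probe classes, mixed 15/15/50/2/10/8 % (stable low / stable high /
  variable unimodal / bimodal / cell-driven / mQTL-driven):
  stable probes at means 0.05/0.95 with central concentration 200;
  variable unimodal probes with means uniform in [0.40, 0.60], central
  concentration 40; epiallele-like two-component mixtures at modes
  0.25/0.75, weight 0.5, component concentration 50; cell-driven probes
  at baseline 0.05 + effect x one included cell proportion (central
  effect 0.80); mQTL-driven probes at baseline 0.25 + effect per minor
  allele (central effect 0.10), Hardy-Weinberg genotypes at MAF 0.30;
* heterogeneity, so that SD-decile selection behaves as on a real array
  rather than on interchangeable probes: per-probe concentration factors
  are log-uniform (stable x0.75-8, variable x1.5-8) and per-probe effect
  sizes uniform (cell x0.5-1.2, mQTL x0.4-1.6 of the central effect),
  giving a long tail of ultra-stable probes and a smooth crossing of the
  variable-decile boundary by genotype- and cell-driven probes;
* all betas drawn from mean/concentration-parameterised beta distributions;
  out-of-range shifted means are clipped (rate logged, < 1% at defaults);
* cell proportions from a Dirichlet around realistic blood means
  (Gran 0.55, CD4T 0.16, CD8T 0.10, B 0.08, Mono 0.07, NK 0.04) at
  concentration 60, matching the several-percent interindividual spread of
  granulocyte fractions; cell-driven probes track one of the five
  proportions included in the correction model;
* a manifest whose island/feature probabilities depend on the class
  (variable probes preferentially at shores and enhancers, stable probes at
  islands and promoters; imprinted flags enriched among variable classes,
  non-CpG flags among stable ones), 22 autosomes tiled by 500 kb TADs with
  100 kb gaps and long-range loops with 10 kb anchors;
* mQTL SNP placement controlling the cis share (default 0.25), the
  same-TAD share of trans pairs (default 0.90) and the loop-connected share
  (default 0.05); a fraction of CpGs (0.15) gets a second distal SNP so the
  cis-and-trans class is populated;
* expression over the discovery samples: per-gene CV targets coupled to the
  realized methylation SD of the gene's probe through a Gaussian copula on
  ranks at `expr_coupling_rho = 0.6`, realised as gamma samples
  (shape 1/CV^2); genes of 5'UTR-annotated bimodal probes instead get
  expression linear-decreasing in the probe's betas (planted negative
  level-coupling) and are excluded from the copula.

Two cohorts are independent draws from one design; all randomness derives
from `rng_seed` through named substreams, so identical designs give
byte-identical bundles.

What the generator does **not** emulate — and hence what green tests do not
establish about real arrays: probe-level technical noise models and batch
or chip effects, linkage disequilibrium among SNPs, spatial autocorrelation
of methylation along the genome, realistic TAD/loop size distributions, and
cross-hybridising or polymorphic probes. Recovery rates measured here are
upper bounds on what identical settings would achieve on real data. Because
the planted Pearson coupling passes through rank scores, the recovered r
slightly undershoots the nominal rho when the SD distribution is far from
Gaussian (mixed-class designs); recovery checks therefore use single-class
designs.

## Numerical and testing choices

* Dip bisection runs to ~1e-13 relative band precision; feasibility
  comparisons use a 1e-12 absolute slack in count units. Null tables make
  the Monte-Carlo p deterministic given (n, B, seed).
* Problem sizes in the acceptance checks: caller recovery on 2,000 probes x
  400+400 samples; dip/oracle agreement exhaustively at n <= 12; dip
  calibration with 2,000 uniform trials at n = 500 against B = 2000 null
  tables drawn from a small pool of seeds (sharing tables across trials
  keeps each p-value an honest B = 2000 Monte-Carlo p while bounding the
  compute; the pool size keeps the between-table contribution to the
  rejection-rate variance small).
* The Fisher implementation is checked against full hypergeometric
  enumeration in exact integer arithmetic over all 2x2 tables with row
  margins <= 20.

## Limitations

The catalogue thresholds (top/bottom decile) are relative, so the VMP/SMP
counts scale with the array and cohort at hand rather than transferring
across studies. The cis window of 500 bp is intentionally much smaller than
conventional cis definitions (~1 Mb); both conventions can be had by
changing `cis_window_bp`. The dip screen tests unimodality, not
two-component structure specifically; strongly skewed but unimodal
distributions are correctly not flagged, while three-state epialleles would
be. Permutation p-values are bounded below by 1/(n_reps + 1).
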