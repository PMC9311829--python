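# Methods

## Superimposition

Configurations are 2-D landmark sets.  Each is centered and scaled to
unit centroid size (CS = √Σ‖xᵢ − x̄‖²); generalized Procrustes
analysis (GPA) then iterates optimal rotation to a consensus that is
re-estimated as the rescaled mean of the aligned sample.  The
rotation is solved in closed form (complex cross-product phase,
equivalent to the 2-D SVD solution with a positive-determinant
constraint); reflections are never introduced implicitly.  The
initial consensus is the first configuration; convergence is declared
when the consensus RMS change drops below 1e-10 (200 iterations
maximum, non-convergence flagged rather than raised).  The tolerance
sits several orders below landmark measurement noise and below the
1e-8 level at which alignment invariance is asserted.  The converged
solution is only defined up to a global rotation, so it is put in a
canonical frame: the consensus's principal axes are rotated onto the
coordinate axes, with the of-two-candidates rotation chosen so the
landmark with the largest |x| has positive x.  This makes GPA output
a pure function of shape — invariant to how specimens were
positioned, scaled, or rotated when photographed.  The
canonicalization is unstable only for consensus shapes with an
(unrealistic) isotropic landmark scatter.

Ordinary Procrustes alignment (`opa_align`) scales the target to the
reference's centroid size and rotates; with both shapes at unit size
the residual is the squared partial Procrustes distance.  The fully
optimal least-squares scale is deliberately not used, so that
`procrustes_distance` is symmetric in its arguments.

## Symmetry decompositions

*Matching symmetry* (wings): left configurations are mirrored about
the y-axis and the whole sample aligned jointly; landmark labels are
homologous across sides, so no relabelling is needed.  Individuals
missing a side are excluded with a warning.

*Object symmetry* (heads): each configuration is paired with a copy
mirrored about the y-axis whose paired landmark labels are swapped
(midline labels fixed), and the doubled sample is aligned jointly.
The symmetric component of a specimen is the mean of original and
mirrored copy, the asymmetric component half their difference.  All
sums of squares from the doubled analysis are divided by two so
tables reflect the real measurement count.

## Procrustes ANOVA

Variance is partitioned Goodall-style on the flattened superimposed
coordinates over the nested design

    location → individual → side (directional asymmetry, DA)
    → side × individual (fluctuating asymmetry, FA)
    → imaging error → digitizing error,

with the last requested stratum as residual.  Sums of squares are
sequential (Type I), computed by orthogonal projection onto the
cumulative design subspaces (group means for the partition strata, a
least-squares fit for the DA stage, whose side main effect is crossed
with individuals).  Additivity — effect SS summing exactly to the
total SS — therefore holds by construction, also under mild
imbalance, where a warning is attached.  A `directional_asymmetry`
row is always emitted: without the side main effect the decomposition
would not be additive, and removing DA before FA scoring is standard
practice even when DA is negligible.

Degrees of freedom are the univariate counts times the shape
dimension: 2k − 4 under matching symmetry; under object symmetry with
p landmark pairs and m midline landmarks, the symmetric and
asymmetric subspaces each have dimension 2p + m − 2 (individual- and
location-type effects use the symmetric dimension, DA/FA the
asymmetric one, error strata the full 2k − 4).  The implementation
asserts the two component dimensions sum to 2k − 4.  For the
29-landmark head scheme used throughout (13 pairs + 3 midline points,
a documented convention of this package — the anatomical pairing is
not published), both components have dimension 27.

Each F ratio uses the next stratum down as denominator; the last
stratum carries no F or p.  Under the no-FA null the FA test holds
its nominal size (type-I error within [0.03, 0.07] at α = 0.05 over
2 000 simulations, checked in the suite), and the expected-mean-square
identity (MS_FA − MS_err)/r recovers an injected per-coordinate FA
variance within 15 % at n = 200 individuals and r = 2 digitizing
replicates.

The error study restricts the table to individuals with replicated
imaging/digitizing.  Verdicts: an error stratum is *nonsignificant*
when its F against the next stratum down does not reach α; the
overall pass additionally requires the individual and FA mean squares
to exceed the first error-stratum mean square.  (A nonzero imaging
variance *should* test significant against digitizing noise at these
df — "errors nonsignificant" is a statement about error magnitudes,
not a hoped-for test outcome.)

## FA indices

`fa2(R, L) = (R − L)/((R + L)/2)`, signed right-minus-left,
scale-invariant.  For matching symmetry R and L are the raw side
centroid sizes (replicates averaged); for object symmetry the
centroid sizes of the pairing-defined right and left landmark subsets
— the side "size" of a single structure is not otherwise defined,
and this subset convention is this package's documented choice.
`fa_shape` is the Procrustes distance between an individual's side
configurations after subtracting the sample-mean directional
asymmetry; the signed FA2 keeps its direction.  Which of the two
feeds the linkage models is a configuration switch (`fa_column`);
the battery defaults to |FA2| because a signed index has mean ≈ 0 by
construction and its magnitude is the stress-relevant quantity, and
because the ladder-of-powers re-expression requires positive values.

## Population genetics

He uses the small-sample unbiased correction 2n/(2n − 1) (per-nest
samples are small).  The Hardy–Weinberg test is the exact conditional
test: the p-value is the total Levene/Haldane probability, given the
allele counts, of genotype arrays no more probable than the observed
one; the array space is enumerated exactly when small (recursion with
forced row-ends; node-capped), otherwise a seeded Monte-Carlo
permutation (alleles shuffled into pairs, +1-corrected, B ≥ 10⁴) is
used — MC agrees with enumeration within binomial error on every
enumerable case tested.  Linkage disequilibrium is tested at the
genotypic level (phase is unknown in diploids): a G statistic on the
two-locus genotype contingency table against a permutation null.
Holm's step-down adjustment is applied within each test family.
Missing genotypes are dropped pairwise.

MLH is the heterozygous fraction of typed loci; d² the mean squared
allele difference in repeat units (allele sizes are divided by the
motif length at load; without motif information a motif of 1 is
assumed with a warning).  Both are invariant to locus order and
allele-label shifts.  Group comparisons gate on per-group
Shapiro–Wilk at α = 0.05: Welch t when both groups pass, Mann–Whitney
U otherwise, Holm-corrected across each requested batch.

## Linkage models

Pool expansion assigns each individual its pool's concentration per
analyte; the output records the number of distinct covariate values
because effective replication for the chemical term is at pool level
(with two pools, any two analyte covariates are affine images of each
other, so |t₂| is identical across all analytes — a structural fact
the tests assert, not an artifact).  Models are plain OLS with
HC-free standard errors, matching how such batteries are usually
reported; the pseudo-replication caveat is surfaced, not corrected.
Residuals are checked by a KS test of the standardized residuals
against N(0, 1) (skipped below 10 residuals; conservative because
parameters are estimated).  A response failing the check anywhere in
its block is re-expressed once on Tukey's ladder (λ grid −5…5, step
0.025, chosen by maximal Shapiro–Wilk W; monotone by construction)
and its block re-fit with λ recorded.  Significance stars at
0.05/0.01/0.001.  Rank deficiency (e.g. a single pool) is flagged on
the result with the collinear columns named, never raised.

## Synthetic data

The generator emulates the study structure end to end.  Landmarks:
template shape (unit centroid size) + per-individual deviation
(`sd_individual`) ± antisymmetric deviation shared by the two sides
(`sd_fa`, scaled by 1/√2 under matching symmetry so the
side-by-individual variance component equals sd_fa² per coordinate
exactly; under object symmetry the plain asymmetric projection has
the same property because the doubled analysis counts it on both
copies) ± a fixed directional-asymmetry vector (`sd_da`, default 0)
+ per-photograph (`sd_image`) and per-digitization (`sd_digit`)
noise.  Each photograph gets one random similarity transform;
digitizing replicates share it (they re-measure the same image).
Individual size is log-normal (`sd_size`) with a relative right/left
size asymmetry (`sd_size_fa`) that feeds FA2.  Genotypes: with
probability F both alleles are one identical-by-descent draw, else
two independent draws from the locus frequency spectrum.  Pooled
burdens mirror the published sampling layout (six pools over two
locations and three taxa) with Hg and summed-PCB levels spanning the
printed concentration ranges and a deterministic per-pool congener
profile so the seven analytes are not mutually collinear across the
four ant pools.

Default study conditions reproduce the published sampling sizes:
64 + 4 bumblebees (forewings k = 20, hindwings k = 6), ants 67 + 48
and 49 + 40 over two species (heads k = 29), nests 7/5 and 5/4,
error-study subsets of 20 bumblebees and 40 ants digitized and imaged
twice, 7 bee and 13 ant microsatellite loci, inbreeding F = 0.05
(the study populations were only weakly inbred).  Noise defaults
(sd_individual 0.03, sd_fa 0.01, sd_digit 0.002 in unit-size shape
space) keep the individual ≫ FA ≫ error ordering the study reports.

The positive control couples each pool's FA scales (`sd_fa`,
`sd_size_fa`) to its summed-PCB burden — a variance effect, because
FA is a variance phenomenon, not a mean shift.  The coupling strength
for "strong dependence" is fixed at 5.0 (FA scale growing sixfold
from the cleanest to the most burdened pool): the measured power
curve of the ant battery at α = 0.001 rises from ≈ 0.93 at coupling
3 to 1.00 at 5, so 5.0 is the start of the saturated regime the
control is meant to occupy.

What the generator does *not* emulate: non-Gaussian digitizing
blunders, landmark-specific error covariance, allometry (shape–size
correlation), null alleles and scoring errors, congener-specific
bioaccumulation kinetics, and spatial structure within locations.
Passing tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those real-data
complications.

## Problem sizes and numerics

The suite calibrates the FA test on 2 000 simulated datasets of 30
individuals × 10 landmarks × 2 digitizing runs; variance recovery
uses 200 individuals; the null calibration of the linkage t-test uses
1 000 replicates at the bumblebee sample size (n = 68, two pools);
the positive-control power check runs 20 full synthetic studies.
These sizes give the binomial/EMS estimates a sampling error
comfortably inside the asserted bands.  Permutation p-values use the
+1 correction and are never zero.  Ties in the HWE tail are resolved
with a 1e-9 log-probability tolerance.  Degenerate inputs (coincident
landmarks, constant transforms, single pools, monomorphic loci) are
either flagged results or explicit errors, as documented per
function.
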