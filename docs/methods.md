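# Methods

This note documents the statistical models implemented in `retdiv`, the
synthetic experiment that drives their verification, and the numerical and
design choices a maintainer should know about.

## The experiment being modelled

The package targets a randomized complete block experiment on aggregated
tree retention in clearcut conifer stands: 10 blocks, each containing five
treatments that vary the size, number and placement (riparian vs upland) of
retention patches at a comparable retained-tree density — riparian
aggregated (RA), upland aggregated (UA), split (S), split with created
snags (SS), and dispersed with snags (DS) — plus a rotation-aged unharvested
reference stand in nine blocks. Small mammals are live-trapped on paired
grids (one in each patch, one in the adjacent clearcut; 2x48, 4x24 or 8x12
traps depending on treatment) for four consecutive nights per stand-year
over three summers. Tagged animals are identified individually on
recapture; shrews are not tagged, and every shrew capture is treated as a
new individual.

## Capture cleaning rules

* Shrews with tail length < 42 mm are classified as vagrant shrew
  (`SORVAG`); all other field-ambiguous shrews are pooled into one code
  (`SORSPP`) covering four largely allopatric *Sorex* species. The pooled
  code counts as a single species in richness analyses.
* In the Washington blocks, *Peromyscus* with tail length >= 95 mm are
  Keen's mouse (`PERKEE`), below that the American deer mouse (`PERMAN`);
  in Oregon every deer mouse is `PERMAN`. Boundary values follow the
  printed rules exactly (42 -> pooled; 95 -> Keen's).
* Richness analyses keep species with at least two captured individuals
  study-wide; a configurable exclusion list handles the non-native species
  dropped despite two captures.
* For cover-type-scale abundance tallies, an individual recaptured in both
  the patch and the clearcut of a stand-year is attributed to the cover
  type of its first capture. The source protocol is silent here; first
  capture is our documented choice, and it preserves the invariant that
  cover-type tallies partition the stand-year tally.
* Unsampled trap nights are represented as missing, never as zero, so
  likelihood contributions can skip them.

## Chao1 richness

For a unit with observed richness S_obs, f1 singletons and f2 doubletons:

* classic: S = S_obs + f1^2 / (2 f2) (f2 > 0; falls back to the
  bias-corrected term with a flag when f2 = 0),
* bias-corrected (default): S = S_obs + f1 (f1 - 1) / (2 (f2 + 1)).

The default matches the behaviour of the common richness software family;
the variant is a flag because the source analysis does not name one. No
variance or interval is computed. Estimation happens at two scales —
stand-year, and stand-year by cover type — whose comparison measures
compositional redundancy between patches and clearcuts; Chao1 is not
additive across scales and no ordering between them is asserted.

## Functional richness

Traits are mean body mass (g, untransformed by default; a log10 flag is
available and documented as changing results), diet guild (carnivore /
insectivore / granivore-mycophage) and activity stratum (arboreal /
semi-arboreal / ground / fossorial). Distances are Gower's: the mass
contribution is |dm|/range(mass) with the range taken over the full trait
table (not the community subset), categorical traits contribute 0/1
mismatches, and the three contributions are averaged with equal weight.
Clustering is UPGMA with merge nodes at half the average linkage distance,
giving an ultrametric tree; linkage ties break on the lexicographically
lowest pair of cluster representative labels so topologies are
deterministic. Functional richness of a community is the total branch
length of the subtree spanning its species. The default convention is
root-inclusive (the spanning subtree always reaches the root), matching the
common dendrogram-FD implementations; `root_inclusive=False` measures only
the subtree below the species' most recent common ancestor. Empty and
singleton communities score zero under both conventions.

## Mixed models

Stand-scale species richness (Chao1) and functional richness are Gaussian
responses; cover-type-scale richness is Poisson after rounding Chao1
half-up (4.5 -> 5; the source states only "nearest integer"). Treatments
are dummy-coded with RA as the reference so the intercept is the RA mean —
the source calls its coding "Helmert" but describes and reports
RA-referenced deviations, so deviation coding is what we implement. Year
enters as a centred numeric covariate; week of sampling is available as a
covariate and is dropped from final models by configuration (not automatic
selection) when its interval covers zero. Random intercepts: stand (the
repeated-measures unit) nested in block. The treatment-by-year interaction
model omits the block intercept, which does not converge at this design
size. Vegetation cover groups (fern, forb, grass from cover-class
midpoints 0.5/3/15/37.5/62.5/85/97.5%; shrub from line-intercept
proportions, square-root transformed) are Gaussian with treatment +
cover-type fixed effects and a block intercept.

Estimation delegates to statsmodels: `MixedLM` (REML) for Gaussian
responses, with blocks as independence groups and stands as a variance
component; `PoissonBayesMixedGLM` (MAP with Laplace posterior SDs) for the
Poisson response, whose 95% intervals are normal-approximation posterior
intervals. A response explained perfectly by the fixed effects (zero
residual) is refit by OLS and flagged degenerate; an all-constant
vegetation response is returned flagged rather than raised.

## Community occupancy model

Occurrence is modelled through latent abundance (Royle-Nichols): species i
at subplot-year j has N_ij ~ Poisson(lambda_ij), occupancy
psi = 1 - exp(-lambda), and nightly detection 1 - (1 - r_ij)^N_ij, so
locally abundant species are detected more often without a separate
heterogeneity term. Covariates: grid-location class (clearcut reference,
upland patch, riparian patch, rotation) on log lambda; standardised
sampling week on logit r; a stand random intercept as the only linkage
across years. Species-level parameters are draws from community Normal
distributions, so class effects are estimable by shrinkage even for species
never detected in a class. Priors: community means ~ Normal(0, 2.5^2),
community SDs and the stand SD ~ half-Normal(1) — configurable, since the
source's priors live in supplementary code we do not reproduce.

Latent N is marginalised rather than sampled: the likelihood sums over
N = 0..N_max (default 50) with the Poisson tail mass folded into the top
bin, and the summation bound adapts per cell to lambda + 10 sqrt(lambda) +
15 (capped at N_max), keeping the fold error below ~1e-12 at realistic
abundances. Because week is a unit-level covariate, (detections, realized
nights) are sufficient per species-unit, which the jitted likelihood kernel
exploits; the general per-occasion form is kept as the reference
implementation and the two are cross-checked in tests.

Sampling is adaptive Metropolis-within-Gibbs. Species-level parameters
update one column at a time but simultaneously across species (their
conditionals are independent given hyperparameters and stand intercepts),
stand intercepts update jointly (disjoint unit sets), community means are
conjugate Gibbs draws, and community SDs use log-scale random walks
interwoven with non-centered rescaling moves (the SD proposal rescales all
species deviations with it), which removes the funnel that otherwise stalls
the scale parameters. A joint "ridge" move shifts each species' abundance
and detection intercepts in opposition, the direction along which the RN
likelihood is weakly identified. Proposal scales adapt toward standard
acceptance targets during warmup only, so the post-warmup chain is a valid
fixed-kernel sampler. Chains are seeded deterministically from the
configured seed; convergence is summarised by split-R-hat (< 1.1 for all
retained parameters, else the fit is flagged, never silently accepted) and
bulk ESS via arviz.

Model fit is assessed by a posterior predictive check with the
Freeman-Tukey discrepancy on per-unit detection counts. The check is
consistent with the truncated likelihood actually fitted: expected counts
use the closed-form truncated expectation of (1-r)^N and replicated data
draw N from the same folded distribution. The Bayesian p-value is the
fraction of draws whose replicated discrepancy reaches the observed one.

A note on the four-night argument: with nightly detection 0.35 the
probability of at least one detection over four nights is
1 - 0.65^4 = 0.8215. We report this closed form; a posterior-averaged
version can differ, and the two interpretations are deliberately not
forced to agree.

## Synthetic data generator

The generator emulates the full design — blocks, treatments, grid layouts,
week rotation across blocks and years, the units the study could not
sample (one UA stand-year, one three-night Split stand, two logged rotation
stands) — and the abundance/detection process matches the occupancy model
exactly, so every estimator has a recoverable target. Key defaults and why:

* Species log-abundance intercepts follow the log-normal rank-abundance
  curve (Gaussian quantiles scaled by sigma = 2.3, centred at
  log lambda = -2.7, plus N(0, 0.3) species noise). A quantile backbone
  rather than i.i.d. draws makes the community reliably dominated by a few
  common species: the four commonest account for ~85% of captured
  individuals, and a stand-year session yields a median of ~25-30
  individuals (range roughly 1-150), matching the study's reported
  conditions.
* Class effects on log abundance are species draws around group means:
  arboreal species get +1.0 in riparian patches and +0.5 in rotation
  stands; all others +0.3 riparian, -0.3 rotation, 0 upland; SD 0.5. The
  signed arboreal-riparian truth emulates the flying-squirrel pattern and
  gives recovery tests a direction to confirm.
* Nightly detection intercepts ~ logit-Normal(-0.7, 0.5) (median r = 0.33,
  near the reported 0.35 for flying squirrels); week effect
  ~ N(0, 0.2) per SD of week; stand intercept SD 0.3.
* Latent N is drawn independently per subplot-year; stand intercepts are
  the only cross-year dependence, mirroring the fitted model.
* Insectivores are generated untagged, so their tallies count captures
  (the shrew assumption), while tagged species deduplicate to individuals.

What the generator does not emulate: trap-level spatial structure and
saturation, behavioural responses (trap-happiness), mortality and
within-season turnover, effort differences between 12- and 48-trap grids
(lambda is per grid, not per trap), and any overdispersion beyond Poisson.
Passing recovery tests therefore demonstrates the estimators are correct
and calibrated under the design's structure, not that the models are
adequate for any particular field dataset.

## Verification scales and expected behaviour

Oracle tests run at full precision (Chao1 and UPGMA against brute-force
re-evaluation; the RN likelihood against enumeration over latent N to
1e-10). Monte-Carlo recovery tests state their problem sizes explicitly:
the Gaussian LMM recovers a -1.8 treatment effect to within 0.1 in mean
over 200 replicates of the 10-block design with interval coverage inside
[90%, 99%]; the community model's effect-parameter credible intervals are
checked for >= 85% pooled coverage over four independent 15-species
experiments at the one-summer scale (the criterion sits below the ~93%
average coverage we measure, because single-experiment coverage varies
binomially and shrinkage misses tail effects of rarely-detected species);
the posterior predictive p-value falls in (0.05, 0.95) for at least 18 of
20 replicates generated from the model class. Larger MCMC runs change
the numbers only within Monte-Carlo error.

## Known limitations

* The Poisson GLMM reports MAP/Laplace intervals, not REML profile
  intervals; for the small counts typical of cover-type richness these are
  mildly conservative.
* The RN sampler is a random-walk scheme: posteriors with hundreds of
  species or very sparse detections will need longer chains than the
  defaults; R-hat flags this rather than failing.
* Chao1 assumes individuals are identified correctly and independently;
  the untagged-shrew convention inflates shrew "individuals" and hence
  their singleton/doubleton counts, exactly as in the field protocol.
* No data augmentation for fully unobserved species: the community model
  covers the observed species list only.
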