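# Methods

## The alignment problem

A label-free LC-MS experiment measures each detectable peptide once per
run as a *feature*: precursor m/z (Thomson), retention time (minutes)
and, with ion-mobility separation, a drift time (milliseconds), plus an
intensity and often a product-ion (fragment) spectrum.  Downstream
quantification needs the same peptide's intensities collected across
runs, but retention times shift and stretch between runs, m/z has small
measurement error, and dense regions contain co-eluting near-isobaric
peptides.  `dpalign` treats cross-run matching as posterior inference in
a Bayesian mixture model rather than as nearest-neighbour search with
hard distance cutoffs.

## Model

Runs are indexed by d, features within a run by i, and *latent peptides*
(mixture components) by j.  A measured coordinate vector is a per-run
linear warp of a latent value plus noise:

    x_{d,i} = eta_d + z_{c_{d,i}} * beta_d + eps_{d,i}
    eps_{d,i} ~ N(0, Sigma)
    z_j      ~ N(mu_j, sigma)          (shared covariance across j)
    mu_j     ~ N(lambda, r)

`eta_d` (shift) and `beta_d` (scale, diagonal — one scale per
coordinate) absorb systematic between-run variation such as gradient
delays; `Sigma` is residual measurement noise; `sigma` is the spread of
repeated measurements of one peptide around its mean.  All four
dimensionalities follow the chosen mode: MZ-RT, MZ-IM, MZ-RT-IM, or
MZ-RT-IM-HE (the last adds fragment profiles, below).

The assignment indicators c_{d,i} carry a Chinese-restaurant-process
prior with concentration `alpha` fixed at the total feature count N,
subject to the hard constraint that a latent peptide holds **at most one
feature per run**.  Features assigned to the same latent peptide are
matched.  Because the number of peptides is unbounded, a feature may
always open a new component instead of accepting a poor match — this is
what keeps false-positive matching low in sparse regions.

The per-measurement latent value z is integrated out everywhere, so the
likelihood of x under an existing component is
N(x | eta_d + mu_j beta_d, B_d) with B_d = diag(beta_d) sigma
diag(beta_d) + Sigma, and the weight of a brand-new component uses the
further closed-form marginal over mu (Gaussian in Gaussian).

### Product-ion profiles

In fragment-enabled mode each feature's <= 50 most intense product ions
are binned over K = 250 fixed fragment-m/z bins (bin limits snapped to
fragment-m/z "deserts" where possible) and normalized to sum to one, so
profiles are invariant to uniform intensity rescaling.  A latent peptide
carries the elementwise mean w_j of its members' profiles; a new
(memberless) peptide carries the blank profile 1/K.  The squared
distance psi = ||y - w||^2 in [0, 2] is modelled Exponential(gamma) with
a conjugate Gamma(a0=1, b0=1) prior on the rate, so the strength of
fragment evidence is *learned from the data*: when assignments are
fragment-consistent, the observed psi values are small, gamma grows, and
profile disagreement becomes strongly penalized.

## Initialization from seed matches

The model is anchored by up to `n_seeds` = 15 *seed matches*: the
sequences identified (with the same charge) in every run, ranked by mean
identification score.  Groups whose m/z or rt residuals exceed 4 robust
standard deviations (normal-consistent MAD) are discarded as likely
wrong identifications.  Averaging a group's coordinates across runs
gives an "implied" peptide; a bisquare IRLS regression (statsmodels RLM)
of each run's measured coordinates on the implied ones yields the warp
prior means (intercept -> a_d, slope -> e_d) with prior variances set
tightly to the squared standard errors.  The inverse-Wishart priors for
Sigma and sigma both take df = (#groups - 1) and scale = the summed
outer products of de-warped seed residuals; lambda and r are the global
coordinate mean and summed squared deviations (deliberately diffuse).
Seed groups stay matched at every iteration.

## Fitting

Collapsed Gibbs sampling, Neal's Algorithm-2 style: each sweep visits
features in a fresh random order, removes the feature, and redraws its
assignment from the full conditional (CRP weight x Gaussian likelihood x
optional fragment factor); a drawn birth instantiates mu from its
conditional given the single member.  Between assignment sweeps all
parameters are redrawn from conjugate full conditionals:

- **mu_j** — normal, combining N(lambda, r) with the members' de-warped
  observations under B_d.
- **eta_d, beta_d** — normal, per dimension, treating the marginal
  residual variance B_d[m,m] as a plug-in constant.  The exact beta
  conditional is non-conjugate because B_d depends on beta; the plug-in
  makes the update a standard normal-normal regression step, and the
  tight seed-derived priors keep the warp identified.
- **Sigma, sigma** — inverse-Wishart.  These updates need the latent
  values, so z is sampled transiently from its exact Gaussian
  conditional (given x, mu and the current covariances), used to form
  the residual and deviation outer products, and discarded.  Assignments
  never see an instantiated z.
- **gamma** — Gamma(a0 + n, b0 + sum psi).

After `burn_in` sweeps at temperature T = 1, simulated annealing sharpens
all full conditionals to the power 1/T with T_k = max(0.95^k, 0.05)
(assignment probabilities renormalized after tempering; normal variances
scaled by T; inverse-Wishart and Gamma parameters transformed so the
tempered density is again of the same family).  The final state is the
MAP estimate.  A flag (`temper_parameters`) restricts tempering to the
assignment draws only.

### Match probabilities and consensus

With all parameters frozen at the MAP, only the assignment indicators
are resampled at T = 1 for `assignment_sweeps` sweeps (default 500;
frequency standard error about 0.02).  The tallied frequencies estimate
each feature's conditional assignment probability given the MAP
parameters — they are *not* marginal posterior match probabilities, a
distinction we keep deliberately since the MAP parameters are tight for
everything except individual latent means.  Draws of "new" are tallied
as unmatched mass; the latent peptide set is fixed so the tallies have a
stable index.  A greedy pass then repeatedly takes the globally largest
(latent peptide, feature) frequency, completes that peptide's group with
each remaining run's best feature, and zeroes the used rows/columns;
ties break on lowest latent id then lowest (run, feature) index, making
the consensus deterministic.  The match probability of two features from
different runs is the product of their assignment probabilities for the
shared latent peptide.

### Partitioning at m/z deserts

For large runs the data are split on the m/z axis at "deserts":
after de-warping with the seed-derived approximate warp, features are
histogrammed in bins one m/z match-standard-deviation wide, and runs of
five or more empty bins admit a split boundary at the desert midpoint
(at most 250 splits; the widest deserts win if more are found).  No two
features whose de-warped m/z differ by less than five match-sd can land
in different splits, so potential matches are never separated.  Splits
share all hyperparameters and are aligned independently — optionally in
parallel, with per-split RNG streams spawned from (seed, split index) so
serial and parallel execution are bit-identical.  The desert histogram
uses warped coordinates; the paper-level alternative (raw coordinates)
differs only when warps are large compared to desert widths.

## Synthetic data

`dpalign.simulate` draws data from the model's own generative reading:
latent coordinates uniform over m/z 400-1200 Th, rt 10-90 min (a
90-minute gradient), drift 2-12 ms; per-run linear warps; Gaussian
noise.  Defaults define the *warp-recovery study*: 3 runs x 200
peptides, rt shifts (-0.5, 0, +0.5) min and rt scales (0.98, 1, 1.02) —
mean-centred across runs because the seed-anchored model identifies
warps only relative to the cross-run mean — and noise sd set to 1/10 of
the median per-dimension nearest-neighbour spacing, which makes matching
non-trivial but solvable.  Identification clusters by peptide (a peptide
is identifiable with probability 0.5 and then identified per run with
probability 0.9), mimicking the fact that abundant, well-fragmenting
peptides are identified consistently; scores ~ N(7, 1.5^2) give usable
5/6/7 thresholds.

Fragment spectra are per-latent reference spectra (uniform fragment m/z,
log-normal intensities) perturbed per measurement by intensity jitter
and per-ion dropout.  Two further canonical studies fix the regimes
where fragment information matters:

- *confusable study*: 15 latent-peptide pairs separated by half a noise
  sd in every coordinate but with distinct spectra; precursor-only
  alignment confuses them, fragment-enabled alignment separates them.
- *decoy study*: a replicate pair where the second run has an appended
  second-species feature list; 15% dropout creates vacant slots and a
  quarter of the decoys are placed within half a noise sd of a vacant
  species-A peptide, the hard case for false matching.

Both studies use sparse, sharply concentrated spectra (8 ions, log-sd
1.5, 3% dropout): with diffuse many-ion spectra the squared-distance
score compresses and the learned gamma cannot separate wrong merges from
births.  This is a real property of the scoring model, not an artifact —
peptides whose spectra share many low-information ions are genuinely
harder to distinguish — and the generator's regime makes the mechanism
measurable at desk scale.

What the generator does **not** emulate: isotope envelopes and charge
states, correlated (non-Gaussian) rt drift, intensity-dependent
identification, shared fragments between different peptides, and real
spectral noise structure.  Passing tests therefore demonstrate the
correctness and calibration of the inference machinery under the model's
own assumptions, not instrument-level performance.

## Numerical choices

- Problem sizes and sweep counts in the tests and the reproduction
  script (e.g. 80 + 80 sweeps at 600 features, 150 + 80 at 180-210
  features, 200-300 assignment-only sweeps) were chosen as the smallest
  runs at which the chains mix reliably for these study sizes.
- The fragment-enabled studies run with `max_splits = 1`: gamma is
  learned per alignment, and with many tiny m/z splits each split's
  handful of profile scores is dominated by the Gamma(1, 1) prior,
  leaving the fragment evidence underweighted.  At realistic split sizes
  (thousands of features) this does not arise.
- Degenerate seed residuals (identical replicates) add a diagonal jitter
  of 1e-6 x mean squared coordinate so the inverse-Wishart priors stay
  proper; non-positive-definite accumulations during sampling receive
  1e-9 x mean-diagonal jitter.
- Ties among the 50 most intense fragments break toward lower m/z; ties
  in the greedy consensus break toward lower latent id then lower (run,
  feature) index.
- Empty components are removed immediately during fitting; during
  assignment-only resampling they are kept (weight zero) so the tally
  index stays stable.
- All randomness flows from a single integer seed through
  `numpy.random.Generator`; per-split streams come from
  `SeedSequence([seed, split_index])`.

## Known limitations

- The variance decomposition between Sigma and sigma is only weakly
  identified when most components hold one or two members; the
  seed-calibrated inverse-Wishart priors regularize it, but with very
  weak priors the fitted covariances shrink below the true noise level
  and distant same-peptide pairs can fail to merge.
- Single-site Gibbs cannot swap two features between two full components
  in one move; when every component holds a feature from every run
  (no dropout), a wrong pairing formed early can persist through
  annealing.  Fragment profiles mitigate this by disfavouring the wrong
  merge before it locks in.
- The blank-profile convention for new components means that opening a
  new component "costs" a fragment-rich feature its distance to the
  uniform profile; with weak fragment evidence this can favour a wrong
  merge over a birth.
- Warps are linear per dimension.  Nonlinear de-warping should be done
  upstream; any preferred method can be applied before alignment.
- Match probabilities are conditional on the MAP parameters, not
  marginalized over them.
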