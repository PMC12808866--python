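# Methods

## The analysis

The package asks whether trial-by-trial physiological similarity structure is
predicted by the similarity structure of subjective affect ratings. All
objects are trial × trial *similarity* matrices (RSMs) over a participant's
trials sorted ascending on one rating dimension — arousal for skin
conductance (SCR), valence for startle eyeblink. Ties in the sort are broken
by presentation order (stable sort), which makes every ordering
deterministic.

Three pairwise similarity models are applied to trial scores
$V_{T_i}, V_{T_j}$:

- **NN**: $V_{max} - |V_{T_i} - V_{T_j}|$, where $V_{max}$ is the maximum of
  the dataset the formula is applied to (the rating-scale maximum, 9, for
  rating-based model RSMs; the maximum of the specific value vector for
  physiological and code-based RSMs). $V_{max}$ only shifts the matrix by a
  constant and is invisible to the rank statistics used downstream, but each
  RSM records which convention produced it.
- **AK**: $\mathrm{mean}(V_{T_i}, V_{T_j}) / N$ with $N$ the trial count.
- **inverted AK**: $1/(\mathrm{mean}(V_{T_i}, V_{T_j}) \cdot N)$, a strictly
  decreasing transform of the AK pair mean, hence an exact rank mirror of AK
  (Spearman −1 over any pair set with two or more distinct means). The $1/N$
  scaling in the AK family is retained literally even though it cancels
  under rank correlation.

Control models reuse the NN formula on nominal or ordinal codes: valence
category (pleasant = 1, unpleasant = 2, neutral = 3), arousal category
(high = 1, low = 2), presentation position (1..T), and the alternative
rating dimension.

Model RSMs are built per participant and averaged cellwise. Physiological
RSMs come in two averaging regimes that bracket the role of intraindividual
variability:

- **dismissing**: sort each participant's preprocessed responses by their own
  ratings, average across participants at each sorted *rank position*
  (ratings are participant-specific, so rank is the only common index), then
  apply the NN formula once to the averaged vector;
- **considering**: apply the NN formula per participant (per-participant
  $V_{max}$), then average the matrices cellwise, ignoring missing cells and
  recording per-cell contributor counts.

The two regimes coincide exactly on rating-locked noise-free responses and
diverge under trial-to-trial variability; the divergence is the scientific
signal, not an artifact.

### Preprocessing

SCR amplitudes (µS, non-negative) are transformed as $\log(1 + \mathrm{SCR})$.
Startle magnitudes (µV) are T-scored within participant
($50 + 10 (x - \bar x)/s$, sample SD) over non-missing trials, with scored
zero-responses included as zeros. Participants with *more than* 50% startle
non-responses (zeros or missing) are excluded — the inequality is strict, so
exactly-50% participants are retained. Missing trials propagate to missing
RSM rows/columns; participants with fewer than 3 usable trials are dropped
with a warning. Repeated presentations of a stimulus are collapsed by
participant-level means before RSM construction (first-presentation-only is
available as an option).

### Inference

Only the strictly-below-diagonal cells enter any comparison (the matrices
are symmetric and the diagonal is self-similarity). Spearman's rho is
computed over pairwise-complete cells with average-rank ties. The
permutation null jointly permutes rows and columns of one RSM with a random
trial-label permutation per iteration (the standard RSA null, preserving
each matrix's internal structure), default 10,000 iterations; the one-sided
p-value uses the add-one estimator $(1 + \#\{\rho_{null} \ge \rho\})/(1+m)$
so it is never zero. For residualized comparisons the model side is an OLS
residual vector defined on triangle cells, so only the physiological matrix
is permuted.

The Bayes factor for a positive association beyond the permutation null
takes H0: $\rho \in$ [1st, 95th percentile of the null distribution] and
H1: $\rho$ above that interval, both under a stretched-beta prior
($(\rho+1)/2 \sim \mathrm{Beta}(1/\kappa, 1/\kappa)$, $\kappa = 1/3$,
the conventional "medium" width) renormalized on each region. The likelihood
uses the Fisher-z normal approximation of the correlation's sampling
distribution at the number of triangle cells; this inherits the usual RSA
pragmatism of treating triangle cells as exchangeable observations. A
degenerate interval falls back to a point null with a warning, and the
interval-null factor converges to the point-null factor as the interval
shrinks (verified numerically to 1%).

Individual-level analyses extract one Spearman similarity index per
participant and aggregate with a one-sided one-sample t-test against zero
plus a directional JZS Bayes factor (Cauchy prior on the standardized effect,
scale $\sqrt{2}/2$, truncated to positive effects; computed by quadrature of
the noncentral-t likelihood over the effect size). Participants with
undefined indexes (zero-variance triangles, e.g. when a control equals the
focal model) are dropped and counted. If every index is exactly zero the
degenerate t is reported as t = 0, p = 0.5 by convention. Evidence labels
follow the Jeffreys thresholds (anecdotal/substantial/strong/decisive at
1, 3, 10, 100).

## The synthetic-data generator

The generator emulates passive picture-viewing-style studies: T = 36 trials
(18 for imagery-task shapes) in three equal stimulus categories with
normative anchors — pleasant (valence 8, arousal 7), unpleasant (valence 2,
arousal 7), neutral (valence 5, arousal 2) on the 1–9 SAM scale — plus
integer-rounded unit-SD jitter per participant × trial, clipped to the
scale. This reproduces the trimodal-valence / bimodal-arousal structure of
normed stimulus sets; both ends of each dimension must be populated for the
NN-vs-AK contrast to be informative. Arousal category is a median split on
the normative anchors.

Physiology is linear in the driving dimension with truncation at zero:
SCR $= b + s\,(\text{arousal}-1) + \varepsilon$,
$\varepsilon \sim \mathcal N(0,\ \sigma_0 + h\,(\text{arousal}-1))$; startle
mirrors the structure on reversed valence (magnitude and noise grow as rated
valence falls, `direction="decreasing"`), scaled by 100 to land in a
plausible µV range. Startle trials go missing independently with
`missing_rate` (default condition 0.1); scored zero-responses are a separate
`zero_response_rate` (default 0) because a zero is a valid magnitude while a
missing trial is an artifact.

Two regime presets are the package's study conditions, fixed once:

| parameter | fingerprint | populations | unit |
|---|---|---|---|
| base_response $b$ | 0.3 | 0.3 | µS |
| slope $s$ | 0.08 | 0.02 | µS per rating unit |
| noise_sd $\sigma_0$ | 0.08 | 0.05 | µS |
| hetero_coef $h$ | 0 | 0.12 | µS per rating unit |

Fingerprint keeps responses rating-locked with homoskedastic noise of the
same order as the trend across one rating step. Populations makes the
heteroskedastic term dominate (SD ≈ 1 µS at the top of the scale versus
0.05 at the bottom) with a deliberately weak mean trend, since one-sided
trial dissimilarity, not the mean trend, is what the AK family encodes.
Linear-in-rating SD is the simplest one-parameter family that produces
one-sided dissimilarity.

What the generator does *not* emulate: habituation and order effects,
oddball trials, within-participant rating drift, skewed/lognormal SCR error,
correlated valence–arousal jitter, and any raw-waveform features. Passing
tests therefore show that the pipeline recovers the planted similarity
structure under idealized trial-level noise, not that real data behave this
way.

## Numerical and design choices

- Stable sorts everywhere; a single integer seed drives generation and all
  permutation draws, so repeated runs are byte-identical.
- Quadrature for both Bayes factors uses adaptive `quad` split at the
  likelihood peak; the JZS implementation was cross-checked against the
  g-space integral formulation and an independent implementation to 1e-3
  relative.
- Averaged RSM cells keep NaN when no participant contributes; contributor
  counts are retained for bookkeeping.
- Pairwise-complete deletion is the default for correlations under missing
  cells (listwise behavior falls out of propagating NaN into both triangles).

## Known limitations

- With linear-in-rating noise SD the trial *variance* is convex in the
  rating, so at a fixed rating sum unequal pairs pool more noise than equal
  pairs ($\sqrt{\sigma_{lo}^2+\sigma_{hi}^2} > \sqrt2\,\sigma_{mid}$). On a
  trimodal dimension (valence) this injects a genuine weak NN-like component
  beyond AK into considering-variability physiological RSMs: in the startle
  battery the NN model retains a small positive residual association
  (rho ≈ 0.10–0.19 at N = 100) after AK is regressed out. The SCR battery
  does not expose this (bimodal arousal, log compression; NN residual is
  clearly negative). This is a property of the generator's noise family, not
  of the inference stack.
- The Fisher-z likelihood treats RSM triangle cells as independent, which
  they are not; the permutation test, which respects the matrix structure,
  is the primary significance criterion.
- The interval-null Bayes factor depends on the permutation interval and is
  therefore itself seed-dependent at small `n_perm`.
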