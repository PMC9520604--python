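# Methods

`critsig` implements, end to end, the computational argument around
"driven" versus "emergent" criticality in neural populations: a stimulated
sparse spiking network that passes through a phase transition as relative
inhibition is tuned, thresholded random-walk surrogates that display
criticality signatures without any coupling, and the statistical battery
used to tell the two apart.  This note records the models, the parameter
choices that matter, and the numerical decisions taken where the design was
genuinely open.

## Avalanche convention

An avalanche is a maximal run of time bins with nonzero population
activity, bracketed by silent bins; runs touching the edges of a recording
are discarded because their bracketing cannot be verified.  Heights are the
per-bin population counts, size `S` their sum, and duration `T` the
**first-return time**: the number of steps from leaving silence until
returning to it, i.e. one more than the number of active bins.  Under this
convention a raster avalanche and a zero-to-zero excursion of a reflected
random walk are the same object — the six-flip walk H,H,H,T,T,T with
heights (1,2,3,2,1,0) is one avalanche with `S = 9`, `T = 6` — and the
analytic fair-coin first-return exponents (`tau -> 4/3`, `alpha -> 3/2`,
`gamma -> 3/2`) apply literally.  The cost is that the textbook inequality
`S >= T` weakens to `S >= T - 1`.

Reflection of the coin-flip walk is implemented as the absolute value of
the cumulative sum; for a +/-1 walk this is pathwise identical to flipping
each negative excursion, not merely equal in distribution.

## Power-law fitting

`fit_power_law` is a discrete truncated power law `p(x) ~ x**-a` on an
integer support `[xmin, xmax]`, fit by maximum likelihood with the
normalising constant written through the Hurwitz zeta function.  `xmin` is
selected by minimising the Kolmogorov-Smirnov distance over candidate
values (capped at 40, log-spaced), `xmax` defaults to the sample maximum.
Goodness is a parametric bootstrap of the KS statistic (200 replicates by
default; the exponent is refit per replicate, the range is held fixed).
Alternatives — discrete exponential and discrete lognormal on the same
support — are compared by Vuong-normalised log-likelihood ratios.

Two practical caveats are built into the tests rather than the fitter.
First, with KS-selected `xmin` any light-tailed sample can look locally
power-law-like far enough into its tail, so misspecification checks
(e.g. geometric data) fix `xmin = 1`.  Second, a hard cutoff that lives in
the few largest order statistics (the biased coin: the reflected walk stops
returning to the origin after roughly `1/|2p-1|` visits) is invisible to
KS but obvious to a censored-tail exceedance test: under the fitted pure
power law the expected number of samples beyond the observed maximum is
large, giving a Poisson tail probability far below 0.05.

## Size-duration scaling and shape collapse

`gamma` is the least-squares slope of log mean size against log duration
over exact-duration classes with at least 10 members.  For the coin-flip
analyses the fit starts at `T = 8`: below that the +/-1 lattice corrections
are strong (the local slope at `T < 8` is ~1.9 against an asymptotic 1.5).

Shape collapse rescales each mean profile to unit duration (`t/T`) and by
`T**(gamma-1)`, interpolates linearly onto a 50-point grid with the profile
anchored at zero at both ends (avalanches are bracketed by silence), and
scores the collapse as the across-duration variance averaged over the grid,
normalised by the squared mean rescaled height.  When `gamma` is free it is
chosen from the grid 1.00-2.50 in steps of 0.01.  Coin-flip collapse uses
duration classes 8-32 with at least 100 members each, so that across-class
sampling noise sits well below the collapse signal; the first and last
interior heights of a +/-1 excursion are pinned at exactly 1, a boundary
effect visible if shorter classes with few members are admitted.

## Hurst exponent

Windowed-standard-deviation scaling: partition the series into disjoint
windows of length `L` (powers of two from 8 to length/8), average the
within-window standard deviations, and take the log-log slope against `L`.
A memoryless walk gives `H ~ 0.5`; the worked two-point version
(STD 70.26 -> 202.13 over an 8-fold window growth) gives `H = 0.51`.  Note
that a Markov "persistent" walk (repeat the last step with probability
0.7) has a correlation length of a few steps and is asymptotically
diffusive; demonstrating `H` clearly above or below 0.5 requires genuine
long memory, which the tests generate as fractional Gaussian noise via
Davies-Harte circulant embedding.

## The spiking network

A discrete-time leaky integrate-and-fire network of `N` neurons, 80%
excitatory, fixed in-degree connectivity at 10% density (each neuron
receives exactly `round(0.1*0.8*N)` excitatory and `round(0.1*0.2*N)`
inhibitory inputs, no self-connections).  Inhibitory efficacy is `-g`
times excitatory; `g` is the control parameter.  One time bin equals one
synaptic delay (1.8 ms); membrane time constant 20 ms, threshold 20 mV
above rest, reset 10 mV, refractory one bin.  Stimulation and noise are
forced spikes.

Two defaults differ from the classical parameterisation, and both exist to
make the pulse-stimulation experiments well-posed:

* **Efficacy and size scaling.** `j_excit = 1.0 mV` quoted at a reference
  size of 1000 neurons and scaled by `1/N`.  With random membrane phases
  (below), the linearised pulse response has branching ratio
  `sigma(g) = 5 j (0.8 - 0.2 g)`, which crosses 1 exactly at `g = 3` for
  `j = 1` — independent of `N`, so finite networks approach the same
  transition from below as fluctuation-driven extinction weakens.  With a
  per-synapse efficacy an order of magnitude smaller, a single pulse in a
  drive-free network either cannot cascade at all or explodes in one bin,
  and no transition exists near `g = 3` at any size.
* **Initial membrane phases.** Potentials start uniform in
  `[0, threshold)` and the pulse is delivered immediately after
  initialisation.  The uniform spread is what converts a pulse of `A`
  spikes into a graded next generation of `sigma * A`; because there is no
  ongoing drive to replenish it, the spread leaks away within a membrane
  time constant, which is why stimulation happens at the start rather than
  deep into a silent run.

Saturated activity alternates with period 2 (half the population fires
while the other half is refractory), so every readout that must not see
that sub-refractory structure — the decay-constant fit and the response
variable for mutual information — first applies a 2-bin boxcar.  Without
it, the saturated state encodes the stimulus in its oscillation phase and
low-`g` mutual information is spuriously high.

Decay constants are fit as an exponential approach to an asymptote: the
plateau is the mean of the last quarter of the 3-40-bin window, the fit
uses only the initial informative segment of the deviation (down to 5% of
its starting value), and a transient already finished before the window
reports a floor constant of one bin.  The plain `A exp(+/- t / tau)`
log-linear fit remains available and is the default of the public
operation.

## Stimulus-response information

Eight stimulus levels `i*N/8` (3 bits), delivered as forced spikes to
randomly chosen neurons; the response is the mean (smoothed) population
count over bins 3-5 after the stimulus.  Responses are discretised into
eight equal-width bins over their observed range and plug-in entropies are
computed in bits; no bias correction is applied, matching the modest trial
counts, and the trial count is configurable so the bias can be bounded
empirically.

The correlated noise drive is a reflected coin-flip walk: `round(3 * x_t)`
of `N_d` designated neurons are forced to spike each bin.  Generated walks
carry a 1000-step burn-in so the drive arrives with the stationary
excursion amplitude of an ongoing process; a walk started at the origin is
only a few units high within a short trial and perturbs nothing.

For the entropy-attribution experiment the same drive and stimulus seeds
feed a connected (10% density) and a fully disconnected copy of the model,
each condition's responses pass through the identical readout and its own
equal-width binning, and the entropy curves are averaged over five
independent topologies and drive realisations before the ratio is taken
(single-model estimates scatter by several points; the five-model average
is stable to within about two).  The reported statistic is
`100 * H_R(disconnected) / H_R(connected)` at the `g` where the connected
response entropy peaks; at desk scale it lands in the mid-to-high 80s.

## Desk-scale presets and what they show

The shipped experiment sizes are chosen to finish in minutes on one core:
networks of 250-2000 neurons, 13-point `g` grids densest near 3, 10-20
trials per level, 2-3 topologies per condition, and coin-flip runs of 1e8
flips (the avalanche count grows only as the square root of the run
length, so the residual exponent scatter is a few hundredths).  At these
sizes the demonstrations are the *structural* ones: the firing-rate phase
transition, the coincidence of the decay-constant and MI peaks near
`g = 3`, the monotone degradation of the MI peak under either noise type,
the persistence of response entropy under strong correlated drive, the
~89/11 entropy attribution, and the disappearance of both peaks at 1-2%
connectivity.  Printed full-scale quantities (a decay peak at `g = 2.99`
with 8000 neurons and 93 grid points; an MI-peak asymptote of
`g = 2.952`) require the full protocol and are not asserted at desk scale.
The connectivity-ablation avalanche harvest uses the weakly driven runs;
in this no-drive-free regime small network-intrinsic cascades cannot
propagate (the leaking membrane spread imposes an ignition floor), so
per-density avalanche fits are reported descriptively rather than
asserted.

The synthetic sources emulate model systems, not recordings: there is no
empirical bin-size selection, no subsampling, no electrode noise, and the
drive processes are exactly the idealised walks.  Passing tests therefore
establish the internal consistency of the argument — that the statistics
separate driven from emergent criticality *in these models* — not that any
particular biological recording is critical.

## Known limitations

* The naive branching-ratio estimator conditions on active ancestor bins
  and is biased under subsampling; subsampling-robust estimators are out
  of scope.
* The discrete lognormal alternative uses a continuous-integral
  normalisation when the support is wide (error negligible at the scales
  fit here).
* Collapse errors depend mildly on the interpolation grid; comparisons are
  made at matched settings.
* The OU surrogate's noise distribution and scale are parameters
  (`noise_scale`, Gaussian by default); published exponent values for
  OU-threshold models depend on unstated implementation details and are
  not reproduction targets.
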