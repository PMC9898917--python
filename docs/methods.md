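# Methods

This note documents the models, numerical choices and limitations of the
package in the order of the pipeline.  All empirical figures quoted here
are computed by the test suite or by `scripts/acceptance.py`.

## Protease specificity and edge enrichment

**PSSM.**  Substrate windows are the eight residues flanking a scissile
bond (P4..P1 on the non-prime side, P1'..P4' on the prime side).  Counts
per position and residue are regularised with an additive pseudocount of
5 per cell before normalisation, i.e. `p(a,j) = (n(a,j) + 5)/(N + 100)`,
which keeps every log-odds cell finite regardless of training-set size.
Scores are natural-log odds against a background distribution; natural
log is load-bearing, because only then does the logistic conversion map a
score of 1.5 to a cleavage probability of ~81.7 % (log base 2 would give
73.9 %).  The packaged default background is the average amino-acid
composition of the reviewed human proteome (UniProtKB/Swiss-Prot
statistics), renormalised over the 20 canonical residues; any positive
20-vector summing to one can be supplied instead.

**Site indexing.**  A cleavage site between residues *i* and *i+1* is
indexed by *i* (the P1 residue), 1-based; its window spans residues
*i−3..i+4*, so positions 4..L−4 of a length-L sequence are scorable.  The
per-position score is the maximum over the supplied matrices — a bond is
cleavable if any protease can cleave it.

**Proximal region.**  For an observed fragment `[start, end]` the
proximal set is `{start−2..start+1} ∪ {end−1..end+2}`, including the
terminal residues themselves.  The two-residue margin absorbs
exopeptidase trimming and imprecision in the training windows.  The
alternative reading that excludes the terminal residue differs by one
residue per edge and was not adopted.

**Edge test.**  One-tailed Mann-Whitney U, alternative "proximal scores
stochastically greater".  For pooled sample sizes up to 12 the null is
enumerated completely over group assignments with midranks, so ties are
exact; larger problems use the tie-corrected normal approximation with
continuity correction (scipy).  Significance is judged at 0.05.

## Thermal-scan extraction

**Tm.**  The I350/I330 ratio is smoothed with a local quadratic
(Savitzky-Golay) filter spanning ~2 °C, differentiated with the same
filter, and the derivative maximum is refined by a quadratic fit over the
points within one smoothing window of the peak.  A curve whose smoothed
dynamic range is below five times the point-to-point noise (MAD estimate)
is flagged "no transition".  Note that with unequal folded/unfolded
baselines the derivative maximum of a *ratio* curve is an apparent Tm
that can sit a fraction of a degree from the thermodynamic midpoint; this
cancels in concentration *differences*, which is why concentration
dependence is summarised by the slope rather than absolute values.

**Tagg.**  A straight line is fitted to the baseline region (first 25 %
of the scanned span, configurable) of the DLS cumulant-radius trace; the
whole trace is then fitted by the same linear form plus a logistic growth
term.  The onset is the first temperature (on a dense grid) at which the
fitted growth exceeds 0.5 % of the model's own baseline.  Comparing the
sigmoidal model against its own baseline component, rather than against
an independently fitted line, makes the crossing a property of the
fitted growth: with two independent fits the 0.5 % criterion (0.015 nm on
a 3 nm protein) is below instrument noise and the first crossing is
essentially random.  In simulations at 5 % radius noise the planted onset
is recovered to ~0.2 °C; noiselessly, to the grid resolution.  The onset
is monotone in the threshold by construction.

**Concentration slopes.**  dTm/dlog c and dTagg/dlog c are least-squares
slopes versus log10(concentration) over at least three concentrations,
in °C per decade; the decade scale makes them unit-invariant.

**Turbidity.**  The heat-test trace is smoothed as above; the maximum
position is reported, with "no turbidity" when the dynamic range is below
five times the robust noise, "beyond scan end" when the maximum sits at
the final temperature, and a reversibility flag when the final turbidity
falls below half of the maximal rise above the starting baseline.

## Two-state unfolding thermodynamics

The free energy combines Gibbs-Helmholtz temperature dependence with the
linear-extrapolation urea dependence (temperatures in Kelvin):

    dG(T, c) = dHm (1 − T/Tm) + dCp (T − Tm − T ln(T/Tm)) − m c

so that `dG(Tm, 0) = 0` and `dCp = 0` reduces to the van't Hoff limit.
The unfolded fraction is `1/(1 + exp(dG/RT))` with R = 8.314 J/(mol K),
and the expected fluorescence at 330/350 nm is the population-weighted
sum of linear folded and unfolded baselines, shared across the urea grid.

**Fitting.**  The model is linear in the eight baseline coefficients, so
they are solved by linear least squares inside the optimiser (variable
projection) and only Tm, dHm, dCp (and m when free) are iterated with a
trust-region least-squares solver.  This removes the usual
baseline-versus-thermodynamics start-value degeneracy and makes a fit
cheap enough for dense bootstrapping.  dCp is bounded to [0, 20]
kJ/(mol K) to prevent degeneracy on narrow scans.  Cold starts use a
derivative-based Tm guess with up to 10 jittered restarts; bootstrap
refits warm-start at the full-data solution.  Zero-urea scans are
excluded by default (simultaneous DLS shows aggregation mostly without
urea, which violates the two-state assumption); an arbitrary per-curve
exclusion predicate covers cases where low-urea scans must also be
dropped.  The m-value can be fixed to a value shared across samples
(7.1 kJ/mol/M is the conventional shared choice for light chains);
fixing m at its true value does not worsen — on average tightens —
recovery of dG37 in simulation.

**Uncertainty.**  100-fold bootstrap resampling capillaries (one scan per
capillary) with replacement.  The default interval is a t-interval on the
bootstrap standard error with `n_units − 1` degrees of freedom and a
`sqrt(n/(n−1))` widening: at 100 bootstrap rounds the extreme order
statistics needed by a percentile interval are Monte-Carlo-noisy and the
resulting interval undercovers (~92 % at nominal 95 % in our
simulations), while the SE-based interval achieves ~95–96 %.  An
expanded-percentile interval remains available via
`ci_method="percentile"`.  Replicates that fail to converge or lose urea
coverage are dropped; more than 20 % drops aborts.

## Aggregation kinetics

The ThT trace is fitted by
`Y = y_i + m_i t + (y_f + m_f t)/(1 + exp(−(t − t50)/k))`: a sloped
initial baseline plus a logistic step whose plateau may also slope.  The
halftime reported is the fitted `t50`; the half-amplitude crossing of the
fitted curve is attached as a diagnostic (the two differ slightly when
baselines slope).  Start values come from trace geometry (baselines from
the first/last tenth of points, t50 from the first mid-intensity
crossing, k as 5 % of the span) with up to 8 jittered restarts.  A trace
whose smoothed dynamic range stays below three times the robust noise is
flagged "no aggregation" and not fitted.  The fold increase deliberately
uses the final reading over the trace minimum — not the peak — because
sedimenting large aggregates make the signal decline after the plateau
and the end-of-run value is the fingerprint quantity.  The aggregated
fraction is `1 − (A280_sup − A280_ThT)/(A280_init − A280_ThT)`, clipped
to [0, 1] with a warning for small overshoots and an error beyond 5 % of
the denominator.

## Fingerprint statistics

Categorical fingerprint entries are encoded on fixed ordered scales
(DSF refolding small/medium/large → 0.33/0.50/0.66; refolding at 2 M
urea 0/<50/>50 → 0/1/2; yes/no flags → 1/0); encoding is lossless and
unknown tokens raise with the offending row and column named.  Remaining
non-numeric cells are treated as missing, mean-imputed, and all columns
standardised to zero mean and unit variance (population SD), which makes
downstream model selection invariant to affine rescaling of any raw
column.  Per-sample exclusions (e.g. a dG value from barely-refolding
material) are applied as a mask before encoding.

Correlation matrices are pairwise-complete Pearson and Spearman with a
minimum of three complete pairs per entry; pairwise deletion can make
them indefinite, so each matrix carries a positive-semidefiniteness flag
instead of failing silently.

The elastic net is grid-searched (penalty 1e-2..1e2 logarithmic, mixing
ratio 0.1..1.0, 10 steps each) with 4-fold cross-validation on negative
mean squared error and refit on all samples.  No separate validation set
is held out — at fingerprint-study sample sizes there is none to spare —
so the summary reports the cross-validated score and the in-sample
Pearson correlation side by side, and the function warns when samples
are fewer than three per feature.  On pure-noise targets the in-sample
correlation of the CV-selected model systematically exceeds the
CV-implied correlation (Freedman's-paradox-style inflation, demonstrated
in the test suite): in-sample correlations from such models must be read
as optimistic.

## Synthetic data: what it emulates and what it does not

All generators are deterministic under a fixed seed and add i.i.d.
Gaussian noise — the simplest model supporting recovery tests.  Study
conditions are built into the defaults: ~200 substrate windows per
protease (a curated-database-scale training set), a 214-residue
kappa-light-chain-length parent sequence, the nine-step 0–5.36 M urea
grid of the standard chemical-denaturation protocol, 25–70 °C melt scans
and 25–90 °C turbidity scans.  Where no instrument noise magnitude is
documented, defaults were chosen at realistic scales: fluorescence noise
0.003 signal units (a fraction of a percent of the normalised intensity),
radius noise 0.15 nm on a 3 nm baseline (sub-percent-to-few-percent
cumulant repeatability), ThT noise ~2 % of the amplitude.

Planted cleavage datasets write motif-drawn windows into the parent
sequence at each fragment's two cut sites, so ground-truth edges are
known exactly; the default motifs are cathepsin-like (bulky hydrophobics
at P2/P1' and basic or aromatic P1).  The DLS generator places the
logistic growth so that the 0.5 % divergence from the baseline occurs
exactly at the requested onset, and the turbidity generator translates
its rise/fall shape so the true peak sits at the requested temperature.

Simulated problem sizes in tests and in the acceptance script (e.g. melt
grids of 23–91 temperatures, 3 capillaries per urea, 50–100 Monte-Carlo
replicates) were chosen as the smallest sets at which the statistical
properties under test are stable.

What the generators do *not* emulate: correlated or heteroscedastic
instrument noise, aggregation coupling to unfolding (curves are strictly
two-state even at zero urea), full DLS size distributions (only the
scalar cumulant radius), exopeptidase trimming beyond the fixed proximal
margin, mass spectra, sedimentation profiles or images.  Passing
recovery tests therefore demonstrates correctness of the estimators
under their stated models, not robustness to every pathology of real
patient-derived data — in particular, real samples where aggregation
intrudes on the melt scans can bias dG estimates in ways the synthetic
suite cannot reveal.

## Known limitations

- The two-state fit shares baselines across the urea grid; real curves
  can show urea-dependent baseline drifts (a per-curve baseline option is
  the natural extension).
- The edge-enrichment test treats per-position scores as exchangeable
  under the null; residue autocorrelation along real sequences makes the
  test mildly anti-conservative, which the planted-null simulations (at
  background motifs) bound at the nominal level for the synthetic model
  only.
- No three-state or aggregation-coupled unfolding models, no mechanistic
  nucleation-elongation kinetics, no viscosity correction of DLS radii in
  urea.
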