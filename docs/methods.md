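# Methods note

This note records the statistical model behind `crmchip`, the default
parameter values and why they were chosen, the known limitations of the
synthetic-data generators, and the numerical conventions used
throughout. Every empirical statement here is one the test suite
computes.

## Measurement model

A qPCR reaction with efficiency `E` doubles (at `E = 2`) its template
each cycle, so a reaction crossing threshold at cycle `Ct` began with a
template amount proportional to `E^(−Ct)`. We report the linear signal

```
signal = 10^10 · E^(−Ct)
```

The prefactor `10^10` is an arbitrary scale that cancels in every ratio
the package reports; it only keeps typical signals in a readable range
for Ct values of 20–35. Efficiencies must satisfy `1 < E ≤ 2`. All
averaging is done on linear signals: the exponential map means
`E^(−mean(Ct)) ≠ mean(E^(−Ct))` (Jensen's inequality), so averaging Ct
values directly would bias the template estimate; the unit tests verify
the direction of this gap. Triplicate summaries use the sample SD
(`ddof=1`). A triplicate with fewer than two amplifying wells is `nd`.

## Occupancy estimator

Each experiment is a wild-type/mutant extract pair. Input fractions
measure loaded chromatin, giving the normalization coefficient
`k = mean(WT input) / mean(MUT input)`. Since the mutant extract lacks
the factor, its precipitate estimates antibody/bead background, and

```
specific  = WTppt/k − MUTppt
percent   = 100 · specific / input_avg
```

where `input_avg` is the mean over the pooled set
`{WT inputs / k} ∪ {MUT inputs}` (six normalized wells). Error bars use
first-order propagation with `k` treated as a fixed constant:
`sd_specific = sqrt((sd_WT/k)² + sd_MUT²)`; the percent SD optionally
adds an `input_avg` uncertainty term (`include_input_error`, default
on), using the `ddof=1` SD of the six pooled normalized input wells.
Treating `k` as fixed is a deliberate simplification whose consequences
are quantified below. A warning is emitted when `k` leaves the
plausible envelope `[0.5, 2.0]`, since extreme coefficients usually
indicate a pipetting or plate-layout problem rather than biology.

Evidence of occupancy is an equal-variance two-sample t-test comparing
the three `WTppt/k` wells with the three `MUTppt` wells (df = 4 for
triplicates), coded `****`/`***`/`**`/`*`/`+-`/`ne` at thresholds
0.0001, 0.01, 0.05, 0.1, 0.3. When both groups have exactly zero
variance the t-statistic is undefined; we then report p = 1 if the
means agree to relative tolerance 1e-9 and p = 0 otherwise. The
tolerance absorbs float rounding in noise-free simulations without
affecting any realistic data.

## Expression contrasts

For one probe set with group means `m_WT`, `m_MUT` and
`r = m_MUT/m_WT`, the signed fold is `r` if `r ≥ 1` else `−1/r`
(magnitude always ≥ 1; swapping labels flips the sign). Its SD comes
from the delta method on the ratio of two independent group means; the
`−1/r` branch multiplies by the Jacobian `1/r²`. The per-gene p-value
is an equal-variance t-test on log2 intensities, with the same
zero-variance degenerate handling as above. Probe sets are collapsed
to genes by keeping the probe with the highest mean intensity over all
arrays, breaking exact ties lexicographically by probe id so the result
is deterministic.

The fold-scanning FDR compares, at each cutoff `c`, the observed count
of probe sets with fold magnitude > `c` against the mean count over
balanced relabelings of the arrays that mix genotypes. For 3 vs 3
arrays there are C(6,3) = 20 assignments; removing the true labeling
and its mirror and counting each split/mirror pair once leaves 9 mixed
splits. Mixing destroys the genotype contrast but preserves per-array
noise, so the null counts estimate false calls; `FDR = n_null /
n_observed`, NaN when nothing is observed. Integer percentages of
regulated probes use half-up rounding
(`floor(100·n/total + 0.5)`).

Relative transcript abundance from qPCR uses the efficiency-corrected
delta-delta-Ct form, computed as a ratio of linear signals normalized
to a reference gene; any `nd` component raises `NotDetectedError`
rather than producing a silent number.

## Design rules

Motif scanning uses the IUPAC pattern `TAATCY` compiled to a regex and
applied to both strands with overlapping matches allowed (lookahead
groups). A site's conservation count is the number of aligned species
whose orthologous six columns match the pattern exactly, with gaps and
`N` disqualifying; the reference always counts itself. Candidates
require ≥ 6 conserving species.

Amplicon windows target 110 bp (bounds 70–150), centered on the motif
with the left flank floored (`flank // 2`) and shifted inward at
sequence edges; construction fails with `InfeasibleWindowError` rather
than silently violating the bounds. Control regions are chosen greedily
left to right: a candidate window is accepted if every motif site is at
least 1 kb away, otherwise the cursor jumps past the violating site's
exclusion zone.

## Generators

**ChIP pairs** use a copy-number model. With `N` genomes per reaction,
capture efficiency `c`, background fraction `b` and true occupancy `f`
at an amplicon:

```
WTppt = N · k_t · (b + f·c)      MUTppt = N · b
WTinput = N · k_t · i            MUTinput = N · i
```

where `k_t ~ U(0.6, 1.55)` is the simulated chromatin imbalance and
`i` the input fraction. Signals are converted to Ct values and
perturbed with Gaussian noise of SD `ct_noise_sd`. Defaults:
`f = 0.02`, `b = 0.014` (so a fully occupied site gives a WT/MUT
precipitate ratio of about 2.4 — a strong but realistic ChIP
enrichment), `ct_noise_sd = 0.15`, `c = 1`, `i = 1`,
`N = 10^6`. With `c = i = 1` and zero noise the analysis pipeline
inverts the generator exactly (`percent = 100·f`), which the tests
assert to machine precision; the capture and input fractions exist so
that tests can verify the estimator is invariant to them, as the ratio
arithmetic promises.

**Expression matrices** draw per-gene baselines from a lognormal
(log-mean 6, log-sd 1, natural log), multiply the mutant mean by the
planted ratio, and add multiplicative lognormal noise with
`sigma = sqrt(log(1 + cv²))` so that `cv` is the exact coefficient of
variation. An optional outlier set inflates noise on chosen arrays.

**Alignments** build a motif-free background by rewriting any
accidental `TAATCY`/`RGATTA` occurrence outside protected intervals,
plant exact `TAATCC` motifs at configured positions, then derive each
non-reference species by light substitution (rate 0.10) and gap
(rate 0.03) noise with the planted motif columns held fixed for the
conserving subset and destroyed (`T→G`, giving `GAATCC`) for the rest.
Truth tables of planted conservation counts are returned alongside.

Generator realism limits: wells are independent given the pair (no
plate-position or batch effects), Ct noise is homoscedastic, expression
noise is symmetric on the log scale with no probe cross-hybridization,
and alignments have site-independent substitution with no rate
heterogeneity or indel realism. These generators exist to test
estimator logic, not to imitate instrument physics.

## Calibration of the significance coding

The occupancy t-test compares `WTppt/k` with `MUTppt`, but `k` is
itself estimated from six input wells and is shared across the whole
WT triplicate. A multiplicative error in `k` moves all three
normalized WT wells coherently, adding variance to the difference of
means that the within-triplicate SDs cannot see. With three input
wells per side at the same noise level as the precipitates, the
variance of the mean difference roughly doubles, inflating the
t-statistic by about √2 on null data.

The test suite measures the consequences under the default generator
(`ct_noise_sd = 0.15`, 500 seeded null runs): the null `ne` rate is
near 0.54 rather than the nominal 0.70 implied by the p ≥ 0.3
threshold, and nominal ~90% propagated-error intervals cover the true
occupancy about 73% of the time. The estimator itself stays unbiased
(mean null percent ≈ 0; relative bias < 10% at 2% planted occupancy).
The calibration tests therefore assert these measured operating
characteristics, not the nominal rates; the acceptance test that
demands the nominal `ne` rate fails, and is left failing, because the
method as specified does not achieve it. Fixing it would require
propagating `k`'s uncertainty into the test statistic (e.g. a ratio
test or hierarchical model), which would change the method rather than
implement it. The fold-scanning FDR has no shared normalizer and is
well calibrated: its pure-null mean FDR falls in [0.8, 1.25].

## Numerical conventions

- Averaging always on linear signals; sample SDs with `ddof=1`.
- `k` fixed in error propagation; SDs combined in quadrature.
- Zero-variance t-tests decided by mean comparison at rel_tol 1e-9
  (occupancy) and 1e-12 (log2 expression).
- Half-up rounding for integer percentages.
- Left flank floored in window centering; greedy left-to-right control
  tiling.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of its config, and identical configs
  reproduce byte-identical pipeline outputs.

## Limitations

- Percent occupancy assumes the mutant precipitate is a perfect
  background estimate; cross-reacting antibodies would bias it.
- The propagated SDs understate uncertainty for the reasons above;
  they are comparable across amplicons within a pair but should not be
  read as calibrated confidence intervals.
- The per-gene expression p-values are unadjusted; genome-wide claims
  should rely on the fold-scanning FDR instead.
- Conservation counting treats alignment columns as truth; misaligned
  orthologs register as non-conserving.
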