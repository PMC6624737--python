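# Methods

## Isotope arithmetic and gas handling

δ¹³C (‰) is converted to ¹³C atom fraction via `x = r/(1+r)` with
`r = r_std·(1 + δ/1000)`. The reference standard is not fixed by the gas
measurements themselves; we adopt VPDB (`r_std = 0.0111802`), the community
default for δ¹³C, and expose it in `IsotopeStandard`/`RunConfig`. Atom
percent excess (APE) is `(x − x₀)·100` percentage points, with the
time-zero atom fraction `x₀` taken per site as the mean of the n = 3
atmosphere samples (a fixed value may be supplied instead).

All mixing arithmetic (the CO₂ spike used to lift low-CO₂ headspace samples
into an analyzer's 300–2,000 μmol mol⁻¹ working range) is done on atom
fractions weighted by CO₂ moles. This is exact at any enrichment, unlike
averaging δ values, so the δ-averaging shortcut is not offered. Dilution
with CO₂-free gas carries no carbon and never enters the isotope balance —
it changes concentration only. Because real spike compositions and
concentrations are instrument-session specific, unmixing inputs are
user-supplied and the pipeline equally accepts pre-unmixed δ values.

## The positional carbon-fate model

The model predicts, per labeled carbon position, the fraction of a substrate
pulse released as ¹³CO₂ versus retained, under five partition fractions in
[0, 1]:

| parameter | meaning | default |
|---|---|---|
| `phi_ppp` | glucose entering the oxidative PPP branch | 0 |
| `a_pent`  | post-decarboxylation pentose carbon retained | 0 |
| `a_pyr`   | pyruvate diverted whole before oxidation | 0 |
| `a_ac`    | acetyl carbon diverted (anabolism *or* accumulated fermentation product) | 0 |
| `a_tca`   | cycle carbon diverted per TCA turn | 0 |

Zeros everywhere mean complete catabolic oxidation. Routing: the oxidative
PPP releases glucose C1 immediately; glycolysis splits glucose into two
pyruvates (C1→pyr C3, C2→pyr C2, C3→pyr C1; C6→C3, C5→C2, C4→C1); the
pyruvate dehydrogenase / pyruvate-ferredoxin oxidoreductase step releases
pyruvate C1 and hands C2/C3 to the acetyl pool as carboxyl/methyl carbon;
acetate maps C1/C2 to the same two acetyl fates.

Each TCA turn applies, in a fixed order: (1) diversion of a fraction
`a_tca` of all cycle carbon, including the acetyl unit entering that turn;
(2) CO₂ release of the two carboxyl positions of the four-carbon acceptor
pool; (3) symmetric redistribution — acetyl carboxyl to the new carboxyl
positions, acetyl methyl to the inner positions, half of surviving inner
carbon promoted to carboxyl (loss of positional identity in the symmetric
succinate intermediate). This is the minimal symmetric-scrambling rule that
reproduces the canonical positional facts: acetyl carboxyl carbon is first
released on cycle 2 (total (1−a)²), methyl carbon from cycle 3 at half the
remainder per cycle (total (1−a)³/(2−(1−a))), and glycolytic glucose C1
shares the methyl schedule. Full stereochemical citrate bookkeeping is not
attempted. The turn order (divert → release → redistribute) only sets the
numeric meaning of `a_tca`; alternative orderings rescale it.

Simplifications, flagged here deliberately: PPP carbons C2–C6 that survive
`a_pent` continue with the glycolytic positional mapping
(transketolase/transaldolase rearrangement and pentose recycling are out of
scope); the Entner–Doudoroff route is not modeled separately — its
immediate-C1-release signature is emulated by `phi_ppp`; `a_pyr`/`a_ac`
conflate anabolism with unconsumed fermentation products, which CO₂ data
cannot distinguish (both overestimate "anabolic" retention).

The release schedule iterates turns until the residual cycling label falls
below 1e−9 (or 10,000 turns, then flagged truncated); per position,
released + retained + residual = 1 to 1e−9. A single-molecule Monte-Carlo
tracker (tests) reproduces every release fraction to binomial precision.

## Isotopomer ratios and parameter fitting

`theoretical_ratio` compares total predicted release of a pair dosed at
equal substrate-carbon (hence equal moles within a pair), with fixed
orientations glucose U:1, pyruvate 1:(2,3), acetate 1:2 (the U:1
orientation follows the convention of plotting uniformly labeled over
1-labeled; it is configurable by inverting). Label purity (99 atom % for
commercial substrates) multiplies both members and cancels within a pair.

`fit_flux_params` minimizes squared log-ratio residuals over a coarse
Cartesian grid refined by bounded L-BFGS-B, breaking exact ties by the
smallest L1 parameter norm. Three pair ratios cannot identify five
parameters, and one direction is structurally invisible: a whole-substrate
diversion (`a_pyr`) rescales both members of the pyruvate pair identically
and trades off exactly against `phi_ppp` in the single glucose equation.
The default free set is therefore {`phi_ppp`, `a_ac`, `a_tca`}. Whatever
set is freed, identifiability is verified a posteriori by profiling: each
parameter is pinned ±0.1 and the rest re-optimized; if the objective does
not rise above the residual noise floor (1-df chi-square scaling), the
parameter is reported in `degenerate` and its point estimate should not be
interpreted. At the catabolic point `phi_ppp` itself is degenerate — when
everything downstream is oxidized, PPP vs glycolysis does not change total
release — which is the model's honest account of why integrated multi-
substrate flux fits on such data fail.

## Rate statistics

APE is regressed on time by OLS per microcosm, including an exact (0, 0)
anchor because APE is defined relative to time zero (configurable off).
Site-level statistics use all 3 × 3 numerator/denominator slope pairings
(n = 9), their mean and SEM, a two-sided one-sample t-test (df = 8) against
the catabolic-only ratio, and across sites one-way ANOVA, Tukey HSD
(family α = 0.05, compact letters by insert-and-absorb), and pairwise Welch
t-tests. Asterisks annotate p < 10⁻³/10⁻⁴/10⁻⁵.

**Caveat (important):** the nine pairwise ratios derive from six
independent slopes. Treating them as independent understates the SE of
their mean by a factor ≈ 2 (the expected sample variance of the 3×3 ratio
array is 0.75·(σ²ₐ+σ²_b) while the variance of its mean is (σ²ₐ+σ²_b)/3),
so the one-sample t-test rejects a true null in roughly a third of
replicates rather than 5%. The convention is replicated because it is the
field's reporting convention; `bootstrap_ratio_test` (resampling microcosms,
seeded, 10,000 draws) is the calibrated alternative and is not the default.
The acceptance suite's type-I calibration test documents this inflation and
fails by construction of the replicated test.

## Functional profiles

Module DEFINITION strings are parsed by a small recursive-descent parser
(space = serial steps/AND, comma = OR, plus = complex/AND, minus = optional
member, parentheses group). Optional members never block satisfaction;
steps consisting only of optional members are excluded from numerator and
denominator. MCR = 100 × satisfied/total mandatory steps, one decimal.
Q-values (a taxonomic-background feasibility statistic from an external
evaluator's genome database) are consumed as optional metadata only;
"biologically feasible" (Q < 0.5) labels appear only when a Q is supplied.

Abundance uses read-depth-weighted copy counts normalized to unassembled
metagenome size; richness uses distinct gene counts normalized to assembled
size; both as counts per billion bases, log2-transformed, with zero counts
kept at zero and a missing log value (no pseudocount). Differential calling
simulates `nss = 5` technical replicates per condition by multinomial draws
at a `pnr = 0.2` depth fraction with ±`v = 0.02` uniform jitter (the cited
simulated-replicates tool's developer-recommended values; all exposed),
computes per-feature M = log2 ratio and D = |difference| of replicate-mean
normalized values, pools (|M|, D) over all within-condition replicate pairs
and features as the noise cloud, and calls a feature significant when the
fraction of noise it dominates exceeds 0.9. Deterministic given the seed.

## Diversity

Shannon in natural log (base configurable), Simpson as 1 − Σp², inverse
Simpson as 1/Σp² (so `inv_simpson = 1/(1 − simpson)` holds identically),
classic (not bias-corrected) Chao1 `S + F1²/(2F2)` with the F2 = 0 fallback
`S + F1(F1−1)/2` and the standard asymptotic SE for each case, Fisher's α
by bracketed root finding of `S = α·ln(1 + N/α)` to 1e−10 (undefined when
every read is a distinct OTU). Rarefaction subsamples without replacement
(multivariate hypergeometric), default 1,000 repetitions, averaged, seeded.

## Synthetic data: what it does and does not establish

The microcosm generator produces linear (zero-order) APE accumulation —
matching the near-linear ¹³CO₂ return seen in substrate-adapted communities
— with Gaussian noise of 0.5 ‰ applied on δ (noise arises at the
spectrometer), triplicate live microcosms and duplicate poisoned controls
per isotopomer, sampling at 2/4/8 h, a small abiotic control rate
(0.002 APE %/h), and an uptake scale of 0.05 APE %/h per unit release
fraction (δ excursions of hundreds of ‰ over 8 h, typical of tracer-level
dosing). KO inventories are log-normal (σ = 1.5) with multinomial sampling
at 10⁶ copies and planted fold changes; OTU tables are log-normal (σ = 1.2)
multinomial samples whose default richness values (491…113) span the
observed hot-spring amplicon range from 60 to 95 °C.

Green tests on these worlds establish that the estimators recover the
structure they assume — linearity, independent Gaussian instrument noise,
well-mixed multinomial sampling. They do not establish robustness to what
real data add: saturating uptake kinetics, instrument drift, spatially
structured sediments, chimeras/contamination, or assembly biases. Field
tables from the original instruments and sequencers are required for that,
and published field values are deliberately not asserted by the test suite.

## Numerical choices

TCA schedules converge to residual < 1e−9 (≤ ~60 turns for any `a_tca`);
fitting grids step 0.1 (0.2 above three free parameters) before local
refinement; fit ties within 1e−9 break to smallest L1; profile-flatness
threshold max(1e−7, 3.84·SSE/n_pairs); Fisher α bracket expands decades
until sign change; all-zero samples, zero denominators, and depth >
total are errors rather than silent NaNs; zero-count features keep missing
log values everywhere.
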