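# Methods

This note documents the models, estimators and design choices behind
`cesdyn`, and what the synthetic-data suite does and does not establish
about real sealed-vial experiments.

## Pressure dynamics

### Signal model

A sealed, light-energized vial is treated as emitting

P(t) = B(t) + A_d · tent(t) + b·(T(t) − 30 °C) + ε(t)

where B is a slowly varying baseline (constant in stable phases, declining
monotonically during a collapse), tent is a piecewise-linear sawtooth that
rises from 0 to 1 over the light phase and falls back over the dark phase,
A_d is the day's diel amplitude (the carbon-cycling proxy), b the physical
temperature–pressure coupling of the sealed headspace, and ε sensor noise.
The sawtooth (rather than a sinusoid) makes the amplitude an exact
generative parameter and matches the observed linear rise/fall of sealed
phototrophic vials. The abiotic control contains everything but the
sawtooth and the collapse, so OLS of control pressure on temperature
identifies b; calibration subtracts b̂·(T − 30) from every biotic trace.
Calibration is per-experiment (one control, one water bath), never
per-vial.

### Cycle metrics

Cycles are half-open 24-h windows starting at light-on; a leading partial
segment and a trailing partial cycle are dropped. Interior sampling gaps up
to 5 min are bridged by linear interpolation; longer gaps invalidate the
cycle (with the reason recorded) rather than biasing it.

* **Amplitude** = max − min of the rolling-median-smoothed cycle.
* **ΔP_net** = smoothed value at the cycle end minus at the cycle start,
  the end value extended from the terminal slope so the difference spans
  exactly 24 h despite the half-open sampling grid (otherwise a perfectly
  balanced sawtooth would show a spurious ΔP_net of one sample's rise).
* **Phase summaries** pool cycles across vials and days: mean, sample SD
  (n−1), CV = 100·SD/mean, and a two-sided one-sample t-test of ΔP_net
  against zero. A ΔP_net vector that is identically zero reports t = 0,
  p = 1 by convention.

### Smoothing window

The smoother is a centered rolling median (robust to the sawtooth's apex
and to dropouts). The window default is 30 min. This was chosen by a
bias–variance analysis at the package's test scale (60-s sampling, 0.5 hPa
sensor noise): max − min is an extreme-value statistic, so residual noise
after smoothing inflates it by roughly twice the smoothed noise's expected
extreme. A 10-min window (11 samples) leaves ≈0.19 hPa residual noise and
inflates a 5-hPa amplitude by 7–11 %; a 30-min window cuts the residual to
≈0.11 hPa while flattening the apex of a 12-h tent by only ≈1 %, and the
two errors partially cancel — measured closure error stays below 3 % at
every phase. A 60-min window starts losing the apex faster than it gains
on noise. At the native 10-s sampling of a real deployment, the same
time-based window simply contains more samples and performs better; the
window is a parameter everywhere it is used.

### Amplitude semantics

"Amplitude" is operationally max − min within the cycle, which for an
asymmetric sawtooth equals the larger of rise and fall (a rise of 10
followed by a fall of 12 gives 12, not 10). The light-phase net rise is
also computed (`DielMetrics.light_rise`) for users who prefer that
definition.

## DOM molecular characterization

### Assignment

Peaks are singly charged deprotonated ions: theoretical m/z = neutral
monoisotopic mass − 1.00727646677 Da (proton). Monoisotopic masses
(C 12 exactly, H 1.0078250319, N 14.0030740052, O 15.9949146221,
S 31.97207069 Da) live in one constants module shared by generation,
assignment and binning. Candidate formulas are all CHNOS compositions
whose ion lies within the ppm tolerance (default 1 ppm) and that satisfy
the plausibility rules: C 4–50, H 4–100, N 0–4, O 1–40, S 0–2;
H/C ∈ [0.3, 2.5]; O/C ≤ 1.2; DBE integer in [0, 25]; NOSC ∈ [−4, 4]. The
NOSC window is part of the rule set because the other rules alone do not
bound the carbon oxidation state above +4 for small heteroatom-rich
compositions. Internally, the full valid-formula set under a rule set is
enumerated once (~2.3 × 10⁵ formulas at the defaults), sorted by m/z and
cached, making both single-m/z queries and whole-peak-list assignment a
binary search; tests verify exact agreement with an independent
nested-loop brute force.

The best candidate is chosen deterministically: smallest |ppm error|, then
fewest N+S atoms, then lowest DBE, then lexicographic element counts.
Peaks resolving to the same formula merge by summing intensity. Isotope
patterns, adducts other than deprotonation, multiple charging and spectral
recalibration are out of scope; classes are stoichiometric proxies, not
structures.

**Accuracy ceiling.** The CHNOS lattice under these bounds contains
near-isobaric pairs separated by as little as 0.33–0.47 mDa (e.g. the
4N+O ↔ 8H+2S replacement). Above m/z ≈ 350 such pairs fit inside a ±1 ppm
window together, and above m/z ≈ 600 the half-separation falls below
2 σ of a 0.2-ppm mass-error distribution, so a minimum-|ppm| assignment
must misassign a percentage of peaks there — no resolution-independent
rule can do better. Measured truth-formula recovery on full-range
(150–750 Da) synthetic spectra is accordingly ≈98.5 % (≈99.8 % below
500 Da), with losses concentrated at high mass. The acceptance suite
asserts a 99 % recovery bar and that check fails by this margin; the
numbers the acceptance script reports are the measured ones.

### Classes and summaries

The seven van Krevelen classes use the conventional H/C–O/C boxes
(evaluated in order, first match wins; anything outside every box is
"unclassified"): lipids H/C [1.5, 2.0], O/C [0, 0.3); aliphatic/peptides
H/C [1.5, 2.2], O/C [0.3, 0.67); carbohydrates H/C [1.5, 2.4],
O/C [0.67, 1.2]; unsaturated hydrocarbons H/C [0.7, 1.5), O/C [0, 0.1);
lignin/CRAM-like H/C [0.7, 1.5), O/C [0.1, 0.67); tannins H/C [0.5, 1.5),
O/C [0.67, 1.2]; aromatic structures H/C [0.2, 0.7), O/C [0, 0.67).
Laboratories differ on the exact boundaries; the scheme is a plain data
object and fully replaceable. Class abundance is intensity-weighted by
default (count-weighted by flag); chemodiversity is Shannon entropy in
nats over intensity shares (the log base is a convention; natural log is
used throughout, and ln/log₂ differ only by a constant factor).

## Community profile

Filtering removes ASVs with fewer than 2 reads summed over all samples
(dataset-wide singleton removal; a per-sample variant is a flag). Genus is
the 6th semicolon-delimited taxonomy rank, with `g__`-style prefixes
stripped and unparseable lineages pooled as `unclassified_genus`.
Bray–Curtis uses raw ASV counts without rarefaction. PCoA is classical
scaling — eigendecomposition of the double-centered −D²/2 — embedding only
positive eigenvalues and reporting negative ones; proportions explained
are relative to the positive spectrum. PERMANOVA uses Anderson's pseudo-F
on squared distances with free label permutation (single-factor design,
no strata); the dispersion test computes distances to group centroids in
the full principal-coordinate space with the imaginary-axis correction
(negative-eigenvalue contributions subtracted) and permutes those
distances across groups. All permutation p-values use (count + 1)/
(permutations + 1), so p = 0 never occurs; every test takes a seed and is
exactly reproducible; exhaustive enumeration replaces sampling for small
designs (n ≤ 8–9).

## Coupling statistics

The Mantel test correlates strictly-upper-triangle distance vectors
(Spearman by default, average ranks for ties), permuting rows and columns
of the second matrix jointly; two-sided p on |ρ|. The genus × DOM grid
computes Spearman ρ between each of the top genera and each (heteroatom
series, 50-Da neutral-mass bin) intensity over 200–600 Da (half-open
bins); cells with |ρ| < 0.3 are masked for display and zero-variance cells
are masked with a recorded reason rather than erroring. With only six
samples the |ρ| ≥ 0.3 mask admits nearly any nonzero rank correlation —
the grid is a description, not an inference. As a global alternative the
pipeline also runs a Mantel test between the genus Bray–Curtis matrix and
the Euclidean distance matrix of z-scored (series, bin) profiles. The KS
comparison of NOSC distributions uses the asymptotic two-sample p by
default (appropriate at thousands of formulas; an exact option exists).
The diversity comparison fits y = a + b·x and y = a + b·ln x by OLS to
paired (microbial Shannon, chemodiversity) points — pairing is per
vial/replicate at each time point — and prefers the higher R²; the log
form winning means chemodiversity falls ever faster per unit of community
diversity lost.

## Synthetic data: what it emulates, and what it does not

The generators encode the study conditions: 12 biotic vials plus one
water-only control over 54 days of 12 h/12 h light–dark cycles at 30 °C;
amplitude targets 18.68 hPa (Days 1–8), 7.22 (31–45) and 4.95 (46–54) with
a collapse (amplitude → 0, baseline declining 15 hPa) over Days 9–25 and a
linear recovery ramp to Day 31; per-unit-per-day lognormal amplitude
jitter (CV 0.35/0.10/0.25 per phase) so the early phase is strong but
erratic and the re-stabilized phase tight, as the scenario demands;
0.5 hPa sensor noise and 0.5 hPa/°C temperature coupling. The diel
temperature term is a sine in quadrature with the light schedule (peaking
6 h after light-on): a water bath's residual diel temperature has no
intrinsic phase lock to the lighting, and quadrature is the neutral
default — a user can set the phase to study confounded geometries, in
which case the linear calibration removes only the linear part. Sampling
defaults to 60 s (configurable down to 10 s) to keep a 12-vial, 54-day
dataset small.

DOM pools: per time point, CHO/CHNO/CHOS counts (3500/3046/682 →
3550/3182/518 → 3600/3448/452) drawn uniformly without replacement from
the enumerated valid-formula set inside each class box, a persistent core
pool (50 % of the smallest per-series count, drawn from the average class
mixture) shared across time points, and fresh draws topping each pool up
to its day's class mixture (58.5 % → 63.4 % → 61.5 % lignin/CRAM-like,
13.7 % → 25.6 % → 30.3 % aliphatic/peptides, minor classes shrinking).
Base intensities follow a rank power law whose exponent is solved by
bisection to hit the day's target chemodiversity; ranks are dealt to
classes by a largest-deficit greedy on cumulative weight so each class's
intensity share tracks its count share instead of riding a top-rank
lottery. Replicates multiply base intensities by lognormal noise and
re-perturb m/z (0.2 ppm).

Communities: a fixed genus succession (*Pseudomonas* 33 % → extinct;
*Brevundimonas* 12 % → 62 % → 84 %; *Porphyrobacter* rising; minor genera
fading) with deterministic truncated-geometric ASV splits within genera,
sampled as Dirichlet-multinomial counts (50 000 reads). The expected
ASV-level Shannon diversity is therefore a closed function of the
trajectories: 2.70 → 1.98 → 1.19 nats. The chemodiversity targets
(6.60, 6.26, 5.70 nats) are placed exactly on a logarithmic curve in these
expected values — the coupled, log-shaped joint decline is the scenario
being emulated, not an empirical finding. Two dispersion defaults were
calibrated once so that this built-in coupling is detectable above
replicate noise in small studies (replicate intensity σ = 0.04; Dirichlet
concentration 5000); both are free parameters the study design does not
pin down, and both are tighter than typical biological replicate
variability — a real experiment with noisier replicates would need more
than n = 2 per time point to distinguish the log from the linear form.

What passing the synthetic suite shows: the estimators recover their own
generative parameters (closure), agree with independent oracles, and hold
their nominal error rates. What it does not show: performance under
instrument drift, mass-dependent calibration error, chimeric or
mis-classified ASVs, compositional artifacts of relative abundance, or
community/chemistry structure unlike the encoded scenario. No fungal or
eukaryotic community component is simulated, no isotopologue peaks, and no
raw reads.

## Numerical conventions

Degenerate inputs fail loudly and specifically: constant-temperature
calibration, double calibration, phases with fewer than two cycles, empty
peak lists, zero-read samples, nonpositive intensities, log fits at
nonpositive diversity all raise typed errors naming the offending
quantity. Interchange files are plain text; writers emit shortest
round-trip float representations and readers parse them with correctly
rounded conversion, so write→read is bit-exact. Pipeline reports contain
no timestamps and echo every seed and permutation count, making identical
configurations byte-identical. Problem sizes in the test and acceptance
suites (60-s sampling, 2000-peak assignment benchmarks, 1000-simulation
type-I calibrations at 199 permutations, 100-seed preference runs) are
the package's chosen test scale; all are parameters.
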