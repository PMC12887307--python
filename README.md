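# cesdyn

Stability analytics for sealed algae–bacteria microcosms (closed microbial
ecosystems, CES): materially sealed, light-energized vials in which an alga
and a soil-derived bacterial community cycle carbon with no external inputs.
The only ecosystem-scale vital sign such a vial emits is its headspace
pressure, which rises over the light phase (net photosynthetic O₂ release)
and falls in the dark (net respiration). `cesdyn` turns that signal — together
with FT-ICR-MS peak lists of the dissolved organic matter (DOM) pool and ASV
tables of the bacterial community — into a quantitative account of whether
the ecosystem is stable, collapsing, or recovering, and of how community
succession couples to the chemistry that sustains it.

It is written for microbial ecologists and biogeochemists running sealed-vial
experiments, and ships a seeded synthetic-data suite emulating a 54-day
biphasic-stability study so the whole pipeline is testable without any
instrument data.

## What it computes

**Diel pressure dynamics** (`cesdyn.pressure`). Raw traces are calibrated to
a 30 °C reference using an abiotic control: OLS of control pressure on
temperature gives the empirical slope b̂ (hPa/°C), and P′ = P − b̂·(T − 30).
Calibrated traces are cut into 24-h light–dark cycles; per cycle the
oscillation amplitude (max − min of the median-smoothed trace, the proxy for
carbon-cycling intensity) and the net daily change ΔP_net (end − start;
zero means photosynthesis and respiration balance). Phase summaries pool
cycles across vials: mean ± SD, CV %, and a one-sample t-test of ΔP_net
against 0.

**DOM molecular characterization** (`cesdyn.dom`). Negative-mode [M−H]⁻
peaks are assigned CHNOS formulas by exact-mass search (default ±1 ppm)
under standard DOM rules (C₄–₅₀H₄–₁₀₀N₀–₄O₁–₄₀S₀–₂, H/C ∈ [0.3, 2.5],
O/C ≤ 1.2, integer DBE ∈ [0, 25], NOSC ∈ [−4, 4]); ties break by smallest
|ppm error|, then fewest N+S, then lowest DBE. Each formula gets van
Krevelen descriptors — H/C, O/C, DBE = C − H/2 + N/2 + 1, and the nominal
oxidation state of carbon NOSC = 4 − (4C + H − 3N − 2O − 2S)/C — and one of
seven compound classes (lipids, aliphatic/peptides, carbohydrates,
unsaturated hydrocarbons, lignin/CRAM-like, tannins, aromatic structures).
Sample summaries: class abundances, heteroatom series counts
(CHO/CHNO/CHOS), shared/unique formula sets between samples, and the
chemodiversity H = −Σ pᵢ ln pᵢ over peak-intensity shares.

**Community profile** (`cesdyn.community`). ASV filtering (dataset-wide
singleton removal), genus-level relative abundance, Shannon diversity
(nats), Bray–Curtis dissimilarity, principal coordinates (classical
scaling, negative eigenvalues reported), seeded PERMANOVA (pseudo-F, R²,
permutation p with the (count+1)/(n+1) convention) and a betadisper-style
homogeneity-of-dispersion test.

**Community–chemistry coupling** (`cesdyn.coupling`). Seeded Mantel test
(exhaustive mode for small n), a genus × (series, 50-Da mass-bin) Spearman
grid over 200–600 Da masked at |ρ| < 0.3, two-sample Kolmogorov–Smirnov
comparison of NOSC distributions between time points, and a linear-vs-
logarithmic OLS comparison of chemodiversity on microbial Shannon diversity
(does chemistry collapse faster than the community?).

**Synthetic study** (`cesdyn.synthetic`). Seeded generators for all three
data streams with full ground truth, defaulting to the biphasic scenario:
high diel amplitude (Days 1–8), collapse and recovery (Days 9–30),
re-stabilization (31–45) and late decline (46–54); CHOS formula counts
falling 682 → 518 → 452 while lignin/CRAM-like composition rises; a genus
succession from *Pseudomonas* to *Brevundimonas*/*Porphyrobacter*
dominance with jointly declining microbial and chemical diversity.

## Worked example

```python
from cesdyn.pressure import analyze_pressure_experiment
from cesdyn.synthetic import default_pressure_scenario, gen_pressure_experiment

traces, control, truth = gen_pressure_experiment(default_pressure_scenario(seed=1))
frame, phases, model = analyze_pressure_experiment(
    traces, control, phases=[(1, 8), (31, 45), (46, 54)])
print(f"calibration slope {model.slope:.3f} hPa/degC")
for window, s in phases.items():
    print(f"days {window}: amplitude {s.mean_amplitude:.2f} +/- "
          f"{s.sd_amplitude:.2f} hPa (CV {s.cv:.1f}%), "
          f"dP_net {s.mean_delta_p_net:+.3f} hPa (p={s.p_value:.3f})")
```

prints

```
calibration slope 0.502 hPa/degC
days (1, 8): amplitude 19.06 +/- 7.02 hPa (CV 36.8%), dP_net +0.004 hPa (p=0.865)
days (31, 45): amplitude 7.21 +/- 0.70 hPa (CV 9.7%), dP_net +0.003 hPa (p=0.864)
days (46, 54): amplitude 5.03 +/- 1.06 hPa (CV 21.1%), dP_net -0.004 hPa (p=0.851)
```

The recovered calibration slope matches the generative temperature coupling
(0.5 hPa/°C); the phase means track the scenario's 18.68/7.22/4.95 hPa
targets; the re-stabilized phase shows both the lowest amplitude CV and a
ΔP_net indistinguishable from zero — the quantitative signature of a
balanced, stable ecosystem.

The same study from the shell:

```bash
cesdyn simulate --out study/ --seed 1
cesdyn pressure --input study/pressure.csv --control CTRL \
    --phases 1:8,31:45,46:54 --out results/
cesdyn dom --peaks study/dom --out results/
cesdyn community --table study/asv_table.tsv --samples study/samples.tsv \
    --seed 42 --out results/
cesdyn couple --peaks study/dom --table study/asv_table.tsv \
    --samples study/samples.tsv --seed 42 --out results/
```

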