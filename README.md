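# gyretrend

Trend detection and symbolic-regression attribution for multidecadal
ocean-productivity time series.

Open-ocean time-series stations (the kind run in subtropical gyres since
the late 1980s) produce depth-resolved records of temperature, density,
macronutrients (NO₃, PO₄, SiO₂), accessory pigments (chlorophyll *a*/*b*,
fucoxanthin, lutein+zeaxanthin) and measured, depth-integrated net primary
productivity (NPP, mg C m⁻² d⁻¹). Two questions recur: *is anything
trending over decades*, and *which physical/chemical drivers explain the
productivity signal*? `gyretrend` implements the full analysis chain for
both, for oceanographers and ecological time-series analysts who want the
pieces as a tested, scriptable library rather than a one-off notebook.

The chain:

1. **Preprocessing** — casts → analysis variables: trapezoid integration
   over the photic zone (0–120 m), mean temperature, the stratification
   ratio ρ(20 m)/ρ(120 m), mixed-layer depth by density threshold
   (Δρ = 0.125 kg m⁻³), time encodings, monthly aggregation with
   month-mean gap filling, complete-case filtering.
2. **Trends** — Mann–Kendall S with tie-corrected variance
   `var(S) = [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18`, Seasonal Kendall
   (per-calendar-month statistics summed, removing the seasonal cycle),
   Sen slopes (median pairwise slope, units yr⁻¹), and rolling 10-year
   windowed scans.
3. **Symbolic regression** — a genetic-programming engine evolving
   expression trees over {+, −, ×, ÷, trig/hyperbolic/inverse, exp, ln,
   logistic, gauss} that map the twelve predictors
   NPP = f(J-day, Y-day, MLD, ΔD, T, NO₃, PO₄, SiO₂, Fuco, Chl b, Chl a,
   Lut-Zea) to NPP, minimising mean absolute error with protected
   operator semantics, in replicate experiments.
4. **Validation** — k-fold cross-validation (k = 10), Pearson r and
   relative absolute error (100% = predicting the mean), with OLS and a
   small back-propagation network as self-contained baselines.
5. **Sensitivity** — per-variable finite-difference impact metrics
   (Sensitivity, %Positive, Positive Magnitude, %Negative, Negative
   Magnitude) and fold-level sign probabilities.

A synthetic-record generator emulates the station design (monthly casts,
fortnightly in winter–spring, 1990–2016, 0–120 m profiles, seasonal
cycles, a +0.021 °C yr⁻¹ warming trend, a planted NPP response law, noise,
missing values) with known ground truth, so every stage is testable
without downloading anything. The ten replicate equations published for
this problem ship as parseable text fixtures, and a structural sign
analysis reproduces their consensus (temperature negative in 9/10,
density ratio negative in 8/10). See `docs/methods.md` for the science
and all numerical conventions.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic record and write tables under `results/`:

```sh
python analysis/01_simulate_record.py
python analysis/02_trend_analysis.py
python analysis/03_fixture_equations.py
python analysis/04_symbolic_regression.py
python analysis/05_cross_validation.py
python analysis/06_sensitivity.py
```

Step 01 generates 432 casts (1990–2016; 254 complete cases at 5%
value-wise missingness). Step 02 then prints, for the record whose only
planted physical trend is the +0.021 °C yr⁻¹ column warming:

```
full-record seasonal Sen slopes (per year):
     temp: +0.01516  p<0.001
      mld: -0.002468  n.s.
      npp: -0.556  n.s.
```

— the warming is detected at p < 0.001 with a slope estimate within
sampling error of the planted rate (this single-seed estimate is ~1.5σ
low; averaged over 200 seeds the estimator is within 1%, which is what
`scripts/acceptance.py` measures), while the un-trended variables stay
non-significant. The NPP drift of about −0.6 mg C m⁻² d⁻¹ yr⁻¹ is the
indirect temperature effect implied by the planted law (−50 × 0.021).

Step 04 evolves ten replicate GP models (r ≈ 0.96, relative error ≈ 28%
against a ~32 noise floor), step 05 cross-validates them against the
baselines (OLS pooled r = 0.972 / 25.2%, MLP 0.959 / 28.2%, GP
0.963 / 29.5%), and step 06 aggregates sensitivity across replicates:

```
     fuco:  positive  sens=0.698  (neg 0/10, pos 10/10)
      no3:  positive  sens=0.294  (neg 0/10, pos 10/10)
     chla:  positive  sens=0.265  (neg 1/10, pos 7/10)
     temp:  negative  sens=0.031  (neg 8/10, pos 1/10)
```

— the planted attribution (pigments and nitrate up, temperature down) is
recovered by majority across replicates. The planted density-ratio effect
is mostly *not* recovered at desk scale: its dynamic range is ~10⁻³ and it
co-varies with temperature, an identifiability limit discussed in
`docs/methods.md`.

The same stages are scriptable via the CLI
(`gyretrend simulate|trends|evolve|validate|sensitivity|run`), and
`gyretrend run` executes the whole study into one reproducible,
manifest-stamped directory.

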