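# bearrhythms

Annual-rhythm analysis for biologging data from free-ranging bears.

Hibernating brown bears (*Ursus arctos*) record months of body temperature
(Tb), heart rate (HR) and locomotor activity on implanted loggers and
collar accelerometers.  Over the year their biological rhythms reorganise:
diel (~24 h) and ultradian (~12 h) rhythms entrained by the light-dark
cycle dominate the active season, while during hibernation physiological
rhythms slow to multiday (infradian) cycles even as activity can stay
diel.  `bearrhythms` turns that analysis into a tested, reusable pipeline
for chronobiologists and wildlife physiologists:

1. **Seasonal segmentation** — den entry is the first autumn day with
   daily mean Tb ≤ 36.4 °C for seven consecutive days, den exit the first
   spring day with daily mean Tb ≥ 36.7 °C for seven days; transition
   states around the den dates get variable-specific extents (Tb, HR and
   activity start their seasonal drift 13, 24 and 25 days before entry
   and 33, 63 and 10 days before exit).
2. **Windowing** — implausible Tb (< 30 °C), 14 days after captures and
   3 days after disturbances are excluded; each state is tiled into
   25-day analysis windows (terminal remainders ≥ 15 days kept; windows
   with sampling gaps > 2 days dropped).
3. **Rhythm detection** — the classical normalized Lomb-Scargle
   periodogram over a 2–168 h band,

   P(ω) = [ (Σᵢ yᵢ cos ω(tᵢ−τ))² / Σᵢ cos² ω(tᵢ−τ)
          + (Σᵢ yᵢ sin ω(tᵢ−τ))² / Σᵢ sin² ω(tᵢ−τ) ] / (2s²),

   with τ the decoupling phase and s² the sample variance — valid for
   uneven sampling.  The highest peak is tested with an analytic
   false-alarm probability (Baluev's aliasing-free bound by default) and
   classified ultradian (2–18 h), diel (18–36 h), infradian (36–168 h) or
   arrhythmic when not significant.
4. **Covariates** — day length from the Forsythe solar-declination model,
   ambient temperature and snow depth interpolated from the three nearest
   weather stations (inverse-distance weighting), plus den attributes and
   intrinsic predictors.
5. **Rhythm-probability models** — penalized multinomial logistic
   regression P(class c | x) = exp(ηc) / Σk exp(ηk) with shrink-to-linear
   spline smooths and ridge-penalized bear/season group effects; candidate
   models are compared by grouped cross-validated expected log predictive
   density (elpd) and near-ties combined by stacking weights on the
   simplex.
6. **Reporting** — double-plot actograms/thermograms (day x beside day
   x+1), sunrise/sunset overlays, and period summary tables per state and
   rhythm class.

Because no public bear dataset accompanies the method, the package ships a
synthetic bear-year generator (`bearrhythms.synthetic`) with known ground
truth — planted den dates, rhythm periods, class labels and multinomial
coefficients — against which every stage is tested end to end.

## Worked example

```python
from bearrhythms.synthetic import SimulationConfig, simulate_bear_year
from bearrhythms import segmentation as seg, windowing as win, spectral

cfg = SimulationConfig(n_bears=1, seed=42, den_date_jitter_days=0)
series, truth = simulate_bear_year(cfg, "bear01", variables=("tb",))

smap = seg.build_state_map(series["tb"], series)
print("den entry:", smap.den_entry, "| den exit:", smap.den_exit)

windows, _ = win.tile_windows(smap.intervals["tb"], series["tb"],
                              den_entry=smap.den_entry)
for w in windows[:3]:
    call = spectral.classify_window(w)
    print(w.start.date(), w.state, call.rhythm_class,
          f"period={call.peak_period_hours:.1f} h")
```

prints

```
den entry: 2015-11-01 | den exit: 2016-04-11
2015-05-01 active diel period=24.0 h
2015-05-26 active diel period=24.0 h
2015-06-20 active diel period=24.0 h
```

The detected den entry matches the planted date exactly (the noisy exit is
one day late — daily-mean noise at the threshold day); the active-season
Tb windows carry a significant 24 h rhythm, and hibernation windows from
the same bear classify as infradian with ~120 h periods.  The same chain
is available from the shell:

```sh
bearrhythms run-all --n-bears 5 --seed 1 --out results/
```

which writes states, windows, rhythm calls, covariates, the merged model
table, a period summary and a run log as CSV/JSON.

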