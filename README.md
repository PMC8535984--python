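# greycast

Grey forecasting and composite correlation analysis for small-sample
annual indicator series — occupational-accident counts and mortality
rates, economic indicators, and similar short positive time series where
only a couple of decades of annual data exist.

The package implements:

* **GM(1,1)** — the classical first-order grey model: cumulative-sum
  (AGO) smoothing, a grey difference equation
  `x⁽⁰⁾(k) + a·z⁽¹⁾(k) = b` fitted by least squares, and the exponential
  whitened solution `x̂⁽¹⁾(k) = (x⁽⁰⁾(1) − b/a)·e^(−a(k−1)) + b/a`.
* **GGM(1,1)** — a Gaussian grey variant in which the background value
  and the right-hand side carry a Gaussian time weight `(k−μ)/σ²`, giving
  the saturating predictor
  `x̂⁽¹⁾(k) = (x⁽⁰⁾(1) − b/a)·e^(a(1−μ)²/(2σ²))·e^(−a(k−μ)²/(2σ²)) + b/a`
  whose increments rise to a single peak and then decline.
* **Grey relational analysis** with the resolution-coefficient
  formula `ξᵢ(k) = (m + ρM)/(Δᵢ(k) + ρM)`, its time-average degree γᵢ,
  the sample Pearson coefficient εᵢ, and the composite coefficient
  `ρᵢ = φ·γᵢ + (1−φ)·εᵢ` that blends shape similarity with linear
  correlation (ρ = 0.5, φ = 0.5 by default).
* A packaged national accident-death series (China, 2000–2020), a
  published correlation-coefficient table, and a seeded synthetic-series
  generator so everything is testable offline.

See `docs/methods.md` for the full model account, conventions and
limitations.

## Worked example

```python
import greycast as gc

series = gc.load_fixture("accident_deaths_2000_2020").series
fit = gc.fit_grey_model(series, mode="gm", error_denominator="fitted")
print(f"a={fit.a:.6f}  b={fit.b:.3f}")
print(f"mean |rel err|={fit.errors.delta:.6f}  max |rel err|={fit.errors.max_abs:.6f}")
fc = gc.forecast(fit, 5)
for year, value in zip(fc.years, fc.values):
    print(year, f"{value:.1f}")
```

prints

```
a=0.073470  b=168409.698
mean |rel err|=0.105358  max |rel err|=0.280389
2021 35394.5
2022 32887.3
2023 30557.7
2024 28393.1
2025 26381.8
```

The development coefficient a ≈ 0.0735 means fitted annual deaths decay
by a factor e^(−a) ≈ 0.929 per year; the maximum relative error of 0.28
sits after the sharp 2015→2016 drop in the raw series, which a smooth
exponential cannot follow (the fit also emits an order-ratio advisory
warning flagging exactly that break). The same call with `mode="ggm"`
fits the Gaussian variant.

The same workflow from the shell:

```sh
greycast fit --input accidents.csv --model gm --error-denominator fitted --out reports/
greycast forecast --input accidents.csv --model ggm --horizon 10 --out reports/
greycast gra --panel panel.csv --references deaths,mort_gdp,mort_workers --out reports/
greycast simulate --spec spec.yaml --out synthetic.csv
```

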