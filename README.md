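# tempmort

Current and future heat- and cold-attributable mortality with distributed
lag non-linear models (DLNM), for epidemiologists and climate-health
analysts who need regional projections under climate, adaptation and
population scenarios.

## What it computes

For each region, daily all-cause death counts are regressed on daily mean
temperature with a quasi-Poisson DLNM:

    log E[Y_t] = α + cb(T, lag; θ) + ns(t; β) + dow(t; γ)

where `cb` is the cross-basis of natural cubic splines over temperature and
over lags 0–21 days, `ns(t)` a natural cubic spline of time (7 df per year)
controlling season and trend, and `dow` day-of-week indicators.  Knots are
either fixed (exposure at the 10th/75th/90th temperature percentiles, two
internal lag knots) or chosen by quasi-AIC.  The fitted surface is reduced
to the overall cumulative relative-risk curve RR(T), centred at the
region's minimum-mortality temperature (MMT, 14–16 °C in the packaged
Finnish county registry), and deaths attributable to non-optimal
temperature follow

    AN_t = D_t · (1 − exp(−log RR(T_t))),

split into heat (T > MMT) and cold (T < MMT), aggregated over calendar
decades, and expressed as the attributable fraction AF = 100·AN/ΣD.
Projections apply the curve to multi-model daily temperature ensembles
under moderate (SSP2-4.5) and high (SSP5-8.5) emission scenarios, with
optional heat-adaptation scaling (0/20/50% reduction of excess heat RR) and
population growth.  95% intervals are empirical Monte-Carlo intervals over
coefficient draws, pooled across ensemble members.

Because the underlying register data are restricted, the package ships a
first-class synthetic-data module (`tempmort.synthetic`) that fabricates
every input with the assumed statistical structure — seasonal AR(1)
temperatures, overdispersed counts from a known exposure-lag-response
surface, data-protection censoring of counts below 3, pseudo-GCM warming
trajectories and a 5-year-step population path.  See `docs/methods.md`.

## Worked example

```python
from tempmort import make_study, RunConfig, run_full_pipeline, predict_rr

study = make_study(n_regions=1, n_members=3, seed=42)   # 18-year region + ensembles
cfg = RunConfig(mc_draws=500, seed=42)
res = run_full_pipeline(cfg, study, adaptations=(0.0, 0.5))

r = res["region1"]
print(round(r["fit"].dispersion, 3))
print(predict_rr(r["curve"], [26.0, -4.0]).round(3).to_string(index=False))
for (scen, a), payload in r["scenarios"].items():
    tab = payload["result"].per_decade
    heat = tab[tab.component == "heat"].set_index("decade")
    print(scen, "a=", a,
          "| 2010s heat AN:", round(heat.loc["2010-2019", "an"], 1),
          "| 2090s heat AN:", round(heat.loc["2090-2099", "an"], 1),
          "| ratio:", payload["heat_ratio"])
```

prints

```
1.492
 temperature    rr  lo95  hi95
        26.0 1.380 1.011 1.884
        -4.0 1.432 1.199 1.710
SSP2-4.5 a= 0.0 | 2010s heat AN: 442.9 | 2090s heat AN: 1524.9 | ratio: 3.4
SSP2-4.5 a= 0.5 | 2010s heat AN: 233.0 | 2090s heat AN: 831.9 | ratio: 3.6
SSP5-8.5 a= 0.0 | 2010s heat AN: 423.0 | 2090s heat AN: 3512.3 | ratio: 8.3
SSP5-8.5 a= 0.5 | 2010s heat AN: 222.2 | 2090s heat AN: 1999.1 | ratio: 9.0
```

The Pearson dispersion 1.492 recovers the generator's overdispersion of
1.5.  The fitted overall cumulative RR at 26 °C (MMT+10) and −4 °C
(MMT−20) brackets the generating values 1.3 and 1.4 within its confidence
intervals.  End-of-century heat-attributable deaths grow roughly 3–4-fold
under moderate emissions and 8–9-fold under high emissions; 50% heat
adaptation roughly halves the excess deaths in every decade (the ratio
itself is similar because baseline and future decades scale together).

There is also a CLI:

```sh
tempmort simulate --out study/ --seed 7 --regions 2 --small-regions 1
tempmort fit --data study/ --region region1 --out results/
tempmort curve --data study/ --region region1 --out results/
tempmort project --data study/ --region region1 --out results/ --adaptation 0.5
tempmort all --out results/ --seed 7
```

Each run writes a `manifest.json` (config hash, seed, version, file list)
sufficient to reproduce outputs bit-identically.

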