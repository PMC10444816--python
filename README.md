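# coraltol

**Emergent coral thermal tolerance from heat stress and bleaching surveys.**

Coral bleaching risk is conventionally predicted from degree heating weeks
(DHW): the 84-day rolling sum of daily sea-surface-temperature exceedances
above a fixed climatological threshold (the maximum of monthly means, MMM),
counting only exceedances ≥ 1 °C and dividing by 7,

```
HotSpot_i = max(0, SST_i − MMM),     DHW_i = Σ_{n=i−83..i} HotSpot_n / 7   (HotSpot_n ≥ 1)
```

But coral assemblages are not static: community turnover, acclimatisation
and adaptation can raise the temperature they tolerate. `coraltol` treats
the rate of that rise, ρ (°C/decade), as an unknown to be estimated from
decades of bleaching surveys. It simulates stress baselines that climb in
annual steps of ρ/10 from a start year (1988 by default), recomputes DHW
under each candidate ρ, fits a beta regression of transformed bleaching
severity on DHW with a Matérn-correlated latent spatial field,

```
CB_i ~ Beta(π_i, θ),   logit(π_i) = β₀ + β₁·DHW_i + u_i,   u ~ GMRF(0, Ω(r, σ))
```

and selects the most-likely historic ρ by parsimony (DIC) across a 13-rate
grid (0–0.3 °C/decade, step 0.025). The selected trajectory can then be
carried forward: bias-correct model (GCM-like) SST by the delta method,
compute future DHW, flag bleaching events (annual-max DHW ≥ 8 °C-weeks) and
"high-frequency bleaching" years (≥ 2 events in the centred decade), and
summarise ensembles as mean ± SE.

The package is for reef researchers who have (or can simulate) per-cell
daily SST and ordinal bleaching-severity surveys (0 = none, 1 = 1–10 %,
2 = 11–50 %, 3 = > 50 %). A synthetic-data generator with known ground
truth makes the whole pipeline testable without satellite downloads.

## Worked example

```python
import numpy as np
from coraltol import (SpatialBetaModel, compute_climatology, run_rate_scan)
from coraltol.synthetic import (SyntheticTruth, default_cells, generate_sst,
                                generate_surveys, true_dhw_fields)

truth = SyntheticTruth(rho_true=0.1, seed=7)     # tolerance rose 0.1 °C/decade
cells = default_cells(20)                        # ~100 km of 0.05° reef cells
sst = generate_sst(cells, (1985, 2020), truth)   # heatwaves in 1998/2010/2017
obs = generate_surveys(true_dhw_fields(sst, truth), cells, truth, n_obs=300)

clim = {cid: compute_climatology(s, (1985, 2012)) for cid, s in sst.items()}
scan = run_rate_scan(sst, obs[["record_id", "date", "day_known",
                               "lat", "lon", "severity"]],
                     clim, cells, seed=7)
print(scan.summary())
```

prints (abridged):

```
Tolerance-enhancement rate scan
============================================================
rates scanned   13 (0.000 .. 0.300 °C/decade)
best rate       0.100 °C/decade (min DIC)
------------------------------------------------------------
  rate       dic   beta1  success_rate  over_rate  under_rate  delta_dic
0.0000 -542.4542  0.3520        0.5767     0.2433      0.1800    47.9702
0.0750 -580.7748  0.4987        0.5933     0.2533      0.1533     9.6496
0.1000 -590.4245  0.5608        0.5967     0.2533      0.1500     0.0000
0.1250 -579.2736  0.6105        0.5500     0.2933      0.1567    11.1509
0.3000 -420.2107  0.6145        0.4667     0.2067      0.3267   170.2138
```

(abridged to five of the 13 rows). The scan recovers the true rate: DIC is
minimised at ρ = 0.1 °C/decade (ΔDIC ≥ 9.6 to every other rate here),
prediction success peaks there, and pushing the rate too high makes the
model increasingly under-predict observed bleaching (under_rate roughly
doubles by ρ = 0.3) because heat stress in the later events is erased —
exactly the signature that identifies a historic tolerance rise. A single
fit is also available statsmodels-style:

```python
from coraltol import attach_dhw, prepare_response
df = prepare_response(attach_dhw(obs, dhw_fields, cells))  # dhw + (0,1) response
res = SpatialBetaModel.from_dataframe(df, spatial=True).fit(seed=1)
print(res.summary())
res.predict(np.linspace(0, 12, 50))   # mean curve + 95% credible band
```

A `coraltol` command-line interface wraps the same steps
(`coraltol synth | climatology | dhw | scan --help`).

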