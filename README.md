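# pfsmoke

Estimating the contribution of **prescribed fire (PF)** — intentional,
controlled burning used for land management and wildfire-fuel reduction —
to ambient fine particulate matter (PM2.5) and its chemical components
(elemental carbon EC, organic carbon OC, nitrate, sulfate, and a residual
"other").

In regions where prescribed burning dominates the fire calendar, such as
the southeastern US, smoke is a major PM2.5 source, yet its contribution
cannot be measured directly: monitors see total PM2.5 from all sources.
`pfsmoke` implements the multistage estimation framework used for this
problem, exercised end to end on synthetic data with known ground truth so
that every stage is testable:

1. **Burned-area calibration** — satellite fire products over-report the
   area of the burns they detect and miss small fires. Gridded daily
   satellite areas are regressed (through the origin) on burn-permit
   records where permit reporting is complete, and the fitted slope is
   applied as a single region-wide scaling factor.
2. **Emissions** — the generic fire-emissions equation: burned area ×
   fuel load × consumption fraction × per-species emission factor.
3. **Zero-out attribution** — the PF contribution is the pointwise
   difference between paired transport-model runs with and without PF
   emissions:
   `ΔC_PF(x,t) = C_all(x,t) − C_no-PF(x,t)`.
4. **Data fusion** — model fields are corrected toward monitor
   observations: a daily polynomial regression plus inverse-distance-
   weighted residual ratios for total PM2.5; for components, fusion acts
   on species-to-total *ratios* and renormalizes them, so fused components
   always sum exactly to the fused total (mass balance). Observation-
   adjusted PF impacts scale the simulated impact by the fused/simulated
   concentration ratio, preserving the simulated PF fraction:
   `ΔPF^DF = ΔPF^sim × C^DF / C^sim`.
5. **Evaluation** — regulatory model-performance statistics (MB, RMSE,
   NMB, NME, MNB, MNE, R²), photochemical-benchmark flags, and 10-fold
   *site-held-out* cross-validation of the fusion.
6. **Aggregation** — exact polygon-cell coverage weights, area-weighted
   regional daily means, seasonal summaries (mean ± SD, median), PF shares
   of ambient levels, and threshold-exceedance statistics.

The synthetic generator produces the burn record (JFMA-heavy seasonal
structure, log-normal areas), degraded satellite/permit views of it, paired
concentration fields from a linear Gaussian-plume toy model, "model"
fields with realistic systematic biases (PM2.5 −20%, EC −29%, OC +42%, …)
plus smooth structural error, and noisy monitor observations on daily and
1-in-3-day schedules. See `docs/methods.md` for the model details and
every default.

## Worked example

```python
from pfsmoke.synthetic import default_fixture
from pfsmoke.fusion import run_fusion
from pfsmoke.evaluation import kfold_cv
from pfsmoke.fields import TOTAL

study = default_fixture(seed=0)            # 30x30 grid, 12 km cells, 120 days
fused = run_fusion(study.model_pair, study.observations, study.sites)
cv = kfold_cv(study.model_pair.all_emissions[TOTAL],
              study.observations, study.sites, study.grid, k=10, seed=0)
print(f"CV RMSE  sim {cv.pooled_sim.rmse:.2f} -> fused {cv.pooled_fused.rmse:.2f} ug/m3")
print(f"CV R^2   sim {cv.pooled_sim.r_squared:.2f} -> fused {cv.pooled_fused.r_squared:.2f}")
```

prints

```
CV RMSE  sim 2.70 -> fused 1.54 ug/m3
CV R^2   sim 0.41 -> fused 0.63
```

i.e. against observations at *withheld* monitor sites, fusion cuts the
error of the raw model (which carries a −20% mean bias and smooth
structural error) roughly in half and raises the explained variance. On
the same fixture the burned-area calibration recovers its 0.66 scaling
factor (fitted slope 0.660), the fused-minus-simulated network bias moves
from −18.7% to ≈0%, and the regional PF–PM2.5 mean is 0.32 μg/m³, about
4.9% of the ambient total over the mid-September–mid-January window, with
EC ≈ 13% and OC ≈ 47% of the PF-attributable mass.

A full pipeline run from the command line:

```sh
pfsmoke run-all --seed 0 --out artifacts/
pfsmoke -v run-all --config my_config.yaml --set generator.noise_sd=0.2 --out artifacts/
```

writes every stage artifact (event CSVs, paired/fused NetCDF fields,
calibration and evaluation JSON, aggregation CSV) plus a `manifest.json`
stamped with the configuration hash and seed; reruns with the same
configuration are bit-identical.

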