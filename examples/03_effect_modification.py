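"""Effect modification by district-level indicator tertiles.

Districts are classified into low/middle/high thirds of an indicator
(here: population density) and the model is refit with PM2.5 x tertile
interaction terms.  The data are generated with a stronger slope in
high-tertile districts, so the high-vs-low contrast should be positive,
while the middle-vs-low p-value stays unremarkable.
"""

import numpy as np

import ccxburden as cx

shift = np.log(1.02) / 10  # extra log-OR per ug/m3 in high-tertile districts
cfg = cx.SimulationConfig(
    n_districts=12,
    date_start="2015-01-01",
    date_end="2016-12-31",
    baseline_deaths_per_district_day=2.0,
    beta_true=np.log(1.005) / 10,
    interaction_shift=(0.0, 0.0, shift),
    seed=3,
)
exposure = cx.simulate_exposure(cfg)
lagged = cx.build_lagged_exposure(exposure)
indicators = cx.simulate_indicators(cfg)
cats = cx.tertile_categorize(
    indicators[["district_id", "population_density"]], "population_density"
)
cat_map = dict(zip(cats["district_id"], cats["category"].astype(str)))
records = cx.simulate_mortality(exposure, cfg, district_categories=cat_map)
ccdata, _ = cx.build_case_crossover(records, lagged)

res = cx.fit_with_interaction(ccdata, ccdata["district_id"].map(cat_map))
print("OR per 10 ug/m3 by population-density tertile")
print("(generated: low/middle OR 1.005, high OR ~1.025)\n")
for level in ("low", "middle", "high"):
    orr, lo, hi = res.ors[level]
    print(f"  {level:>6}: {orr:.4f} (95% CI {lo:.4f}-{hi:.4f})")
print(f"\nWald p, middle vs low: {res.p_middle:.3f}")
print(f"Wald p, high vs low:   {res.p_high:.3f}")

b = res.fit.params["_x_high"]
se = (res.fit.cov.loc["_x_high", "_x_high"]) ** 0.5
print(
    f"\nhigh-vs-low contrast: {b:+.6f} per ug/m3 "
    f"(generated {shift:+.6f}); |error| = {abs(b - shift) / se:.1f} SE"
)
print("at this sample size the contrast is estimated consistently but a")
print("significant p-value is not expected — power for modification of")
print("this size needs far larger studies")
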