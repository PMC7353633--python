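# milkscreen

Compositional fraud screening for UHT milk.

Liquid milk is among the most frequently adulterated foods: it is traded
in bulk, priced on composition, and easy to stretch with water or to
"correct" with nitrogen-rich compounds (melamine, urea), dairy or plant
powders, carbohydrates, or concealing preservatives. `milkscreen`
implements an anomaly-screening pipeline for the seven compositional
features reported by FTIR milk analysers — protein, fat, total solids,
solids-non-fat, lactose (% w/w), density (g/L) and freezing-point
depression (°C) — aimed at food-quality laboratories and researchers in
food-authenticity chemometrics:

- **Univariate percentile boundaries.** Per-variable 0.5th/99.5th
  percentile limits from a genuine control set, plus a variance-adjusted
  variant `x_new = (x − μ)·f + μ` (f = 2) that widens limits to the
  dispersion seen in large raw-milk monitoring programmes.
- **One-class classifiers.** KNN (mean distance to the k nearest genuine
  samples), SIMCA (distance to a principal-component class model) and an
  RBF one-class SVM, each autoscaled and thresholded at the 99% quantile
  of pooled leave-30%-out cross-validation scores (100 repetitions,
  scikit-learn estimator API: `fit` / `predict` / `decision_function`).
- **Adulteration simulator.** Mass-balance prediction of apparent
  composition for 24 adulterants in 5 categories — 288 single- and 51
  combined-adulteration recipes (339 samples) — including the Kjeldahl
  nitrogen→apparent-protein effect (× 6.38) and cryoscopic
  freezing-point shifts.
- **Consensus screening.** A sample is *suspect* when ≥ 3 of 4 criteria
  fire (two boundary sets × two KNN models); prevalence is aggregated by
  production area.
- **Vulnerability regression.** Principal component regression (LOO
  cross-validated) of per-area suspect prevalence on 13 fraud-vulnerability
  factor ranks (opportunities, motivations, controls).

The package bundles, as plain CSV, the published control-pool statistics,
boundary sets, the 43 flagged market-survey records with their detection
annotations, per-area survey totals, fraud-factor ranks, and the
adulterant registry.

## Worked example

```python
import pandas as pd
import milkscreen as ms
from milkscreen.boundaries import PercentileBoundaryDetector

records, annotations = ms.load_market_survey(with_annotations=True)
measured, adjusted = ms.load_control_boundaries()
det_m = PercentileBoundaryDetector.from_boundary_set(measured)
det_v = PercentileBoundaryDetector.from_boundary_set(adjusted)

print(det_m.count_flagged(records)["n_flagged"],
      det_v.count_flagged(records)["n_flagged"])
# 37 12    <- samples outside the measured / variance-adjusted boundaries

criteria = ms.build_criteria(records, detector_measured=det_m,
                             detector_varadj=det_v, annotations=annotations)
suspects = ms.consensus(criteria, min_votes=3)
print(len(suspects), suspects)
# 12 ['1', '2', '4', '5', '6', '12', '13', '14', '18', '19', '21', '26']

areas = pd.Series(records["area"].values, index=records["sample_id"].astype(str))
prev = ms.prevalence_by_area(suspects, areas, ms.load_survey_area_totals())
print(prev["display_pct"].to_dict())
# {'E': 38, 'N': 31, 'NW': 13, 'NE': 0, 'S': 21}
```

Of the 52 surveyed samples, 12 (23%) are flagged by the 3-of-4 consensus
rule; prevalence is highest in the Eastern (38%) and Central-Northern
(31%) production areas and lowest in the North-West (13%) and North-East
(0%). Sample 1 — low in every feature and with a freezing point shifted
toward zero past even the variance-adjusted limit — is the strongest
water-dilution candidate.

Regressing prevalence on the fraud-factor ranks:

```python
model = ms.fit_vulnerability_model(ms.load_fraud_factors(), prev["percentage"])
print(model.n_components_, round(model.coefficients_[4], 3))
# 2 0.16    <- supply-chain-relationship factor: positive coefficient
```

A positive coefficient for factor 4 means poorer supply-chain
relationships go with higher suspect prevalence; negative coefficients on
the managerial-control factors (9, 10, 13) point the same way — weaker
controls, more suspects.

The same estimators run on your own data: fit
`PercentileBoundaryDetector` or `KNNOneClass` on a control table (
`milkscreen.generate_controls` produces a seeded synthetic one) and
`predict` on survey records. A `milkscreen` CLI wraps the library
(`simulate`, `boundaries`, `occ-fit`, `screen`, `regress`); try
`milkscreen screen --out-dir out/`.

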