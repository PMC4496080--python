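# otosr

Reconstructing the movement histories of migratory Amazonian catfish
(*Brachyplatystoma* spp. — dourada, piramutaba, piraíba) from the strontium
isotope ratios archived in their otoliths.

Otoliths accrete material continuously from a fish's birth (core) to its
death (edge), and ⁸⁷Sr/⁸⁶Sr is not biologically fractionated, so a
laser-ablation transect across an otolith is a lifetime record of the water
the fish lived in. Because river ⁸⁷Sr/⁸⁶Sr reflects the age and composition
of the upstream geology — young Andean sediment gives low ratios, old
shield terrain gives high ones — those records can be mapped back to
regions of the Amazon basin.

`otosr` implements the full inference chain as a tested, reusable library:

1. **Geology covariates** (`otosr.geology`) — per-watershed age-class and
   rock-class area fractions and area-weighted mean age (Ma) from a tabular
   geology description.
2. **Isoscape regression** (`otosr.regression`) — OLS of baseline river
   ⁸⁷Sr/⁸⁶Sr on those covariates with pairwise interactions, model selection
   by AICc (small-sample Akaike criterion) over all term subsets of size ≤ 4
   — exhaustively when the model space is small, by a seeded genetic
   algorithm otherwise — an optional held-out validation split, and
   prediction intervals for unsampled watersheds:
   `hw = t₀.₉₇₅,ₙ₋ₚ · √(s²(1 + x′(X′X)⁻¹x))`.
3. **River groups** (`otosr.groups`) — a one-dimensional quadratic
   discriminant over three geochemically coherent river groups (mainstem &
   western tributaries; Beni-Madeira & lower Negro; lower Amazon
   tributaries) with equal priors:
   `score_k(x) = −½·log σₖ² − (x−μₖ)²/(2σₖ²) + log πₖ`.
4. **Movement** (`otosr.movement`) — exact penalized changepoint
   segmentation of each otolith transect into stable-mean segments by a
   from-scratch PELT (Pruned Exact Linear Time) dynamic program
   (within-segment SSE cost, penalty 10⁻⁴ per changepoint), a reproducible
   fragment-merging rule (< 10 integration points → merge into the
   neighbour with the closer mean), discriminant classification of each
   stable segment, and per-fish / per-species movement summaries.
5. **Synthetic data** (`otosr.simulate`) — watershed geology, water
   baselines generated from a known isoscape model, and piecewise-constant
   otolith transects with known changepoints at the laser cadence
   (30 μm/s × 0.262 s ≈ 7.86 μm per point), so every stage is testable
   against known truth.

The package bundles two plain-text reference tables: the literature water
baseline for the basin (29 sites: 24 sampled, one flagged as a regression
outlier, plus 5 regression-predicted) and the 24-fish specimen table.

## Worked example

```python
import otosr
from otosr.regression import predict_interval, select_on_sites

sites = otosr.load_water_baseline()

# isoscape model: AICc-best <=4-term model on the 23 usable sampled sites
sel = select_on_sites(sites, validation_fraction=0.0, method="exhaustive")
print(sel.model.terms, round(sel.model.adjusted_r2, 3))

jari = next(s for s in sites if s.site_name == "Jari (Predicted)")
pred = predict_interval(sel.model, jari.covariates.as_dict(), watershed_id="Jari")
print(round(pred.predicted_ratio, 5), "+-", round(pred.interval_halfwidth, 5))

# river-group discriminant and its error rates on the 28-site training set
print(round(100 * otosr.apparent_error(sites).error_rate, 1), "%")
print(round(100 * otosr.loocv_error(sites).error_rate, 1), "%")
```

prints

```
('carboniferous:mean_age', 'mean_age:precambrian', 'precambrian', 'precambrian:tertiary') 0.938
0.73644 +- 0.00611
3.6 %
10.7 %
```

The selected model keeps a Precambrian-fraction main effect plus three
interactions and explains 93.8% of baseline variation (adjusted R²). The
unsampled lower Jari watershed is predicted at 0.73644 with a 95%
prediction-interval halfwidth of 0.00611. The discriminant misassigns
exactly one of the 28 training sites (3.6%, the predicted Amazon-mouth
point, whose ratio falls in the Beni-Madeira score region); honest
leave-one-out cross-validation, which refits without each site before
classifying it, flips two further boundary sites (10.7%).

Segmenting and classifying a simulated cohort:

```python
from otosr.movement import segment_and_classify, summarize_movement

model = otosr.qda_fit(sites)
cohort = otosr.simulate_cohort(seed=0)
classified = [(t, segment_and_classify(t, model)) for t, _ in cohort]
rows, by_species = summarize_movement(classified)
print(by_species[["n_fish", "pct_signature_movers", "pct_group_movers"]])
```

```
            n_fish  pct_signature_movers  pct_group_movers
species
dourada         14             71.428571         14.285714
piraiba          3             66.666667         66.666667
piramutaba       5             40.000000          0.000000
```

A command-line surface mirrors the library (`otosr isoscape fit`,
`otosr groups loocv`, `otosr movement segment`, `otosr simulate cohort`,
`otosr convert-xlsx`); see `otosr --help`.

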