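# canopycc

Chromatic-coordinate analysis of canopy RGB imagery for drought-stress
monitoring in ornamental shrubs.

Urban greening shrubs lose ornamental value under water stress well before
they die, and the loss shows up first as a change in canopy color.  This
package implements, end to end, the image-based workflow used to quantify
that change in factorial irrigation experiments: repeated RGB photographs of
each plot are segmented into vegetation and background by HSV thresholding,
the vegetation pixels are summarized as chromatic coordinates, treatments
are compared through log response ratios and ANOVA, and the soil-water
content (SWC) needed to keep a color criterion is estimated by inverting a
fitted dose-response curve.  It is written for plant-phenotyping and urban
forestry researchers who want the full pipeline — including a synthetic
experiment generator, so everything is testable without field data.

## The quantities

For an image with mean digital numbers (DN) `R`, `G`, `B` over the
vegetation mask:

```
G_CC = G / (R + G + B)      R_CC = R / (R + G + B)      B_CC = B / (R + G + B)
Y_CC = (G_CC + R_CC) / 2
```

A pixel belongs to the vegetation mask when its hue lies in an inclusive
window (default 50–180°, wrapping through 0° for red foliage windows such
as 300–40°), saturation `S > 0.1` and value `V < 0.95`.

Treatment responses are compared by the log response ratio

```
RR = ln(B_s / B_ns)
```

where `B_s` is the index under a reduced-irrigation condition and `B_ns`
under full irrigation; `RR > 0` means an increase under the comparison
condition.  Stage statistics use the early (Apr 1 – May 31), middle
(Jun 1 – Jul 31) and late (Aug 1 – Sep 30) growing-season phases.  The SWC
threshold for a criterion `c` is the smallest SWC at which a monotone fit
`f(SWC)` (four-parameter logistic, isotonic fallback) reaches `c`, with a
plot-level percentile bootstrap CI.

## Worked example

```python
from canopycc import PipelineConfig, run_pipeline

manifest = run_pipeline(
    PipelineConfig(out_dir="run2022", simulate={"year_label": "2022"}, seed=1,
                   write_images=False)
)
print(manifest.row_counts)
```

prints `{'indices': 1539, 'rr': 342, 'cv': 9, 'plot_stage_means': 81,
'thresholds': 3}`: the simulated 2022 design (81 plots × 19 photo dates)
produced 1539 index records, 342 response-ratio points, one CV per
species × treatment, and one SWC threshold per species.  `run2022/
thresholds.json` then contains (abridged):

```json
{
  "berberis":  {"index_name": "r_cc", "criterion": 0.398, "swc_star": 42.8,
                "ci_low": 36.6, "ci_high": 62.1, "achievable": true},
  "euonymus":  {"index_name": "g_cc", "criterion": 0.375, "swc_star": 58.2,
                "ci_low": 53.5, "ci_high": 62.6, "achievable": true},
  "ligustrum": {"index_name": "y_cc", "criterion": 0.385, "swc_star": 38.2,
                "ci_low": 35.7, "ci_high": 40.3, "achievable": true}
}
```

Read: to keep 95 % of its fully irrigated greenness the green-leaved
archetype needs SWC near 60 %, while the red- and yellow-leaved archetypes
hold their color criteria down to SWC around 40 % — the red archetype is the
water-saving choice.  The same stages are available from the shell:

```
canopycc simulate --year 2022 --seed 1 --out data/
canopycc index --images data/ --metadata data/metadata.csv --swc data/swc.csv --out indices.csv
canopycc rr --indices indices.csv --control full --out rr.csv
canopycc stats anova --indices indices.csv
canopycc threshold --indices indices.csv --index g_cc --criterion 0.4 --out thresh.json
canopycc all --config config.yaml
```

## Layout

| module | contents |
| --- | --- |
| `canopycc.design` | factorial experiment designs (plots, treatments, periods) |
| `canopycc.synthetic` | seasonal color model, SWC regimes, canopy renderer, dataset bundles |
| `canopycc.segmentation` | HSV thresholds and vegetation masks |
| `canopycc.indices` | chromatic coordinates, observation records, time series |
| `canopycc.response` | response ratios, CV, growth stages |
| `canopycc.inference` | OLS correlation, balanced ANOVA with partial η², Tukey HSD |
| `canopycc.thresholds` | `SWCResponseModel` / results, criterion inversion, bootstrap |
| `canopycc.experiments` | calibration simulation studies |
| `canopycc.io`, `canopycc.cli` | formats, pipeline config, `canopycc` command |

See `docs/methods.md` for the model, its assumptions, and known limitations.
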