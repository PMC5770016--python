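# dentinchron

Dentin sclerochronology from daily incremental growth lines.

Counts of Growth Layer Groups (GLGs) — the coarse repeating layer pairs in
the dentin of marine-mammal teeth — are the standard age indicator for
toothed whales, but in beluga (*Delphinapterus leucas*) it has long been
disputed whether one or two GLGs form per year. The two readings halve or
double every age-based life-history parameter, so the deposition rate
matters for population assessment. `dentinchron` implements the
fine-scale test: dentin mineralization pulses daily, leaving short-period
incremental lines ~1.3–2.3 μm apart, so counting (or equivalently,
measuring the mean spacing of) daily lines inside one GLG yields the
number of days that GLG represents.

## The statistic

For one GLG of thickness *T* (μm, measured along the dentin tubules) with
*n* measured daily-line spacings of mean *m* and standard error SE:

* predicted mean spacing under annual deposition: *T*/365; under
  semi-annual deposition: *T*/182.5;
* estimated days in the GLG: *D* = *T*/*m*, i.e. unreadable stretches are
  imputed at the readable deposition rate;
* conservative bounds from the 3·SE band of the mean, pushed through the
  ratio: *D*⁻ = *T*/(*m* + 3·SE), *D*⁺ = *T*/(*m* − 3·SE). The bounds are
  asymmetric because *D* varies as 1/*m*.

A GLG supports the deposition hypothesis whose predicted spacing lies
nearer its observed mean (distance reported in units of 3·SE), and the
day interval's coverage of 365 and 182.5 days is reported alongside.

The package also ships:

* a line-detection pipeline for grayscale micrographs (focus projection
  of z-stacks, profile extraction along a tubule-direction polyline,
  detrending, prominence-based dark-line centre picking with sub-pixel
  refinement, and a periodogram period estimate as an independent
  cross-check);
* a synthetic-dentin generator producing spacing tables and
  micrograph-like images (calcosphere-warped arcuate lines, GLG-scale
  modulation, tubule streaks, patchy readability, noise) with exact
  ground truth, so the entire pipeline is testable from scratch;
* a packaged reference dataset: per-GLG summaries for seven beluga GLGs
  from three Chukchi Sea whales, with the matching published day
  estimates.

## Worked example

```python
from dentinchron import fixtures
from dentinchron.pipeline import run_summarize

records = fixtures.beluga_records()
res = run_summarize(records, summaries=fixtures.beluga_summaries())
print(res.day_table.round(2).to_string(index=False))
```

```
        glg  mean_um  pred_1glg_um  pred_2glg_um   days  err_minus  err_plus
 2012LDL3-a     1.47          1.32          2.64 327.89      16.92     18.87
 2012LDL3-b     1.41          1.12          2.24 289.94      17.40     19.77
 2012LDL8-a     1.79          1.92          3.84 391.23      30.25     35.78
 2012LDL8-b     2.05          1.95          3.90 347.13      22.19     25.44
 2012LDL8-c     1.87          1.94          3.88 378.41      22.82     25.95
2009LDL10-a     1.46          1.45          2.91 363.70      18.89     21.08
2009LDL10-b     1.50          1.57          3.14 382.42      23.90     27.32
    Average     1.65          1.61          3.22 354.39      21.77     24.89
```

Every GLG's observed mean spacing sits near the annual prediction and far
from the semi-annual one (all seven classify as annual), and the average
estimated days — 354.39 recomputed here from the rounded per-GLG means,
354.22 when the published full-precision estimates are aggregated — is
consistent with a 365-day year within its 3·SE bounds.

The numbered scripts under `analysis/` run the full study: `01` the
reference-dataset chronology above, `02` parameter recovery on simulated
spacing tables (annual and semi-annual), `03` the end-to-end image
pipeline on a simulated micrograph (mean estimated days within ~0.1% of
truth at default conditions). Each writes its tables under `results/`.

A command-line interface mirrors the library:

```sh
dentinchron simulate --seed 1 --out sim/
dentinchron summarize --measurements sim/measurements.csv --metadata sim/metadata.csv --out out/
dentinchron validate --dir sim/ --out out/
dentinchron measure --image stack.tif --scale 0.103 --path path.yaml --out spacings.csv
```

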