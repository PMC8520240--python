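# dendratrack

Simulation and quantification of photoconvertible **Dendra2** imaging
experiments in the retina.

Dendra2 (D2) is a monomeric fluorescent protein that irreversibly
photoconverts from a green-emitting state (gD2, ex 490 / em 507 nm) to a
red-emitting state (rD2, ex 553 / em 573 nm) under 405-nm light. Driven
by the *Cx3cr1* promoter it labels retinal microglia and monocytes, and
converting the cells in a chosen region tags a spatial subpopulation
that can be followed for days — by scanning-laser ophthalmoscopy, by
hyperspectral imaging, and by flow cytometry — as it responds to focal
injury or widespread photoreceptor degeneration.

`dendratrack` implements the complete quantitative chain for such
experiments, together with a synthetic-data generator that provides
ground-truth inputs for every stage, so the whole pipeline is testable
without a microscope or a mouse:

* **photophysics** — pool kinetics `dg/dt = −(k_conv + k_bg)·I·g`,
  `dr/dt = k_conv·I·g − k_br·I·r` with strict conservation and one-way
  conversion; day-scale turnover `r(t) = r₀·e^(−k_t·t)`; split-Gaussian
  reference spectra pinned to the published peaks; long-pass detection
  filters; radiant-exposure dosimetry (J/cm²) with ocular transmittance.
* **synthetic_data** — retina-like cell mosaics, hyperspectral
  conversion series, healthy / injury / degeneration time-lapse frames,
  and 200,000-event flow-cytometry tables with ground-truth labels.
* **unmixing** — non-negative least-squares decomposition of observed
  spectra into rD2 + autofluorescence; the gain-invariant statistic
  `normalized_rd2 = c_rD2 / c_AF`.
* **timecourse** — 10-nm spectral binning, green/red peak-bin
  conversion traces, baseline photobleaching slopes, mono-exponential
  turnover fits.
* **imaging_analysis** — rolling-ball background normalization, the
  `signal strength = ROI mean ÷ background` statistic, injury-response
  time courses, labeled-cell counting.
* **cytometry** — the sequential gate chain singlets → live →
  CD45⁺CD11b⁺ → high-green, classification into gD2-only vs. green/red
  double-positive rD2 microglia, spillover compensation, and per-group
  mean ± SE comparison.

## Worked example

Convert a cell's Dendra2 pool at the standard in-vivo dose, then watch
the red protein turn over for a week:

```python
import numpy as np
from dendratrack import photophysics as pp

rates = pp.KineticRates()
print(pp.radiant_exposure(pp.IN_VIVO_LOCAL))                  # 22.518 (cornea, J/cm²)
print(pp.radiant_exposure(pp.IN_VIVO_LOCAL, at_retina=True))  # 9.007 (retina, J/cm²)

pool = pp.photoconvert(pp.DendraPool(g=1.0), rates, pp.IN_VIVO_LOCAL).final
print(round(pool.r, 3), round(pool.g, 3))   # 0.84 0.007

week = pp.turnover(pool, 7.0, rates)
print(round(week.final.r / pool.r, 3))      # 0.043
```

A 22.5 J/cm² corneal exposure delivers 9 J/cm² to the retina and
converts 84 % of the protein to the red form (0.7 % stays green —
conversion is never complete once bleaching competes); by day 7 only
4.3 % of the converted protein remains, which is why photoconverted
cells fade to baseline within a week.

Gate a simulated flow sample from a converted retina:

```python
from dendratrack import synthetic_data as sd, cytometry as cy

table = sd.generate_flow_sample(sd.CONVERTED_SPEC, seed=11)
result = cy.apply_gates(table)
print(result.n_total, result.n_gd2 + result.n_rd2)  # 200000 60083
print(round(result.frac_rd2, 3))                    # 0.176
```

Of 200,000 events, 60,083 survive the gate chain; 17.6 % of the gated
microglia are green/red double positive, recovering the configured 16 %
red fraction within binomial and misclassification error.

The same pipeline is scriptable from the shell:

```sh
dendratrack simulate-flow --preset converted --out events.csv
dendratrack flow --events events.csv --out gates.json
dendratrack demo --out demo_out/        # all scenarios + summary report
```

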