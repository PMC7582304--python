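# cryoleaf

Freezing-stress analysis for leaves of high-elevation plants.

Small alpine herbs live in a thermal world the weather station cannot
see: under a clear night sky their leaves radiate heat away and can
drop many degrees below the 2 m air temperature, supercool, and then
freeze one by one as ice nucleates in each leaf independently.
`cryoleaf` implements the measurement chain used to quantify that
process, from raw thermocouple logs to cellular morphometry:

* **Exotherm detection (DTA).** When supercooled leaf water
  crystallizes, latent heat produces a sudden transient warming.  The
  detector scans each leaf channel for ΔT = T(t) − T(t − 10 s) ≥
  threshold with a subzero pre-rise temperature and no coincident rise
  in the air channel, merges nearby flags into single events, and
  reports the ice nucleation temperature (the leaf temperature just
  before the rise) plus supercooled and frozen durations.
* **Frost microclimate.** Daily extrema, frost-night rates per leaf
  sensor (mean ± SD across sensors), nocturnal leaf−air temperature
  depressions, and snow-cover classification from damped daily
  amplitudes near 0 °C.
* **Freezing resistance (LT50).** Viability (chlorophyll-fluorescence
  Fv/Fm) versus treatment temperature is fitted with the Boltzmann
  sigmoid
  `Fv/Fm(T) = (vmin − vmax) / (1 + exp((T − LT50)/dx)) + vmax`;
  LT50 — the median lethal temperature — is estimated by repeatedly
  drawing 4 yields per treatment temperature, refitting, and reporting
  the mean ± SD over 250 replicates.  Gas-exchange normalization
  (A/GH2O and Rd/GH2O relative to the pre-treatment baseline) is
  included.
* **Infrared differential thermal analysis (IDTA).** Frame-by-frame
  subtraction of IR video turns advancing ice fronts into bright
  transients; per leaf region the first frame on which enough pixels
  brighten marks nucleation, and a cumulative coverage curve tracks the
  front's spread.
* **Freezing-cytorrhysis morphometry.** Cell areas from traced
  outlines, frozen-to-baseline area shares, tissue comparison by
  Wilcoxon rank-sum (exact for small samples), diameter/length shares
  of cylindrical palisade cells, and the cylinder-model volume
  reduction `100·(1 − d_share²·l_share)`.
* **Synthetic campaigns.** A generator that emulates the field
  structure — diel air cycles, radiative leaf depressions, stochastic
  nucleation around −2.6 ± 0.9 °C, exotherm signatures, snow clamping,
  Boltzmann assays, shrinking cell outlines, freezing IR stacks — with
  ground truth, so every estimator is validated by parameter recovery.

## Worked example

`examples/` contains one narrative script per capability.  Detecting
exotherms in a 5-night synthetic campaign
(`python examples/01_detect_exotherms.py`):

```
true freezing events injected : 32
events detected               : 32
mean nucleation temperature   : -2.71 degC (generator: -2.6)
mean frozen duration          : 377 min
```

Every injected event is found, and the mean recovered nucleation
temperature agrees with the generating distribution.  Estimating LT50
from a synthetic assay (`python examples/03_lt50_resampling.py`):

```
true LT50      : -11.00 degC
estimated LT50 : -10.72 +- 0.13 degC (250/250 fits converged)
```

The same pipelines run from the shell:

```sh
cryoleaf simulate --seed 7 --out-dir run/
cryoleaf detect --input run/log.csv --meta run/meta.csv --out run/events.csv
cryoleaf summarize --input run/log.csv --meta run/meta.csv --out run/summary.csv
```

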