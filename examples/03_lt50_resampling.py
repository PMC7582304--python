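"""LT50 estimation from a chlorophyll-fluorescence frost-damage assay.

Generates a 6-temperature x 10-leaf Fv/Fm assay on a known Boltzmann
viability curve (LT50 = -11 degC), then estimates LT50 by the
subsample-and-refit scheme: 4 random yields per temperature, Boltzmann
fit, 250 repetitions, mean +- SD over converged fits.
"""

from cryoleaf import BoltzmannParams, resampled_lt50
from cryoleaf.synthetic import simulate_lt50_assay

truth = BoltzmannParams(vmin=0.03, vmax=0.80, lt50=-11.0, dx=1.2)
assay = simulate_lt50_assay(truth, [-20, -16, -13, -11, -9, -6], leaves_per_temp=10, noise_sd=0.05, seed=5)
est = resampled_lt50(assay, k_per_temp=4, n_reps=250, seed=5)

print(f"true LT50      : {truth.lt50:.2f} degC")
print(f"estimated LT50 : {est.mean:.2f} +- {est.sd:.2f} degC "
      f"({est.n_converged}/{est.n_reps} fits converged)")
print()
print("LT50 is the inflection point of the Fv/Fm-vs-temperature sigmoid -")
print("the temperature at which half of the photosystem II capacity is lost.")
print("The resampling SD propagates leaf-to-leaf spread into the estimate.")
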