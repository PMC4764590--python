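"""Build a composite "average embryo" from five simulated embryos.

Simulates seam-cell trajectories for five embryos whose developmental
clocks are offset by known integer timepoint shifts, registers them by the
inflection points of three-parameter logistic fits to the axial (Z)
coordinate, averages the shifted trajectories, re-fits the averages with
the per-cell-type function families, and prints the recovered shifts and
axial growth parameters.
"""

import numpy as np

import untwist as ut
from untwist.trajectories import (align_and_average, fit_composite,
                                  neighbor_differences)

true_shifts = [0, 2, 4, -1, 5]
tset, truth = ut.make_trajectory_set(n_embryos=5, true_shifts=true_shifts,
                                     dt=2.5, noise_sd=2.0, seed=7)

res = align_and_average(tset, reference_embryo=0)
by_embryo = {}
for (e, cell), s in res.shifts.items():
    by_embryo.setdefault(e, []).append(s)
recovered = [int(np.median(v)) for _, v in sorted(by_embryo.items())]
print(f"true shifts      : {true_shifts}")
print(f"recovered shifts : {recovered}  (integer timepoints of 2.5 min)")

comp = fit_composite(res.averaged, res.shifts)
print("\naxial (Z) logistic fits of the averaged trajectories:")
for cell in ("H0", "V3", "T"):
    fr = comp.fits[cell]["Z"]
    A_true = truth.cells[cell]["Z"][1]["A"]
    print(f"  {cell}: A = {fr.params['A']:6.1f} µm (true {A_true:5.1f}), "
          f"B = {fr.params['B']:.3f}/min, C = {fr.params['C']:5.1f} min")

nd = neighbor_differences(comp)
changes = nd.groupby("pair")["start_to_end_change"].first()
print("\naxial separation changes over the recording (adjacent pairs):")
for pair in ("origin-H0", "V3-V4", "V6-T"):
    print(f"  {pair}: {changes[pair]:+.1f} µm")
print("(averaging five embryos shrinks per-timepoint noise by ~sqrt(5); "
      "the fitted curves are the noise-free composite model)")
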