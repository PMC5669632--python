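"""pH-gating analysis: concerted-model curves, Hill summaries, mutant fits.

Reproduces the gating-model bookkeeping of a KcsA proton-gating study: for
each construct the two-sensor concerted (MWC) parameters are turned into a
Po(pH) curve, summarized by a Hill fit (pH_1/2 and nH), and compared with
the Hill fits reported for the recordings themselves.  A synthetic noisy
dataset then exercises the constrained two-stage workflow used for mutants
whose H25 sensor loses its state-dependence.
"""
import numpy as np

from permeon import (
    KCSA_GATING,
    PoSyntheticConfig,
    generate_po_dataset,
    hill_summary_of_mwc,
    mwc_po,
    two_stage_mwc_fit,
)

print(f"{'construct':10s} {'pH_1/2':>7s} {'nH':>6s}   published Hill fit")
for name, row in KCSA_GATING.items():
    hill = hill_summary_of_mwc(row["mwc"])
    pub = row["hill"]
    print(f"{name:10s} {hill.ph_half:7.2f} {hill.nh:6.2f}   "
          f"pH_1/2 = {pub['ph_half']}, nH = {pub['nh']}")
print("The half-activation points match the recordings; the ideal concerted")
print("curves are somewhat steeper than the Hill fits of the noisy data,")
print("most visibly for the two-sensor constructs (see docs/methods.md).\n")

# constrained workflow: noisy data from a channel whose H25 sensor has lost
# its state-dependence (as in the outer-helix mutant)
truth = KCSA_GATING["L40A"]["mwc"]
data = generate_po_dataset(PoSyntheticConfig(params=truth, seed=22))
init = KCSA_GATING["control"]["mwc"].replace(lo=1e-6)
stage1, stage2 = two_stage_mwc_fit(data, init)
print("two-stage fit of synthetic mutant data (5 bilayers, sd 0.05):")
print(f"  stage 1 active constraints: {stage1.active_bounds}")
if stage2 is None:
    # with bilayer-level noise the bound occasionally stays (barely)
    # inactive; the workflow then reports the unconstrained stage-1 fit
    raise SystemExit("stage-1 bound inactive for this draw")
lo, se = stage2.params["lo"], stage2.stderr["lo"]
print(f"  stage 2 (pKa1_closed pinned to pKa1_open): "
      f"Lo = {lo:.2e} ({se:.0e}); truth 6.2e-04")
print(f"  Po(pH 5.3) of the fitted model: "
      f"{mwc_po(truth.replace(lo=lo), 5.3):.3f}")
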