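"""Generate a synthetic per-fish dose-response dataset.

Reproduces the study design: 10 fish at each of 3 nutmeg-oil
concentrations, with induction time falling, recovery time rising, and
stress-elevated hematology, plus 3% multiplicative lognormal noise.
"""

import numpy as np

import fishann as fa

profile = fa.make_profile(fa.Species.COMMON_CARP, seed=1)
records = fa.generate_dataset(profile)
print(f"{len(records)} fish ({profile.n_per_dose} per dose)\n")

print("dose uL/L   mean IT s   mean RT s   mean WBC   mean HCT %")
for c in profile.concentrations:
    sub = [r for r in records if r.concentration == c]
    it = np.mean([r.IT for r in sub])
    rt = np.mean([r.RT for r in sub])
    wbc = np.mean([r.WBC for r in sub])
    hct = np.mean([r.HCT for r in sub])
    print(f"{c:9.0f}   {it:9.1f}   {rt:9.1f}   {wbc:8.1f}   {hct:8.1f}")

print(
    "\nHigher doses anesthetize faster (IT falls) but prolong recovery "
    "(RT rises);\nWBC and HCT rise with dose as an acute stress response."
)
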