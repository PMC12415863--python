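"""Evaluate the packaged published networks at their tested doses.

Loads the zoo of 18 transcribed 1-H-1 networks (3 species x 6 endpoints)
and runs each species' WBC model across its tested concentration range.
The printed numbers are raw forward-pass outputs of the published weights;
because the input scale of those weights could not be verified from the
source tables, every prediction carries an ``input_scale`` tag and any
transcription caveats.
"""

import fishann as fa

for entry in fa.load_zoo():
    if entry.endpoint is not fa.Endpoint.WBC:
        continue
    lo, hi = fa.zoo.dose_range(entry.species)
    mid = (lo + hi) / 2
    print(f"\n{entry.species.value}: WBC model {entry.architecture} "
          f"({entry.hidden_activation_tag}-purelin, {entry.trainer_name})")
    for c in (lo, mid, hi):
        pred = fa.zoo_predict(entry.species, entry.endpoint, c)
        print(f"  {c:7.1f} uL/L -> {pred.value:10.4f}   "
              f"[input scale: {pred.input_scale}]")

print(
    "\nValues are the transcribed networks' raw outputs; they are faithful "
    "to the published weights,\nnot validated predictions (the original "
    "per-fish data and the weights' input scale were never released)."
)
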