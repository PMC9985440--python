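"""Generate synthetic Cα structures and inspect their geometry.

Builds one mixed-topology structure and a noisy structural family,
then prints chain geometry and within-family similarity.  Consecutive
Cα distances near 3.8 Å and within-family TM-scores near 1 show the
generator produces physically plausible, tightly related folds.
"""

import numpy as np

from threadfold import SynthSpec, make_family, make_structure, structural_align

spec = SynthSpec(
    seed=7,
    topology=(("H", 16), ("C", 4), ("E", 9), ("C", 4), ("E", 9), ("C", 5), ("H", 14)),
    coordinate_noise=0.4,
    n_members=4,
)

trace = make_structure(spec)
steps = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
print(f"structure {trace.id}: L={trace.L}")
print(f"designed secondary structure: {trace.ss}")
print(f"consecutive Ca-Ca distances: {steps.min():.2f} - {steps.max():.2f} A")

members, core_mask = make_family(spec)
print(f"\nfamily of {len(members)} members, coordinate noise {spec.coordinate_noise} A")
for member in members[1:]:
    sup = structural_align(members[0], member)
    print(f"  {members[0].id} vs {member.id}: TM-score {sup.tm_score_by_a:.3f}, "
          f"RMSD {sup.rmsd:.2f} A over {len(sup.correspondence)} residues")
print("TM-scores near 1 confirm the members share one fold.")
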