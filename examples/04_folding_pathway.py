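"""Infer a folding pathway from a remote-homolog ensemble.

Builds a 12-member family that shares an exact three-helix core with a
divergent, per-member re-sampled periphery, computes the per-residue
frequency track (ResFscore), segments the target by secondary
structure, and selects the folding intermediate adaptively.  The
conserved core should emerge as the intermediate and lead the
predicted folding order.
"""

import numpy as np

from threadfold import SynthSpec, infer_pathway, make_family, make_structure

spec = SynthSpec(
    seed=23,
    topology=(("H", 14), ("C", 3), ("H", 14), ("C", 3), ("H", 14),   # conserved core
              ("C", 6), ("E", 9), ("C", 6), ("E", 9)),               # divergent periphery
    coordinate_noise=0.5,
    n_members=12,
    peripheral_divergence=30 / 78,
)
members, core_mask = make_family(spec)
target = make_structure(spec, trace_id="target")

pathway, segments = infer_pathway(target, members)
track = pathway.track

print(f"target L={target.L}, {track.N_t} homolog templates")
print(f"mean ResFscore: core {track.resfscore[core_mask].mean():.3f}, "
      f"periphery {track.resfscore[~core_mask].mean():.3f}")
print(f"\nsegments (avg ResFscore), selected I_cut={pathway.i_cut:.2f}:")
for seg in segments:
    print(f"  {seg.ss_type}{seg.start}-{seg.end}: {seg.avg:.3f}")
print("\n" + pathway.report())
print("\nthe three core helices form the intermediate and fold first;")
print("the re-sampled periphery scores near 0 and folds last.")
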