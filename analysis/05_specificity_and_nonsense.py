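#!/usr/bin/env python
"""Off-target specificity (R-loop panel) and nonsense-mutation calling.

Two closing analyses of the screen:

1. simulate the four-site orthogonal R-loop panel at a planted
   sgRNA-independent off-target rate of 0.10, quantify each site, and form
   the on:off specificity ratio against the context-independent editor's
   mean on-target efficiency;
2. build a coding target carrying a CAA codon inside the editing window,
   plant stop-creating C-to-T edits, and measure the nonsense-mutation
   introduction efficiency (stop-gained / splice-disrupted / start-lost
   reads over accepted substitution-only reads).
"""

import json
from pathlib import Path

import numpy as np

from deamscope.editquant import (
    TargetDefinition,
    orient_and_align,
    quantify_target,
)
from deamscope.phenocall import (
    GeneModel,
    nonsense_efficiency,
    on_off_ratio,
    rloop_offtarget_summary,
)
from deamscope.synthdata import (
    EditorSimConfig,
    simulate_reads,
    simulate_rloop_reads,
)

SEED = 20240903
RESULTS = Path("results/screen")


def specificity() -> None:
    summary = json.loads((RESULTS / "uniform" / "summary.json").read_text())
    mean_on = summary["library"]["mean"]
    panel_reads = simulate_rloop_reads(off_rate=0.10, depth=2000, seed=SEED)
    profiles = {}
    for site, (target, reads) in panel_reads.items():
        q = quantify_target(reads, target, efficiency_method="mean_window")
        profiles[site] = q.edit_profile
    panel = rloop_offtarget_summary(profiles, efficiency_method="mean_window")
    spec = on_off_ratio(mean_on, panel)
    print("R-loop panel per-site efficiency: "
          + ", ".join(f"{s}={e:.3f}" for s, e in
                      panel.site_efficiencies.items()))
    print(f"on:off specificity ratio: {spec.mean_on:.3f} / "
          f"{spec.mean_off:.3f} = {spec.ratio:.2f}")


def nonsense() -> None:
    # self-targeting construct whose protospacer holds a CAA codon in frame;
    # a C1 edit converts CAA -> TAA (stop)
    spacer = "CAAGACTTCGGTACGTACGT"
    left = "ATG" + "GATACC"  # start + two codons upstream, keeps frame 0
    amplicon = left + spacer + "TGG" + "ACGTACGTAC"
    target = TargetDefinition(target_id="tyr_like", amplicon_seq=amplicon,
                              protospacer_start=len(left))
    model = GeneModel(coding_strand="+",
                      cds_segments=((0, len(amplicon) - len(amplicon) % 3, 0),),
                      start_codon=(0, 3))
    model.validate_reference(amplicon)
    cfg = EditorSimConfig(base_rate=0.5, window_shape={1: 1.0, 2: 0.4},
                          depth=2000, seed=SEED + 1)
    reads, truth = simulate_reads(target, cfg)
    alns = (orient_and_align(r, target) for r in reads)
    alleles = [a.aligned_read for a in alns if a is not None and not a.has_gaps]
    eff = nonsense_efficiency(alleles, model, amplicon)
    print(f"nonsense-mutation introduction efficiency: {eff:.3f} "
          f"(planted stop-creating C1 rate "
          f"{truth['planted_ct_rates'][1]:.2f})")


def main() -> None:
    specificity()
    nonsense()


if __name__ == "__main__":
    main()
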