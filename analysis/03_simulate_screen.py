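#!/usr/bin/env python
"""Simulate the sgRNA-target screen: library design plus edited reads.

Builds a 102-member self-targeting amplicon library (20-nt protospacer,
NGG PAM at positions 21-23, >=1 C at protospacer positions 2-8, 84% of
spacers with GC in [40%, 65%]) and, for two editor phenotypes, amplicon
reads at 2,000x with planted per-position C-to-T rates:

* "uniform" — context-independent editing across the protospacer with a
  2% indel byproduct rate (a CD0208-like phenotype);
* "tc_pref" — a strong TC-context preference (an eA3A-like phenotype).

FASTQ files go to scratch/screen/<editor>/; truth records and the target
table go to results/screen/.
"""

import json
from pathlib import Path

import numpy as np

from deamscope.pipeline import write_targets
from deamscope.seqio import write_fastq
from deamscope.synthdata import (
    EditorSimConfig,
    LibrarySimConfig,
    simulate_library,
    simulate_reads,
)

SEED = 20240902
SCRATCH = Path("scratch/screen")
RESULTS = Path("results/screen")

EDITORS = {
    "uniform": EditorSimConfig(
        base_rate=0.45, window_shape={p: 1.0 for p in range(1, 21)},
        indel_rate=0.02, seq_error_rate=0.001, depth=2000),
    "tc_pref": EditorSimConfig(
        base_rate=0.5, window_shape={p: 1.0 for p in range(1, 21)},
        context_multipliers={"AC": 0.05, "CC": 0.05, "GC": 0.05, "TC": 1.0},
        indel_rate=0.02, seq_error_rate=0.001, depth=2000),
}


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    targets, _, summary = simulate_library(
        LibrarySimConfig(n_targets=102, seed=SEED))
    write_targets(targets, RESULTS / "targets.tsv")
    print(f"library: {len(targets)} targets, "
          f"{summary['gc_in_band_fraction']:.1%} of spacers with GC in "
          f"[40%, 65%]")

    for offset, (editor, cfg) in enumerate(EDITORS.items(), start=1):
        out = SCRATCH / editor
        out.mkdir(parents=True, exist_ok=True)
        truths = {}
        root = np.random.SeedSequence(SEED + offset)
        for t, child in zip(targets, root.spawn(len(targets))):
            reads, truth = simulate_reads(t, cfg,
                                          rng=np.random.default_rng(child))
            write_fastq(reads, out / f"{t.target_id}.fastq")
            truths[t.target_id] = truth
        (RESULTS / f"truth_{editor}.json").write_text(
            json.dumps(truths, indent=2, sort_keys=True, default=float) + "\n")
        print(f"{editor}: {len(targets)} FASTQ files at depth {cfg.depth} "
              f"-> {out}")


if __name__ == "__main__":
    main()
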