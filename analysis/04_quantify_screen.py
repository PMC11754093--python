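#!/usr/bin/env python
"""Quantify the simulated screen and compare the two editor phenotypes.

For each simulated editor, aligns every read to its amplicon, computes
per-position C-to-T frequencies, calls editing windows under the
>=50%-of-maximum rule, summarizes NC-context preference and the edit-type
matrix, and writes the library-level report.  Prints the side-by-side
context means, which separate the context-independent editor from the
TC-preferring one.
"""

import json
from pathlib import Path

from deamscope.pipeline import ScreenConfig, run_screen

SCRATCH = Path("scratch/screen")
RESULTS = Path("results/screen")


def main() -> None:
    for editor in ("uniform", "tc_pref"):
        cfg = ScreenConfig(
            targets=str(RESULTS / "targets.tsv"),
            fastq_dir=str(SCRATCH / editor),
            out_dir=str(RESULTS / editor),
            position_range=(3, 7),
        )
        summary, report = run_screen(cfg)
        lib = summary["library"]
        ctx = summary["context"]
        print(f"\n=== {editor} ===")
        print(f"targets quantified: "
              f"{report.stage_counts['quantify']['n_quantified']}")
        print(f"editing efficiency: mean {lib['mean']:.3f}, "
              f"median {lib['median']:.3f} "
              f"(Q1 {lib['q1']:.3f}, Q3 {lib['q3']:.3f})")
        print(f"mean indel frequency: {lib['mean_indel_frequency']:.4f}")
        means = {c: (f"{m:.3f}" if m is not None else "NA")
                 for c, m in ctx['means'].items()}
        print(f"context means (positions 3-7): {means}")
        print(f"context-independent: {ctx.get('context_independent')}")
        print(f"C-to-T purity (share of substitution events): "
              f"{summary['edit_types']['CtoT']:.3f}")


if __name__ == "__main__":
    main()
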