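"""End-to-end orchestration of discovery and screening runs.

``run_discovery`` chains candidate filtering, TM-matrix assembly, leader
clustering and seeded representative sampling; ``run_screen`` chains
per-target read quantification, editing-window / context / edit-type
summaries and, when gene models or an R-loop panel are supplied, nonsense
calling and on:off specificity.  Every run writes plain TSV/JSON artifacts
plus a machine-readable report whose stage counts reconcile (kept +
rejected == input, assigned + discarded == reads), and is deterministic
given its seed.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import editquant, phenocall, seqio, structcluster

logger = logging.getLogger("deamscope")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(asctime)s] %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_EMPTY = 4


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run."""

    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    parameters: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, **counts: int) -> None:
        self.stage_counts[stage] = {k: int(v) for k, v in counts.items()}

    def to_json(self) -> str:
        return json.dumps(
            {"stage_counts": self.stage_counts,
             "parameters": self.parameters,
             "warnings": self.warnings},
            indent=2, sort_keys=True,
        )


@dataclass(frozen=True)
class DiscoveryConfig:
    fasta: str
    hits: str
    pair_scores: str
    out_dir: str
    tm_threshold: float = 0.7
    mode: str = "by_first"
    fraction: float = 0.10
    seed: int = 0
    evalue_cutoff: float = 0.01
    domain_mode: str = "require_any"
    write_tree: bool = False


def _stage(name: str):
    logger.info("stage %s", name)
    return time.monotonic()


def run_discovery(config: DiscoveryConfig) -> tuple[
        structcluster.ClusterSet, dict[int, list[str]], RunReport]:
    """filter -> TM matrix -> leader clustering -> representative sampling."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters={
        "tm_threshold": config.tm_threshold,
        "mode": config.mode,
        "fraction": config.fraction,
        "seed": config.seed,
        "evalue_cutoff": config.evalue_cutoff,
        "domain_mode": config.domain_mode,
    })

    t0 = _stage("filter_candidates")
    records = seqio.read_fasta(config.fasta)
    hits = seqio.parse_hmmer_tblout(config.hits)
    kept, rejected = seqio.filter_candidates(
        records, hits,
        evalue_cutoff=config.evalue_cutoff,
        domain_mode=config.domain_mode,
    )
    report.record("filter_candidates", n_input=len(records),
                  n_kept=len(kept), n_rejected=len(rejected))
    pd.DataFrame(
        sorted(rejected.items()), columns=["seq_id", "reason"]
    ).to_csv(out / "rejected.tsv", sep="\t", index=False)
    logger.info("filter: %d kept, %d rejected (%.1fs)",
                len(kept), len(rejected), time.monotonic() - t0)
    if not kept:
        raise seqio.FormatError("no candidates pass the filters")

    t0 = _stage("leader_cluster")
    sset = structcluster.StructureSet(
        ids=tuple(r.id for r in kept),
        lengths={r.id: len(r.sequence) for r in kept},
    )
    rows = seqio.read_pair_scores(config.pair_scores)
    rows = [r for r in rows if r.id_a in set(sset.ids) and r.id_b in set(sset.ids)]
    matrix = structcluster.build_tm_matrix(rows, sset, mode=config.mode)
    cluster_set = structcluster.leader_cluster(
        sset, matrix,
        structcluster.ClusteringParams(tm_threshold=config.tm_threshold),
    )
    report.record("leader_cluster", n_proteins=len(sset),
                  n_clusters=len(cluster_set))
    cluster_rows = [
        {"cluster_index": c.index, "center_id": c.center_id,
         "member_id": m, "length": sset.lengths[m]}
        for c in cluster_set.clusters for m in c.member_ids
    ]
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    logger.info("clustering: %d clusters (%.1fs)",
                len(cluster_set), time.monotonic() - t0)

    if config.write_tree:
        t0 = _stage("upgma")
        ids = list(sset.ids)
        n = len(ids)
        d = np.zeros((n, n))
        sym = structcluster.build_tm_matrix(rows, sset, mode="symmetric_min")
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = 1.0 - sym.lookup(ids[i], ids[j])
        tree = structcluster.upgma(d, ids)
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        logger.info("tree written (%.1fs)", time.monotonic() - t0)

    t0 = _stage("select_representatives")
    selection = structcluster.select_representatives(
        cluster_set,
        structcluster.SamplingParams(fraction=config.fraction, seed=config.seed),
    )
    sizes = {c.index: len(c) for c in cluster_set.clusters}
    sel_rows = [
        {"cluster_index": ci, "selected_id": sid,
         "k_c": len(sel), "n_c": sizes[ci]}
        for ci, sel in sorted(selection.items()) for sid in sel
    ]
    pd.DataFrame(sel_rows).to_csv(out / "selection.tsv", sep="\t", index=False)
    n_selected = sum(len(v) for v in selection.values())
    report.record("select_representatives", n_clusters=len(cluster_set),
                  n_selected=n_selected)
    logger.info("selection: %d representatives (%.1fs)",
                n_selected, time.monotonic() - t0)

    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(vars(config) | {}, sort_keys=True))
    return cluster_set, selection, report


@dataclass(frozen=True)
class ScreenConfig:
    targets: str            # TSV: target_id, amplicon_seq, protospacer_start, strand
    fastq_dir: str          # <target_id>.fastq[.gz] per target
    out_dir: str
    rel_threshold: float = 0.5
    min_peak: float = 0.01
    position_range: tuple[int, int] = (3, 7)
    efficiency_method: str = "max_position"
    gene_models: str | None = None  # TSV, see read_gene_models
    rloop_fastq_dir: str | None = None
    rloop_targets: str | None = None


def read_targets(path: str | Path) -> list[editquant.TargetDefinition]:
    df = pd.read_csv(path, sep="\t")
    required = {"target_id", "amplicon_seq", "protospacer_start", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise seqio.FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        editquant.TargetDefinition(
            target_id=str(r.target_id),
            amplicon_seq=str(r.amplicon_seq),
            protospacer_start=int(r.protospacer_start),
            protospacer_strand=str(r.strand),
        )
        for r in df.itertuples()
    ]


def write_targets(targets: list[editquant.TargetDefinition],
                  path: str | Path) -> None:
    pd.DataFrame([
        {"target_id": t.target_id, "amplicon_seq": t.amplicon_seq,
         "protospacer_start": t.protospacer_start,
         "strand": t.protospacer_strand}
        for t in targets
    ]).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> dict[str, phenocall.GeneModel]:
    """Gene-model TSV: target_id, coding_strand, cds_start, cds_end, frame,
    donor_pos, acceptor_pos, start_pos (comma-separated lists; '.' = none)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")

    def _ints(cell: str) -> tuple[int, ...]:
        return tuple(int(x) for x in str(cell).split(",")) if cell != "." else ()

    models: dict[str, phenocall.GeneModel] = {}
    for r in df.itertuples():
        start = None
        if r.start_pos != ".":
            s = int(r.start_pos)
            start = (s, s + 3)
        models[str(r.target_id)] = phenocall.GeneModel(
            coding_strand=str(r.coding_strand),
            cds_segments=((int(r.cds_start), int(r.cds_end), int(r.frame)),),
            splice_donor_sites=_ints(r.donor_pos),
            splice_acceptor_sites=_ints(r.acceptor_pos),
            start_codon=start,
        )
    return models


def run_screen(config: ScreenConfig) -> tuple[dict, RunReport]:
    """Quantify every target's FASTQ; write per-target and library reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters={
        "rel_threshold": config.rel_threshold,
        "min_peak": config.min_peak,
        "position_range": list(config.position_range),
        "efficiency_method": config.efficiency_method,
    })
    targets = read_targets(config.targets)
    gene_models = (read_gene_models(config.gene_models)
                   if config.gene_models else {})
    fastq_dir = Path(config.fastq_dir)

    quants: list[editquant.TargetQuantification] = []
    per_target_rows: list[dict] = []
    window_rows: list[dict] = []
    nonsense_rows: list[dict] = []
    failures: list[str] = []
    profile_pairs: list[tuple[editquant.TargetDefinition,
                              editquant.PositionProfile]] = []
    edit_pairs: list[tuple[editquant.TargetDefinition, editquant.EditProfile]] = []

    t0 = _stage("quantify")
    for target in targets:
        fq = fastq_dir / f"{target.target_id}.fastq"
        if not fq.exists():
            fq = fastq_dir / f"{target.target_id}.fastq.gz"
        if not fq.exists():
            failures.append(target.target_id)
            report.warnings.append(f"{target.target_id}: no FASTQ found")
            continue
        try:
            reads = list(seqio.read_fastq(fq))
            if not reads:
                raise seqio.FormatError("empty FASTQ")
            quant = editquant.quantify_target(
                reads, target,
                rel_threshold=config.rel_threshold,
                min_peak=config.min_peak,
                efficiency_method=config.efficiency_method,
            )
        except seqio.FormatError as exc:
            failures.append(target.target_id)
            report.warnings.append(f"{target.target_id}: no accepted reads ({exc})")
            continue
        quants.append(quant)
        profile_pairs.append((target, quant.profile))
        edit_pairs.append((target, quant.edit_profile))
        for p in quant.edit_profile.c_positions:
            per_target_rows.append({
                "target_id": target.target_id,
                "position": p,
                "ref_base": "C",
                "coverage": quant.edit_profile.n[p],
                "f_CtoT": quant.edit_profile.f_ct[p],
                "f_CtoG": quant.edit_profile.f_cg[p],
                "f_CtoA": quant.edit_profile.f_ca[p],
            })
        window_rows.append({
            "target_id": target.target_id,
            "window": quant.window.label(),
            "peak": quant.window.peak,
            "efficiency": quant.efficiency,
            "indel_frequency": quant.indel_frequency,
            "n_reads": quant.profile.n_accepted,
            "n_discarded": quant.n_discarded,
        })
        if target.target_id in gene_models:
            model = gene_models[target.target_id]
            model.validate_reference(target.amplicon_seq)
            # re-align to collect substitution-only alleles
            alns = [editquant.orient_and_align(r, target) for r in reads]
            alleles = [a.aligned_read for a in alns
                       if a is not None and not a.has_gaps]
            if alleles:
                eff = phenocall.nonsense_efficiency(
                    alleles, model, target.amplicon_seq)
                nonsense_rows.append({
                    "target_id": target.target_id,
                    "nonsense_efficiency": eff,
                    "n_alleles": len(alleles),
                })
    logger.info("quantify: %d targets ok, %d failed (%.1fs)",
                len(quants), len(failures), time.monotonic() - t0)
    report.record("quantify", n_targets=len(targets),
                  n_quantified=len(quants), n_failed=len(failures))

    pd.DataFrame(per_target_rows).to_csv(out / "per_position.tsv",
                                         sep="\t", index=False)
    pd.DataFrame(window_rows).to_csv(out / "windows.tsv", sep="\t", index=False)
    if nonsense_rows:
        pd.DataFrame(nonsense_rows).to_csv(out / "nonsense.tsv",
                                           sep="\t", index=False)

    summary: dict[str, Any] = {"failed_targets": failures}
    if quants:
        summary["library"] = editquant.aggregate_library(quants)
        ctx = editquant.context_profile(edit_pairs,
                                        position_range=config.position_range)
        summary["context"] = {
            "means": ctx.means, "n_obs": ctx.n_obs,
            "position_range": list(ctx.position_range),
            "ranking": ctx.ranking(),
        }
        defined = [m for m in ctx.means.values() if m is not None]
        if len(defined) == 4 and min(defined) > 0:
            spread = max(defined) / min(defined)
            summary["context"]["context_independent"] = bool(spread < 1.5)
        pd.DataFrame(
            [{"context": c, "mean_f": ctx.means[c], "n": ctx.n_obs[c]}
             for c in editquant.CONTEXTS]
        ).to_csv(out / "context.tsv", sep="\t", index=False)
        etm = editquant.edit_type_matrix(profile_pairs)
        etm.proportions.to_csv(out / "edit_types.tsv", sep="\t")
        summary["edit_types"] = {
            "n_events": etm.n_events,
            "CtoT": float(etm.proportions.loc["C", "T"]) if etm.n_events else None,
        }

    if config.rloop_fastq_dir and config.rloop_targets:
        t0 = _stage("rloop")
        rl_targets = read_targets(config.rloop_targets)
        profiles: dict[str, editquant.EditProfile] = {}
        for rt in rl_targets:
            fq = Path(config.rloop_fastq_dir) / f"{rt.target_id}.fastq"
            if not fq.exists():
                report.warnings.append(f"R-loop site {rt.target_id}: no FASTQ")
                continue
            reads = list(seqio.read_fastq(fq))
            q = editquant.quantify_target(reads, rt,
                                          rel_threshold=config.rel_threshold)
            profiles[rt.target_id] = q.edit_profile
        if profiles:
            panel = phenocall.rloop_offtarget_summary(
                profiles, efficiency_method=config.efficiency_method)
            mean_on = summary.get("library", {}).get("mean")
            if mean_on is not None:
                spec = phenocall.on_off_ratio(mean_on, panel)
                summary["specificity"] = {
                    "mean_on": spec.mean_on,
                    "mean_off": spec.mean_off,
                    "ratio": spec.ratio,
                    "ratio_defined": spec.ratio_defined,
                    "site_efficiencies": panel.site_efficiencies,
                }
        logger.info("rloop done (%.1fs)", time.monotonic() - t0)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    (out / "report.json").write_text(report.to_json() + "\n")
    return summary, report
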