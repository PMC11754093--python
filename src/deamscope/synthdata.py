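"""Synthetic-data generators with the statistical structure the screen assumes.

Three generators stand in for the raw inputs of a real screen:

* a structure set with planted clusters whose pairwise TM-scores are drawn
  from separated within / between distributions (defaults: uniform on
  [0.72, 0.95] within, [0.10, 0.60] between, straddling the 0.7 threshold),
  so leader clustering can be checked against the planted partition;
* an sgRNA-target amplicon library of self-targeting constructs — each
  amplicon embeds its own 20-nt protospacer with an NGG PAM at positions
  21-23 and at least one C within protospacer positions 2-8, with a
  configurable fraction of spacers holding GC content inside a band
  (defaults: 84% inside [0.40, 0.65]);
* amplicon-length single-end reads carrying planted per-position C-to-T
  rates shaped by a window profile and 5'-context multipliers, minor C-to-G
  / C-to-A channels, indels and uniform sequencing error, alongside a truth
  record of the planted expectations.

Every generator takes an explicit seed and is deterministic under it.
Reads are full-amplicon with a constant Q40 quality string: the target of
the tests is the quantification logic, not sequencing physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .editquant import TargetDefinition, revcomp
from .seqio import ConfigError, PairScoreRow, ReadRecord, SequenceRecord
from .structcluster import StructureSet

__all__ = [
    "StructureSimConfig",
    "LibrarySimConfig",
    "EditorSimConfig",
    "WINDOW_PRESETS",
    "study_scale_cluster_sizes",
    "simulate_structure_set",
    "simulate_library",
    "simulate_reads",
    "simulate_rloop_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class StructureSimConfig:
    """Planted-cluster TM-score matrix simulation.

    ``tm_within``/``tm_between`` are uniform supports for the by-longer
    normalized score of within- and between-cluster pairs.  In the
    ``separated`` regime the within support must sit entirely above the
    clustering threshold and the between support entirely below it.
    """

    cluster_sizes: tuple[int, ...] = (5, 3, 2)
    length_range: tuple[int, int] = (150, 400)
    tm_within: tuple[float, float] = (0.72, 0.95)
    tm_between: tuple[float, float] = (0.10, 0.60)
    norm_jitter: float = 0.03  # shorter-normalized score exceeds longer by <= this
    seed: int = 0
    separated: bool = True
    tm_threshold: float = 0.7

    def __post_init__(self) -> None:
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ConfigError("cluster sizes must be positive")
        for lo, hi in (self.tm_within, self.tm_between):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ConfigError("TM supports must be ordered within [0,1]")
        if self.separated:
            if not (self.tm_within[0] > self.tm_threshold > self.tm_between[1]):
                raise ConfigError(
                    "separated regime requires tm_within support above the "
                    "threshold and tm_between support below it"
                )


def simulate_structure_set(
    config: StructureSimConfig,
) -> tuple[StructureSet, list[PairScoreRow], dict[str, int]]:
    """Simulate lengths and pairwise TM-scores with a planted partition.

    The by-longer normalized score is the primary draw; the by-shorter score
    adds non-negative jitter (capped at 1), matching the fact that
    normalizing a TM-score by the longer protein can only lower it.  Cluster
    centers are forced to be the longest member of their cluster.  Returns
    (structure set, pair rows, planted labels id -> cluster number).
    """
    rng = np.random.default_rng(config.seed)
    ids: list[str] = []
    lengths: dict[str, int] = {}
    labels: dict[str, int] = {}
    lo, hi = config.length_range
    for c, size in enumerate(config.cluster_sizes, start=1):
        drawn = sorted(rng.integers(lo, hi + 1, size=size), reverse=True)
        # force strict length descent within the cluster so the planted
        # center (longest member) is unambiguous
        for k in range(1, size):
            drawn[k] = min(drawn[k], drawn[k - 1] - 1)
        if drawn[-1] < 1:
            raise ConfigError("length range too narrow for cluster size")
        for m, length in enumerate(drawn, start=1):
            pid = f"C{c:03d}_P{m:03d}"
            ids.append(pid)
            lengths[pid] = int(length)
            labels[pid] = c

    rows: list[PairScoreRow] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            support = (config.tm_within if labels[a] == labels[b]
                       else config.tm_between)
            by_longer = float(rng.uniform(*support))
            by_shorter = min(1.0, by_longer + float(rng.uniform(0, config.norm_jitter)))
            if lengths[a] >= lengths[b]:
                norm_a, norm_b = by_longer, by_shorter
            else:
                norm_a, norm_b = by_shorter, by_longer
            rows.append(PairScoreRow(a, b, norm_a, norm_b))
    return StructureSet(ids=tuple(ids), lengths=lengths), rows, labels


def study_scale_cluster_sizes() -> tuple[int, ...]:
    """A synthetic cluster-size distribution at discovery-screen scale.

    Synthetic stand-in (not measured data): 184 clusters over 1,483
    candidates whose sizes follow the leader-clustering shape of a few large
    clusters and a long tail of small ones, and whose representative count
    under ``max(1, ceil(0.10 * n))`` totals 272.
    """
    sizes = (
        [120] + [60] * 2 + [40] * 5 + [25] * 10 + [15] * 20 + [12] * 12
        + [3] * 81 + [2] * 53
    )
    return tuple(sizes)


@dataclass(frozen=True)
class LibrarySimConfig:
    """Self-targeting sgRNA-target library simulation."""

    n_targets: int = 102
    spacer_len: int = 20
    gc_band: tuple[float, float] = (0.40, 0.65)
    gc_in_band_fraction: float = 0.84
    flank_len: int = 25
    seed: int = 0
    max_tries: int = 10_000

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ConfigError("n_targets must be >= 1")
        if not 0.0 <= self.gc_in_band_fraction <= 1.0:
            raise ConfigError("gc_in_band_fraction must lie in [0,1]")
        if self.flank_len < 3:
            raise ConfigError("flank_len must be >= 3 (room for a minus-strand PAM)")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _draw_spacer(rng: np.random.Generator, config: LibrarySimConfig,
                 want_in_band: bool) -> str:
    """Rejection-sample a spacer with >=1 C at positions 2-8 and the desired
    GC-band membership."""
    lo, hi = config.gc_band
    for _ in range(config.max_tries):
        spacer = _random_dna(rng, config.spacer_len)
        if "C" not in spacer[1:8]:  # 1-based positions 2..8
            continue
        in_band = lo <= _gc_fraction(spacer) <= hi
        if in_band == want_in_band:
            return spacer
    raise ConfigError("could not satisfy spacer constraints within max_tries")


def simulate_library(
    config: LibrarySimConfig,
) -> tuple[list[TargetDefinition], list[SequenceRecord], dict]:
    """Generate self-targeting amplicons: flank + spacer + NGG PAM + flank.

    Each target's amplicon embeds its own protospacer (plus strand) with the
    PAM at protospacer positions 21-23.  A Bernoulli draw per target decides
    whether its spacer GC content falls inside the configured band, so the
    emitted in-band fraction matches ``gc_in_band_fraction`` in expectation.
    Returns (targets, FASTA records, summary with the realized GC fractions).
    """
    rng = np.random.default_rng(config.seed)
    targets: list[TargetDefinition] = []
    records: list[SequenceRecord] = []
    gc_values: list[float] = []
    n_in_band = 0
    for t in range(config.n_targets):
        want_in_band = bool(rng.random() < config.gc_in_band_fraction)
        spacer = _draw_spacer(rng, config, want_in_band)
        pam = "ACGT"[int(rng.integers(0, 4))] + "GG"
        left = _random_dna(rng, config.flank_len)
        right = _random_dna(rng, config.flank_len)
        amplicon = left + spacer + pam + right
        tid = f"T{t + 1:04d}"
        targets.append(
            TargetDefinition(
                target_id=tid,
                amplicon_seq=amplicon,
                protospacer_start=config.flank_len,
                protospacer_strand="+",
                protospacer_len=config.spacer_len,
            )
        )
        records.append(SequenceRecord(id=tid, sequence=amplicon))
        gc = _gc_fraction(spacer)
        gc_values.append(gc)
        n_in_band += config.gc_band[0] <= gc <= config.gc_band[1]
    summary = {
        "n_targets": config.n_targets,
        "gc_band": config.gc_band,
        "gc_in_band_fraction": n_in_band / config.n_targets,
        "gc_values": gc_values,
    }
    return targets, records, summary


WINDOW_PRESETS: dict[str, dict[int, float]] = {
    # per-position multipliers over protospacer C1..C20 (absent -> 0)
    "narrow_C4_C6": {4: 0.9, 5: 1.0, 6: 0.9},
    "rAPOBEC1_C4_C7": {3: 0.15, 4: 0.9, 5: 1.0, 6: 0.95, 7: 0.85, 8: 0.15},
    "wide_C1_C9": {p: 1.0 - 0.03 * abs(p - 5) for p in range(1, 10)},
}

UNIFORM_CONTEXT = {"AC": 1.0, "CC": 1.0, "GC": 1.0, "TC": 1.0}


@dataclass(frozen=True)
class EditorSimConfig:
    """Planted editing behaviour of a simulated cytosine base editor."""

    base_rate: float = 0.5
    window_shape: str | dict[int, float] = "narrow_C4_C6"
    context_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(UNIFORM_CONTEXT))
    cg_rate: float = 0.0  # minor C->G channel
    ca_rate: float = 0.0  # minor C->A channel
    indel_rate: float = 0.0
    seq_error_rate: float = 0.0
    depth: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_rate", "cg_rate", "ca_rate", "indel_rate",
                     "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        shape = self.resolve_window_shape()
        worst = max((m for m in shape.values()), default=0.0)
        ctx_max = max(self.context_multipliers.values(), default=1.0)
        if self.base_rate * worst * ctx_max + self.cg_rate + self.ca_rate > 1.0:
            raise ConfigError("per-position total alteration probability > 1")

    def resolve_window_shape(self) -> dict[int, float]:
        if isinstance(self.window_shape, str):
            if self.window_shape not in WINDOW_PRESETS:
                raise ConfigError(f"unknown window preset {self.window_shape!r}")
            return WINDOW_PRESETS[self.window_shape]
        return dict(self.window_shape)


def planted_rates(target: TargetDefinition,
                  config: EditorSimConfig) -> dict[int, float]:
    """Expected C-to-T rate at each reference-C protospacer position."""
    shape = config.resolve_window_shape()
    rates: dict[int, float] = {}
    for p in range(1, target.protospacer_len + 1):
        if target.protospacer_base(p) != "C":
            continue
        ctx = target.context(p)
        mult = config.context_multipliers.get(ctx, 1.0) if ctx else 1.0
        rates[p] = config.base_rate * shape.get(p, 0.0) * mult
    return rates


def _apply_indel(rng: np.random.Generator, amplicon: str,
                 target: TargetDefinition) -> str:
    """One 1-3 bp insertion or deletion uniformly inside the protospacer."""
    size = int(rng.integers(1, 4))
    lo = target.protospacer_start
    hi = lo + target.protospacer_len
    pos = int(rng.integers(lo, hi))
    if rng.random() < 0.5 and pos + size <= hi:
        return amplicon[:pos] + amplicon[pos + size:]
    insert = _random_dna(rng, size)
    return amplicon[:pos] + insert + amplicon[pos:]


def simulate_reads(
    target: TargetDefinition,
    config: EditorSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], dict]:
    """Simulate amplicon-length reads with planted editing outcomes.

    Per read: with probability ``indel_rate`` a single 1-3 bp indel inside
    the protospacer (no substitutions on that read — indel and substitution
    events are mutually exclusive per read); otherwise each reference C at
    protospacer position p converts to T with rate
    ``base_rate * window_shape(p) * context_multiplier``, or to G/A at the
    minor rates.  Uniform sequencing error is applied per base afterwards.
    Quality strings are constant Q40.  Returns (reads, truth record).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    amplicon = target.amplicon_seq
    n, depth = len(amplicon), config.depth
    rates = planted_rates(target, config)

    is_indel = rng.random(depth) < config.indel_rate
    n_sub_reads = int((~is_indel).sum())

    ref = np.frombuffer(amplicon.encode(), dtype=np.uint8)
    mat = np.tile(ref, (n_sub_reads, 1))
    minus = target.protospacer_strand == "-"
    for p, rate in rates.items():
        i = target.amplicon_index(p)
        u = rng.random(n_sub_reads)
        to_t = u < rate
        to_g = (u >= rate) & (u < rate + config.cg_rate)
        to_a = (u >= rate + config.cg_rate) & (u < rate + config.cg_rate + config.ca_rate)
        # protospacer-strand alt -> amplicon-strand base
        t_base, g_base, a_base = (b"T"[0], b"G"[0], b"A"[0]) if not minus \
            else (b"A"[0], b"C"[0], b"T"[0])
        mat[to_t, i] = t_base
        mat[to_g, i] = g_base
        mat[to_a, i] = a_base

    if config.seq_error_rate > 0:
        err = rng.random(mat.shape) < config.seq_error_rate
        if err.any():
            # replace with one of the three other bases, uniformly
            offsets = rng.integers(1, 4, size=int(err.sum()))
            base_to_idx = np.zeros(256, dtype=np.uint8)
            for k, b in enumerate(b"ACGT"):
                base_to_idx[b] = k
            cur = base_to_idx[mat[err]]
            mat[err] = _BASES[(cur + offsets) % 4]

    reads: list[ReadRecord] = []
    sub_iter = iter(range(n_sub_reads))
    qual_full = "I" * n
    for r in range(depth):
        rid = f"{target.target_id}_r{r + 1:06d}"
        if is_indel[r]:
            seq = _apply_indel(rng, amplicon, target)
            if config.seq_error_rate > 0:
                seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                err = rng.random(len(seq_arr)) < config.seq_error_rate
                if err.any():
                    offsets = rng.integers(1, 4, size=int(err.sum()))
                    base_to_idx = np.zeros(256, dtype=np.uint8)
                    for k, b in enumerate(b"ACGT"):
                        base_to_idx[b] = k
                    cur = base_to_idx[seq_arr[err]]
                    seq_arr[err] = _BASES[(cur + offsets) % 4]
                seq = bytes(seq_arr).decode()
            reads.append(ReadRecord(id=rid, sequence=seq, quality="I" * len(seq)))
        else:
            row = next(sub_iter)
            reads.append(ReadRecord(id=rid, sequence=bytes(mat[row]).decode(),
                                    quality=qual_full))
    truth = {
        "target_id": target.target_id,
        "depth": depth,
        "planted_ct_rates": rates,
        "cg_rate": config.cg_rate,
        "ca_rate": config.ca_rate,
        "indel_rate": config.indel_rate,
        "seq_error_rate": config.seq_error_rate,
        "n_indel_reads": int(is_indel.sum()),
        "note": "indel and substitution events are mutually exclusive per read",
    }
    return reads, truth


def simulate_rloop_reads(
    off_rate: float,
    n_sites: int = 4,
    depth: int = 2000,
    seed: int = 0,
    flank_len: int = 25,
) -> dict[str, tuple[TargetDefinition, list[ReadRecord]]]:
    """Per-site reads for the orthogonal R-loop off-target panel.

    Each site is an independent synthetic amplicon edited with uniform,
    context-free C-to-T conversion at ``off_rate`` across its protospacer.
    """
    if not 0.0 <= off_rate <= 1.0:
        raise ConfigError("off_rate must lie in [0,1]")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sites)
    lib_cfg = LibrarySimConfig(n_targets=n_sites, flank_len=flank_len, seed=seed)
    targets, _records, _summary = simulate_library(lib_cfg)
    panel: dict[str, tuple[TargetDefinition, list[ReadRecord]]] = {}
    for k, target in enumerate(targets):
        site_name = f"Sa_site{k + 3}"  # panel naming: Sa site3..site6
        target = TargetDefinition(
            target_id=site_name,
            amplicon_seq=target.amplicon_seq,
            protospacer_start=target.protospacer_start,
            protospacer_strand=target.protospacer_strand,
            protospacer_len=target.protospacer_len,
        )
        cfg = EditorSimConfig(
            base_rate=off_rate,
            window_shape={p: 1.0 for p in range(1, 21)},
            context_multipliers=dict(UNIFORM_CONTEXT),
            depth=depth,
        )
        rng = np.random.default_rng(children[k])
        reads, _truth = simulate_reads(target, cfg, rng=rng)
        panel[site_name] = (target, reads)
    return panel
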