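"""Amplicon read alignment and per-position base-editing quantification.

Reads from an amplicon deep-sequencing experiment are globally aligned to
their reference amplicon (both orientations; the better one wins),
classified as reference / substituted / indel, and tallied into per-position
base counts.  C-to-T conversion frequencies are reported in protospacer
coordinates C1..C20 (PAM at 21-23), with the editing window defined as the
span of positions reaching at least half the maximum per-position frequency,
the 5'-dinucleotide (NC) context preference over a position range, the
ref->alt edit-type matrix, and indel frequency.  All per-read denominators
for substitution statistics exclude indel-containing reads.

Coordinates are 0-based half-open internally; every report speaks 1-based
protospacer positions on the protospacer strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import ConfigError, FormatError, ReadRecord

__all__ = [
    "Scoring",
    "TargetDefinition",
    "AlignmentResult",
    "ReadClass",
    "PositionProfile",
    "EditProfile",
    "EditingWindow",
    "ContextProfile",
    "EditTypeMatrix",
    "TargetQuantification",
    "align_global",
    "orient_and_align",
    "classify_read",
    "build_position_profile",
    "ctot_profile",
    "call_editing_window",
    "context_profile",
    "edit_type_matrix",
    "indel_frequency",
    "target_efficiency",
    "quantify_target",
    "aggregate_library",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
DEL = 4  # deletion column in the count matrix


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -1
    gap: int = -2


@dataclass(frozen=True)
class TargetDefinition:
    """An amplicon with its protospacer annotation.

    ``protospacer_start`` is the 0-based offset of the protospacer-matching
    region on the amplicon.  On the ``-`` strand the protospacer sequence is
    the reverse complement of that region and the PAM lies 5' of it on the
    amplicon.  ``quantification_window`` is a closed interval of 1-based
    protospacer positions.
    """

    target_id: str
    amplicon_seq: str
    protospacer_start: int
    protospacer_strand: str = "+"
    protospacer_len: int = 20
    quantification_window: tuple[int, int] = (1, 20)

    def __post_init__(self) -> None:
        seq = self.amplicon_seq.upper()
        object.__setattr__(self, "amplicon_seq", seq)
        if set(seq) - set("ACGTN"):
            raise FormatError(f"{self.target_id}: amplicon has non-ACGTN characters")
        if self.protospacer_strand not in "+-":
            raise ConfigError(f"{self.target_id}: strand must be '+' or '-'")
        lo, hi = self.protospacer_start, self.protospacer_start + self.protospacer_len
        if not (0 <= lo and hi <= len(seq)):
            raise ConfigError(f"{self.target_id}: protospacer outside amplicon")
        # PAM immediately 3' of the protospacer on the protospacer strand
        if self.protospacer_strand == "+":
            if hi + 3 > len(seq):
                raise ConfigError(f"{self.target_id}: no room for PAM 3' of protospacer")
        else:
            if lo - 3 < 0:
                raise ConfigError(f"{self.target_id}: no room for PAM 3' of protospacer")
        wlo, whi = self.quantification_window
        if not (1 <= wlo <= whi <= self.protospacer_len):
            raise ConfigError(f"{self.target_id}: bad quantification window")

    # -- protospacer-coordinate helpers -------------------------------------

    def amplicon_index(self, position: int) -> int:
        """Amplicon index of 1-based protospacer position ``position``.

        Positions 21-23 address the PAM; position 0 addresses the base 5' of
        the protospacer on the protospacer strand.
        """
        if self.protospacer_strand == "+":
            return self.protospacer_start + position - 1
        return self.protospacer_start + self.protospacer_len - position

    def protospacer_base(self, position: int) -> str:
        """Reference base at a protospacer position, on the protospacer strand."""
        base = self.amplicon_seq[self.amplicon_index(position)]
        if self.protospacer_strand == "-":
            base = base.translate(_COMPLEMENT)
        return base

    @property
    def protospacer_seq(self) -> str:
        return "".join(self.protospacer_base(p)
                       for p in range(1, self.protospacer_len + 1))

    @property
    def pam_seq(self) -> str:
        return "".join(self.protospacer_base(p)
                       for p in range(self.protospacer_len + 1,
                                      self.protospacer_len + 4))

    def context(self, position: int) -> str | None:
        """5'-dinucleotide context (e.g. ``"TC"``) of a protospacer position.

        Position 1 uses the amplicon base immediately 5' of the protospacer
        on the protospacer strand; ``None`` when that base falls off the
        amplicon.
        """
        idx = self.amplicon_index(position - 1) if position == 1 else None
        if position == 1:
            if not 0 <= idx < len(self.amplicon_seq):
                return None
            five = self.amplicon_seq[idx]
            if self.protospacer_strand == "-":
                five = five.translate(_COMPLEMENT)
        else:
            five = self.protospacer_base(position - 1)
        return five + self.protospacer_base(position)

    def window_amplicon_span(self) -> tuple[int, int]:
        """Closed amplicon-index interval covered by the quantification window."""
        wlo, whi = self.quantification_window
        i, j = self.amplicon_index(wlo), self.amplicon_index(whi)
        return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class AlignmentResult:
    """A global read-vs-amplicon alignment (amplicon frame).

    ``aligned_ref``/``aligned_read`` carry ``-`` gap characters; ungapping
    recovers the amplicon and the (possibly reverse-complemented) read.
    ``orientation`` records whether the read matched forward (+) or as its
    reverse complement (-) — amplicon coordinates are unaffected.
    """

    aligned_ref: str
    aligned_read: str
    score: int
    orientation: str = "+"

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_read):
            raise ConfigError("aligned strings differ in length")

    @property
    def has_gaps(self) -> bool:
        return "-" in self.aligned_ref or "-" in self.aligned_read

    def per_position(self) -> tuple[list[str], list[int]]:
        """Observed base or gap per amplicon position, plus insertion anchors.

        Returns (observed, insertion_anchors): ``observed[i]`` is the read
        base aligned to amplicon position ``i`` or ``"-"`` for a deletion;
        each insertion contributes the amplicon index it precedes.
        """
        observed: list[str] = []
        insertions: list[int] = []
        ref_i = 0
        for r, q in zip(self.aligned_ref, self.aligned_read):
            if r == "-":
                insertions.append(ref_i)
            else:
                observed.append(q)
                ref_i += 1
        return observed, insertions


class ReadClass:
    """Exhaustive, mutually exclusive per-read outcome labels."""

    REFERENCE = "reference"
    SUBSTITUTED = "substituted"
    INDEL = "indel"
    DISCARDED = "discarded_low_quality"

    ALL = (REFERENCE, SUBSTITUTED, INDEL, DISCARDED)


def _make_aligner(scoring: Scoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                matrix[a, b] = scoring.match
            else:
                matrix[a, b] = scoring.mismatch  # N mismatches everything
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner


_DEFAULT_SCORING = Scoring()
_ALIGNER_CACHE: dict[Scoring, PairwiseAligner] = {}


def _aligner_for(scoring: Scoring) -> PairwiseAligner:
    if scoring not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[scoring] = _make_aligner(scoring)
    return _ALIGNER_CACHE[scoring]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FormatError(f"{what}: empty sequence")
    if set(seq) - set("ACGTN"):
        raise FormatError(f"{what}: non-DNA characters (only ACGTN allowed)")
    return seq


def _gapless_score(a: str, b: str, scoring: Scoring) -> int:
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    n_pos = len(a)
    matches = int(np.sum((arr_a == arr_b) & (arr_a != ord("N"))))
    return matches * scoring.match + (n_pos - matches) * scoring.mismatch


def align_global(read: str, amplicon: str,
                 scoring: Scoring = _DEFAULT_SCORING) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment of a read to its amplicon.

    Scoring defaults to match +2 / mismatch -1 / gap -2 (linear).  When the
    sequences have equal length and the gapless comparison already attains
    the optimal score, the gapless (pure-substitution) alignment is returned;
    otherwise a deterministic optimal traceback is taken.
    """
    read = _check_dna(read, "read")
    amplicon = _check_dna(amplicon, "amplicon")
    aligner = _aligner_for(scoring)
    best = int(aligner.score(amplicon, read))
    if len(read) == len(amplicon) and _gapless_score(amplicon, read, scoring) == best:
        return AlignmentResult(aligned_ref=amplicon, aligned_read=read, score=best)
    aln = aligner.align(amplicon, read)[0]
    return AlignmentResult(aligned_ref=str(aln[0]), aligned_read=str(aln[1]),
                           score=best)


def orient_and_align(
    read: str | ReadRecord,
    target: TargetDefinition,
    scoring: Scoring = _DEFAULT_SCORING,
    min_score_frac: float = 0.6,
) -> AlignmentResult | None:
    """Align a read in both orientations and keep the better one.

    Returns ``None`` (caller records ``discarded_low_quality``) when neither
    orientation reaches ``min_score_frac`` of the perfect score
    (``match * len(amplicon)``).
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    seq = _check_dna(seq, "read")
    amplicon = target.amplicon_seq
    aligner = _aligner_for(scoring)
    rc = revcomp(seq)
    score_fwd = int(aligner.score(amplicon, seq))
    score_rev = int(aligner.score(amplicon, rc))
    best, oriented, orientation = (
        (score_fwd, seq, "+") if score_fwd >= score_rev else (score_rev, rc, "-")
    )
    if best < min_score_frac * scoring.match * len(amplicon):
        return None
    if len(oriented) == len(amplicon) and \
            _gapless_score(amplicon, oriented, scoring) == best:
        return AlignmentResult(aligned_ref=amplicon, aligned_read=oriented,
                               score=best, orientation=orientation)
    aln = aligner.align(amplicon, oriented)[0]
    return AlignmentResult(aligned_ref=str(aln[0]), aligned_read=str(aln[1]),
                           score=best, orientation=orientation)


def classify_read(alignment: AlignmentResult, target: TargetDefinition) -> str:
    """reference / substituted / indel, judged inside the quantification window.

    ``indel`` iff any insertion or deletion overlaps the window;
    else ``substituted`` iff at least one mismatch falls in the window;
    else ``reference``.
    """
    w_lo, w_hi = target.window_amplicon_span()
    observed, insertions = alignment.per_position()
    for anchor in insertions:
        if w_lo + 1 <= anchor <= w_hi:  # strictly between two window bases
            return ReadClass.INDEL
    window_obs = observed[w_lo:w_hi + 1]
    window_ref = target.amplicon_seq[w_lo:w_hi + 1]
    if "-" in window_obs:
        return ReadClass.INDEL
    if any(o != r for o, r in zip(window_obs, window_ref)):
        return ReadClass.SUBSTITUTED
    return ReadClass.REFERENCE


@dataclass
class PositionProfile:
    """Per-amplicon-position base counts from non-indel reads.

    ``counts`` has shape (amplicon length, 5) with columns A, C, G, T,
    deletion; ``insertions[i]`` counts insertions anchored before position i.
    Conservation: each row sums to the non-indel read count.
    """

    target_id: str
    amplicon_seq: str
    counts: np.ndarray
    insertions: np.ndarray
    n_reference: int = 0
    n_substituted: int = 0
    n_indel: int = 0

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_accepted(self) -> int:
        return self.n_reference + self.n_substituted + self.n_indel


def build_position_profile(
    alignments: Iterable[AlignmentResult],
    target: TargetDefinition,
) -> PositionProfile:
    """Tally aligned reads into per-position base counts.

    Indel-classified reads are counted in ``n_indel`` only; substitution
    statistics come from reference + substituted reads (CRISPResso-like
    convention).
    """
    n = len(target.amplicon_seq)
    counts = np.zeros((n, 5), dtype=np.int64)
    ins = np.zeros(n + 1, dtype=np.int64)
    ref_arr = np.frombuffer(target.amplicon_seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    n_ref = n_sub = n_indel = 0
    got_any = False
    for aln in alignments:
        got_any = True
        cls = classify_read(aln, target)
        if cls == ReadClass.INDEL:
            n_indel += 1
            continue
        if cls == ReadClass.REFERENCE:
            n_ref += 1
        else:
            n_sub += 1
        if not aln.has_gaps:
            obs = np.frombuffer(aln.aligned_read.encode(), dtype=np.uint8)
            cols = lut[obs]
            valid = cols >= 0  # N bases drop out of the tally
            counts[np.nonzero(valid)[0], cols[valid]] += 1
            # N positions still count as coverage? No: exclude entirely.
            continue
        observed, insertions = aln.per_position()
        for anchor in insertions:
            ins[anchor] += 1
        for i, base in enumerate(observed):
            if base == "-":
                counts[i, DEL] += 1
            elif base in _BASE_INDEX:
                counts[i, _BASE_INDEX[base]] += 1
    if not got_any:
        raise FormatError(f"{target.target_id}: no accepted alignments")
    return PositionProfile(
        target_id=target.target_id,
        amplicon_seq=target.amplicon_seq,
        counts=counts,
        insertions=ins[:n],
        n_reference=n_ref,
        n_substituted=n_sub,
        n_indel=n_indel,
    )


@dataclass
class EditProfile:
    """C-to-T (and minor C-to-G / C-to-A) frequencies per protospacer position.

    Keys are 1-based protospacer positions whose reference base (protospacer
    strand) is C.  ``None`` marks positions with zero coverage (undefined,
    not zero).
    """

    target_id: str
    f_ct: dict[int, float | None]
    f_cg: dict[int, float | None]
    f_ca: dict[int, float | None]
    n: dict[int, int]

    @property
    def c_positions(self) -> list[int]:
        return sorted(self.f_ct)

    def defined(self) -> dict[int, float]:
        return {p: v for p, v in self.f_ct.items() if v is not None}


# protospacer-strand edit -> amplicon-strand observed base, by target strand
def _observed_base_for(proto_alt: str, strand: str) -> str:
    return proto_alt if strand == "+" else proto_alt.translate(_COMPLEMENT)


def ctot_profile(profile: PositionProfile, target: TargetDefinition) -> EditProfile:
    """Per-position C-to-T frequencies in protospacer coordinates.

    On a ``-`` strand protospacer the amplicon-strand observation of a
    protospacer C-to-T edit is G-to-A; the mapping is handled here so the
    returned profile always speaks protospacer-strand edits.
    """
    f_ct: dict[int, float | None] = {}
    f_cg: dict[int, float | None] = {}
    f_ca: dict[int, float | None] = {}
    n: dict[int, int] = {}
    cov = profile.coverage
    for p in range(1, target.protospacer_len + 1):
        if target.protospacer_base(p) != "C":
            continue
        i = target.amplicon_index(p)
        depth = int(cov[i])
        n[p] = depth
        if depth == 0:
            f_ct[p] = f_cg[p] = f_ca[p] = None
            continue
        for alt, store in (("T", f_ct), ("G", f_cg), ("A", f_ca)):
            obs = _observed_base_for(alt, target.protospacer_strand)
            store[p] = float(profile.counts[i, _BASE_INDEX[obs]]) / depth
    return EditProfile(target_id=target.target_id,
                       f_ct=f_ct, f_cg=f_cg, f_ca=f_ca, n=n)


@dataclass(frozen=True)
class EditingWindow:
    """Editing window under the >=50%-of-maximum frequency rule."""

    qualifying: frozenset[int]
    span: tuple[int, int] | None  # contiguous reported span (C_lo - C_hi)
    peak: int | None
    rel_threshold: float

    @property
    def empty(self) -> bool:
        return self.span is None

    def label(self) -> str:
        if self.span is None:
            return "empty"
        return f"C{self.span[0]}-C{self.span[1]}"


def call_editing_window(
    edit_profile: EditProfile,
    rel_threshold: float = 0.5,
    min_peak: float = 0.01,
) -> EditingWindow:
    """Positions whose frequency reaches ``rel_threshold`` of the maximum.

    The reported span is the closed interval from the first to the last
    qualifying position (interior dips are spanned); the peak is the
    smallest position attaining the maximum.  A maximum below ``min_peak``
    yields an empty window.
    """
    defined = edit_profile.defined()
    if not defined:
        raise FormatError(f"{edit_profile.target_id}: no defined C-to-T frequencies")
    m = max(defined.values())
    if m < min_peak:
        return EditingWindow(qualifying=frozenset(), span=None, peak=None,
                             rel_threshold=rel_threshold)
    qualifying = {p for p, f in defined.items() if f >= rel_threshold * m}
    peak = min(p for p, f in defined.items() if f == m)
    return EditingWindow(
        qualifying=frozenset(qualifying),
        span=(min(qualifying), max(qualifying)),
        peak=peak,
        rel_threshold=rel_threshold,
    )


CONTEXTS = ("AC", "CC", "GC", "TC")


@dataclass
class ContextProfile:
    """Mean editing frequency by 5'-dinucleotide context (NC motif)."""

    means: dict[str, float | None]
    n_obs: dict[str, int]
    position_range: tuple[int, int]

    def ranking(self) -> list[str]:
        defined = {c: m for c, m in self.means.items() if m is not None}
        return sorted(defined, key=lambda c: -defined[c])


def context_profile(
    targets_with_profiles: Iterable[tuple[TargetDefinition, EditProfile]],
    position_range: tuple[int, int] = (3, 7),
) -> ContextProfile:
    """Mean C-to-T frequency per NC context over (target, position) pairs.

    Each reference C inside ``position_range`` contributes its frequency to
    the mean of its 5'-neighbour context; contexts with zero observations
    are flagged ``None``.
    """
    lo, hi = position_range
    sums = {c: 0.0 for c in CONTEXTS}
    counts = {c: 0 for c in CONTEXTS}
    for target, profile in targets_with_profiles:
        for p, f in profile.defined().items():
            if not lo <= p <= hi:
                continue
            ctx = target.context(p)
            if ctx in sums:
                sums[ctx] += f
                counts[ctx] += 1
    means = {c: (sums[c] / counts[c] if counts[c] else None) for c in CONTEXTS}
    return ContextProfile(means=means, n_obs=counts, position_range=(lo, hi))


@dataclass
class EditTypeMatrix:
    """Proportions of ref->alt substitution events (12 off-diagonal cells)."""

    proportions: pd.DataFrame  # index=ref base, columns=alt base
    n_events: int
    denominator: str = "total_events"

    @property
    def empty(self) -> bool:
        return self.n_events == 0


def edit_type_matrix(
    pairs: Iterable[tuple[TargetDefinition, PositionProfile]],
    denominator: str = "total_events",
) -> EditTypeMatrix:
    """Count substitution events by ref->alt type inside the window.

    Counts are taken on the protospacer strand.  ``denominator`` is either
    ``total_events`` (all cells sum to 1) or ``per_ref_base`` (each row sums
    to 1 over observed alts).
    """
    if denominator not in ("total_events", "per_ref_base"):
        raise ConfigError(f"unknown denominator {denominator!r}")
    events = pd.DataFrame(0, index=list(_BASES), columns=list(_BASES), dtype=float)
    for target, profile in pairs:
        wlo, whi = target.quantification_window
        for p in range(wlo, whi + 1):
            ref = target.protospacer_base(p)
            if ref not in _BASE_INDEX:
                continue
            i = target.amplicon_index(p)
            for alt in _BASES:
                if alt == ref:
                    continue
                obs = _observed_base_for(alt, target.protospacer_strand)
                events.loc[ref, alt] += int(profile.counts[i, _BASE_INDEX[obs]])
    total = float(events.values.sum())
    if total == 0:
        return EditTypeMatrix(proportions=events, n_events=0,
                              denominator=denominator)
    if denominator == "total_events":
        props = events / total
    else:
        row_sums = events.sum(axis=1)
        props = events.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return EditTypeMatrix(proportions=props, n_events=int(total),
                          denominator=denominator)


def indel_frequency(read_classes: Iterable[str]) -> float:
    """Fraction of accepted reads carrying an indel in the window."""
    n_indel = n_accepted = 0
    for cls in read_classes:
        if cls == ReadClass.DISCARDED:
            continue
        n_accepted += 1
        n_indel += cls == ReadClass.INDEL
    if n_accepted == 0:
        raise FormatError("no accepted reads")
    return n_indel / n_accepted


def target_efficiency(edit_profile: EditProfile,
                      method: str = "max_position",
                      window: tuple[int, int] | None = None) -> float | None:
    """Scalar per-target editing efficiency.

    ``max_position`` (default): the maximum per-position C-to-T frequency in
    the protospacer.  ``mean_window``: the mean over defined positions inside
    ``window`` (default: all C positions).  ``None`` when nothing is defined.
    """
    defined = edit_profile.defined()
    if window is not None:
        defined = {p: f for p, f in defined.items() if window[0] <= p <= window[1]}
    if not defined:
        return None
    if method == "max_position":
        return max(defined.values())
    if method == "mean_window":
        return float(np.mean(list(defined.values())))
    raise ConfigError(f"unknown efficiency method {method!r}")


@dataclass
class TargetQuantification:
    """Everything the screen reports for one target."""

    target: TargetDefinition
    profile: PositionProfile
    edit_profile: EditProfile
    window: EditingWindow
    read_classes: dict[str, int]
    indel_frequency: float
    efficiency: float | None
    n_discarded: int = 0


def quantify_target(
    reads: Iterable[ReadRecord | str],
    target: TargetDefinition,
    scoring: Scoring = _DEFAULT_SCORING,
    min_score_frac: float = 0.6,
    rel_threshold: float = 0.5,
    min_peak: float = 0.01,
    efficiency_method: str = "max_position",
) -> TargetQuantification:
    """Full per-target quantification: align, classify, profile, window."""
    alignments: list[AlignmentResult] = []
    n_discarded = 0
    for read in reads:
        aln = orient_and_align(read, target, scoring=scoring,
                               min_score_frac=min_score_frac)
        if aln is None:
            n_discarded += 1
        else:
            alignments.append(aln)
    if not alignments:
        raise FormatError(f"{target.target_id}: no accepted reads")
    profile = build_position_profile(alignments, target)
    ep = ctot_profile(profile, target)
    window = call_editing_window(ep, rel_threshold=rel_threshold,
                                 min_peak=min_peak)
    classes = {
        ReadClass.REFERENCE: profile.n_reference,
        ReadClass.SUBSTITUTED: profile.n_substituted,
        ReadClass.INDEL: profile.n_indel,
    }
    indel_f = profile.n_indel / profile.n_accepted
    return TargetQuantification(
        target=target,
        profile=profile,
        edit_profile=ep,
        window=window,
        read_classes=classes,
        indel_frequency=indel_f,
        efficiency=target_efficiency(ep, method=efficiency_method),
        n_discarded=n_discarded,
    )


def aggregate_library(
    quantifications: Sequence[TargetQuantification],
) -> dict:
    """Library-level distribution statistics over per-target efficiencies.

    Quartiles use linear interpolation (declared in the output).  The
    position-wise mean profile averages defined C-to-T frequencies per
    protospacer position across targets.
    """
    if not quantifications:
        raise FormatError("no target summaries to aggregate")
    effs = [q.efficiency for q in quantifications if q.efficiency is not None]
    arr = np.array(effs, dtype=float)
    per_position: dict[int, list[float]] = {}
    for q in quantifications:
        for p, f in q.edit_profile.defined().items():
            per_position.setdefault(p, []).append(f)
    stats = {
        "n_targets": len(quantifications),
        "n_with_efficiency": len(effs),
        "quantile_convention": "linear",
    }
    if len(arr):
        stats.update(
            mean=float(arr.mean()),
            median=float(np.percentile(arr, 50)),
            q1=float(np.percentile(arr, 25)),
            q3=float(np.percentile(arr, 75)),
            min=float(arr.min()),
            max=float(arr.max()),
        )
    stats["position_mean_f"] = {
        p: float(np.mean(v)) for p, v in sorted(per_position.items())
    }
    stats["mean_indel_frequency"] = float(
        np.mean([q.indel_frequency for q in quantifications])
    )
    return stats
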