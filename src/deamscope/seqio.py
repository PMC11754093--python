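"""Readers, writers and record-level filters for the formats the pipeline touches.

FASTA and FASTQ go through Biopython; HMMER per-sequence hit tables
(``tblout``) and TM-score pair tables are small whitespace/TSV dialects
parsed here with line-number-addressable errors.  Gzip is handled
transparently for FASTA/FASTQ by file suffix.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "DomainHit",
    "ReadRecord",
    "PairScoreRow",
    "FormatError",
    "ConfigError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "demultiplex_reads",
    "parse_hmmer_tblout",
    "filter_candidates",
    "read_pair_scores",
    "write_pair_scores",
]


class FormatError(ValueError):
    """Malformed input file (parse or validation failure)."""


class ConfigError(ValueError):
    """Invalid run configuration (bad parameter combination)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein or DNA sequence.

    A trailing ``*`` in the raw FASTA sequence is stripped into
    ``terminal_stop_flag`` — internal asterisks are rejected, so the stored
    sequence is always residue-only.
    """

    id: str
    sequence: str
    description: str = ""
    terminal_stop_flag: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if "*" in self.sequence:
            raise FormatError(f"record {self.id!r}: internal '*' in sequence")


@dataclass(frozen=True)
class DomainHit:
    """One per-sequence hit from a HMMER search (full-sequence E-value)."""

    seq_id: str
    profile_id: str
    full_seq_evalue: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.full_seq_evalue < 0:
            raise FormatError(
                f"hit {self.seq_id}/{self.profile_id}: negative e-value"
            )


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with its per-base quality string."""

    id: str
    sequence: str
    quality: str
    barcode: str | None = None

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True, slots=True)
class PairScoreRow:
    """Pairwise TM-score between two structures under both normalizations.

    ``tm_norm_a`` is the score normalized by the length of ``id_a``,
    ``tm_norm_b`` by the length of ``id_b``.
    """

    id_a: str
    id_b: str
    tm_norm_a: float
    tm_norm_b: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise FormatError(f"self-pair {self.id_a!r} not allowed")
        for name in ("tm_norm_a", "tm_norm_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(
                    f"pair ({self.id_a},{self.id_b}): {name}={v} outside [0,1]"
                )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved.  A trailing ``*`` becomes ``terminal_stop_flag``.
    Raises :class:`FormatError` on an empty file or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            raw = str(rec.seq)
            flag = raw.endswith("*")
            seq = raw.rstrip("*")
            desc = rec.description[len(rec.id):].strip()
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=seq,
                    description=desc,
                    terminal_stop_flag=flag,
                )
            )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA; ``terminal_stop_flag`` is re-emitted as ``*``."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.sequence + ("*" if rec.terminal_stop_flag else "")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily yield reads from a (possibly gzipped) 4-line FASTQ file.

    Truncated records and sequence/quality length mismatches raise
    :class:`FormatError` naming the offending record.
    """
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0] if title else title
                if len(seq) != len(qual):
                    raise FormatError(
                        f"{path}: read {rid!r}: sequence/quality length mismatch"
                    )
                yield ReadRecord(id=rid, sequence=seq, quality=qual)
        except ValueError as exc:  # Biopython signals truncation via ValueError
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_reads(
    reads: Iterable[ReadRecord],
    barcode_map: Mapping[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to samples by 5' barcode, trimming the barcode off.

    A read is assigned to the unique barcode with minimal Hamming distance
    ``<= max_mismatch``; distance ties and over-budget reads go to the
    unassigned pile untouched.  Reads are conserved: every input read appears
    exactly once in the output.
    """
    if max_mismatch < 0:
        raise ConfigError("max_mismatch must be >= 0")
    barcodes = dict(barcode_map)
    if not barcodes:
        raise ConfigError("empty barcode map")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ConfigError("barcodes must all have equal length")
    if len(set(barcodes.values())) != len(barcodes):
        raise ConfigError("duplicate barcode sequences in barcode map")
    blen = lengths.pop()

    assigned: dict[str, list[ReadRecord]] = {s: [] for s in barcodes}
    unassigned: list[ReadRecord] = []
    for read in reads:
        prefix = read.sequence[:blen]
        if len(prefix) < blen:
            unassigned.append(read)
            continue
        dists = [(sample, _hamming(prefix, bc)) for sample, bc in barcodes.items()]
        best = min(d for _, d in dists)
        winners = [s for s, d in dists if d == best]
        if best <= max_mismatch and len(winners) == 1:
            assigned[winners[0]].append(
                ReadRecord(
                    id=read.id,
                    sequence=read.sequence[blen:],
                    quality=read.quality[blen:],
                    barcode=prefix,
                )
            )
        else:
            unassigned.append(read)
    return assigned, unassigned


def parse_hmmer_tblout(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER ``--tblout`` per-sequence hit table.

    Columns (whitespace-delimited): target name, target accession, query
    name, query accession, full-sequence E-value, full-sequence score, ...
    Lines starting with ``#`` are comments.
    """
    hits: list[DomainHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >=6 whitespace-delimited fields"
                )
            try:
                evalue = float(fields[4])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric e-value field {fields[4]!r}"
                ) from exc
            try:
                score = float(fields[5])
            except ValueError:
                score = 0.0
            hits.append(
                DomainHit(
                    seq_id=fields[0],
                    profile_id=fields[2],
                    full_seq_evalue=evalue,
                    score=score,
                )
            )
    return hits


# rejection reasons, in priority order (one primary reason per record)
_REASONS = ("no_start_met", "no_terminal_stop", "no_hit", "evalue_above_cutoff")


def filter_candidates(
    records: Iterable[SequenceRecord],
    hits: Iterable[DomainHit],
    evalue_cutoff: float = 0.01,
    domain_mode: str = "require_any",
    required_profiles: tuple[str, str] = ("PF08210", "PF05240"),
    completeness_policy: str = "auto",
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Apply the candidate-protein filters: start Met, completeness, E-value.

    A record is kept iff its sequence starts with methionine, it is judged
    full-length under ``completeness_policy``, and its domain E-values beat
    the cutoff strictly (``< evalue_cutoff``) under ``domain_mode``:

    * ``require_any`` — at least one required profile below the cutoff;
    * ``require_both`` — every required profile present and below the cutoff.

    ``completeness_policy``:

    * ``auto`` — if any record in the batch carries ``terminal_stop_flag``,
      require the flag; otherwise pass everything through with a warning
      (protein FASTA conventionally omits the stop);
    * ``require_flag`` — always require the flag;
    * ``ignore`` — never require it.

    Returns the kept records plus a map of rejected id -> primary reason.
    """
    if domain_mode not in ("require_any", "require_both"):
        raise ConfigError(f"unknown domain_mode {domain_mode!r}")
    if completeness_policy not in ("auto", "require_flag", "ignore"):
        raise ConfigError(f"unknown completeness_policy {completeness_policy!r}")
    records = list(records)

    by_seq: dict[str, dict[str, float]] = {}
    for h in hits:
        best = by_seq.setdefault(h.seq_id, {})
        # keep the best e-value per (sequence, profile)
        if h.profile_id not in best or h.full_seq_evalue < best[h.profile_id]:
            best[h.profile_id] = h.full_seq_evalue

    if completeness_policy == "auto":
        any_flag = any(r.terminal_stop_flag for r in records)
        require_flag = any_flag
        if not any_flag:
            warnings.warn(
                "no record carries a terminal stop flag; completeness check "
                "skipped (completeness_policy='auto')",
                stacklevel=2,
            )
    else:
        require_flag = completeness_policy == "require_flag"

    kept: list[SequenceRecord] = []
    rejected: dict[str, str] = {}
    for rec in records:
        reason = None
        if not rec.sequence.startswith("M"):
            reason = "no_start_met"
        elif require_flag and not rec.terminal_stop_flag:
            reason = "no_terminal_stop"
        elif rec.id not in by_seq:
            reason = "no_hit"
        else:
            evals = by_seq[rec.id]
            present = [evals[p] for p in required_profiles if p in evals]
            if domain_mode == "require_both":
                ok = len(present) == len(required_profiles) and all(
                    e < evalue_cutoff for e in present
                )
            else:
                ok = any(e < evalue_cutoff for e in present)
            if not ok:
                reason = "evalue_above_cutoff"
        if reason is None:
            kept.append(rec)
        else:
            rejected[rec.id] = reason
    return kept, rejected


def read_pair_scores(path: str | Path) -> list[PairScoreRow]:
    """Read a TM pair-score TSV with header id_a, id_b, tm_norm_a, tm_norm_b."""
    rows: list[PairScoreRow] = []
    with _open_text(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["id_a", "id_b", "tm_norm_a", "tm_norm_b"]
        if header[:4] != expected:
            raise FormatError(f"{path}: expected header {expected}, got {header[:4]}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                a, b = float(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                rows.append(PairScoreRow(fields[0], fields[1], a, b))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_pair_scores(rows: Iterable[PairScoreRow], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("id_a\tid_b\ttm_norm_a\ttm_norm_b\n")
        for r in rows:
            fh.write(f"{r.id_a}\t{r.id_b}\t{r.tm_norm_a:.6f}\t{r.tm_norm_b:.6f}\n")
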