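"""Functional consequence calling and R-loop specificity summaries.

A cytosine base editor can silence a gene without a double-strand break by
creating a premature stop codon (CAA/CAG/CGA -> TAA/TAG/TGA on the sense
strand, or TGG -> TAG/TGA/TAA via the antisense C), by destroying a splice
donor GT or acceptor AG dinucleotide, or by perturbing the ATG start.  This
module maps amplicon positions to codons under a small gene model, labels
edited alleles with the consequences they trigger, and computes the
nonsense-mutation introduction efficiency over classified reads.

The orthogonal R-loop assay quantifies sgRNA-independent off-target
deamination at a panel of dead-Cas exposure sites; the on:off specificity
ratio divides the mean on-target efficiency by the mean off-target
efficiency (undefined, never pseudocounted, when the off mean is zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Seq import Seq

from .editquant import EditProfile, revcomp, target_efficiency
from .seqio import ConfigError, FormatError

__all__ = [
    "GeneModel",
    "ConsequenceCall",
    "RLoopPanel",
    "SpecificitySummary",
    "STOP_CODONS",
    "NONSENSE_LABELS",
    "map_codons",
    "call_consequence",
    "nonsense_efficiency",
    "rloop_offtarget_summary",
    "on_off_ratio",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

STOP_GAINED = "stop_gained"
SPLICE_DISRUPTED = "splice_disrupted"
START_LOST = "start_lost"
OTHER_CODING = "other_coding"
SILENT = "silent"
NONE = "none"

NONSENSE_LABELS = frozenset({STOP_GAINED, SPLICE_DISRUPTED, START_LOST})


@dataclass(frozen=True)
class GeneModel:
    """Coding annotation of an amplicon.

    ``cds_segments`` are 0-based half-open amplicon intervals with the frame
    offset of their first base (0 = first base of a codon) ordered along the
    coding strand.  Splice sites are the amplicon indices of the first base
    of the canonical donor GT / acceptor AG dinucleotide on the coding
    strand; ``start_codon`` is the amplicon interval of the ATG, if present.
    """

    coding_strand: str = "+"
    cds_segments: tuple[tuple[int, int, int], ...] = ()
    splice_donor_sites: tuple[int, ...] = ()
    splice_acceptor_sites: tuple[int, ...] = ()
    start_codon: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.coding_strand not in "+-":
            raise ConfigError("coding_strand must be '+' or '-'")
        for lo, hi, frame in self.cds_segments:
            if not (0 <= lo < hi):
                raise ConfigError(f"bad CDS segment ({lo}, {hi})")
            if frame not in (0, 1, 2):
                raise ConfigError(f"bad frame offset {frame}")

    def validate_reference(self, amplicon: str) -> None:
        """Check donor GT / acceptor AG / start ATG against the reference."""
        for site in self.splice_donor_sites:
            if _coding_dinucleotide(amplicon, site, self.coding_strand) != "GT":
                raise ConfigError(f"donor site at {site} is not GT on coding strand")
        for site in self.splice_acceptor_sites:
            if _coding_dinucleotide(amplicon, site, self.coding_strand) != "AG":
                raise ConfigError(f"acceptor site at {site} is not AG on coding strand")
        if self.start_codon is not None:
            lo, hi = self.start_codon
            if _coding_slice(amplicon, lo, hi, self.coding_strand) != "ATG":
                raise ConfigError("start_codon interval is not ATG on coding strand")


def _coding_slice(amplicon: str, lo: int, hi: int, strand: str) -> str:
    seq = amplicon[lo:hi]
    return seq if strand == "+" else revcomp(seq)


def _coding_dinucleotide(amplicon: str, site: int, strand: str) -> str:
    """Two coding-strand bases starting at amplicon index ``site``.

    On the minus strand the dinucleotide runs 5'->3' on the coding strand,
    i.e. amplicon indices (site, site-1) complemented.
    """
    if strand == "+":
        return amplicon[site:site + 2]
    return revcomp(amplicon[site - 1:site + 1])


def map_codons(
    gene_model: GeneModel,
    amplicon: str,
) -> dict[int, tuple[int, int]]:
    """Map each CDS amplicon position to its (codon_index, offset-in-codon).

    Offsets are 0/1/2 along the coding strand; minus-strand models traverse
    the amplicon right to left.  A trailing partial codon is dropped with a
    warning.  Non-CDS positions are absent from the map.
    """
    for lo, hi, _frame in gene_model.cds_segments:
        if hi > len(amplicon):
            raise ConfigError("CDS segment extends past amplicon")
    mapping: dict[int, tuple[int, int]] = {}
    codon_cursor = 0
    carry = 0  # bases already consumed of the current codon
    for seg_i, (lo, hi, frame) in enumerate(gene_model.cds_segments):
        idxs = list(range(lo, hi))
        if gene_model.coding_strand == "-":
            idxs.reverse()
        if seg_i == 0:
            carry = frame
            codon_cursor = 0
        for pos in idxs:
            mapping[pos] = (codon_cursor, carry)
            carry += 1
            if carry == 3:
                carry = 0
                codon_cursor += 1
    if carry != 0:
        trailing = [p for p, (ci, _o) in mapping.items() if ci == codon_cursor]
        for p in trailing:
            del mapping[p]
        warnings.warn(
            f"CDS length not a multiple of 3; ignoring {len(trailing)} trailing "
            "base(s)",
            stacklevel=2,
        )
    return mapping


def _codons_from_mapping(
    seq: str,
    mapping: Mapping[int, tuple[int, int]],
    strand: str,
) -> dict[int, str]:
    """Codon index -> codon string on the coding strand."""
    codons: dict[int, list[str | None]] = {}
    comp = str.maketrans("ACGTN", "TGCAN")
    for pos, (ci, off) in mapping.items():
        base = seq[pos]
        if strand == "-":
            base = base.translate(comp)
        codons.setdefault(ci, [None, None, None])[off] = base
    out: dict[int, str] = {}
    for ci, bases in codons.items():
        if None in bases:
            continue  # codon partially off-amplicon; cannot be evaluated
        out[ci] = "".join(bases)  # type: ignore[arg-type]
    return out


@dataclass(frozen=True)
class ConsequenceCall:
    """Set of consequence labels for one edited allele."""

    labels: frozenset[str]

    @property
    def is_nonsense(self) -> bool:
        return bool(self.labels & NONSENSE_LABELS)


def call_consequence(
    edited_allele: str,
    gene_model: GeneModel,
    amplicon: str,
) -> ConsequenceCall:
    """Label a substitution-only allele with its functional consequences.

    * ``stop_gained`` — a codon that was not a stop in the reference now
      reads TAA/TAG/TGA; reference stops are never re-counted.
    * ``splice_disrupted`` — any base of a donor GT or acceptor AG differs.
    * ``start_lost`` — the annotated ATG is no longer ATG.
    * otherwise ``other_coding`` (amino-acid change), ``silent`` (CDS base
      change, same protein) or ``none`` (no change, or changes confined to
      non-CDS, non-splice positions).
    """
    edited_allele = edited_allele.upper()
    amplicon = amplicon.upper()
    if len(edited_allele) != len(amplicon):
        raise FormatError("edited allele and amplicon lengths differ")
    labels: set[str] = set()
    mapping = map_codons(gene_model, amplicon)
    ref_codons = _codons_from_mapping(amplicon, mapping, gene_model.coding_strand)
    alt_codons = _codons_from_mapping(edited_allele, mapping, gene_model.coding_strand)

    any_cds_change = False
    any_aa_change = False
    for ci, ref_codon in ref_codons.items():
        alt_codon = alt_codons.get(ci)
        if alt_codon is None or alt_codon == ref_codon:
            continue
        if ref_codon in STOP_CODONS:
            continue  # edits inside an existing stop are not consequences
        any_cds_change = True
        if alt_codon in STOP_CODONS:
            labels.add(STOP_GAINED)
        elif str(Seq(ref_codon).translate()) != str(Seq(alt_codon).translate()):
            any_aa_change = True

    for site in gene_model.splice_donor_sites + gene_model.splice_acceptor_sites:
        if gene_model.coding_strand == "+":
            span = (site, site + 2)
        else:
            span = (site - 1, site + 1)
        if edited_allele[span[0]:span[1]] != amplicon[span[0]:span[1]]:
            labels.add(SPLICE_DISRUPTED)

    if gene_model.start_codon is not None:
        lo, hi = gene_model.start_codon
        if _coding_slice(edited_allele, lo, hi, gene_model.coding_strand) != "ATG":
            labels.add(START_LOST)

    if not labels:
        if any_aa_change:
            labels.add(OTHER_CODING)
        elif any_cds_change:
            labels.add(SILENT)
        else:
            labels.add(NONE)
    return ConsequenceCall(labels=frozenset(labels))


def nonsense_efficiency(
    read_alleles: Iterable[str],
    gene_model: GeneModel,
    amplicon: str,
) -> float:
    """Fraction of accepted reads whose call includes a nonsense label.

    ``read_alleles`` are substitution-only alleles (indel reads are handled
    upstream and, by default, excluded from the denominator).
    """
    n = n_nonsense = 0
    for allele in read_alleles:
        n += 1
        if call_consequence(allele, gene_model, amplicon).is_nonsense:
            n_nonsense += 1
    if n == 0:
        raise FormatError("no accepted reads")
    return n_nonsense / n


@dataclass
class RLoopPanel:
    """Per-site off-target efficiencies at the dead-Cas exposure panel."""

    site_efficiencies: dict[str, float | None]
    mean_off: float | None
    n_sites_defined: int
    flagged_undefined_sites: tuple[str, ...] = ()


def rloop_offtarget_summary(
    panel_profiles: Mapping[str, EditProfile],
    efficiency_method: str = "max_position",
) -> RLoopPanel:
    """Scalar off-target efficiency per R-loop site and their mean.

    Uses the same per-site scalar convention as on-target quantification.
    Sites whose profile defines no frequency are flagged and excluded from
    the mean; all sites undefined is an error.
    """
    if not panel_profiles:
        raise FormatError("empty R-loop panel")
    site_eff: dict[str, float | None] = {}
    flagged: list[str] = []
    for site, profile in panel_profiles.items():
        eff = target_efficiency(profile, method=efficiency_method)
        site_eff[site] = eff
        if eff is None:
            flagged.append(site)
    defined = [e for e in site_eff.values() if e is not None]
    if not defined:
        raise FormatError("all R-loop sites undefined")
    return RLoopPanel(
        site_efficiencies=site_eff,
        mean_off=float(np.mean(defined)),
        n_sites_defined=len(defined),
        flagged_undefined_sites=tuple(flagged),
    )


@dataclass(frozen=True)
class SpecificitySummary:
    """On-target vs off-target editing specificity."""

    mean_on: float
    mean_off: float
    ratio: float | None  # None when mean_off == 0 (flagged undefined)

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def on_off_ratio(mean_on: float, rloop_panel: RLoopPanel) -> SpecificitySummary:
    """Specificity ratio mean_on / mean_off; no pseudocount is applied."""
    if mean_on < 0:
        raise ConfigError("mean_on must be non-negative")
    mean_off = rloop_panel.mean_off
    if mean_off is None or mean_off < 0:
        raise ConfigError("mean_off must be defined and non-negative")
    ratio = mean_on / mean_off if mean_off > 0 else None
    return SpecificitySummary(mean_on=mean_on, mean_off=mean_off, ratio=ratio)
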