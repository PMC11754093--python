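"""Shared fixtures and independent reference implementations (oracles).

The oracles deliberately avoid the code paths they check: alignment scores
are enumerated recursively, leader clustering is re-derived by per-iteration
scanning, and consequence calls re-translate the whole CDS.
"""

from __future__ import annotations

import numpy as np
import pytest

from deamscope.editquant import revcomp
from deamscope.phenocall import GeneModel, STOP_CODONS

# --------------------------------------------------------------- oracles


def bruteforce_nw_score(a: str, b: str, match: int = 2, mismatch: int = -1,
                        gap: int = -2) -> int:
    """Optimal global alignment score by exhaustive recursion (no DP reuse)."""

    def rec(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = -(10 ** 9)
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] != "N") else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def naive_leader_partition(ids, lengths, lookup, threshold):
    """Leader clustering re-derived step by step: scan the pool each round
    for the longest remaining protein, collect its above-threshold
    neighbours, remove them, repeat.  Returns a list of (center, members)."""
    pool = set(ids)
    clusters = []
    while pool:
        center = min(pool, key=lambda i: (-lengths[i], i))
        members = [center]
        for other in sorted(pool, key=lambda i: (-lengths[i], i)):
            if other != center and lookup(center, other) > threshold:
                members.append(other)
        pool.difference_update(members)
        clusters.append((center, tuple(members)))
    return clusters


_CODON_LEN = 3


def oracle_consequence_labels(edited: str, model: GeneModel,
                              amplicon: str) -> set[str]:
    """Re-derive nonsense labels by whole-CDS re-translation.

    Independent of the per-position codon mapping: the coding sequence is
    rebuilt from scratch for reference and edited alleles, leading/trailing
    partial codons dropped, and stop content compared positionally.
    """
    from Bio.Seq import Seq

    def coding_seq(seq: str) -> str:
        parts = []
        for lo, hi, _frame in model.cds_segments:
            parts.append(seq[lo:hi])
        joined = "".join(parts)
        if model.coding_strand == "-":
            # coding order traverses the amplicon right-to-left; segments are
            # given in coding order, each segment's bases reversed+complemented
            joined = "".join(revcomp(seq[lo:hi]) for lo, hi, _f in model.cds_segments)
        return joined

    frame = model.cds_segments[0][2] if model.cds_segments else 0
    lead = (3 - frame) % 3 if frame else 0

    def codons(seq: str) -> list[str]:
        cs = coding_seq(seq)[lead:] if frame else coding_seq(seq)
        return [cs[i:i + 3] for i in range(0, len(cs) - len(cs) % 3, 3)]

    labels: set[str] = set()
    for ref_codon, alt_codon in zip(codons(amplicon), codons(edited)):
        if ref_codon not in STOP_CODONS and alt_codon in STOP_CODONS:
            labels.add("stop_gained")

    for site in model.splice_donor_sites + model.splice_acceptor_sites:
        if model.coding_strand == "+":
            lo, hi = site, site + 2
        else:
            lo, hi = site - 1, site + 1
        if edited[lo:hi] != amplicon[lo:hi]:
            labels.add("splice_disrupted")

    if model.start_codon is not None:
        lo, hi = model.start_codon
        region = edited[lo:hi]
        if model.coding_strand == "-":
            region = revcomp(region)
        if region != "ATG":
            labels.add("start_lost")
    return labels


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# -------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
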