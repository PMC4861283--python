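"""Promoter scanning for the AW-box, the WRI1-binding cis-element.

The AW-box is the 14-bp degenerate consensus ``CNTNG(N)7CG``: five fixed
positions (C, T, G, C, G) and nine fully degenerate ones.  On uniform
random sequence a position matches with probability 4^-5 per strand.

Scanning is exact and position-based: all (possibly overlapping) matches
are reported with 0-based offsets.  The default policy scans the forward
(promoter) strand only, since the element is orientation-specific in the
WRI1 literature; a both-strand mode reports reverse-complement matches
with the offset of the match's leftmost base on the forward sequence.
Any IUPAC degenerate consensus can be substituted for the default
pattern.  ``N`` in the *sequence* is treated as an unknown base: it never
satisfies a fixed pattern position but does satisfy pattern ``N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["MotifHit", "AW_BOX", "scan_awbox", "count_awbox_per_gene",
           "iupac_regex"]

AW_BOX = "CNTNGNNNNNNNCG"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_VALID_SEQ = set("ACGTN")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int        # 0-based offset on the forward sequence
    strand: str       # "+" or "-"
    site: str         # the matched 14-mer, forward-strand orientation


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC consensus into an overlapping-match regex.

    Fixed positions match only their base (never N in the sequence);
    pattern ``N`` matches any base including N.
    """
    parts = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern")
        parts.append(f"[{_IUPAC[ch]}]")
    return re.compile(f"(?=({''.join(parts)}))")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def scan_awbox(
    sequence: str,
    seq_id: str = "",
    both_strands: bool = False,
    pattern: str = AW_BOX,
) -> list[MotifHit]:
    """All matches of the consensus in one sequence, sorted by start."""
    seq = sequence.upper()
    bad = sorted(set(seq) - _VALID_SEQ)
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    rx = iupac_regex(pattern)
    hits = [
        MotifHit(seq_id=seq_id, start=m.start(), strand="+", site=m.group(1))
        for m in rx.finditer(seq)
    ]
    if both_strands:
        L, w = len(seq), len(pattern)
        for m in rx.finditer(_revcomp(seq)):
            start = L - m.start() - w
            # site is reported as read on the minus strand, so it
            # satisfies the consensus literally
            hits.append(MotifHit(seq_id=seq_id, start=start, strand="-",
                                 site=m.group(1)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def count_awbox_per_gene(
    fasta,
    both_strands: bool = False,
    pattern: str = AW_BOX,
) -> tuple[dict, list[MotifHit]]:
    """Per-gene AW-box counts over a promoter FASTA.

    ``fasta`` is a path/handle readable by Bio.SeqIO, or an iterable of
    (gene_id, sequence) pairs.  Headers must be unique gene ids; genes
    with zero hits are included with count 0.
    """
    if hasattr(fasta, "read") or isinstance(fasta, (str, bytes)) or \
            hasattr(fasta, "__fspath__"):
        records = ((r.id, str(r.seq)) for r in SeqIO.parse(fasta, "fasta"))
    else:
        records = iter(fasta)
    counts: dict = {}
    all_hits: list[MotifHit] = []
    for gene, seq in records:
        if gene in counts:
            raise ValueError(f"duplicate promoter header {gene!r}")
        hits = scan_awbox(seq, seq_id=gene, both_strands=both_strands,
                          pattern=pattern)
        counts[gene] = len(hits)
        all_hits.extend(hits)
    return counts, all_hits
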