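"""Off-target screening by exhaustive ungapped near-match search.

A candidate 19-nt core is screened against a transcriptome for ungapped
placements with up to ``max_mismatches`` substitutions on either strand.
Matching is seeded with a k-mer index and verified by Hamming distance; the
pigeonhole principle guarantees completeness: any placement with at most m
mismatches contains an exact k-mer for k = floor(core_len / (m + 1)), so the
index is transparently rebuilt at that word size whenever the configured k is
too large for the requested mismatch budget. The scan is therefore exact (no
heuristic misses), unlike a local-alignment heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seq_io import Transcript, reverse_complement

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True, order=True)
class OfftargetHit:
    """One ungapped near-match of a query core on a subject transcript.

    ``subject_start`` is 0-based on the subject's given (forward) strand;
    for antisense hits it is the start of the window whose reverse complement
    matches the core."""

    mismatches: int
    subject_id: str
    subject_start: int
    strand: str  # SENSE or ANTISENSE (of the subject)
    query_id: str = ""
    query_start: int = -1


class KmerIndex:
    """Deterministic k-mer -> positions index over both strands of a
    transcriptome."""

    def __init__(self, transcriptome: Sequence[Transcript], k: int = 11):
        if not transcriptome:
            raise ValueError("empty transcriptome")
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.transcripts = list(transcriptome)
        # per subject, keep both strand sequences for seed verification
        self._strands: dict[str, dict[str, str]] = {
            t.id: {SENSE: t.seq, ANTISENSE: reverse_complement(t.seq)}
            for t in self.transcripts
        }
        self._index: dict[str, list[tuple[str, str, int]]] = {}
        for t in self.transcripts:
            for strand, seq in self._strands[t.id].items():
                for pos in range(len(seq) - k + 1):
                    self._index.setdefault(seq[pos : pos + k], []).append((t.id, strand, pos))

    def lookup(self, kmer: str) -> list[tuple[str, str, int]]:
        return self._index.get(kmer, [])

    def strand_seq(self, subject_id: str, strand: str) -> str:
        return self._strands[subject_id][strand]

    def keys(self) -> Iterable[str]:
        return self._index.keys()


def build_index(transcriptome: Sequence[Transcript], k: int = 11) -> KmerIndex:
    """Build the two-strand k-mer index used by scan_offtargets."""
    return KmerIndex(transcriptome, k=k)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def scan_offtargets(
    core: str,
    index: KmerIndex,
    max_mismatches: int = 2,
    exclude_id: str | None = None,
) -> list[OfftargetHit]:
    """Every ungapped placement of ``core`` (either strand) on any subject
    other than ``exclude_id`` with at most ``max_mismatches`` mismatches.

    Hits are sorted by (mismatches, subject_id, subject_start). Complete by
    pigeonhole word-size selection (the index is rebuilt at a smaller k
    internally when needed)."""
    n = len(core)
    if n != 19:
        raise ValueError(f"core must be 19 nt, got {n}")
    safe_k = n // (max_mismatches + 1)
    if index.k > safe_k:
        index = KmerIndex(index.transcripts, k=safe_k)
    k = index.k
    seen: set[tuple[str, str, int]] = set()
    hits: list[OfftargetHit] = []
    for off in range(n - k + 1):
        for subject_id, strand, pos in index.lookup(core[off : off + k]):
            if subject_id == exclude_id:
                continue
            start = pos - off
            seq = index.strand_seq(subject_id, strand)
            if start < 0 or start + n > len(seq):
                continue
            key = (subject_id, strand, start)
            if key in seen:
                continue
            seen.add(key)
            mm = hamming(core, seq[start : start + n])
            if mm <= max_mismatches:
                fwd_start = start if strand == SENSE else len(seq) - start - n
                hits.append(
                    OfftargetHit(
                        mismatches=mm,
                        subject_id=subject_id,
                        subject_start=fwd_start,
                        strand=strand,
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.subject_id, h.subject_start, h.strand))
    return hits


def is_specific(
    core: str,
    index: KmerIndex,
    max_mismatches: int = 2,
    exclude_id: str | None = None,
) -> bool:
    """A core is flagged non-specific when any off-target placement with at
    most ``max_mismatches`` mismatches exists outside the intended target."""
    return not scan_offtargets(core, index, max_mismatches, exclude_id)
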