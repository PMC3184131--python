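"""Sequence records and elementary RNA arithmetic.

Transcripts are handled internally as uppercase RNA strings over {A, C, G, U}
with 0-based half-open coordinates; every downstream module (candidate
enumeration, off-target scanning, the synthetic generators) builds on the
primitives here. IUPAC ambiguity codes are rejected outright rather than
skipped: the design criteria are defined on unambiguous bases, so a masked
window cannot be evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger("sirnakit")

RNA_ALPHABET = frozenset("ACGU")
_DNA_TO_RNA = str.maketrans("ACGTU", "ACGUU")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the accepted DNA/RNA alphabet."""


@dataclass(frozen=True)
class Transcript:
    """One mRNA record: identifier, RNA sequence, and the 0-based index of the
    A of the initiation codon AUG."""

    id: str
    seq: str
    cds_start: int

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"transcript {self.id!r}: invalid character(s) {sorted(bad)}"
            )
        if not (0 <= self.cds_start <= len(self.seq) - 3):
            raise ValueError(
                f"transcript {self.id!r}: cds_start {self.cds_start} out of range"
            )
        if self.seq[self.cds_start : self.cds_start + 3] != "AUG":
            raise ValueError(
                f"transcript {self.id!r}: no AUG at cds_start {self.cds_start}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def to_rna(s: str) -> str:
    """Normalize a DNA-or-RNA string to uppercase RNA (T -> U). Idempotent."""
    up = s.upper()
    bad = set(up) - set("ACGTU")
    if bad:
        raise SequenceAlphabetError(f"invalid character(s) {sorted(bad)}")
    return up.translate(_DNA_TO_RNA)


def reverse_complement(s: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C). Involution."""
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise SequenceAlphabetError(f"invalid character(s) {sorted(bad)}")
    return s.translate(_RNA_COMPLEMENT)[::-1]


def gc_content(s: str) -> float:
    """G+C percentage of a non-empty RNA string, unrounded, in [0, 100]."""
    if not s:
        raise ValueError("gc_content of empty string is undefined")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def read_cds_map(path: str | Path) -> dict[str, int]:
    """Read a two-column delimited file ``id<TAB>1-based AUG position`` and
    return a mapping of id -> 0-based AUG index."""
    out: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
        ident, pos = fields
        pos1 = int(pos)
        if pos1 < 1:
            raise ValueError(f"{path}:{lineno}: AUG position must be >= 1 (1-based)")
        out[ident] = pos1 - 1
    return out


def read_fasta(
    path: str | Path,
    cds_start_map: Mapping[str, int] | None = None,
) -> list[Transcript]:
    """Read a FASTA file into Transcript records, in file order.

    Sequences are normalized to uppercase RNA. The AUG index for each record
    is taken from ``cds_start_map`` when present, otherwise it defaults to the
    first AUG occurrence; records with no AUG and no map entry are logged and
    skipped. Ambiguity codes raise ``SequenceAlphabetError``.
    """
    cds_start_map = cds_start_map or {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[Transcript] = []
    for rec in records:
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"{path}: record {rec.id!r} is empty")
        try:
            seq = to_rna(raw)
        except SequenceAlphabetError as exc:
            raise SequenceAlphabetError(f"record {rec.id!r}: {exc}") from None
        if rec.id in cds_start_map:
            cds_start = cds_start_map[rec.id]
        else:
            cds_start = seq.find("AUG")
            if cds_start == -1:
                logger.warning("record %r has no AUG and no CDS map entry; skipped", rec.id)
                continue
        out.append(Transcript(id=rec.id, seq=seq, cds_start=cds_start))
    return out


def write_fasta(transcripts: Sequence[Transcript], path: str | Path, width: int = 60) -> None:
    """Write transcripts as wrapped FASTA (round-trips through read_fasta)."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                fh.write(t.seq[i : i + width] + "\n")
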