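"""Seeded synthetic data: transcripts with planted guideline-perfect sites,
decoy transcriptomes with planted near-matches, and simulated dose-response
measurements.

Everything here is deterministic given a seed, so the design engine, the
off-target scanner and the decay fit are testable without any sequence
download. Background bases are drawn i.i.d. at a target GC fraction — no
codon structure or UTR composition is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dose_response import DosePoint
from .seq_io import Transcript, reverse_complement, write_fasta

#: A core satisfying every hard filter: GC 7/19 (36.8%), starts G, ends A
#: (antisense 5' is U), 6 A/U among the last 7 bases.
IDEAL_CORE = "GCAUGGCAUAUGCAUAUUA"
#: Flanks giving pooled GC exactly 50% (12 of 24), upstream ending AA (the
#: antisense UU overhang base-pairs) and downstream starting UU (best sense
#: overhang class).
IDEAL_FLANK_UP = "GCGCGCGCGCAA"
IDEAL_FLANK_DOWN = "UUAUAUAUAUGC"

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic transcript."""

    length: int
    gc: float = 0.5  # background GC fraction
    seed: int = 0
    planted_sites: tuple[tuple[int, str], ...] = field(default_factory=tuple)
    cds_start: int = 0  # an AUG is forced here

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc fraction must lie in [0, 1]")
        if self.length < self.cds_start + 3:
            raise ValueError("transcript too short for the forced AUG")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return rng.choice(_BASES, size=n, p=p)


def generate_transcript(spec: SynthSpec, id: str = "synth") -> Transcript:
    """Background bases at the target GC fraction, an AUG forced at
    cds_start, and planted regions written verbatim over the background.

    A planted site is ``(core_start_offset, template)`` where template is
    either a 19-nt core (planted bare, flanks left random) or ``"ideal"``
    (the guideline-perfect core plus designed flanks and overhang context).
    Overlapping planted regions, out-of-bounds offsets, and plants that would
    overwrite the initiation codon are errors."""
    rng = np.random.default_rng(spec.seed)
    seq = _random_bases(rng, spec.length, spec.gc)
    seq[spec.cds_start : spec.cds_start + 3] = list("AUG")
    occupied: list[tuple[int, int]] = []
    for offset, template in spec.planted_sites:
        if template == "ideal":
            block = IDEAL_FLANK_UP + IDEAL_CORE + IDEAL_FLANK_DOWN
            lo = offset - len(IDEAL_FLANK_UP)
        else:
            block = template
            lo = offset
        hi = lo + len(block)
        if lo < 0 or hi > spec.length:
            raise ValueError(f"planted site at offset {offset} out of bounds")
        if hi > spec.cds_start and lo < spec.cds_start + 3:
            raise ValueError(f"planted site at offset {offset} overlaps the AUG")
        for plo, phi in occupied:
            if lo < phi and plo < hi:
                raise ValueError(f"planted site at offset {offset} overlaps another plant")
        occupied.append((lo, hi))
        seq[lo:hi] = list(block)
    return Transcript(id=id, seq="".join(seq), cds_start=spec.cds_start)


def mutate_core(core: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute n_mut distinct positions of core with different bases."""
    if n_mut > len(core):
        raise ValueError("more mutations than positions")
    out = list(core)
    for pos in rng.choice(len(core), size=n_mut, replace=False):
        out[pos] = rng.choice([b for b in "ACGU" if b != out[pos]])
    return "".join(out)


def generate_offtarget_transcriptome(
    query_core: str,
    plants: Sequence[tuple[int, int, int, str]],
    n_subjects: int = 10,
    length: int = 1000,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[list[Transcript], list[tuple[str, int, int, str]]]:
    """Decoy transcriptome with planted near-matches of a query core.

    Each plant is ``(subject_index, position, n_mismatches, strand)``; for
    antisense plants the reverse complement of the mutated copy is written,
    and the returned position is always on the subject's forward strand.
    Returns (transcripts, truth) with truth entries
    ``(subject_id, position, n_mismatches, strand)``."""
    rng = np.random.default_rng(seed)
    seqs = [_random_bases(rng, length, gc) for _ in range(n_subjects)]
    for s in seqs:
        s[0:3] = list("AUG")
    truth: list[tuple[str, int, int, str]] = []
    for subject_idx, pos, n_mut, strand in plants:
        if not (3 <= pos and pos + len(query_core) <= length):
            raise ValueError(f"plant position {pos} out of bounds")
        copy = mutate_core(query_core, n_mut, rng)
        if strand == "antisense":
            copy = reverse_complement(copy)
        seqs[subject_idx][pos : pos + len(copy)] = list(copy)
        truth.append((f"decoy{subject_idx}", pos, n_mut, strand))
    transcripts = [
        Transcript(id=f"decoy{i}", seq="".join(s), cds_start=0) for i, s in enumerate(seqs)
    ]
    return transcripts, truth


def generate_dose_data(
    a: float,
    b: float,
    doses: Sequence[float],
    replicates: int = 1,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[DosePoint]:
    """Simulated knockdown measurements rel = a*exp(-b*x)*exp(eps),
    eps ~ Normal(0, sigma^2). Multiplicative lognormal noise keeps the ratio
    positive and matches the log-linear fitting model; sigma = 0 gives exact
    model values."""
    if a <= 0:
        raise ValueError("amplitude a must be > 0")
    if b < 0:
        raise ValueError("decay rate b must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[DosePoint] = []
    for x in doses:
        for _ in range(replicates):
            eps = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
            out.append(DosePoint(conc=float(x), rel_mrna=float(a * np.exp(-b * x) * np.exp(eps))))
    return out


def write_fixture_bundle(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a canonical synthetic test bundle: two design targets with one
    ideal planted site each, an off-target decoy transcriptome, and a noisy
    dose-response table. Returns the paths keyed by role."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    genes = [
        generate_transcript(
            SynthSpec(length=600, gc=0.5, seed=seed + i, planted_sites=((200 + 40 * i, "ideal"),)),
            id=f"gene{i}",
        )
        for i in range(2)
    ]
    genes_path = directory / "genes.fasta"
    write_fasta(genes, genes_path)

    decoys, _ = generate_offtarget_transcriptome(
        IDEAL_CORE, plants=[(0, 100, 0, "sense"), (1, 250, 1, "sense")], seed=seed + 100
    )
    tx_path = directory / "transcriptome.fasta"
    write_fasta(genes + decoys, tx_path)

    points = generate_dose_data(
        a=0.9, b=0.028, doses=[0, 25, 50, 100], replicates=4, noise_sigma=0.1, seed=seed + 200
    )
    dose_path = directory / "dose.csv"
    with open(dose_path, "w") as fh:
        fh.write("conc_uM,rel_mrna\n")
        for p in points:
            fh.write(f"{p.conc:g},{p.rel_mrna:.6f}\n")
    return {"genes": genes_path, "transcriptome": tx_path, "dose": dose_path}
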