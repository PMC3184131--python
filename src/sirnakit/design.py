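"""Guideline-based siRNA candidate design.

The design engine slides a 19-nt window over an mRNA, evaluates each window
against an eight-criterion guideline, builds the corresponding 21-nt duplex
(19-bp paired core + 2-nt 3' overhangs), and runs a staged
filter-then-rank selection that returns two siRNAs per gene by default.

Criteria are named semantically:

=============  =================================================================
GC_CORE        GC content of the 19-nt core within [35%, 55%]
SENSE_5P       first base of the sense strand (core[0]) is G or C
ANTISENSE_5P   first base of the antisense strand (complement of core[-1]) is A/U
POSITION       core starts >= 75 nt downstream of the end of the AUG codon
FLANK_GC       pooled GC of the two 12-nt mRNA flanks, preferred 50%
AU_SEED7       more than three A/U bases among the 7 nt at the antisense 5' end
               (equivalently, the last 7 bases of the core)
OVERHANG_AS    antisense 3' overhang is UU and still base-pairs with the target
               (i.e. the mRNA bases just upstream of the core are AA)
OVERHANG_S     sense 3' overhang, taken verbatim from the mRNA, matches one of
               the accepted patterns UU / U. / .U / AA
=============  =================================================================

Selection is staged: GC_CORE, SENSE_5P, ANTISENSE_5P and AU_SEED7 are hard
filters; POSITION is applied next; survivors are then ranked by closeness of
the flank GC to 50%, then by overhang quality, with the transcript position as
the final tie-break. FLANK_GC is rank-only by default because the guideline
marks specific flank-GC values as bad without stating a numeric band; an
optional hard cutoff (``flank_gc_max_dev``) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .seq_io import Transcript, gc_content, reverse_complement

logger = logging.getLogger("sirnakit")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SenseOverhang(Enum):
    """Accepted sense-strand 3' overhang patterns, best first."""

    UU = "UU"
    AA = "AA"
    U_FIRST = "U_FIRST"  # U then any base
    U_SECOND = "U_SECOND"  # any base then U
    FAIL = "FAIL"


class AntisenseOverhang(Enum):
    UU = "UU"  # the fixed UU overhang base-pairs with the target (mRNA has AA upstream)
    OTHER = "OTHER"


#: Rank penalties; smaller is better. U_FIRST and U_SECOND tie.
SENSE_OVERHANG_PENALTY = {
    SenseOverhang.UU: 0,
    SenseOverhang.AA: 1,
    SenseOverhang.U_FIRST: 2,
    SenseOverhang.U_SECOND: 2,
    SenseOverhang.FAIL: 3,
}
ANTISENSE_OVERHANG_PENALTY = {AntisenseOverhang.UU: 0, AntisenseOverhang.OTHER: 1}


@dataclass(frozen=True)
class DesignParams:
    """Tunable thresholds of the design guideline (defaults are the
    guideline's published values)."""

    core_len: int = 19
    strand_len: int = 21
    gc_min: float = 35.0
    gc_max: float = 55.0
    min_downstream: int = 75
    flank_len: int = 12
    flank_gc_target: float = 50.0
    flank_gc_max_dev: float | None = None  # None = rank-only flank criterion
    au_min_in_seed7: int = 4  # "more than three" A/U bases
    n_select: int = 2
    require_nonoverlap: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min <= self.gc_max <= 100):
            raise ValueError("require 0 <= gc_min <= gc_max <= 100")
        if self.core_len + 2 != self.strand_len:
            raise ValueError("strand_len must equal core_len + 2")
        if self.au_min_in_seed7 > 7:
            raise ValueError("au_min_in_seed7 cannot exceed 7")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")


@dataclass(frozen=True)
class CandidateSite:
    """A 19-nt target core on the mRNA with its two 12-nt flanks."""

    transcript_id: str
    start: int  # 0-based index of the core on the mRNA
    core: str  # sense orientation
    flank_up: str  # 12 nt immediately 5' of the core
    flank_down: str  # 12 nt immediately 3' of the core

    @property
    def upstream2(self) -> str:
        """The 2 mRNA bases immediately 5' of the core."""
        return self.flank_up[-2:]

    @property
    def downstream2(self) -> str:
        """The 2 mRNA bases immediately 3' of the core."""
        return self.flank_down[:2]

    @property
    def end(self) -> int:
        return self.start + len(self.core)


@dataclass(frozen=True)
class CriterionReport:
    gc_core: float
    pass_gc: bool
    sense5: str
    pass_sense5: bool
    antisense5: str
    pass_antisense5: bool
    downstream_offset: int
    pass_position: bool
    flank_gc: float
    flank_gc_dev: float
    au_in_seed7: int
    pass_au: bool
    s_overhang_class: SenseOverhang
    as_overhang_class: AntisenseOverhang


@dataclass(frozen=True)
class SiRNADuplex:
    """A 21-nt/21-nt duplex: 19-bp paired core plus 2-nt 3' overhangs.

    The antisense overhang is always synthesized as UU; the sense overhang is
    the verbatim next two mRNA bases (residues correspond to the target, no
    silent substitutions)."""

    sense21: str
    antisense21: str
    s_overhang: str
    as_overhang: str
    s_overhang_class: SenseOverhang
    as_overhang_class: AntisenseOverhang

    @property
    def core(self) -> str:
        return self.sense21[:19]


@dataclass
class RankedCandidate:
    site: CandidateSite
    report: CriterionReport
    duplex: SiRNADuplex
    rank_key: tuple[float, int, int, int]
    rank: int = 0
    selected: bool = False
    offtarget_hits: int | None = field(default=None)


# ---------------------------------------------------------------------------
# Criterion predicates (pure functions; evaluate_site composes them)
# ---------------------------------------------------------------------------

def passes_gc_band(s: str, gc_min: float = 35.0, gc_max: float = 55.0) -> bool:
    """Inclusive GC-band predicate: gc_min <= GC% <= gc_max."""
    return gc_min <= gc_content(s) <= gc_max


def au_count_seed7(core: str) -> int:
    """A/U count among the 7 bases at the 5' end of the antisense strand.

    Because the antisense strand is the reverse complement of the core, this
    equals the A/U count of the last 7 core bases."""
    return sum(1 for b in core[-7:] if b in "AU")


def evaluate_site(c: CandidateSite, t: Transcript, p: DesignParams) -> CriterionReport:
    """Evaluate all guideline criteria for a candidate site on its transcript."""
    gc_core = gc_content(c.core)
    sense5 = c.core[0]
    antisense5 = _COMPLEMENT[c.core[-1]]
    downstream_offset = c.start - (t.cds_start + 3)
    flank_gc = gc_content(c.flank_up + c.flank_down)
    au7 = au_count_seed7(c.core)
    dup = construct_duplex(c)
    return CriterionReport(
        gc_core=gc_core,
        pass_gc=p.gc_min <= gc_core <= p.gc_max,
        sense5=sense5,
        pass_sense5=sense5 in "GC",
        antisense5=antisense5,
        pass_antisense5=antisense5 in "AU",
        downstream_offset=downstream_offset,
        pass_position=downstream_offset >= p.min_downstream,
        flank_gc=flank_gc,
        flank_gc_dev=abs(flank_gc - p.flank_gc_target),
        au_in_seed7=au7,
        pass_au=au7 >= p.au_min_in_seed7,
        s_overhang_class=dup.s_overhang_class,
        as_overhang_class=dup.as_overhang_class,
    )


def construct_duplex(c: CandidateSite) -> SiRNADuplex:
    """Build the 21-nt strands for a candidate site.

    sense21 = core + the next two mRNA bases, verbatim.
    antisense21 = revcomp(core) + UU (the overhang is always synthesized UU;
    it is classed UU only when the mRNA bases upstream of the core are AA, so
    the overhang still base-pairs with the target)."""
    sense21 = c.core + c.downstream2
    antisense21 = reverse_complement(c.core) + "UU"
    d2 = c.downstream2
    if d2 == "UU":
        s_class = SenseOverhang.UU
    elif d2 == "AA":
        s_class = SenseOverhang.AA
    elif d2[0] == "U":
        s_class = SenseOverhang.U_FIRST
    elif d2[1] == "U":
        s_class = SenseOverhang.U_SECOND
    else:
        s_class = SenseOverhang.FAIL
    as_class = AntisenseOverhang.UU if c.upstream2 == "AA" else AntisenseOverhang.OTHER
    return SiRNADuplex(
        sense21=sense21,
        antisense21=antisense21,
        s_overhang=d2,
        as_overhang="UU",
        s_overhang_class=s_class,
        as_overhang_class=as_class,
    )


# ---------------------------------------------------------------------------
# Enumeration, scoring, staged selection
# ---------------------------------------------------------------------------

def enumerate_sites(t: Transcript, p: DesignParams = DesignParams()) -> list[CandidateSite]:
    """All core placements with full 12-nt flanks, in ascending start order."""
    f, k = p.flank_len, p.core_len
    if len(t.seq) < 2 * f + k:
        logger.info("transcript %r shorter than minimum window (%d nt); no sites", t.id, 2 * f + k)
        return []
    out = []
    for s in range(f, len(t.seq) - k - f + 1):
        out.append(
            CandidateSite(
                transcript_id=t.id,
                start=s,
                core=t.seq[s : s + k],
                flank_up=t.seq[s - f : s],
                flank_down=t.seq[s + k : s + k + f],
            )
        )
    return out


def score_candidate(r: CriterionReport, start: int) -> tuple[float, int, int, int]:
    """Total rank order: flank-GC deviation, sense overhang, antisense
    overhang, then transcript position. Smaller tuples rank better."""
    return (
        r.flank_gc_dev,
        SENSE_OVERHANG_PENALTY[r.s_overhang_class],
        ANTISENSE_OVERHANG_PENALTY[r.as_overhang_class],
        start,
    )


def design_sirnas(t: Transcript, p: DesignParams = DesignParams()) -> list[RankedCandidate]:
    """Staged filter-then-rank selection of siRNAs for one transcript.

    1. enumerate all candidate sites;
    2. hard-filter on GC_CORE, SENSE_5P, ANTISENSE_5P, AU_SEED7;
    3. filter on POSITION;
    4. optionally hard-filter on flank-GC deviation;
    5. rank survivors (flank GC closest to 50%, then overhang quality, then
       position) and mark the best ``n_select`` as selected, skipping
       candidates whose core overlaps an already-selected one by default.

    Returns ALL survivors, ranked, with selection flags. Fewer than
    ``n_select`` survivors is reported via the log, not an error.
    """
    survivors: list[RankedCandidate] = []
    for site in enumerate_sites(t, p):
        rep = evaluate_site(site, t, p)
        if not (rep.pass_gc and rep.pass_sense5 and rep.pass_antisense5 and rep.pass_au):
            continue
        if not rep.pass_position:
            continue
        if p.flank_gc_max_dev is not None and rep.flank_gc_dev > p.flank_gc_max_dev:
            continue
        survivors.append(
            RankedCandidate(
                site=site,
                report=rep,
                duplex=construct_duplex(site),
                rank_key=score_candidate(rep, site.start),
            )
        )
    survivors.sort(key=lambda c: c.rank_key)
    chosen: list[RankedCandidate] = []
    for i, cand in enumerate(survivors, start=1):
        cand.rank = i
        if len(chosen) >= p.n_select:
            continue
        if p.require_nonoverlap and any(
            cand.site.start < c.site.end and c.site.start < cand.site.end for c in chosen
        ):
            continue
        cand.selected = True
        chosen.append(cand)
    if len(chosen) < p.n_select:
        logger.warning(
            "transcript %r: only %d of %d requested siRNAs could be selected",
            t.id, len(chosen), p.n_select,
        )
    return survivors


def design_all(transcripts: Sequence[Transcript], p: DesignParams = DesignParams()) -> dict[str, list[RankedCandidate]]:
    """Run design_sirnas over many transcripts, keyed by transcript id."""
    return {t.id: design_sirnas(t, p) for t in transcripts}
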