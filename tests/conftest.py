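from __future__ import annotations

import pytest

from sirnakit import CandidateSite, Transcript


def make_site_transcript(
    core: str,
    flank_up: str = "GCGCGCGCGCAA",
    flank_down: str = "UUAUAUAUAUGC",
    downstream_offset: int = 100,
) -> tuple[CandidateSite, Transcript]:
    """Embed core (with given flanks) in a minimal transcript such that the
    core starts at the requested offset past the end of the AUG codon."""
    start = 3 + downstream_offset
    pad = start - len(flank_up) - 3
    assert pad >= 0, "offset too small for a 12-nt upstream flank"
    seq = "AUG" + "A" * pad + flank_up + core + flank_down + "AAA"
    t = Transcript(id="t", seq=seq, cds_start=0)
    site = CandidateSite(
        transcript_id="t", start=start, core=core,
        flank_up=flank_up, flank_down=flank_down,
    )
    assert t.seq[start : start + len(core)] == core
    return site, t


@pytest.fixture
def site_factory():
    return make_site_transcript
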