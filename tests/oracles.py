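"""Independent brute-force oracles, written deliberately apart from the
package's staged/seeded code paths so that agreement is meaningful."""

from __future__ import annotations

import numpy as np

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rc(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def brute_force_design(seq: str, cds_start: int, *, gc_min=35.0, gc_max=55.0,
                       min_downstream=75, flank=12, core_len=19, au_min=4,
                       flank_gc_target=50.0, flank_gc_max_dev=None,
                       n_select=2, nonoverlap=True):
    """Enumerate every window, apply each guideline predicate independently,
    sort by the ranking tuple, select greedily. Returns a list of
    (start, rank_key, selected) triples in rank order."""
    survivors = []
    for s in range(len(seq)):
        if s < flank or s + core_len + flank > len(seq):
            continue
        core = seq[s:s + core_len]
        gc = 100.0 * sum(b in "GC" for b in core) / core_len
        if not (gc_min <= gc <= gc_max):
            continue
        if core[0] not in "GC":
            continue
        if COMP[core[core_len - 1]] not in "AU":  # antisense 5' base
            continue
        if sum(b in "AU" for b in core[core_len - 7:]) < au_min:
            continue
        if s - (cds_start + 3) < min_downstream:
            continue
        flanks = seq[s - flank:s] + seq[s + core_len:s + core_len + flank]
        fgc = 100.0 * sum(b in "GC" for b in flanks) / len(flanks)
        fdev = abs(fgc - flank_gc_target)
        if flank_gc_max_dev is not None and fdev > flank_gc_max_dev:
            continue
        d2 = seq[s + core_len:s + core_len + 2]
        if d2 == "UU":
            spen = 0
        elif d2 == "AA":
            spen = 1
        elif "U" in d2:
            spen = 2
        else:
            spen = 3
        apen = 0 if seq[s - 2:s] == "AA" else 1
        survivors.append((s, (fdev, spen, apen, s)))
    survivors.sort(key=lambda t: t[1])
    out, picked = [], []
    for s, key in survivors:
        sel = False
        if len(picked) < n_select:
            if not nonoverlap or all(s + core_len <= q or q + core_len <= s for q in picked):
                sel = True
                picked.append(s)
        out.append((s, key, sel))
    return out


def brute_force_scan(core: str, transcripts, max_mm: int, exclude_id=None):
    """All-window Hamming scan on both strands; returns a sorted list of
    (mismatches, subject_id, forward_start, strand)."""
    n = len(core)
    hits = []
    for t in transcripts:
        if t.id == exclude_id:
            continue
        for s in range(len(t.seq) - n + 1):
            win = t.seq[s:s + n]
            mm = sum(a != b for a, b in zip(core, win))
            if mm <= max_mm:
                hits.append((mm, t.id, s, "sense"))
            mm_as = sum(a != b for a, b in zip(core, rc(win)))
            if mm_as <= max_mm:
                hits.append((mm_as, t.id, s, "antisense"))
    hits.sort()
    return hits


def loglinear_fit(concs, rels):
    """Independent closed-form log-linear fit via polyfit: returns (a, b)."""
    slope, intercept = np.polyfit(np.asarray(concs, float), np.log(rels), 1)
    return float(np.exp(intercept)), float(-slope)
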