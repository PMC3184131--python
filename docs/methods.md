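# Methods

## Design model

An siRNA duplex is represented by its 19-nt target core on the mRNA (sense
orientation) plus the two 12-nt mRNA flanks. The antisense (guide) strand is
the reverse complement of the core with a fixed 2-nt UU 3′ overhang; the
sense strand is the core plus the next two mRNA bases taken verbatim — the
duplex always corresponds residue-for-residue to the target, and a poor
overhang pattern demotes a candidate's rank but never triggers a silent
sequence substitution, so every reported strand can be checked against the
input mRNA by eye.

Criteria are split into *hard filters* (core GC within [35, 55]%; sense 5′
base G/C; antisense 5′ base A/U; more than three A/U bases among the seven
at the antisense 5′ end), a *position filter* (core start at least 75 nt
downstream of the end of the initiation codon, keeping the duplex clear of
the translation-initiation region), and *ranking criteria* (deviation of the
pooled 24-nt flank GC from 50%; sense-overhang class UU ≺ AA ≺ U·/·U ≺
other; antisense-overhang pairing, best when the mRNA carries AA just
upstream of the core so the UU guide overhang base-pairs). The staged order
— hard filters, then position, then rank — mirrors how such guidelines are
applied in practice: composition rules prune first, location second, and the
softer context criteria only order the survivors.

Interpretation choices where the guideline is qualitative:

- "More than three" A/U bases means a count ≥ 4; the boundary is tested
  explicitly (3 fails, 4 passes).
- The position rule is read conservatively as `core_start − (AUG_end) ≥ 75`
  so 75 passes and 74 fails.
- Core GC is computed on the 19-nt paired core, not the 21-nt strand: the
  overhangs are partly synthetic (the guide overhang is always UU) and would
  distort the composition of the region that actually base-pairs.
- Flank GC is a single pooled value over the concatenated 24 nt. It is
  rank-only by default — known-bad flank values exist (58%, 37%, 25% pooled
  deviations all rank strictly below a 50% flank) but no defensible numeric
  cutoff does, so none is invented; `flank_gc_max_dev` turns it into a hard
  filter when the user wants one.
- The GC band edges are inclusive. On a 19-nt core 35% and 55% are not
  exactly representable (0.35·19 is not an integer); the band predicate
  (`passes_gc_band`) is a pure function and its edge behaviour is exercised
  on 20-mers, where they are.
- Windows without both full 12-nt flanks are never candidates (their flank
  GC is undefined).
- Selected siRNAs must have non-overlapping cores by default, matching the
  common practice of synthesizing two independent duplexes per gene and
  injecting them as a mixture (`--allow-overlap` disables this).

Ranking is a lexicographic tuple `(flank_gc_dev, sense_overhang_penalty,
antisense_overhang_penalty, start)`. The final position component makes the
order total, so output is deterministic and byte-identical across runs.

## Parameters

| parameter          | default | unit | meaning |
|--------------------|---------|------|---------|
| `core_len`         | 19      | nt   | paired duplex length |
| `strand_len`       | 21      | nt   | core + 2-nt 3′ overhang |
| `gc_min`, `gc_max` | 35, 55  | %    | core GC band (inclusive) |
| `min_downstream`   | 75      | nt   | gap between AUG end and core start |
| `flank_len`        | 12      | nt   | each flank length |
| `flank_gc_target`  | 50      | %    | preferred pooled flank GC |
| `flank_gc_max_dev` | none    | %    | optional hard flank cutoff |
| `au_min_in_seed7`  | 4       | count| minimum A/U in the antisense-5′ 7-mer |
| `n_select`         | 2       | —    | siRNAs selected per gene |
| `max_mismatches`   | 2       | count| off-target near-match budget |
| `k` (index)        | 11      | nt   | seeding word size |
| `level`            | 0.5     | —    | knockdown ratio defining the EC |

## Off-target screening

Candidate cores are screened by an exhaustive ungapped near-match scan over
both strands of a user-supplied transcriptome: k-mer seeding followed by
Hamming verification. Completeness is guaranteed by the pigeonhole
principle — any placement with ≤ m mismatches contains an exact k-mer for
k = ⌊19/(m+1)⌋, and the index is transparently rebuilt at that word size
whenever the configured k is too large for the requested budget (for the
default m = 2, k = 6). The scan is therefore exact, with no heuristic
misses; this is deliberately stricter than a local-alignment heuristic and
is feasible because the query is only 19 nt. A candidate is flagged
non-specific when any placement with ≤ 2 mismatches (17/19 identity, the
conventional near-perfect band) exists outside the intended target; seed-
region-only (miRNA-like) off-target effects and gapped alignments are out
of scope.

## Dose–response model

Relative target-mRNA level y after injection of x µM siRNA is modelled as
y = a·e^(−b·x): a the amplitude (model value at dose 0, dimensionless
treated/control ratio) and b the decay rate per µM. The fit is ordinary
least squares of ln y on x — closed-form, deterministic, and well matched
to multiplicative measurement noise on a ratio; no iterative nonlinear
refinement is attempted. R is reported as the magnitude of the Pearson
correlation on the log scale; on the bundled five-point knockdown table this
convention yields R = 0.9133, agreeing to all printed digits with the value
historically reported for that fit, which is why it was adopted. The median
effective concentration is the unique solution of a·e^(−b·x) = 0.5,
EC = ln(a/0.5)/b — an absolute 50% knockdown, not half of a; it requires
b > 0 and a > 0.5 and errors otherwise.

Raw qPCR input is converted by ΔΔCt with an assumed amplification efficiency
of exactly 2 (no standard-curve correction), normalized to a reference gene
and a buffer-injected control; in Ct mode the definitional control point
(0 µM, ratio 1.0) is appended before fitting.

## Synthetic data

The generator draws background bases i.i.d. at a target GC fraction, forces
an AUG at the declared CDS start, and writes planted regions verbatim over
the background. The "ideal" plant is a core that passes every hard filter
together with designed flanks (pooled GC exactly 50%, AA immediately
upstream, UU immediately downstream), so its rank tuple is the best possible
`(0, 0, 0, ·)` and a planted site can only be displaced by an exact
three-way tie. Decoy transcriptomes plant copies of a query core with an
exact number of substitutions, on either strand, at known coordinates. Dose
data are simulated as y = a·e^(−b·x)·e^ε with ε ~ N(0, σ²) — multiplicative
lognormal noise, consistent with the log-linear estimator and with
positivity of a ratio; σ = 0 reproduces the model exactly. Defaults emulate
the reference experimental design: doses {0, 25, 50, 100} µM, 3–4 replicates,
σ = 0.1.

What the generator does *not* emulate: codon structure, UTR composition,
repeat content, transcript-abundance bias, qPCR efficiency drift, or
between-individual variability beyond the single lognormal term. Passing
tests therefore demonstrate algorithmic correctness (filters, ranking,
completeness, estimator calibration), not biological effectiveness of the
designed siRNAs on real transcripts.

## Problem sizes and numerics

The test suite and the reproduction script use 50 random transcripts of
300–2000 nt for design-oracle comparisons, 20 decoy transcriptomes of
10 × 1 kb for off-target completeness, and 200 simulated experiments
(4 doses × 4 replicates) for estimator calibration — sizes chosen so the
whole suite runs in seconds while leaving the statistical assertions
well-powered (the analytic sampling s.d. of b under the simulated design is
≈ 2.4% of its value, so the 5%-median and 25%/90% bands are comfortable but
not vacuous). GC percentages are kept unrounded internally and rounded to
one decimal only in reports; coordinates are 0-based half-open internally
and 1-based inclusive in all output.

## Known limitations

- No thermodynamic asymmetry or free-energy scoring; ranking uses only the
  composition and context criteria above.
- First-AUG defaulting can mis-anchor the position filter on transcripts
  with 5′-UTR AUGs; supply an explicit CDS map in that case.
- IUPAC ambiguity codes are rejected, not masked: a window containing N
  cannot be evaluated against composition criteria.
- The EC is a model-based extrapolation; with a ≤ 0.5 (no half-knockdown
  reachable) it is reported as undefined rather than clamped.
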