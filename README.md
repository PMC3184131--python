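# sirnakit

Rational siRNA design and RNAi knockdown analysis for insect embryonic
injection experiments (developed with the silkworm *Bombyx mori* in mind,
but sequence-generic).

Given an mRNA with a known initiation codon, `sirnakit` enumerates every
19-nt target site, evaluates an eight-criterion design guideline, assembles
the 21-nt duplex strands (19-bp paired core + 2-nt 3′ overhangs), and runs a
staged filter-then-rank selection that returns two siRNAs per gene. It also
screens candidate cores against a transcriptome for near-exact off-target
matches, and fits the exponential knockdown dose–response model used to
summarize qPCR measurements.

## The guideline

A candidate 19-nt core (sense orientation, with its two 12-nt mRNA flanks)
is scored on:

1. **GC_CORE** — core GC content within [35%, 55%] *(hard filter)*
2. **SENSE_5P** — first sense base is G or C *(hard filter)*
3. **ANTISENSE_5P** — first antisense base (complement of the last core
   base) is A or U *(hard filter)*
4. **AU_SEED7** — more than three A/U bases among the 7 nt at the antisense
   5′ end *(hard filter)*
5. **POSITION** — the core starts ≥ 75 nt downstream of the end of the AUG
   codon *(filter, applied after 1–4)*
6. **FLANK_GC** — pooled GC of the 24 flanking nt, preferred 50% *(ranking:
   deviation from 50%)*
7. **OVERHANG_S** — sense 3′ overhang (the verbatim next two mRNA bases)
   matches UU ≻ AA ≻ U·/·U ≻ other *(ranking)*
8. **OVERHANG_AS** — the antisense 3′ overhang is always synthesized UU; it
   ranks best when the mRNA bases upstream of the core are AA so the
   overhang still base-pairs with the target *(ranking)*

Survivors are ranked by (|flank GC − 50|, sense-overhang class,
antisense-overhang class, position) and the top two non-overlapping sites
are selected.

## The dose–response model

Relative target-mRNA level y after injecting x µM siRNA is modelled as
exponential decay, fitted by exact log-linear least squares:

    y(x) = a·e^(−b·x),   ln y = ln a − b·x  (OLS)

with R the magnitude of the Pearson correlation on the log scale. The median
effective concentration is the dose where the fitted model predicts y = 0.5:
EC = ln(a/0.5)/b.

## Worked example

```bash
sirnakit fixtures --out-dir demo --seed 0
sirnakit design --fasta demo/genes.fasta --transcriptome demo/transcriptome.fasta --out demo/report.tsv
head -3 demo/report.tsv | cut -f1-3,7,8,19-21
```

```
gene_id  start_1based  end_1based  gc_core_pct  flank_gc_pct  rank  selected  offtarget_hits
gene0    201           219         36.8         50.0          1     1         3
gene0    317           335         52.6         50.0          2     1         0
```

The top siRNA for `gene0` targets 1-based positions 201–219: core GC 36.8%
(inside the 35–55% band), flanking GC exactly the preferred 50%, rank 1,
selected, with 3 near-exact (≤2-mismatch) matches elsewhere in the supplied
transcriptome — a warning that this core is not unique to its target. The
runner-up at 317–335 has no off-target match.

Fitting a knockdown table (`conc_uM,rel_mrna`) and solving for the median
effective concentration:

```bash
sirnakit fit --csv demo/dose.csv
```

```
n       16
a       0.887447
b_per_uM        0.0283212
R       0.9960
ec_uM   20.26
```

i.e. y ≈ 0.89·e^(−0.0283x) on the simulated measurements (true generating
model 0.9·e^(−0.028x)), and the fitted curve crosses y = 0.5 at ≈ 20.3 µM.

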