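# isomirkit

Small RNA sequencing of a tissue yields millions of short reads that are not
clean copies of the annotated mature miRNAs: reads start and end a few bases
away from the miRBase coordinates (isomiRs), carry nontemplate adenines or
uracils at their 3' end (tailing), and sometimes come from the hairpin arm
that carries no annotation at all (opposite-arm products). `isomirkit` is a
toolkit for profiling exactly these phenomena in a pair of small-RNA
libraries (e.g. tumor vs adjacent normal tissue) and for comparing the two
libraries: differential expression in TPM, 5p/3p arm-usage shifts, and
pathway enrichment of the targets of the miRNAs that change. It is aimed at
computational biologists analysing bulk small RNA-seq who want every
threshold of the analysis explicit and testable.

## The mapping algorithm

Clean reads are aligned to pre-miRNA hairpins with **no mismatches**.
Paralogous miRNA families make mismatch-tolerant mapping ambiguous, but a
strict policy would discard every tailed read, because nontemplate 3' bases
mismatch by definition. The resolution is 3'-iterative trimming: terminal 3'
bases are removed one at a time until the remainder matches a hairpin
perfectly, subject to a floor of 18 nt. For read *r* and hairpin set *H*,

    L* = max { L ≥ 18 : r[1..L] is an exact substring of some h ∈ H }

The read maps at every occurrence of `r[1..L*]` (equal fractional weights),
and `r[L*+1..]` is the recovered 3' tail. The implementation finds L*
directly by seed-and-extend on an 18-mer index — provably identical to the
literal trim-and-retry loop, which survives as the brute-force oracle in the
test suite.

From each alignment and a mature annotation (1-based, hairpin-relative,
e.g. `5p:16-36`) the isomiR record follows:

* `shift5 = read_start − annotated_start`, `shift3 = matched_end −
  annotated_end` (the tail is *not* a position shift);
* tail category in {A, U, AA, UU, AU, C, G, other, none};
* per-miRNA expression = Σ isomiR counts; `TPM = count / library_total × 1e6`;
* fold change = `TPM_tumor / TPM_normal`; arm usage = `count_5p / count_3p`
  per library, compared as `log2(ratio_tumor / ratio_normal)`.

Reads failing hairpin mapping descend an ordered cascade of reference sets
(mRNA, tRNA, rRNA, snoRNA, scaRNA, snRNA, other ncRNA, repeat; ≤1
substitution, first match wins) or end as "unknown". Pathway enrichment of
target-gene unions uses the upper-tail hypergeometric test P(X ≥ k) with
Benjamini–Hochberg FDR.

A synthetic-study generator (`isomirkit.synthdata`) emits paired libraries
with per-read ground truth under published study conditions (class
composition, shift spectra, tailing rates, designated fold changes and
arm-ratio switches), so the whole pipeline is verifiable by parameter
recovery without any external download.

## Worked example

```python
from isomirkit import synthdata, pipeline

cfg = synthdata.study_config(seed=1, n_reads=50_000)
study = synthdata.generate_paired_study(cfg)
result = pipeline.analyze_study(
    study.reads,
    study.references.hairpins,
    study.references.annotations,
    study.references.reference_sets,
    pipeline.AnalysisParams(adapter=cfg.adapter),
)
```

prints (via the obvious accessors):

```
clean reads (normal): 49244
% miRNA reads:        74.85
% with 3' tail:       16.14
5' shift spectrum:    {-1: 0.007, 0: 0.959, 1: 0.034}
fc syn-miR-003-5p:    9.68  (generated at 9.88)
arm ratio syn-mir-001: normal 0.71, tumor 3.13
```

Reading: of ~49k clean reads in the synthetic normal library, ~75% map to
hairpins; ~16% of miRNA reads carry a 3' nontemplate tail; the 5' ends sit
almost exactly on the annotated position (96% at shift 0) — 3' ends are far
more ragged; a miRNA generated with a 9.88× tumor/normal expression ratio is
recovered at 9.68; and the designated arm-switch hairpin flips from
3p-dominant (ratio 0.71) in normal to 5p-dominant (3.13) in tumor.

The same pipeline runs from files (`isomirkit run config.yaml`), and each
stage has its own CLI subcommand (`trim`, `map`, `isomir`, `classify`,
`quantify`, `enrich`, `simulate`, `report`).

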