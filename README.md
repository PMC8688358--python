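# paremodes

Characterize how plant miRNA precursors are processed — and fix their
annotations — from PARE/degradome sequencing data.

## The problem

In plants, DCL1 releases the miR-5p/miR-3p duplex from a pri-miRNA hairpin
by successive cuts that proceed either **base-to-loop** (first cut below
the duplex) or **loop-to-base** (first cut above it), in a **short** (two
cuts) or **sequential** (extra cuts ~21 nt apart) fashion. Each cut leaves
a polyadenylated 3' remnant whose uncapped 5' end is cloned by PARE
(Parallel Amplification of RNA Ends, a.k.a. degradome sequencing) as a
20-nt tag. The positions of those tags around miR-3p therefore fingerprint
the processing mode:

| mode | diagnostic 5'-end tag positions |
|------|---------------------------------|
| short base-to-loop (shBL) | single peak at `pe` (just after the miR-3p 3' end) |
| sequential base-to-loop (seBL) | peak at `pe + 21` |
| short loop-to-base (shLB) | major peak at `p0` (the miR-3p 5' start), minor at `pe` |
| sequential loop-to-base (seLB) | additional peaks on the upstream grid `p0 − 21k` |

Two complications make this non-trivial. First, mature miRNAs are also
20 nt, so a contaminated library shows spurious `p0` tags; `paremodes`
quantifies contamination using known base-to-loop miRNAs (which should have
*no* `p0` signal) and a one-sided exact Wilcoxon signed-rank test of
downstream vs miR-3p tag percentages per library. Second, miR-3p
annotations are often wrong by a nucleotide or missing entirely; the
package infers miR-3p from miR-5p via the 2-nt 3' overhang rule on the
hairpin structure, and corrects annotated borders from the dominant remnant
peak.

The package is aimed at small-RNA researchers with aligned PARE tags
(BAM or a 5'-end count TSV), precursor sequences (FASTA) and miRNA
annotations (miRBase-style GFF3 or TSV). A seeded synthetic-degradome
generator reproduces the essential tag structure of each mode with known
ground truth, so the entire pipeline is testable without external data.

## Worked example

Simulate a two-library study (8 precursors per mode, depth 100, 5% tag
jitter, no contamination), QC it against the base-to-loop reference set,
and classify:

```sh
paremodes simulate --seed 42 --outdir demo/data --n-per-mode 8 --n-samples 2 --jitter 0.05
paremodes qc --fasta demo/data/precursors.fasta --annotations demo/data/annotations.tsv \
    --structures demo/data/structures.tsv \
    --tags demo/data/tags_lib01.tsv --tags demo/data/tags_lib02.tsv \
    --reference-set demo/reference.tsv --outdir demo/qc
paremodes classify --fasta demo/data/precursors.fasta --annotations demo/data/annotations.tsv \
    --structures demo/data/structures.tsv \
    --tags demo/data/tags_lib01.tsv --tags demo/data/tags_lib02.tsv --outdir demo/modes
paremodes report --outdir demo/modes
```

prints

```
library_id  n_bl  n_lb  p_bl        p_lb        contamination_fraction  passed
tags_lib01  8     8     0.00390625  0.00390625  0.0                     True
tags_lib02  8     8     0.00390625  0.00390625  0.0                     True

== modes (96 rows) ==
mode
seBL    8
seLB    8
shBL    8
shLB    8
```

Reading the QC row: over the 8 base-to-loop reference miRNAs, downstream
tags exceed miR-3p tags in every pair, giving the minimum exact one-sided
signed-rank p of 1/2⁸ ≈ 0.0039 < 0.005, so the library passes with an
estimated contamination fraction of 0. The consensus mode table recovers
the generating mode for all 32 precursors (per-library rows also report
the class counts C0/Ce/Cup/Cdown and first-cut accuracy, e.g. 0.93 at 5%
jitter):

```
precursor_id library_id mode  C0  Ce  Cup_total  Cdown  first_cut_accuracy
sim-seBL-000 tags_lib01 seBL   0   0          0    100                0.93
```

The same workflow on real data replaces the simulated inputs with your
FASTA/GFF3/BAM files and an ortholog-based reference set; `paremodes
correct --modes-table ...` then emits miR-3p boundary corrections with the
2-nt overhang check.

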