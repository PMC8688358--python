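# Methods

## Model and coordinate conventions

All positional math runs in precursor-local coordinates: 0-based,
half-open, counted along the precursor's own 5'→3' direction. GFF3
(miRBase dialect), BAM and 1-based TSV inputs are converted at the I/O
boundary, including the strand flip for minus-strand loci. A PARE tag is
reduced to its biological 5' end (leftmost aligned base on `+`, rightmost
on `-`), and only reads of exactly the expected tag length are counted —
20 nt by default for MmeI libraries, settable to 27 for EcoP15I ones.
Multi-mapper allocation is assumed to have been done by the aligner
workflow upstream; only primary alignments are counted.

## Tag profiles and key positions

For each precursor the 5'-end counts are collected in a window
`[mir3p.start − W, mir3p.end + W)`, W = 50 by default, clipped at the
precursor ends (anchoring the window on both miR-3p boundaries contains
either reading of "a ±50 nt window around miR-3p"). Precursors are kept
when one sample has ≥ 10 tags in the window or two samples have ≥ 5
(inclusive comparisons).

Mode evidence is read off four position classes: `p0` = miR-3p 5' start
and `pe` = first base after the miR-3p 3' end, each ±2 nt (DCL1 cut-site
imprecision); the upstream grid `p0 − 21k`, k = 1..K (K = 3), and the
downstream point `pe + 21`, each ±3 nt. The 21-nt spacing is the duplex
periodicity of consecutive DCL1 cuts. Every window position belongs to at
most one class (nearest key position; core classes win ties), so class
sums never double-count. Peaks require count ≥ 5, ≥ 5% of the window
total, and a local maximum over ±2 nt with ties broken toward the smaller
position; the peak criterion is a formalization of what is normally judged
by eye on profile plots, and both thresholds are exposed.

## Contamination QC

Mature miR-3p molecules are the same length as PARE tags and align exactly
at `p0`, so base-to-loop miRNAs — which produce no polyadenylated remnant
starting at `p0` — act as built-in negative controls. Per library, each
reference miRNA contributes `m` (tags in the `p0` class) and `d` (tags in
the `pe` class), expressed as percentages of the set-wide `Σ(m+d)`;
records are kept when `max(pct) > 0.5%` and `m + d > 10` (both strict).
The library passes when a one-sided Wilcoxon signed-rank test finds
downstream > miR-3p at α = 0.005 (an α = 0.05 preset suits sparser crop
libraries); a loop-to-base reference set is tested in the opposite
direction as a positive control. Because the percentages are a global
rescaling of the counts, the signed ranks are identical either way.

The test is the *paired* signed-rank (the two tag classes are measured on
the same miRNAs); the unpaired rank-sum variant is available behind a flag
for sensitivity analysis. The p-value is exact for n ≤ 25 — the
distribution of the rank sum over all 2ⁿ sign assignments, computed by
dynamic programming with average ranks for tied |differences| and zero
differences dropped — and a normal approximation with tie and continuity
corrections above that. The exact implementation is verified against a
literal 2ⁿ enumeration and against an independent library implementation
in the tie-free case.

Sensitivity caveat: with contamination spread evenly over the reference
miRNAs, the paired test only fails a library once contaminant counts rival
the remnant signal per miRNA (a contaminant fraction around 0.5). A
library at, say, 30% uniform contamination still shows `d > m` on every
pair and passes — the `contamination_fraction` estimate (`Σm/Σ(m+d)` over
the BL set), not the verdict, is the sensitive readout at moderate
contamination. Real contamination is typically concentrated in a few
highly expressed miRNAs, which the rank test punishes sooner.

## Mode classification

With class totals `C0, Ce, Cup, Cdown` and `T` their sum: `T < 10` →
undetermined; else `C0/T ≥ 0.2` → loop-to-base, sequential iff
`Cup/T ≥ 0.1`; else base-to-loop, sequential iff `Cdown > Ce`.
Loop-to-base is tested first because a genuine `p0` peak is mechanistically
diagnostic — base-to-loop processing cannot produce a polyadenylated
remnant starting at `p0`, and contamination false-positives are handled by
library QC, not per precursor. The thresholds were chosen so the four
archetypal single-library patterns (a lone `pe` peak; a lone `pe + 21`
peak; 80:20 at `p0`:`pe`; upstream-grid peaks plus `p0`) yield their
expected calls, and all are configuration-exposed. A `pe` peak is not
required for shLB. Signal at non-key positions (partial cleavage,
AGO1-mediated slicing, re-adenylated 5' fragments) is recorded as evidence
but never drives the call.

First-cut accuracy is `count(expected) / count(expected ± 3)` at the
expected first-cut remnant position per mode (`pe`, `pe + 21`, `p0`, or
the most 5' upstream grid hit for seLB); the exact published formula for
this statistic lives in prior work we could not consult directly, so this
ratio is a declared stand-in. Per-library calls aggregate to a consensus
by modal vote (undetermined calls counted but non-voting; ties →
undetermined), and family × species conservation collapses
short/sequential to the processing direction, reporting the majority share
among determined members.

## Duplex inference and boundary correction

`infer_mir3p` implements the 2-nt 3' overhang rule on a dot-bracket
pairing map: miR-3p's last base = partner(miR-5p first base) + 2, miR-3p's
first base = partner(miR-5p third-to-last base). When an anchor base is
unpaired, the nearest paired base within 5 nt substitutes and the offset is
compensated — a stated choice for reconciling small bulges, bounded at
5 nt to avoid drifting across plant hairpin bulges. Intervals are clipped
at sequence boundaries with the clip flagged. On bulge-free stems the
5p→3p and 3p→5p inferences are mutual inverses and realized overhangs are
exactly (2, 2). External RNAfold structures are accepted as two-column
TSV; the bundled Nussinov maximum-pairing fold (deterministic traceback,
GU allowed, min loop 3) is a structural fallback for synthetic hairpins
and tests, not a thermodynamic prediction. Arm assignment for sRNA
evidence takes the single most abundant read species (ties toward smaller
position, then shorter read) and compares its start to the midpoint of the
longest unpaired run between the outermost pair.

Boundary corrections search ±3 nt around the annotated border for the
dominant qualifying peak (ties: smaller |offset|, then smaller position).
For base-to-loop miRNAs the remnant's 5' base is the first base *after*
the mature 3' end, so the corrected exclusive end equals the peak
position; "a peak starting one nucleotide of gap after the annotated end"
therefore lengthens the annotation by 1 — the reading that reproduces the
published 21-nt corrected ath-miR169a-3p. For loop-to-base miRNAs the
remnant 5' end *is* the mature 5' start; the corrected interval shifts as
a whole (length preserved) unless independent 3' evidence is supplied.
Corrections are idempotent and are emitted as a report, never written back
into annotation files. The 2-nt overhang check (zero tolerance, both ends)
labels each correction when a structure is available.

## Synthetic studies

The generator emulates the tag-level structure of a PARE experiment:
perfect-complement stems (45 bp) with an 8-nt loop and 10/30-nt flanks,
miR-5p placed 5 nt into the stem and miR-3p derived by the overhang rule,
so every simulated duplex obeys the 2-nt rule by construction; per-mode
signal positions as in the table in the README, with the shLB first:second
remnant ratio defaulting to 70:30 (mirroring the major/minor peak pattern
of short loop-to-base exemplars) and seLB weighted 0.4/0.4/0.2 across
`p0`/upstream grid/`pe`; fixed or Poisson depth (default fixed 100); each
tag jittered ±1 nt with probability 0.1 by default (DCL1 imprecision is
near-adjacent in real profiles); and a contaminant fraction ρ of the
library placed exactly at `p0` with tag length 20 — deliberately the worst
case for the QC statistic. One seeded generator drives every draw, so a
config is byte-reproducible from its seed.

What the simulations do **not** model: realistic base composition or
folding heterogeneity (stems are perfect), expression skew across miRNAs
and the concentration of contamination in a few abundant species,
AGO1-mediated slicing and partial-cleavage background, multi-mapping
ambiguity, or library-prep biases. Passing tests therefore demonstrate
the correctness of the positional logic and statistics under the stated
generative model, not performance on real libraries — with the QC
sensitivity consequence noted above.

## Problem sizes used in the test suite

Classifier recovery runs 50 precursors × 4 modes noiselessly (recovery
must be exact, first-cut accuracy 1.0) and 200 × 4 at 10% jitter, depth
200 (recovery ≥ 0.9); QC verdicts use 20 base-to-loop + 20 loop-to-base
reference miRNAs at depth 100 over 20 seeds; Wilcoxon exactness is checked
against full enumeration for 100 random tables with n ≤ 8. These sizes
keep the whole suite under a few seconds while leaving the statistical
assertions comfortably away from their thresholds.
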