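# Methods

This note records the models, rules, and numerical choices behind
`methmark`, and what the synthetic-data generators do and do not emulate.

## Beta-values

Array methylation is carried as the Illumina beta-value,
β = M/(M + U + 100), the methylated fraction of probe intensity with a
100-unit offset stabilising low-intensity probes. β lies in [0, 1) for
finite intensities, is strictly increasing in M and — whenever M > 0 —
strictly decreasing in U. All statistics run on the β scale; the ×100
percent scale exists only for display. Missing probe values (failed array
measurements) propagate as NaN and are excluded pairwise: each probe is
tested on its non-missing samples only, and blood positivity denominators
count non-missing samples.

## DMR discovery

For a chosen target tissue, each probe is tested with a two-sample
Wilcoxon rank-sum test (target vs. all other discovery tissues pooled per
probe), with mid-ranks and tie-corrected variance in the normal
approximation; the exact null distribution is used when the combined
sample size is ≤ 12 and the data are tie-free. p-values are
Benjamini–Hochberg adjusted jointly across all probes tested in the run.

A probe is a differentially methylated CpG when, with strict inequalities
exactly as the thresholds are stated: FDR < 1e-10, Δβ (target mean −
other mean) > 0.3, and other-tissue mean < 0.1. The regional-density rule
operationalises "≥ 2 differentially methylated probes within a 5 kb
region" as a window of ±2.5 kb centred on each CpG: a probe survives iff
at least `min_probes_in_window` passing probes (itself included) lie
within 2,500 bp on its chromosome, boundary inclusive. DMR assembly is
single-linkage clustering at the same 2.5 kb gap; a DMR spans the
min-to-max member position with no flanking padding. Single-linkage at
gap g is equivalent to the transitive closure of the pairwise
|Δpos| ≤ g relation, which is how the tests verify it.

Blood exclusion drops probes whose blood-reference median β exceeds 0.1
or whose positivity (fraction of samples with β > 0.2) exceeds 0.02 —
both strictly greater-than, so a probe exactly on a boundary is retained.
DMRs that fall below the minimum probe count after exclusion are dropped.
Probes absent from the blood matrix cannot be scored; they are carried
forward with a warning rather than silently excluded, since absence of
evidence of blood signal is not evidence of absence.

All three filters are monotone: relaxing any threshold can only enlarge
the retained set.

## Bisulphite conversion and MSP design

Conversion follows the chemistry: every cytosine not followed by guanine
becomes T; a CpG cytosine is retained as C only on a methylated template.
The bottom strand is the reverse complement converted by the same rule
(equivalently, top-strand conversion of the reverse complement — tested
as an identity). A terminal C with no known following base cannot be
classified and is conservatively converted, with a flag on the template.
Conversion preserves sequence length, so converted coordinates equal
source coordinates and variant masks transfer directly (reflected for the
bottom strand).

Design runs on the methylated converted top strand by default (bottom via
flag; the strand choice is a free design parameter). Candidate amplicons
are all windows of 58–72 bp containing ≥ 6 CpGs — the minimum compatible
with two CpGs in each of three oligos. Within a window, the forward
primer starts at the window start and must end 3′ on a retained CpG C;
the reverse primer ends at the window end, is the reverse complement of
the converted sense strand, and its binding site must start on a CpG C so
its 3′ G pairs with that cytosine; the probe (18–30 nt, like the primers)
lies strictly between the two primers. Hard constraints — ≥ 2 CpGs per
oligo, the 3′ anchors, no masked variant position or N under any oligo —
are never relaxed; candidates failing them are counted per constraint and
not emitted.

Primer/probe length bounds (18–30 nt) and the strict between-primers
probe placement are standard MSP practice, adopted as package defaults
and configurable; melting temperature is deliberately not a pass/fail
criterion. Conversion-specificity (CH) counts are taken from the source
strand: the non-CpG cytosines under an oligo's binding site are exactly
the positions that convert and would mismatch unconverted DNA, for the
reverse primer just as for the forward (they appear as A in the reverse
primer sequence).

Scoring is a per-criterion traffic light with the overall rating the
worst across criteria and oligos: amplicon length green at 58–72 bp,
yellow up to the conventional 120 bp recommendation, red beyond; GC green
at 40–60%, yellow within 5 points outside, red beyond; CH per oligo green
at ≥ 3, yellow at 1–2 (the relaxed regime), red at 0; poly-G green at
runs ≤ 3, yellow at 4, red at ≥ 5. The numeric yellow/red boundaries for
GC and poly-G are this package's calibration of qualitative guidance, and
all live in `DesignRules`. Ranking is fully deterministic: rating, then
total CpG coverage, then shorter amplicon, then leftmost start, then
lexicographic oligo sequences.

## Assay performance and quantification

Single-molecule screens follow the Poisson occupancy model: at λ copies
per reaction a replicate is positive with probability 1 − e^(−ελ), ε the
per-molecule detection efficiency. Positivity rates carry exact binomial
(Clopper–Pearson) 95% intervals — chosen as the default because the
published intervals this package is benchmarked against are consistent
with the exact method; Wilson is available as an option and the method
tag is always recorded. Rates are compared with the two-sided Fisher
exact test (probability-mass summation convention).

Digital PCR inverts the same model per partition: with k of N partitions
positive, λ = −ln(1 − k/N) molecules per partition, copies/reaction =
λN, and copies/mL plasma applies the extraction scale factor. The CI on
λ propagates the exact binomial CI on k/N through the same transform.
Saturated plates (k = N) raise rather than report an unbounded estimate;
k = 0 is a genuine zero (undetectable marker), not a missing value.

Clinical cohorts are summarised per sample as absolute marker copies/mL
and marker percent of a total-cfDNA reference target, with group
medians/IQRs and a Kruskal–Wallis test per measure. The chi-square
approximation is the default (typical group counts here are far from the
asymptotic regime, but it is the conventional reported test); an exact
enumeration branch over all multinomial assignments is provided for total
n ≤ 10 and is the oracle-verified path.

### Reconstructing counts from published summaries

When only a rounded positivity rate, a CI, and a replicate-count range
are published, the underlying (k, n) can usually be pinned by
enumeration. `reconstruct_binomial_counts` keeps every (k, n) in the
range whose rate matches at printed precision and whose exact CI
reproduces both printed bounds within one printed rounding unit (0.1
percentage point); `single_copy_comparison` then evaluates Fisher's test
on every candidate pair and, when a published p-value exists, uses it as
one more constraint to resolve the remainder. Rounded summaries do not
always identify the counts uniquely, and a printed bound can sit just
past the half-ulp of every candidate — the one-ulp tolerance and the
p-value disambiguation are the package's documented procedure for that
situation, and outputs always report the recomputed statistics, never
the published ones.

## Synthetic data

Generators are seeded through named, hierarchically split streams: one
integer seed plus a purpose string yields an independent generator, so
adding a call never perturbs other draws and everything is
bit-reproducible.

Background β noise is Beta-distributed (mean 0.03, concentration 20 for
tissue; concentration 30 for blood, keeping the spurious β > 0.2 tail
well under the 2% positivity rule), respecting the [0, 1] support — a
deliberate simplification of real array noise. Planted DMR probes draw
from a Beta with mean shifted by Δβ in the target tissue only. Default
cohort sizes mirror a realistic 450K atlas setting: 45 target vs. 489
other samples over 16 tissues, 662 whole-blood references, clinical
groups of 9/5/7/2. Background probes are laid out in 2 kb pairs so the
regional-density filter is genuinely exercised under the null rather
than trivially satisfied. Synthetic discovery matrices default to 206
probes — enough to make the joint FDR adjustment and region logic
meaningful at desk scale.

Genomic regions plant CpG dinucleotides at a target density (binomially
drawn count, non-adjacent placement, optionally clustered centrally like
a CpG island) into random background at a chosen GC fraction, with
accidental CG dinucleotides broken so the realised CpG count equals the
planted one; the break step slightly biases background composition, which
is irrelevant to the design logic being tested. Screens and partitions
are exact Binomial(n, 1 − e^(−ελ)) draws.

What passing tests on these generators show: the pipeline's filters,
estimators, and tests recover planted truth at the stated sample sizes
and stay calibrated under the null. What they do not show: robustness to
probe-affinity artefacts, batch effects, cross-platform differences,
copy-number confounding, bimodal intermediate methylation, or cfDNA
fragmentation biology — none of which the generators model.

## Known limitations

- Discovery pools all non-target tissues into one comparison group; no
  per-tissue or covariate-adjusted contrasts.
- Design does not screen thermodynamics (dimers, hairpins) or multiplex
  compatibility, and reports no melting temperature criterion.
- The chi-square Kruskal–Wallis p is anti-conservative at the default
  clinical group sizes; the exact branch is limited to total n ≤ 10.
- Published-count reconstruction is only as good as the printed
  precision; it reports the full candidate set when summaries do not
  pin the counts.
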