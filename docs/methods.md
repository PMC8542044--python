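# Methods

## Quantification model

Each phosphosite carries raw intensities for three SILAC channels —
vehicle, stimulus, stimulus + inhibitor — per replicate and timepoint.
Ratios are formed *within* a replicate (`log2(stimulus/vehicle)`,
`log2(stimulus+inhibitor/vehicle)`), so the design is paired by
construction: channel-level normalization differences cancel inside each
run.  Zero intensities are treated as "not detected" (missing), never as a
ratio of zero, because an absent SILAC signal carries no magnitude
information.  A site is *quantified* in a replicate when both the numerator
and the vehicle channel are present.

Input ratios are assumed pre-normalized by the upstream quantification
software; an optional per-replicate median-centring of log₂ ratios exists
but is off by default.

## QC policy

* Localization probability ≥ 0.75.  The filter is phrased "over 75%" in
  common usage; the boundary here is **inclusive**, because supplementary
  tables round to exactly 0.75 and an exclusive boundary would silently
  drop those rows.
* Quantified in ≥ 2 replicates, enforced **per timepoint** with a
  configurable scope (`all_timepoints` by default; `any_timepoint`
  available).  The protein-level "covered at every timepoint" statistic is
  reported separately by `summarize_global`.
* Replicate CV ≤ 0.25 (linear-scale sd/mean of the replicate ratios) only
  *annotates* by default; set `drop_high_cv=True` to remove.

QC is idempotent: re-applying a policy to its own output changes nothing.

## Regulation and dependence calls

The regulation test is a two-tailed one-sample *t*-test of the replicate
log₂ ratios against 0.  The published analysis names an unpaired
two-sample Student's *t*; because SILAC channels are paired within a run,
the one-sample form on ratios is the equivalent paired analysis and is the
default here (a Welch two-sample mode on log₂ intensities is provided for
comparison).  Gates: `up` iff mean log₂ ratio ≥ 0.485 **and** p < 0.05;
`down` symmetric.  The ratio boundary is inclusive, p strictly below.  No
multiple-testing correction is applied to the gate (a BH-adjusted column is
emitted for transparency); this mirrors the raw-p convention of the
source analysis, where the ratio gate does most of the filtering.

Replicates with zero variance and a nonzero mean would give an undefined
*t*; they receive a capped statistic (|t| = 1e6) so p is tiny but finite.

The rescue fraction is computed on **mean** log₂ ratios,
`f = 1 − mean_log2r_TN / mean_log2r_T`, not per-replicate-then-averaged;
this matches the figure-level comparison of the two ratio axes and keeps
`f` well-defined when individual replicates are missing in one arm.  `f`
may exceed 1 (over-rescue) or go negative (amplification).  `f ≥ 0.5`
(inclusive) classifies an up site as *inhibited* and a down site as
*rescued*.  The scale choice (log₂ mean-of-ratios) is the main documented
source of discrepancy risk against externally published site lists.

## Temporal patterns

"Early" is the first half of the timepoint vector (15 min, 0.5 h by
default), "late" the second half (2 h, 4 h).  Decision table, first match
wins: `insufficient` (< 2 timepoints) → `none` (nothing regulated) →
`late_dependent` (dependent at ≥ 1 late and no early timepoint) →
`sustained` → `early_only` → `late_only` → `mixed`.  `late_dependent`
precedes `sustained` so a site up at all four timepoints but
inhibitor-sensitive only late — the archetypal late-dependence profile —
gets the dependence-aware label.

## PCA

Descriptive only.  Samples are the (arm, timepoint) mean-ratio profiles;
missing values are imputed to 0 on the log₂ scale ("no change"), columns
mean-centred, top-2 SVD taken.  Component signs are fixed by making each
component's largest-magnitude loading positive.  An all-constant matrix is
a degenerate-variance error.

## Motif discovery

Greedy motif-x on 15-mer windows centred on the phosphoresidue (S/T
analysed jointly by default, Y separately).  Step statistic: exact binomial
tail P(X ≥ k | n, p_bg), where p_bg adds a 0.5 pseudocount to the
background count (denominator + 0.5 × 20) so zero frequencies never divide.
A pair is fixed when p < 1e-6 with ≥ 20 foreground occurrences (classical
motif-x defaults; the original analysis used a web tool with unstated
parameters, so these are approximations).  Both foreground and background
are restricted to matching sequences after each fixing step, and completed
motifs remove their support from both sets, so supports are disjoint.
Identical windows are deduplicated first — one biological site, one vote.
`_` padding at protein termini is excluded from all counts.  Ties break by
(p, offset, residue).  The default background is the windows of all
QC-passing quantified sites, which controls for detectability bias; a
proteome-wide background can be supplied instead.

## Enrichment and modules

Hypergeometric upper tail with BH adjustment across tested terms; rows
sorted by (p, term_id).  The annotation database is an input GMT file — no
GO snapshot is bundled, because term content is database-version dependent.

MCODE: vertex weight = highest-k-core number of the closed neighbourhood ×
that core's density (density without self-loops, 2m/(n(n−1))).  Nodes
below the degree cutoff (2) weigh 0.  Seeds are processed in descending
weight with node-id tie-breaks; expansion admits unclaimed neighbours with
weight ≥ (1 − 0.2) × seed weight; haircut removes singly connected module
members; modules < 3 nodes are discarded with their nodes still claimed.
Parameters are the canonical published defaults.  Recovering any
particular published module list additionally requires that study's
(unstated) interaction-network source, so module identity on real data is
treated as qualitative.

## RNA-seq cascade

Counts are normalized with DESeq2-style median-of-ratios size factors.
The internal differential test (`simple_de`) is a Welch *t* on log₂
normalized counts with BH adjustment — a deliberately simple stand-in used
only on synthetic data; real-data runs pass an externally produced DE
table into the cascade.  Stage 1 uses **raw** p < 0.05 by default (the
convention the published stage counts follow); `use_adjusted_p=True`
switches to the BH-adjusted variant described in the upstream methods —
the two conventions genuinely differ in the source material, so both are
exposed.  All ratio gates are strict `>` as printed in the filter scheme,
including the final 0.26 gate on the phosphomimetic-vs-phosphodead
contrast.  A 0.5 pseudocount guards every log ratio.  Genes absent from a
ratio map are excluded at that stage and counted.

ΔΔCT: per replicate ΔCT = Ct_target − Ct_reference; ΔΔCT subtracts the
gene's mean control ΔCT; fold = 2^(−ΔΔCT).  Invariant to constant Ct
shifts; the reference gene defaults to the conventional housekeeping
choice and is configurable.

## Synthetic data: what it emulates, and what it does not

The phospho generator plants five site classes — null;
stimulus-responsive inhibitor-independent; early-only;
dependent-late up and down — at fractions (0.70 / 0.10 / 0.05 / 0.10 /
0.05) with a 1.0 log₂ effect and 0.8 rescue depth, 6 replicates × 4
timepoints (15 min, 0.5 h, 2 h, 4 h), under multiplicative log-normal
noise with σ = √ln(1 + CV²) so the linear-scale intensity CV matches the
0.15 target (replicate *ratio* CVs are then ≈ √2 × larger, ~0.21, most
below the 0.25 QC line).  Early sites change at the first two timepoints
only, so the planted classes map one-to-one onto the temporal decision
table; dependent-late sites change at the last two with the inhibitor
channel removing 80% of the change.  60% of dependent-late windows carry
R at −3 and P at +1; other positions are uniform over the 20 amino acids
and the central residue is drawn S/T/Y at 0.85/0.10/0.05.  The
distributional form of SILAC ratio noise is not established; log-normal is
an assumption, and passing tests show correct recovery *under that model*,
not under real-data pathologies (shared-peptide interference, missing not
at random, batch structure — none are simulated).

Networks: planted cliques on disjoint nodes embedded in Erdős–Rényi noise
(background probability applied to every non-clique pair).  RNA-seq:
shared-dispersion negative-binomial counts (α = 0.005) for the 4 genotype
× 2 treatment panel, 6 replicates, with per-sample library factors uniform
in (0.7, 1.3).  Planted cascade genes get a high base mean (4000 counts)
and generous log₂ offsets (3 for the stage-1 fold, 0.8 for the `> 0`
gates, 0.13 — the midpoint of the (0, 0.26) corridor — for stage-4-only
genes) so stage membership is decided by the gates, not by counting noise;
default planted chain (50, 30, 20, 12, 7) up plus 20 down.  qPCR Ct values
are generated from the inverse ΔΔCT model with Gaussian Ct noise.

## Problem sizes

The default analyses run at 2000 phosphosites, a 210-node network, 1000
genes × 48 samples, and 100 qPCR replicates; the full test suite and the
reproduction script each finish in seconds at these sizes, which are ample
for the planted effects to be recovered at the documented thresholds.

## Known limitations

* The rescue-fraction arithmetic (log₂ vs linear scale, mean-of-ratios vs
  ratio-of-means) is a documented choice; external site lists derived with
  a different convention will disagree near the 50% boundary.
* `simple_de` is not a dispersion-modelling DE method and is not intended
  for real count data.
* Motif discovery fixes exact residues only — no PWM scoring, no width
  selection beyond the ±7 window.
* The MCODE "fluff" option is implemented but off by default and untested
  against the original implementation's fluff semantics.
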