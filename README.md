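# phosphorescue

Quantitative analysis of kinase-inhibitor-rescue phosphoproteomics and its
downstream transcriptional readout.

## The problem

In TNFα-induced necroptosis, the kinase RIPK1 drives a programme of
phosphorylation events that unfold over hours.  A triple-label SILAC design
measures each phosphosite in three channels within the same run — vehicle,
stimulus (TNFα), and stimulus plus the RIPK1 inhibitor Nec-1s — across
replicates and timepoints.  A site is *stimulus-regulated* when its
stimulus/vehicle log₂ ratio clears a magnitude gate with statistical
support, and *kinase-dependent* when the inhibitor arm removes at least
half of that change.  Dependent sites are then characterised three ways:
their temporal pattern (early vs late dependence), their sequence context
(consensus-motif enrichment around the phosphoresidue), and their protein
neighbourhood (densely connected modules in an interaction network).  A
parallel RNA-seq arm follows one such site — a phosphoserine on a
transcriptional repressor — through a phosphomimetic reconstitution panel
(KO; WT-, phosphodead- and phosphomimetic-reconstituted KO) with a
five-stage gene-filtering cascade, and a ΔΔCT qPCR module closes the loop
on individual cytokine transcripts.

The package is for analysts who have a quantified phosphosite table
(MaxQuant-style or generic TSV) plus optional RNA-seq counts, and want the
whole chain — QC, ratio statistics, dependence calls, motifs, modules,
cascade — as tested, scriptable pieces.

## The statistics at the core

* **Regulation call** per site × timepoint: mean replicate log₂(T/V) with a
  two-tailed one-sample *t*-test against 0; *up* iff mean ≥ 0.485 and
  p < 0.05 (down symmetric).
* **Rescue fraction** `f = 1 − log₂r_TN / log₂r_T`: the share of the
  stimulus-induced log₂ change removed by the inhibitor.  `f ≥ 0.5` ⇒
  *inhibited* (up sites) or *rescued* (down sites).
* **Consensus motifs**: greedy motif-x — at each step the (offset, residue)
  pair with the smallest exact binomial tail P(X ≥ k | n, p_bg) is fixed,
  sequences are restricted, and completed motifs claim their support
  disjointly.
* **Gene-set enrichment**: upper-tail hypergeometric P(X ≥ k | N, K, n)
  with Benjamini–Hochberg adjustment.
* **MCODE modules**: vertex weight = (highest k-core of the closed
  neighbourhood) × (density of that core); seeds expand to neighbours
  within `1 − node_score_cutoff` of the seed weight.
* **Cascade**: S1 = {p < 0.05 and |log₂FC| > 2 vs vehicle}; S2–S4 chain
  strict `> 0` gates on KO/WT, mimetic/WT and mimetic/dead log₂ ratios;
  S5 requires mimetic/dead > 0.26.  Nesting S5 ⊆ … ⊆ S1 is enforced.
* **qPCR**: fold = 2^(−ΔΔCT), ΔΔCT = ΔCT(treated) − mean ΔCT(control).

A synthetic-data module generates all inputs with known ground truth
(planted site classes, motifs, cliques, cascade genes), so every stage is
testable end to end without any external download.

## Worked example

```python
from phosphorescue import (PhosphoSimConfig, simulate_phospho_dataset,
                           compute_site_quant)
from phosphorescue.differential_phospho import call_sites
from phosphorescue.motif_enrichment import extract_windows, find_motifs

config = PhosphoSimConfig(n_sites=2000, seed=42)
records, truth = simulate_phospho_dataset(config)
quants = [compute_site_quant(r) for r in records]
calls = call_sites(quants, config.timepoints)

n_dep_4h = sum(1 for c in calls
               if c.timepoint == "4h" and c.dependence in ("inhibited", "rescued"))
print(f"inhibitor-dependent sites at 4 h: {n_dep_4h}")

fg_ids = {c.site_id for c in calls
          if c.timepoint == "4h" and c.direction == "up"
          and c.dependence == "inhibited"}
fg = extract_windows(r.window for r in records if r.site_id in fg_ids)
motifs = find_motifs(fg, [r.window for r in records])
top = motifs[0]
print(f"top motif: {top.display}  support {top.support}/{len(fg)}  "
      f"fold {top.fold_enrichment:.1f}  step p {top.p_binomial:.2e}")
```

prints

```
inhibitor-dependent sites at 4 h: 300
top motif: RxxpSP  support 119/200  fold 6.7  step p 4.75e-16
```

All 300 planted dependent sites (out of 2000) are recovered at 4 h, and the
top-ranked consensus motif is the planted arginine at −3 / proline at +1
around the phosphoserine — the RxxSP signature of the kinase's substrate
preference — carried by 119 of the 200 up-and-inhibited foreground windows
at a 6.7-fold enrichment over the all-quantified-sites background.

The same analyses are available from a shell:

```sh
phosphorescue simulate phospho --n-sites 2000 --seed 42 --out sites.tsv
phosphorescue qc sites.tsv --out kept.tsv
phosphorescue classify kept.tsv --outdir run/
phosphorescue run-all --outdir run/ --seed 42
```

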