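# dynapquant

Quantitative analysis pipeline for the cell biology of DynAPs — the
liquid-like cytoplasmic organelles of multiciliated cells in which axonemal
dynein motors are pre-assembled before deployment to cilia. The package
implements the three statistical workflows such a study rests on, plus
synthetic-data generators with known ground truth for every input:

1. **APMS enrichment scoring** — given peptide-spectral-match (PSM) count
   tables from an affinity purification of a GFP-tagged bait and a matched
   GFP-only control, score every protein orthogroup for specific
   interaction with the bait;
2. **FRAP kinetics** — normalize fluorescence-recovery-after-photobleaching
   traces and fit single-exponential recovery to obtain exchange rate,
   half-time and mobile fraction (stably retained vs. rapidly fluxing
   components);
3. **Colocalization and axoneme profiles** — per-cell Pearson correlation
   of two imaging channels within focus ROI masks (full vs. partitioned
   sub-organelle overlap), and intensity profiles along normalized axoneme
   length ratioed against a co-expressed membrane marker.

It is aimed at cell biologists analyzing spectral-count pulldowns and
live-imaging data of membrane-less organelles, and at anyone needing a
tested, scriptable reference implementation of these statistics.

## The statistics

Counts are first collapsed to orthology groups (homeologs summed within
each run) and replicate runs pooled by summation. Over the *n* groups with
at least one PSM in either sample, each group *i* receives

- a pseudocounted compositional log2 fold-change

  $$FC_i = \log_2\frac{(PSM_{i,expt}+1)\,/\,\sum_j (PSM_{j,expt}+1)}
                      {(PSM_{i,ctrl}+1)\,/\,\sum_k (PSM_{k,ctrl}+1)}$$

- a one-sided two-proportion Z statistic on raw frequencies
  $f_i = PSM_i/\sum_j PSM_j$, with pooled frequency
  $f_{i,comb} = (PSM_{i,expt}+PSM_{i,ctrl})/(T_{expt}+T_{ctrl})$:

  $$Z_i = \frac{f_{i,expt}-f_{i,ctrl}}
         {\sqrt{\tfrac{f_{i,comb}(1-f_{i,comb})}{T_{expt}}
               +\tfrac{f_{i,comb}(1-f_{i,comb})}{T_{ctrl}}}}$$

- an upper-tail normal p-value $p_i = 1-\Phi(Z_i)$ and a Benjamini–Hochberg
  FDR. Groups with $Z \ge 1.645$ (the one-sided 95% critical value) are
  flagged significant; the bait row is kept and flagged as the screen's
  positive control.

FRAP traces are double-normalized, $(roi/ref)$ rescaled to a pre-bleach
mean of 1, and fitted post-bleach with
$I(t) = F + (P-F)(1-e^{-kt})$ (floor $F$ fixed at the first post-bleach
point), giving half-time $\ln 2/k$ and mobile fraction $(P-F)/(1-F)$.
Colocalization is the sample Pearson R over ROI pixels per z-section,
averaged per cell.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`. Scoring a simulated pulldown
(one 5,000-PSM bait run with the bait enriched 50×, two pooled GFP-control
runs, 200 orthogroups):

```sh
$ python analysis/01_simulate_pulldowns.py
$ python analysis/02_score_enrichment.py
universe n=199, significant at z>=1.645: 5
top 5 hits:
group_id  psm_expt  psm_ctrl  log2_fc    z       fdr  is_bait
    g000       566        29     5.21 32.6 1.63e-231     True
    g197        14         8     1.71 3.02     0.127    False
    g187         7         5     1.39 1.84     0.999    False
    g055         3         1     1.97 1.77     0.999    False
    g184         3         1     1.97 1.77     0.999    False
the bait ranks #1 — the positive control of the screen
```

The bait (`g000`) is recovered as the strongest hit by a wide margin —
566 of 5,000 bait-run PSMs vs. 29 of 10,000 control PSMs gives a log2
fold-change of 5.2 and Z = 32.6 — while background groups scatter around
Z ≈ 0 and a handful clear the 1.645 gate by chance, as a 5% one-sided test
should allow. The same numbers flow into `results/edges.tsv`, the weighted
bait–prey edge list behind a spoke-diagram visualization.

The other drivers print, for example:

```text
$ python analysis/04_frap_recovery.py
100 traces, true k=0.1/s (t1/2=6.93s), mobile fraction 0.8
median fitted k=0.0991/s (relative error 2.5%)
median fitted mobile fraction=0.800 (absolute error 0.006)

$ python analysis/05_colocalization_sweep.py
overlap=0.00: mean per-cell R = 0.456 (sd 0.043, n=20)
overlap=1.00: mean per-cell R = 0.858 (sd 0.013, n=20)
```

i.e. recovery kinetics are estimated to a few percent from realistic-noise
traces, and the foci phantom spans the Pearson range from partitioned
(R ≈ 0.45) to fully colocalized (R ≈ 0.85) marker pairs.

A `dynapquant` console script exposes the same operations
(`enrich`, `frap-fit`, `coloc`, `profile`, `simulate`); see
`dynapquant --help`.

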