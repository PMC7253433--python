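# rg4kit

Tools for studying how RNA-binding proteins engage RNA G-quadruplexes
(RG4s) — four-stranded structures of stacked G-quartets that act as strong
translational control elements — built around three analyses:

1. **RG4 motif prediction** (`rg4kit.qgrs`): a QGRS-style scanner that finds
   windows of at most 30 nt containing four equal-length G-runs (tetrad
   number *g* ≥ 2) separated by three loops, scores them with a G-score
   rewarding more tetrads and shorter, more even loops, keeps hits with
   score ≥ 19, and assigns them to 5′UTR / CDS / 3′UTR regions.
2. **CLIP-site enrichment** (`rg4kit.enrichment`): intersects protein
   binding sites (BED6, extended ±25 nt) with the RG4 catalog and tests
   enrichment against 10,000 random background sites with a two-sided
   Fisher exact test, reporting odds ratios, −log10 p, RG4 densities per Mb
   and the fraction of catalog RG4s bound.
3. **Differential RNA pull-down proteomics** (`rg4kit.msdiff`): a paired
   label-free (LFQ) analysis contrasting proteins bound to a folded
   quadruplex bait (WT) versus its unfoldable 7-deaza-G analog (7dG):
   contaminant filtering, log2, a ≥3-valid-values filter, downshifted-
   Gaussian imputation of missing-not-at-random values (width 0.3 s,
   downshift 1.8 s), a sign-flip permutation test with SAM-style q-values,
   and classification into **RG4-BPs** (WT/7dG ≥ 1.5, q ≤ 0.05) and
   **G-rich-BPs** (WT/7dG ≤ 1/1.5, q ≤ 0.05).

`rg4kit.assays` adds the closed-form assay quantifications used around such
screens (2^(−ΔΔCT) qPCR expression, RIP enrichment normalised to IgG /
input / a reference mRNA, heavy-polysome translational efficiency
HP/(NP+LP+HP), Rluc/Fluc reporter ratios, clonogenic plating efficiency),
and `rg4kit.simulate` generates every pipeline input with known ground
truth: transcriptomes with planted quadruplex motifs, CLIP-like sites with
a tunable placement preference for planted motifs, paired LFQ matrices with
planted fold changes and intensity-dependent dropout, and assay fixtures.

The package is aimed at computational biologists who want a tested,
reusable version of these analyses that can be validated end-to-end on
synthetic data before being pointed at real transcript FASTA + BED +
proteinGroups-style tables.

## Worked example

```python
from rg4kit import simulate as sim, qgrs, enrichment as enr, msdiff as ms

# transcriptome with planted G4s (ground truth known)
txs, truth = sim.simulate_transcriptome(sim.SimTranscriptomeConfig(n_transcripts=50, seed=1))
catalog = qgrs.predict_catalog(txs, qgrs.RG4Params())
print(catalog.region_summary)
#  region  n_hits  total_length_nt
#    5UTR      15            10223
#     CDS      28            64815
#    3UTR      41            41673

# CLIP-like sites placed with an 8-fold preference for planted G4s
sites = sim.simulate_clip_sites(txs, truth, sim.SimClipConfig(n_sites=500, g4_enrichment_factor=8.0, seed=2))
results, _ = enr.enrichment_experiment(sites, catalog, txs, enr.EnrichConfig(seed=3))
print(enr.results_to_frame(results))
# region    a    b     c     d  odds_ratio  neg_log10_p  density_obs_per_mb  density_bg_per_mb
#   5UTR   28   27  1496  8504       5.895        9.273            3359.086           1310.158
#    CDS   46  208   473  9527       4.454       13.680            1291.264            464.712
#   3UTR   58  133  1042  8958       3.749       13.127            2548.263            982.847
#    all  132  368   771  9229       4.294       33.188            1968.621            720.882
```

Per region, `a`/`b` count observed sites with/without an RG4 overlap and
`c`/`d` the same for random background sites drawn from that region's
sequence space; the strongly positive odds ratios and large −log10 p
recover the simulated 8-fold binding preference. Densities are RG4s per Mb
of (merged, flank-extended) site sequence.

```python
# paired WT vs 7dG pull-down LFQ with 10% planted WT-preferring proteins
table, protein_truth = sim.simulate_lfq(sim.SimLfqConfig(seed=0))
per_protein, summary = ms.run_differential(table, ms.MSConfig(seed=1))
print(summary["class_counts"])
# {'RG4-BP': 93, 'G-rich-BP': 0, 'unclassified': 868, 'background': 0, 'excluded': 39}
```

Of the 100 planted WT-preferring proteins, 93 are recovered as RG4-BPs at
q ≤ 0.05 and 1.5-fold enrichment; no 7dG-preferring proteins were planted
and none are called.

The same steps are available from a shell:

```bash
rg4kit simulate transcriptome --out-dir sim/ --seed 1
rg4kit predict --fasta sim/transcripts.fa --regions sim/regions.tsv --out hits.bed
rg4kit enrich --sites clip.bed --catalog hits.bed --fasta sim/transcripts.fa \
       --regions sim/regions.tsv --flank 25 --n-background 10000 --seed 3 --out enrich/
rg4kit msdiff --table lfq.tsv --seed 5 --out diff/
rg4kit assay ddct --table ct.tsv --out folds.tsv
```

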