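# cpgchrom

TSS-anchored chromatin profiling of genes with and without CpG-island
promoters.

More than half of human genes initiate transcription inside CpG islands —
CpG-dinucleotide- and G+C-rich regions that stay unmethylated at active
promoters. Because transcription itself strongly shapes chromatin, asking
whether promoter *type* has its own chromatin signature requires comparing
CpG and non-CpG promoter genes at **matched expression levels**. `cpgchrom`
is a reusable, tested implementation of that comparative analysis for
anyone working with ChIP-seq / MNase-seq read sets, gene annotations, and
expression tables: it classifies promoters, builds expression-matched gene
sets, turns mapped reads into nucleosome-dyad tracks, computes oriented
metagene profiles, and quantifies the promoter-level statistics that
distinguish the two gene classes.

## What it computes

- **Promoter classification.** A gene is a CpG-promoter gene when its most
  5' TSS falls inside a CpG island. Independently, promoter sequence from
  −1,200 to +300 bp of the TSS is scanned with a sliding 500 bp window: a
  promoter is **HCP** if any window has CpG observed/expected ratio
  o/e > 0.75 *and* GC% > 55, **LCP** if every window has o/e ≤ 0.48, else
  **ICP**, where o/e = N<sub>CpG</sub>·L / (N<sub>C</sub>·N<sub>G</sub>).
- **Expression matching.** Genes are ranked by expression and split into
  three equal tiers; per tier, 500 non-CpG genes are sampled and each is
  paired with the CpG gene of nearest log expression, accepted only when
  |ln e₁ − ln e₂| ≤ 0.1.
- **Dyad tracks.** Mapped reads (6-column BED) are deduplicated, shifted
  75 bp in the sequencing direction to the nucleosome dyad, rescaled to
  10 M fragments, and tallied per base.
- **Metagene profiles.** Per-gene, strand-oriented dyad counts from 500 bp
  upstream to 3 kb downstream of the TSS; group averages are smoothed with
  loess (tricube weights, local quadratic, 180 bp span) with a ±2 SE band,
  and modification tracks can be background-subtracted against nucleosome
  occupancy with a sliding 75 bp window. G+C-content and interval-density
  (e.g. exon) profiles and expression-ordered heatmap matrices round out
  the profile set.
- **Promoter statistics.** (i) Asymmetry scores — the fraction of ±500 bp
  promoter reads that fall upstream of the TSS — compared between classes
  by Wilcoxon rank-sum (or signed-rank for matched pairs); (ii) the
  leftmost position of maximal modification within 2 kb of the TSS,
  Spearman-correlated with expression rank; (iii) CTCF-overlap fractions
  in ten expression bins per class with Wilson 95% intervals and an
  overall χ² test.

A fully seeded synthetic-data module generates genomes, gene models,
CpG-rich/poor promoter sequences, expression, and reads from parameterised
nucleosome-occupancy and modification-placement models, so the entire
pipeline is testable end to end without external downloads.

## Worked example

Generate a miniature dataset (200 genes, nucleosome occupancy plus three
modification tracks) and run the full pipeline:

```bash
cpgchrom make-fixtures --out demo --n-genes 200 --seed 3
cpgchrom run-all --config demo/run.yaml
python -m json.tool demo/results/stats/report.json
```

Selected output (seed 3):

```
"asymmetry_mark_asym":          { "statistic": 5.30,  "p_value": 1.1e-07 }
"peak_shift_mark_shift_CPG":    { "rho": 0.865, "p_value": 7.1e-21, "n": 66 }
"peak_shift_mark_shift_NONCPG": { "rho": 0.913, "p_value": 1.1e-26, "n": 66 }
"ctcf_enrichment":              { "chi2": 21.8, "p_value": 3.1e-06,
                                  "table": [[38, 28], [12, 54]] }
```

Reading these numbers: the promoter mark simulated with 70% of its mass
upstream at CpG promoters (vs 45% at non-CpG) produces a strongly
significant rank-sum difference in asymmetry scores; the gene-body mark
whose peak drifts downstream with expression tier yields the expected
positive Spearman correlation between per-gene peak position and
expression rank; and CTCF-site overlap is enriched at CpG promoters
(38/66 vs 12/66; χ² without continuity correction). `demo/results/`
also contains the six class-by-tier average/smoothed profiles per track
(`profiles/`), background-subtracted profiles (`background/`),
expression-ordered heatmap matrices (`heatmaps/`), and a manifest with
input checksums; reruns are byte-identical.

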