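# glycomud

Middle-up-down glycoproteomics in Python: in silico glycopeptide
libraries, accurate-mass glycoform identification, and grouped
glycosite biomarker statistics.

## The problem

Site-specific glycosylation of serum glycoproteins changes in cancer,
but classical glycoproteomics needs tandem MS and heavy sample
preparation. The *middle-up-down* approach reads glycopeptides from a
single-stage MS run instead: a target glycoprotein (the reference
workflow uses serum haptoglobin, whose β-subunit carries four N-glycan
sites — Asn184; Asn207 and Asn211; Asn241 — on three tryptic peptides
called GP1, GP2 and GP3) is digested with trypsin, the deconvoluted
neutral masses are matched against an *in silico* glycopeptide library,
and the resulting samples × glycoforms matrix feeds a biomarker
discovery procedure. `glycomud` implements the computational side of
that platform end to end, plus a synthetic cohort generator so every
stage can be validated without clinical data.

## The method

**Library.** Trypsin cleaves C-terminal to K/R, not before P; N-glycan
sequons are N-X(≠P)-[S/T]. For each sequon-bearing backbone *p* and a
panel of glycan compositions *g* = (n_Hex, n_HexNAc, n_Fuc, n_NeuAc),
theoretical neutral monoisotopic masses are

    M(p, g) = Σ residue masses(p) + H2O + Σ mods
            + n_Hex·162.05282 + n_HexNAc·203.07937
            + n_Fuc·146.05791 + n_NeuAc·291.09542

For a two-site backbone, all unordered glycan pairs plus all
single-occupancy forms are enumerated (41 glycans → C(41,2) + 41 + 41 =
902 glycoforms) and forms with equal *total* composition — hence equal
mass — are merged into one library entry.

**Identification.** Each feature with S/N ≥ 5.0 is assigned to the
library entry minimising |10⁶·(m_obs − m_theo)/m_theo| within a 10 ppm
tolerance; ties are flagged ambiguous and excluded from quantitation.

**Statistics.** Glycoforms detected in ≥ 70% of all samples enter a
two-tailed Welch t-test on raw abundances; markers require p < 10⁻⁵
and detection frequency ≥ 90%. Each marker gets a ROC AUC
(AUC = P(score_cancer > score_control) + ½P(tie), the normalised
Mann–Whitney U); each GP group gets a combined logistic-regression
panel scored in-sample. Glycans are rolled up into five biosynthetic
classes (HM, C/H, C/H-F, C/H-S, C/H-FS) for log2 fold-change and
relative-abundance comparisons.

## Worked example

`examples/04_biomarker_discovery.py` simulates a 47-control/43-cancer
cohort with 2-fold increases planted on the 23 most abundant
fucosylated-sialylated glycoforms (6 GP1 + 8 GP2 + 9 GP3) and runs the
full discovery procedure:

```
cohort: 47 control / 43 cancer; 23 planted 2-fold C/H-FS markers
glycoforms quantified: 559; after 70% frequency filter: 434
selected markers (p<1e-5, freq>=90%): 23  [recovered 23/23 planted, 0 false]

 marker                                   p-value    AUC   log2FC
  GP1:Hex4HexNAc3Fuc1NeuAc1               9.12e-08  0.864  +1.00
  ...
combined logistic panels (in-sample):
  GP1: 6 members, best individual AUC 0.910 -> combined AUC 0.999
  GP2: 8 members, best individual AUC 0.913 -> combined AUC 1.000
  GP3: 9 members, best individual AUC 0.945 -> combined AUC 1.000
```

Every selected marker's log2 fold change sits near the planted value of
+1, each marker's AUC reflects a 2-fold shift at ~40% CV, and the
combined panels beat their best members — the behaviour the discovery
procedure is supposed to show when real group differences exist. The
other examples build the library (`01`), identify glycoforms in a
single sample (`02`), and run replicate QC by per-group Pearson
correlation (`03`).

The same workflow is scriptable from the shell:

```sh
glycomud simulate --out cohort/ --seed 0
glycomud run --fasta hp.fasta --glycans glycans.csv \
             --features cohort/features.csv --manifest cohort/manifest.csv \
             --out run/
```

## Notes on the packaged data

The shipped haptoglobin FASTA is a synthetic stand-in: its β-subunit
region (residues 162–406, containing all four glycosites with canonical
numbering) is exact, while the signal/α region is filler that preserves
length and tryptic boundaries. The default 41-glycan panel is a
representative serum N-glycan list (see `docs/methods.md`); both are
replaceable by user files via `build_library(fasta, glycans_csv)`.
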