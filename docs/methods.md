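# Methods

This note records the models, conventions and numerical choices behind
`glycomud`, and what the synthetic validation does and does not show.

## Mass model

All masses are neutral monoisotopic daltons. A peptide's mass is the
sum of standard amino-acid residue masses (from pyteomics) plus one
water plus fixed-modification deltas; carbamidomethyl-C (+57.02146 Da)
is applied by default because the platform's sample preparation reduces
and alkylates cysteines (the three haptoglobin glycopeptide backbones
contain no cysteine, so their masses are unaffected). Glycans
contribute *residue* (dehydrated) monosaccharide masses — Hex
162.05282, HexNAc 203.07937, Fuc 146.05791, NeuAc 291.09542 — because
the glycan condenses onto the peptide; this makes glycan mass exactly
linear in the composition counts. The packaged defaults reproduce the
published haptoglobin glycopeptide masses to three decimal places.

## Digestion and sequons

Trypsin: cleave C-terminal to K/R unless the next residue is P. This
community-standard rule, with 0 missed cleavages by default (the three
reference backbones are fully tryptic; missed cleavages are
configurable), tiles the protein exactly. Sequons are N-X(≠P)-[S/T]
with the S/T required to lie inside the peptide; on the canonical
haptoglobin numbering this recovers exactly Asn184, 207, 211, 241.
Sequon-bearing backbones are labelled GP1, GP2, … in protein order.

## Library combinatorics

One glycan at most per sequon, at least one site occupied, site order
not distinguished (identification is by mass alone, so site-resolved
assignments are unknowable from a match). A two-site backbone with n
glycans therefore has n(n+1)/2 unordered pairs plus n single-occupancy
forms — 902 for n = 41. Glycoforms with equal total composition have
equal mass and are merged into one entry; all contributing site
assignments are kept, and reported glycan localisation is the *set* of
consistent assignments, never a specific site. Singly- and
doubly-occupied forms with equal totals merge too, and the entry's
`occupied_sites` reports the largest consistent occupancy. Unoccupied
(naked) peptides are not library members. A `pairs_only` switch
restricts multi-site enumeration to full occupancy for comparison.

With the packaged 41-glycan panel the two-site backbone dedups to 477
entries; the count depends on which 41 compositions are in the panel.

## The default glycan panel

The panel shipped in `data/default_nglycans_synthetic.csv` is a
representative serum N-glycome stand-in, not a measured list: Man5–Man9
high mannose, undecorated, fucosylated, sialylated and
fucosylated-sialylated complex/hybrid compositions, 41 in total, unique,
including every composition in the published reference mass table and
expressing every published two-site total as a pair. Users with a
measured panel for their glycoprotein should supply it as CSV
(`label,hex,hexnac,fuc,neuac`).

## Glycan classes

HM requires exactly 2 HexNAc (the chitobiose core), 5–9 Hex (Man5–Man9)
and no decoration; hexnac = 2 with hex < 5 (or > 9) is classified C/H.
Everything else is complex/hybrid, subdivided by fucose/sialic-acid
presence into C/H, C/H-F, C/H-S, C/H-FS. The rule is total and
deterministic. Two-site totals are classified on the total composition;
a total with fuc > 0 and neuac > 0 counts as C/H-FS even though the
decorations might sit on different site glycans — a composition-level
convention, recorded here because mass-only identification cannot do
better.

## Matching

Each feature is assigned to the entry minimising |ppm| within the
tolerance (10 ppm default), implemented by binary search over the
sorted mass list and verified in tests against a full-scan oracle.
Exact ties at the minimal |ppm| (e.g. duplicated masses across
backbones) are flagged ambiguous and excluded from quantitation — a
conservative choice; with the haptoglobin library the closest pair of
entries is ~7 ppm apart, so ambiguity is rare at 1 ppm mass accuracy.
Retention time is carried through for reporting but never used as a
match constraint. S/N filtering (≥ 5.0, boundary inclusive) happens
before matching. Multiple unambiguous features hitting one entry in one
sample are summed; non-detected cells are zero-imputed. Both policies
are recorded in the matrix metadata: zero-imputation biases group means
of low-frequency glycoforms downward, which is why the frequency
filters matter for the t-test's validity.

## Statistics

*Frequency filter*: detection fraction over all samples pooled
(boundary inclusive); the "in all samples" phrasing of frequency
criteria is read as pooled, with a per-group option
(`frequency_scope="per_group"`).

*Two-sample test*: Welch (unequal-variance) t-test by default — the
variance assumption is the safer default when group variances differ,
with `equal_var=True` available for fidelity to pooled-variance
conventions. Zero variance in both groups gives p = 1 for equal means,
p = 0 otherwise. No multiple-testing correction enters selection (the
stringent p < 10⁻⁵ cutoff is used raw); a Benjamini–Hochberg column is
reported alongside. Under a simulated null the test's type-I error at
α = 0.05 is within 0.05 ± 0.01 and p-values are uniform (checked in the
test suite at 10,000 replicates).

*Selection*: p < threshold strictly, frequency ≥ threshold inclusively,
both required (defaults 10⁻⁵ and 0.90).

*ROC*: cancer is the positive class; AUC is reported raw (no folding
around 0.5), computed as the normalised Mann–Whitney U with ties
counted half.

*Combined panel*: features standardised, maximum-likelihood logistic
regression via statsmodels, scored by the in-sample linear predictor.
In-sample scoring mirrors the platform's reporting convention and
overstates generalisation — a documented limitation, not a bug; no
cross-validation is attempted. When the fit is degenerate (perfect
separation is routine at these effect sizes and n = 90) a
ridge-penalised logistic fit (C = 1) is used and flagged
`separation_fallback`; because the ROC is invariant to monotone
transforms this changes coefficients, not the single-marker AUC
identity.

*Class summaries*: per (GP group, class), class abundance is the sum of
member glycoforms; log2FC uses raw class-abundance group means (NaN and
flagged when a group mean is zero — never ±∞); relative abundances are
normalised within (sample, GP group) — the denominator choice is a
convention and is recorded in the output. *Site map*: glycoforms ranked
by share of group abundance, tiers > 10%, 1–10% (≥ 1% inclusive),
< 1%.

## Synthetic cohorts

The generator emulates what the analysis assumes about real serum
cohorts, no more:

- **Baseline profile** — a fixed per-glycoform abundance pattern: the
  bi-antennary di-sialylated glycan Hex5HexNAc4NeuAc2 takes 55% of each
  group's glycan pool (matching the dominance seen in serum
  haptoglobin), the rest spread lognormally (σ_ln = 1.2, several orders
  of magnitude). Two-site entry weights are sums of products of glycan
  weights (independent site occupancy). The profile is drawn from
  `profile_seed`, separate from the cohort seed: the glycosylation
  pattern is a property of the biology being emulated, so replicate
  cohorts share it.
- **Abundances** — lognormal around baseline, σ_ln = 0.4 (~40% CV,
  typical of label-free LC–MS), group totals 10⁷ arbitrary units.
- **Effects** — multiplicative fold changes on chosen glycoforms in the
  cancer cohort. The default scenario plants 2-fold on the
  highest-baseline C/H-FS glycoforms, 6/8/9 per GP group, echoing the
  relative marker richness of the three haptoglobin glycosites.
  Planting is restricted to detectable glycoforms by construction:
  effects planted below the detection floor are unrecoverable by any
  selection rule and would measure the dropout model, not the pipeline.
- **Dropout** — detection probability logistic in log10 abundance
  (midpoint 10², slope 0.4 decades), so dominant glycoforms are always
  seen and the low tail drops out, making the frequency filters
  consequential.
- **Mass error** — observed mass = theoretical × (1 + ε),
  ε ~ N(0, 1 ppm); **S/N** lognormal (median ≈ 20, ~1% below the 5.0
  filter); **decoys** — 25 per sample, uniform over the library mass
  range but ≥ 50 ppm from every library mass, so they can never match.
- **Cohort sizes** — 47 control / 43 cancer by default.
- All randomness flows from one integer seed through named
  `numpy.random.SeedSequence` children; identical seed + config gives
  byte-identical outputs.

What passing the end-to-end tests shows: under these conditions the
pipeline recovers planted 2-fold C/H-FS markers at ≥ 90% with < 1 false
marker on average, estimates their log2FC without material bias, and
its combined panels beat their members in-sample. What it does not
show: performance on real sera — real cohorts have between-run
intensity drift, correlated glycoform noise (shared biosynthesis),
non-lognormal tails, batch effects and co-eluting isobaric
interferences, none of which are simulated. Published clinical marker
counts and AUCs are properties of the study sera and are not
reproducible from synthetic data; the validation surface here is
property-based by design.

## Problem sizes

Default validation scales were chosen to exercise the statistics at the
study's own cohort size: 20 simulated 47/43 cohorts for the recovery
suite, 10,000 replicates for null calibration, 100 random
library/feature sets for matcher-oracle equivalence. The whole test
suite runs in well under a minute of CPU.

## Known limitations

- No MS/MS scoring exists, so no decoy-library FDR can be calibrated;
  identification confidence rests entirely on mass accuracy and library
  sparsity.
- No retention-time prediction or alignment; RT is reporting-only.
- No isotope envelopes, charge states or chromatographic integration —
  the input contract starts at deconvoluted neutral masses.
- In-sample panel AUCs are optimistic; treat them as descriptive.
- The packaged FASTA's α region is synthetic filler (the β-subunit is
  exact); digest output outside the glycopeptide region is illustrative
  only.
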