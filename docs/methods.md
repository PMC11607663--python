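# Methods

This note documents the models, conventions, and numerical choices behind
`lipidqa`, in the order the pipeline runs.

## Nomenclature and composition templates

Shorthand names follow the LIPID MAPS convention as used for plasma
profiling: a subclass head token and a chain list, where a single `C:D`
token is sum-composition (*species*) level, `_` separates chains of known
composition but unknown position (*molecular species*), and `/` fixes
sn-positions. Sphingolipids carry a `d` prefix on the backbone chain
(`Cer(d18:1/24:0)`); ether lipids carry `O-` (plasmanyl) or `P-`
(plasmenyl) prefixes. Because the alkyl/alkenyl distinction was not fully
resolved for several subclasses, `O-` names in the pooled subclasses
(PC O/P, PE O/P, LPE O/P) carry a `plasmalogen_unresolved` flag; LPC is the
one head whose `O-` form is bookkept as its own subclass (LPC O).

Neutral compositions are closed forms in (NC, DB) per subclass, assembled
from standard scaffolds (e.g. TG = glycerol + 3 acyl − 3 H2O →
C(NC+3)H(2NC−2DB+2)O6; PC → C(NC+8)H(2NC−2DB+16)NO8P; acylcarnitine →
C(NC+7)H(2NC−2DB+13)NO4). Every template is unit-tested against a
hand-assembled reference formula, and two structural identities are
enforced as properties: +1 carbon adds exactly CH2 and +1 double bond
removes exactly H2. Ether (`O-`) chains replace one ester oxygen
(−O +2H relative to the acyl template); plasmenyl (`P-`) chains are the
ether composition with one extra double-bond equivalent (the vinyl-ether
double bond is not counted in the shorthand DB). Monoisotopic masses come
from a vendored CODATA/NIST table (C = 12 exactly), cross-checked in the
tests against pyteomics as an independent oracle.

Kendrick quantities use the CH2 base unit with nearest-integer rounding of
the Kendrick mass, the standard convention for homologous-series plots.

## Adduct chemistry and hierarchy consensus

The shipped registry holds the singly charged forms observed on this
method: ESI(+) [M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH4]⁺, [M+C2H7N2]⁺ (interpreted
as the ammonium–acetonitrile cluster NH4·CH3CN, consistent with the mobile
phase), and the water-loss in-source fragment; ESI(−) [M−H]⁻, acetate, the
choline methyl-loss fragment, and sodium-acetate cluster ladders
[M+CH3COO+n·NaC2H3O2]⁻ for n = 1..6 (repeat mass 82.0031 Da). Ion m/z is
(n·M + m(added) − m(removed) − z·mₑ)/|z|.

Feature grouping accepts a profile only when two or more co-eluting
features (within 0.2 min) agree on one neutral mass (within 10 ppm) under
distinct adducts — mass determined unambiguously by adduct co-presence —
and resolves conflicts greedily by descending summed intensity after
canonically sorting the input, so results are permutation-invariant.

Consensus building admits only profiles with ≥ 2 adducts. cQualForm marks
an adduct *required* at ≥ 90% presence within the subclass and *optional*
otherwise; cSquantForm orders adducts by mean within-profile intensity rank
and merges consecutive ranks into one tier when the pairwise order is
reproduced in < 80% of profiles observing both. Both thresholds are
exposed in the pipeline config; they are the package's own defaults since
no canonical values exist for this construction. Intensity ties break by
registry order for determinism. AHRL is the number of consecutive tiers,
starting at tier 1, with at least one observed member. Compliance
screening reports foreign adducts (outside cQualForm) and hierarchy
inversions, where a lower-tier adduct's intensity is **greater than or
equal to** an observed higher-tier adduct's — the ≥ convention matters for
reproducing potassium/sodium exception counts.

For the sphingolipid chain-isomer elution rule, the wording "unsaturation
on the acyl chain of the backbone" is interpreted, consistently with the
worked Cer example, as the double-bond count of the sphingoid backbone:
within one sum composition, more backbone unsaturation elutes later
(opposite to the glycerophospholipid rules, attributable to the trans
backbone double bond versus cis acyl double bonds).

TG MS/MS bookkeeping matches neutral losses from [M+NH4]⁺ precursors
against FA(c:d) + NH3 for c = 2..30, d = 0..min(8, c/2), at 10 ppm; a
fragment assignable under ≥ 2 precursors is chimeric and makes the
spectrum convoluted.

## Retention rules

The 19-min program is segmented I1 [0,1), G1 [1,3.5), I2 [3.5,10),
G2 [10,11), I3 [11,17.1), G3 [17.1,19]; segment assignment is half-open
with the final endpoint mapped to the last segment, so it is total on the
run. Monotonicity checks use strict inequality with a 0.01-min equality
tolerance (instrument RT resolution): a carbon series violates when RT
drops by more than 0.01 min between consecutive members, an unsaturation
series when it rises by more than that. TG ECN clustering flags (i)
within-series RT spread > 2 × 0.2 min, (ii) non-increasing series medians,
and (iii) narrowing per-ECN-unit RT gaps (the gap between series should
widen as ECN grows; gaps are normalized per ECN unit so unevenly spaced
series compare fairly). Replicate RT uncertainty is the width of the
t-based 95% CI of the mean, flagged above 0.2 min.

Expected-RT validation interpolates piecewise-linearly on the matching
reference series (carbon series at the candidate's DB, unsaturation series
at its NC), extrapolating linearly at the ends; no functional form beyond
local linearity is assumed. Residuals beyond 0.2 min are hard flags,
except that candidates outside the gross subclass RT range get a *soft*
flag only: out-of-range species (e.g. short-chain TG eluting well before
the main TG region) are plausible extensions, not automatic false
positives, and the final call is left to the caller.

## m/z QC

Errors are signed ppm against the theoretical adduct m/z, reliable within
±10 ppm. Z-scores standardize within subclass using the sample (n−1) SD —
subclass groups are small. Zero-SD subclasses assign Z = 0; singletons are
skipped with a warning. The summary counts |Z| < 2 strictly, so a boundary
value of exactly 2 falls in the 2–3 band (documented in the summary
output).

## Targeted extraction

Find-by-formula matches, per selected adduct, the most intense feature
within 10 ppm and ±0.2 min of the database values (defaults mirror the
method's reliability bound and RT-robustness ceiling; both configurable).
Isotopologue patterns are predicted by convolving per-element nominal-mass
abundance ladders, normalized to M = 1 (the M+1/M ratio of a TG-sized
C55H102O6 is ≈ 0.61). The isotope score is 1 minus the largest relative
deviation of observed from predicted ratios over M+1..M+2, with an
absolute floor of 0.05 in the denominator so negligible predicted ratios
(e.g. M+1 of water) cannot dominate; threshold 0.9. A ratio-agreement
score was chosen over cosine similarity because cosine over three points is
dominated by the monoisotopic component and cannot reject a decoy whose
M+1 is off by a factor of two (cosine ≈ 0.97 for a TG-sized formula),
which is exactly the failure mode the screen exists for. When no
isotopologue peak is found at all the score is undefined and does not count
against the match — absence of isotope information is not evidence of a
mismatch. The quantifier is the tier-1 cSquantForm adduct when available,
else the most intense match. Feature-table areas are used as-is; mzML
input is flattened to centroid rows and integrated across scans by the
window logic.

Blank subtraction removes the entry-wise mean blank area (floored at 0)
and flags entries with sample/blank mean ratio < 3 as background. TUS
normalization divides each sample column by its sum (idempotent by
construction). Coverage counts entries detected in ≥ 1 sample.

Metrics operate on blank-subtracted TUS areas: abundance-corrected
averages are area-weighted means of NC or DB over detected members
(invariant to uniform rescaling); the four O/P-pooled ether subclasses are
excluded from unsaturation averages because their DB bookkeeping is
ambiguous. Mann-Whitney U tests are two-sided (scipy's exact method where
applicable), Bonferroni-adjusted by the number of pairs. Profile
correlations are squared Pearson coefficients of log10 abundance
percentages with zeros excluded pairwise; a linear-scale variant is
available since the published analyses do not pin the transform.

## Synthetic lipidome generator

The generator's defaults are the study conditions: 592 species over the 20
subclasses at the curated census (TG 135, PC 93, PC O/P 64, …), drawn
without replacement from per-subclass (NC, DB) grids spanning realistic
plasma ranges. RT is additive per subclass — positive carbon slope,
negative double-bond slope, intercepts calibrated so each subclass elutes
inside its observed window — which guarantees both monotonic rules by
construction; TG instead use a convex quadratic in ECN
(6.5 + 0.08·ECN + 0.002·ECN²), so same-ECN TG co-elute exactly before
jitter and inter-series gaps widen with ECN. Adduct intensities follow
per-subclass tier ratios (1 : 0.30 : 0.10 : 0.03) with log-normal
rank-preserving noise (σ = 0.2 log units; adjacent-tier inversion
probability ≈ 10⁻⁵); species base areas are log-normal (σ = 0.8), the
standard distributional choice for MS areas. m/z error is a per-subclass
bias (defaults cycle through ±3 ppm) plus N(0, 1 ppm) noise; RT jitter is
N(0, 0.02 min), consistent with a replicate CI95 width well under the
0.2-min ceiling; per-adduct dropout defaults to 1.5%, matching the small
fraction of database entries not observed in a cohort of real runs.
Blanks contain only uniform background features and, in negative mode, the
sodium-acetate ladder anchored on the acetate anion.

What the generator does **not** emulate: chromatographic peak shapes,
isomer-level chain structure (species are sum-composition), detector
saturation, correlated noise between adducts of different species, and
isobaric/isomeric interference. Tests passing on synthetic data therefore
demonstrate the *internal consistency* of the rule implementations and
their recovery behavior under the stated noise model, not performance on
real chromatograms.

## Problem sizes and determinism

Round-trip and recovery checks run on the full 592-entry database with 2–3
samples per polarity and one blank, the smallest batch that exercises both
polarities, blank subtraction, and coverage; bias-recovery pools three
sample runs per polarity so each subclass contributes enough draws for a
±0.5 ppm check. The family-wise error simulation uses 1000 global-null
replicates of three n = 8 groups. All randomness flows through
`numpy.random.default_rng` seeded from a single integer; fixed seeds make
every database, run, and test reproducible bit-for-bit.

## Known limitations

- Composition templates cover the 20 database subclasses only; oxidized
  lipids, stereochemistry, double-bond positions and HexCer glycan isomers
  are out of scope.
- Multiply charged ions are not modeled (|z| = 1 throughout the registry).
- The hierarchy-compliance summary is reported against two denominators
  (all entries, and non-reference entries only); the choice between them is
  a reporting convention, not a computed fact.
- Expected-RT screening assumes locally linear series; strongly curved
  series would need a richer reference model.
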