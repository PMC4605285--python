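# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic-data generator does and does not emulate.

## Mass model

All masses are monoisotopic, computed from a single hard-coded atomic-mass
table (H 1.0078250319, C 12, ¹³C 13.0033548, N 14.0030740052,
O 15.9949146221, P 30.97376151; proton 1.00727646 for charging). An n-mer
is the sum of its nucleoside compositions plus (HPO₃ − H₂O) per
phosphodiester bond; terminal chemistry adds HPO₃ per phosphate (5′-ppp =
3 × HPO₃; 2′,3′-cyclic phosphate = linear − H₂O). Negative-mode m/z is
(M − n·1.00727646)/n. Isotope labels substitute ¹²C → ¹³C in the
composition itself (G: 10, C/U: 9 substitutions), and enrichment is
treated as complete: heavy species are matched at the fully labeled mass.
A float fast path caches per-residue masses; the full
elemental-composition route is retained as the reference and the two are
asserted equal in the tests.

Default precursor charges are enumerated as 1..⌈M/1000⌉, which covers 2−
for a ~1.6 kDa 5-mer through 4− and beyond for a ~5.7 kDa 18-mer, the
states at which such ions are actually observed. One consequence is a
benign asymmetry: a heavy species can cross a boundary of this enumeration
that its light twin does not reach, leaving a partner-less heavy ion at
one charge; pairing at the shared charges is unaffected.

MS/MS ladders use the four dominant RNA CID series, c/y (5′/3′ of the
phosphodiester oxygen) and w/a−B, at charge 1. Complementarity
(c_i + y_(n−i) = M + H₂O) is exact by construction and asserted to 1 µDa.
The a−B ion loses the 3′-terminal base of the prefix *with its
base-placement modifications*, which is what makes the methylated-base
loss from the precursor diagnostic for base- vs ribose-methyl placement;
positional isomers on the base ring (m¹A vs m⁶A) are not distinguishable
from CID data and are reported under one canonical code per base.

## Digestion model

RNase T1 cleaves 3′ of G, RNase A 3′ of C/U; both leave 5′-OH and a
3′-phosphate (linear by default; the 2′,3′-cyclic variant, −18.0106 Da,
is available). A site whose residue carries a 2′-O-methyl is not cleaved —
the 2′-OH is the transesterification nucleophile — so a partially
methylated site appears as cut products (weight 1−f) plus a merged
fragment carrying the methyl (weight f). Base modifications do not block;
pseudouridine is still a pyrimidine for RNase A. Coordinates are 1-based
inclusive throughout; a 0-based BED export exists at the I/O boundary.
End fragments inherit the parent termini, so the in-vitro reference's
5′-triphosphate (vs the cellular 5′-monophosphate) is carried into its
5′-end fragment mass. Missed cleavages default to at most one.

## Search and identification

The theoretical index holds every fragment × {light, heavy} × charge ×
variable-modification state: up to two unlocalized methyls (+k × CH₂) on
the light channel, optional specific single-site mods (e.g. ac⁴C), and
optional cyanoethyl states; the heavy reference is unmodified by
construction and gets none. Matching is binary search at 20 ppm (MS1) with
all interpretations returned; the pipeline then keeps, per feature, only
interpretations within 1 ppm of the best one (winner-take-all with a tie
margin). Features whose surviving interpretations still span more than one
fragment identity — anagrammatic fragments have *identical* elemental
composition, so this genuinely happens — are flagged ambiguous and
excluded from quantification and Ψ calling; resolving them is what
complementary digests and RNase H segmentation are for, and the
redundancy analyzer suggests the cut windows.

Localization scores a candidate placement by the fraction of its c/y/w/a−B
ladder matched at 750 ppm (MS2), plus a 0.1 bonus when the
methylated-base-loss diagnostic agrees with the placement. A top candidate
matching less than 30% of its ladder is rejected outright (a mass
coincidence, not an identification). Ranking is deterministic with a
position/code tie-break.

## Quantification

The estimator uses the *unmodified* light species against the heavy
reference — modified species may ionize differently — so
f̂ = 1 − I_light,unmod/I_heavy per observation (one per charge state ×
replicate × missed-cleavage variant), under the default 1:1 mixing
assumption (an optional normalization factor is the median light/heavy
ratio over modification-free fragments). Per-observation estimates are
averaged **unclipped** and the clip to [0, 1] is applied to the aggregated
value: clipping before averaging would bias sites near the boundaries
upward by several percent under multiplicative noise. A fragment whose
heavy reference is observed with no co-eluting unmodified light partner is
scored fully modified. Fragment-level fractions are attributed to a site
only when that site is the single localized/called site in the fragment's
span and the fragment is not the boundary product of a cleavage-blocking
methyl (whose depletion reflects the neighbor's occupancy); multi-site
fragments fall back to the directly observed modified-species share and
are exported with a shared-evidence flag.

## Pseudouridine calling

Cyanoethylation converts Ψ with probability 0.30 and U with 0.05 per
molecule (the optimized-condition efficiencies; configurable). For a
fragment with k uridine-type residues and modified fraction f (from the
pre-derivatization run), the expected CE'd fraction of the light signal is
1 − (1−u)ᵏ under the all-plain-U null and
1 − [(1−f)(1−u)ᵏ + f(1−u)^(k−1)(1−ψ)] when one residue is Ψ. The observed
fraction (intensity-pooled across charges — a +53 Da shift can change the
charge enumeration, so per-charge fractions would be biased) is assigned
to the nearer hypothesis; a one-sided z-test against the null (assumed
fraction noise 0.01) feeds Benjamini–Hochberg control across fragments at
FDR 0.05. Equal efficiencies make the hypotheses indistinguishable and
the test abstains. The Ψ position within a multi-U fragment is read from
the MS/MS ladder of the most intense CE'd species; without MS/MS it is
assigned only in single-U fragments, otherwise reported as an interval.
Without a CE run, a plain-mass light species at a shifted retention time
in a fragment with positive modified fraction is reported as Ψ evidence.

## Simulator

The generator emits, per digest fragment: the heavy reference species
(relative intensity 1; 5′-ppp on the 5′-end fragment), light species split
over modification-occupancy subsets (independent per-site Bernoulli
occupancy; cleavage-blocking sites are handled at the fragmentation-
pattern level so impossible species — a cut 3′ of a present 2′-O-methyl —
never arise), and missed-cleavage variants at 10% relative abundance.
Retention times are deterministic per fragment (hash-placed on a 60-min
gradient) with class-wise shifts for modified species (defaults: Ψ −48 s,
2′-O-methyl +90 s, base methyl +60 s, cyanoethyl +60 s per adduct — the
direction of such shifts varies in practice and no published magnitudes
exist, so these are plausible configurable constants). Noise is
multiplicative lognormal intensity error (CV 0.05), Gaussian m/z error
(3 ppm), and Gaussian rt jitter (2 s); a fixed seed gives bit-identical
output. Species below 10⁻⁵ of the base intensity are dropped (a detection
floor). Cyanoethylation states are aggregated per adduct count (same-count
placements are isobaric): the count distribution is exact
(Poisson-binomial), counts above 2 are lumped into one species so
intensity is conserved, and the modal placement (most reactive residues
first) carries the MS/MS. MS/MS spectra, when enabled, are complete
theoretical ladders plus the per-residue base-loss peaks — real spectra
are neither complete nor clean, so localization performance on simulated
data is an upper bound.

The designer `design_ground_truth` builds validation experiments the way
one would at the bench: T1-sized segments, one site per fragment, the
fragment downstream of a blocking Gm left free, Ψ fragments with
enumerable U counts, site-class composition echoing eukaryotic rRNA maps
(Ψ and 2′-O-methyls dominant), occupancies cycling through
{1.0, 0.997, 0.9, 0.76, 0.68, 0.44}, and — because ~100 random fragments
always contain a few identical-composition pairs — ground-truth sites are
kept off mass-confounded fragments (verified after placement against the
full simulated species inventory at 5 ppm). What passing the no-noise
identity test shows is therefore that the *inference chain* is exact on
identifiable inputs; it does not show robustness to chimeric spectra,
co-elution interference, or ionization-efficiency differences between
modified and unmodified species, none of which are modeled.

## Problem sizes and defaults

The validation map uses 30 sites on a ~600-nt parent (one T1 digest, with
CE and MS/MS); stoichiometry recovery uses 8 Ψ sites at occupancies
{0, 0.22, 0.44, 0.68, 0.76, 0.90, 0.997, 1} with 8 replicates, pooling
~100–200 observations per site across charges and digest variants; the
calibration series spans heavy/light ratios 0.1–10 with 4 replicates.
Search defaults: 20 ppm MS1, 750 ppm MS2, ≤2 variable methyls, ≤1 missed
cleavage, 30 s co-elution window (0.5 min on a 60-min gradient), 300 s
rt gate for crediting post-CE species to a fragment.

## Known limitations

* Quantification assumes equal ionization of light and heavy twins
  (exactly true — they are chemical twins) but attributes multi-site
  fragments only qualitatively.
* Base-ring positional isomers of methylation are reported under canonical
  codes (m⁶A, m⁵C, m⁷G, m³U); distinguishing them needs orthogonal data.
* The charge-enumeration heuristic is a proxy for an instrument's actual
  charge-state envelope.
* mzML ingestion is targeted (XIC against a theoretical index), not a
  general feature finder, and reads MS1 float arrays (32/64-bit, optional
  zlib) only.
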