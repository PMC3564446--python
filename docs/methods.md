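# Methods

## Scope and design

`thiolox` analyses differential thiol-trapping (light/heavy ICAT) time
courses of chronologically aging *S. cerevisiae*: per-peptide % thiol
oxidation from paired isotope envelopes, trajectory classification into
seven oxidation classes, early-target detection, cysteine
flanking-sequence enrichment, glutathione/NADPH redox computations, and an
integrated event timeline. Peptide identification, retention-time
alignment, FDR control, and cross-run intensity normalization are out of
scope: spectra arrive centroided and already attributed to a peptide, and
the reduced-form m/z is an input rather than computed from sequence.

## Envelope-pair quantification

Each labeling state *k* = 0..*n* of an *n*-cysteine peptide is looked up
at m/z = reduced_mz + *k*·Δ/charge with Δ = 9.0302 Da per heavy label
(nine ¹³C substitutions; a "nominal" 9.0 Da mode reproduces textbook
18-Da-per-2-Cys arithmetic). An envelope is integrated as the sum of the
most intense peak within ±0.1 Da (a MALDI-TOF-scale tolerance,
configurable) of each of the first five isotopologue positions, spaced by
1.0033548378/charge. This deconvolution-free integration is adequate
because consecutive labeling states are ~9 Da apart — far beyond any
5-isotopologue envelope. Correction for residual envelope overlap between
states is not implemented.

An envelope whose monoisotopic position has no matching peak is a flagged
zero, not an error; a spectrum with zero total signal yields a flagged,
non-numeric result. Fractional oxidation is the label-weighted ratio
100·Σ*k*·I_k/(*n*·ΣI_k). Two-state mode (*k* ∈ {0, *n*}) is the default
because disulfide-coupled vicinal cysteine pairs oxidize jointly; full
mode serves peptides with independent thiols. The two agree exactly
whenever the intermediate states are empty, which is tested.

Replicate aggregation uses the arithmetic mean and sample SD over
quantifiable replicates and masks any peptide-day observed in fewer than
3 replicates (configurable). The strict matrix filter keeps only peptides
observed at every sampled day, the criterion behind
"reproducibly identified in all samples" peptide sets.

## Trajectory classes

Missing values are imputed by k-nearest neighbours: 5 neighbours, plain
Euclidean distance over the columns both rows have observed, donor rows
restricted to those observed on the target column; rows with ≤ 30% of
values known are dropped and reported. This is implemented directly (about
30 lines) rather than via `sklearn.impute.KNNImputer`, whose
`nan_euclidean` rescaling and lack of row-dropping differ from the
contract above. Imputed values stay within [0, 100] by construction
(means of in-range donors, clipped defensively).

k-means (Euclidean, best of 10 restarts, seeded — `sklearn.cluster.KMeans`)
provides the unsupervised partition. The scientific labels come from
threshold rules evaluated in the priority order F, G, D, E, A, B, C so
that labels are mutually exclusive and early risers outrank the general
pattern:

* F: range < 15 points and max < 30%;
* G: min ≥ 50% and no day reaches 1.5× the day-0 value;
* D/E: value at the first/second early day ≥ 1.5× day 0 **and** the rise
  is ≥ 10 points (the absolute floor suppresses spurious 1.5-fold calls on
  near-zero baselines);
* A/B: day 0 < 30% and the collapse-day/late-day value > 50%;
* C: day 0 ≥ 40% and the collapse-day value ≥ day 0 + 15 points.

The A/B log-phase ceiling is 30% (a stricter 20% reading also circulates;
the threshold is configurable). The F/G and C numeric rules operationalize
"remains reduced/oxidized" and "~50% start with a significant increase";
all seven thresholds live in one configurable record. Under caloric
restriction the sampling schedule skips day 6, so the nominal day-6 late
day maps to the first sampled day ≥ 6 (day 7). A flat trajectory at
exactly the 50% floor satisfies G — "never leaves the oxidized regime" —
by design.

Whether published class labels of this kind derive from k-means alone or
from threshold rules is ambiguous in practice; both are computed here and
can be cross-tabulated, with the rule classifier treated as authoritative
throughout.

## Early targets and sequence context

Early targets are the union of D/E-labeled peptides across conditions
(the conditions probe one cascade, time-shifted, so a peptide qualifying
under either counts). Day-cell flags use v_d ≥ 2·v_0, or v_d ≥ 1.5·v_0
with v_d strictly > 60% ("exceeding" read literally); fold changes with
v_0 = 0 are reported as undefined, not infinite. The summary counts
targets strictly above 45% oxidation at standard day 2 and their day-2
fold range, without asserting any particular count.

Windows span 5 residues either side of the identified cysteine, truncated
(never padded) at termini, with frequencies computed over actually counted
positions. Residue types: cysteine; D,E negative; K,R,H positive; F,W,Y
aromatic; S,T,N,Q polar; A,V,L,I,M,P,G nonpolar — H→positive and
G→nonpolar are package choices, and the whole table is replaceable.
Enrichment is frequency-based (occurrences, not per-window
presence/absence), normalized to the entire window library, central
cysteines excluded everywhere; the weighted mean of a cluster's ratios is
identically 1, which is tested. Cluster comparisons use a Pearson
chi-square on the 2×k type-count contingency (`scipy.stats
.chi2_contingency`, no continuity correction; df = k−1 = 5 with cysteine,
4 with cysteines removed; counts, not rescaled frequencies). A type with
zero expected count aborts with advice to merge categories. Logo output is
a per-position frequency TSV rather than a rendered graphic.

## Redox metabolites and timeline

E_GSH = E₀ + (RT/2F)·ln([GSSG]/[GSH]²), E₀ = −240 mV, R = 8.314462
J mol⁻¹ K⁻¹, F = 96485.332 C mol⁻¹, concentrations molar. T defaults to
303.15 K, the 30 °C cultivation temperature; the slope RT/2F is 13.062 mV
per ln-unit there (12.846 at 298.15 K). Because two GSH oxidize per GSSG,
E_GSH shifts by a computable constant under a uniform unit rescaling of
both concentrations — documented rather than hidden, and the unit-free
detections (NADPH onset, event ordering) are tested to be rescaling
invariant. GSH/GSSG are taken as molar intracellular concentrations; no
whole-cell-to-intracellular conversion layer is included.

The E_GSH shift day is the first day ≥ 15 mV above day 0. NADPH decline
onset is the first day after the series maximum at which NADPH ≤ 80% of
that maximum (drop fraction configurable; it operationalizes "rapid
decrease"). Between-condition delays are 24·(onset_CR − onset_std) hours.

Timeline events: NADPH decline, E_GSH shift, early-oxidation onset (first
day any peptide passes the D/E early-rise test), redox collapse (first day
the median oxidation of the A/B peptides exceeds 50%), and the 50%
viability crossing (linear interpolation between sampled days, the one
fractional-day event). Undefined events — e.g. no collapse under
hypometabolic cultivation — are carried as `none` and sort last.

## Synthetic data

The generator defines the study conditions the tests run under.

*Trajectories*: seven archetypes per condition, chosen so each satisfies
its own class rule with a comfortable margin at zero noise (e.g. standard
A = 20, 20, 22, 80, 90; D = 20, 45, 65, 80, 88). Four replicates (the
study's replicate structure), additive Gaussian noise of SD 5 percentage
points per replicate (measurement noise for these percentages is not
published; 5 points is a placeholder on the scale of typical label-pair
SDs), values clipped to [0, 100], optional Bernoulli missingness.
Classification operates on the replicate-mean matrix, as replicate-
averaged matrices are what gets clustered in practice; averaging four
replicates halves the effective noise. Under water cultivation the
archetypes deliberately stay flat (the collapse does not occur), so there
the labels record peptide identity, not a satisfiable rule.

*Peptide libraries*: residues i.i.d. from a background distribution —
default uniform over the 20 amino acids, a neutral null that callers can
replace with organism-specific frequencies — except in the ±5 window of
designated-class cysteines, where the cysteine probability is multiplied
by the planted boost and renormalized.

*Spectra*: isotopologue envelopes with a binomial shape from an
averagine-like carbon count (≈ 0.0444 C per Da, ¹³C abundance 0.0107),
two-state weights (1−f, f) by default, mixed binomial states opt-in,
multiplicative Gaussian peak noise (default relative SD 0.05).

*Metabolites*: curves anchored at the qualitative findings — NADPH peaks
near day 0.5 and declines (onset day 1 standard / day 3 caloric
restriction, a 48-h lag), E_GSH rises ≥ 15 mV by day 1 / day 3, ATP holds
at or above day-0 through day 5 / day 7, viability is logistic with 50%
crossings at day 7 / 11 / 16. GSH decays slowly from 8 mM and GSSG is
back-computed from the target potential via the Nernst relation, so the
generated couple reproduces the intended E_GSH exactly up to noise
(default 2% relative, with detection margins ≥ ~3 SD). A day-4
NADPH/NADP⁺ rebound is included in the standard-condition shape as an
observed-but-uninterpreted feature.

Seeds are mandatory; there is no hidden global RNG state, and identical
configuration plus seed is bit-identical.

**What passing tests do and do not show.** The generator produces
well-separated archetypes, Gaussian noise, and missingness that is
independent of signal. Real time courses have peptide-specific variance,
correlated replicate structure, chimeric and low-S/N spectra, and
trajectories genuinely intermediate between classes. Recovering ≥ 95%
correct assignments here validates the machinery (rules, imputation,
quantifier) under the stated conditions; it does not certify accuracy on
arbitrary real data, and dataset-wide counts from any particular study
(total identified peptides, database-overlap percentages, printed
p-values) are not reproducible without that study's full peptide library.

## Numerical choices and degenerate inputs

Envelope lookup takes the most intense peak per tolerance window (robust
to noise splinters); absence of the monoisotopic peak flags the envelope.
Sample SD uses ddof = 1 and is withheld below n = 2. Imputation warns and
uses all available donors when fewer than k exist; a column nobody
observed stays missing. k-means requires a complete matrix and k ≤ n
rows. Rule classification of a row missing a named day raises for a
single trajectory and yields `unassigned` in matrix scans, so partially
observed peptides survive a condition-wise pass (the bundled reference
dataset has rows without caloric-restriction measurements). Fold changes
at zero baseline are undefined; viability series must start ≥ 50% and a
never-crossing series yields a flagged `none`. Problem sizes in the test
suite (70–300 trajectories, 140-protein libraries, 200 simulated spectra)
were chosen as the smallest sets whose acceptance statistics have
comfortable margins.

## Known limitations

No isotopic-overlap correction between labeling states; no charge-state
deconvolution beyond the fixed per-peptide charge; CTWC-style two-way
clustering is replaced by the kNN imputation above; chi-square p-values on
small window sets are asymptotic; the timeline reports ordering and lags
but performs no significance testing on them.
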