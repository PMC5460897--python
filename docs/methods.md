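# Methods

## Residue charge model

Charges are Henderson–Hasselbalch ionization fractions at a fixed pH
(default 7.4, elementary-charge units): basic groups contribute
`+1/(1+10^(pH−pKa))`, acidic groups `−1/(1+10^(pKa−pH))`. The default
pKa set — Lys 10.40, Arg 12.00, His 6.10, Glu 4.40, Asp 3.90, Cys 8.43,
α-amino 9.80, α-carboxyl 3.10 — was **back-solved** so that the
fractional charges at pH 7.4 equal the conventional three-decimal
reference values (+0.999, +1.000, +0.048, −0.999, −1.000, −0.085,
+0.996, −1.000) exactly; it is not copied from any single experimental
compilation (the Cys value in particular is chosen for the −0.085
charge, not a literature pKa). Users can override any entry via
`ResidueChargeTable(entries=...)` or a key/value config file.

Two simplification modes matter downstream:

* **rounding** — `integer` (default) maps each fractional charge to its
  nearest integer, so only K, R, D, E carry charge; `three_decimals`
  keeps fractions. All window analyses default to integer mode; the
  fractional+termini variant exists for the sensitivity comparison and
  gives very similar window distributions.
* **his_mode** — His at pH 7.4 is ~5% protonated, so the default rounds
  it to 0 (the more physiological choice); `plus_one` forces +1 for
  comparability with older analyses that counted His as basic. This is
  the one documented violation of "rounded = nearest integer".
* **termini** — free α-amino/α-carboxyl charges are excluded by default
  (they nearly cancel and would shift only the first/last windows);
  when enabled they are added only for full-length proteins.

Ambiguity and non-standard codes (B, Z, X, J, and U/O) are charge 0
with a logged warning; non-letter symbols are errors, and lowercase is
uppercased.

## Window scan and coordinates

Window length defaults to 30 residues — the approximate nascent-chain
span inside the ribosome exit tunnel. Coordinates are 1-based,
inclusive: window *i* covers residues *i..i+29*, a protein of length
*L* has *L−29* windows, and "the N-terminal net charge" means window 1.
The scan is a rolling sum (exact integer arithmetic in integer mode);
its equality with brute-force per-window summation is oracle-tested.
Proteins shorter than the window are skipped with a logged count, never
an error, when scanning a collection.

Heat-map matrices cover three fixed regions of 100 window starts:
N-terminal (starts 1–100), core (starts 130–229) and C-terminal (the
last 100 starts, labelled by the negative offset of the window's first
residue from the sequence end, −129..−30). Proteins shorter than a
tile's window simply do not contribute to that tile: tiles carry a
support count and zero-support tiles are missing (NaN), never
zero-filled. This support-weighted treatment keeps proteins of length
< 259 in the analysis rather than excluding them.

The first-vs-last window correlation requires length ≥ 60 so the two
windows cannot overlap. The trait-correlation helper gates on the
D'Agostino–Pearson omnibus normality test of both margins (α = 0.05):
Pearson when both pass, Spearman otherwise; it refuses n < 8, where the
omnibus test is undefined, and reports an undefined coefficient for
constant margins rather than raising.

**Supercharged stretches** are maximal runs of consecutive window
starts whose charge is ≥ +14 (or ≤ −14; runs are sign-specific). Each
run is reported once — first qualifying start, last start, peak charge
— with the window plus the following 30 residues (60 aa) as sequence
context, truncation at the protein end flagged. Collapsing overlapping
windows into runs reports stretches, not window counts; both
per-protein and per-proteome counts are available.

## Ribosome occupancy

The pipeline starts from per-codon read counts (gene, codon, count;
codon 0 = start codon); trimming, rRNA removal and alignment are
upstream concerns outside its scope. Choices:

* **Coverage filter** — genes with < 50% of codon positions carrying at
  least one read are removed; exactly 50% is retained (the rule
  eliminates strictly-below).
* **Normalization** — each gene is divided by its own *mean* count, so
  a featureless gene sits at 1.0 and the metagene baseline is
  interpretable; a `total` switch divides by the summed count instead
  (the two differ only by the gene-length factor and give identical AUC
  ratios within a group of fixed genes).
* **Charge groups** — integer first-window charges, His = 0, split as
  ≥+8 (+8..+13), +7, +6, +5, 0, −1, −6, ≤−7 (−7..−15); other charges
  are unassigned. Annotation-defined groups (e.g. mitochondrial genes)
  may be added and may overlap the numeric groups.
* **Metagene** — unweighted mean of normalized profiles at each codon
  0..150; genes stop contributing beyond their own length, and per-codon
  support is recorded.
* **AUC ratio** — trapezoidal area over codons 0..90 inclusive (the
  tunnel-transit span of the first 30 residues, in the profile's native
  codon units) divided by the charge-0 group's area. Normalization makes
  the ratio exactly invariant to global depth scaling.

## Monosome/polysome stratification

Five categories: `orf_lt_590` (ORF < 590 nt, strict — 590 itself goes
to the score branch), `monosome`, `no_enrichment`, `polysome`, and
`top300_polysome` (the 300 most polysome-skewed scores, kept disjoint
from `polysome`). Because published category boundaries come from an
external experimental dataset, the primary input mode is a precomputed
label table; when only log-ratio scores are available, symmetric
cutoffs of ±0.5 log2 units around zero are the package default — a
deliberate, configurable convention, not a reproduction of the original
thresholds. Segment means use window 1 (N), window start 121 (core;
start 130 available by flag, since both conventions appear in the
field) and the last window (C). The 16-bin table bins first-window
charges into ≤−7, each of −6..+7, and ≥+8; per-bin category percentages
sum to 100 by construction, empty bins are reported missing rather than
as zero rows, and the size-weighted average of bin rows reproduces the
all-protein baseline exactly.

## Synthetic data generator

The generator emulates the three inputs the analyses need, with known
planted structure and bit-reproducible output under a fixed seed.

**Proteomes.** Lengths are lognormal (median 400 aa, log-sd 0.45,
minimum 60 — a yeast-like length scale); residues are drawn iid from a
yeast-like composition; every protein starts with Met. Optional
features:

* *Positional bias* — an additive probability boost for chosen residues
  (e.g. K/R, +0.12 split between them) over a 1-based position range,
  renormalized per position; the generator exposes the closed-form
  expected charge and variance per position, so recovery tests compare
  against an analytic value, not a second simulation.
* *Planted first-window charges* — residues 2–30 are built from exact
  counts of K/R and D/E plus neutral residues so window 1 has a
  requested integer charge.
* *Supercharged plants* — a 30-mer of exact target charge with charged
  residues at both ends, flanked on each side by one opposite-sign
  guard residue and 14 neutral residues. The guards make the
  29-residue-overlap neighbour windows fall below the ±14 detection
  threshold, so the detected run starts exactly at the planted offset
  for |target| ≤ 15; larger targets necessarily drag neighbour windows
  over the threshold and are documented as recoverable only up to run
  membership. Background windows adjacent to the guard region can
  occasionally clear the threshold on their own; they appear as
  separate runs and do not displace the planted one.
* *Signal-peptide-like prefixes* — Met + basic residue + 8–12
  hydrophobic core residues, flagged in the ground truth.

**Ribosome counts.** Each gene gets a lognormal depth (mean 2
reads/codon, log-sd 0.5) and a multiplicative occupancy factor *m(q)*
of its first-window charge applied to codons 0–90 *before*
normalization (matching the causal picture: slow codons accumulate
reads). The default response is 1.0 for −5 ≤ q ≤ +4, linearly rising to
2.0 at q ≥ +8, and 0.8 at q ≤ −6 — a nonlinear shape in which only
strongly basic N-termini roughly double density. Counts are negative
binomial (dispersion 10) by default, reflecting the overdispersion of
profiling data; Poisson is available for closed-form checks. The
generator also emits an **analytic expectation table**: per gene the
expected normalized profile is its rate vector over its own mean (for a
gene of L codons wholly covered by the effect this is
`m·L/(91·m+L−91)` on codons 0–90), averaged per group exactly as the
metagene does, then put through the same trapezoid. Note the
expectation is *not* m itself: per-gene normalization attenuates the
multiplier (≈1.6 observed for m = 2 at L ≈ 400), which is why recovery
is defined against the expectation table.

**M:P scores.** `score = coupling_charge·q − coupling_length·z(log ORF)
+ N(0, noise_sd)`; zero couplings make category assignment independent
of charge, the configuration used to validate that the 16-bin table
shows no spurious structure.

### What the generator does not emulate

Real proteomes have domain structure, positional autocorrelation,
signal-dependent composition and families of homologs; real profiling
data have codon-specific dwell times, A-site offset uncertainty and
5'/3' edge effects; real M:P scores reflect initiation kinetics. Tests
passing on synthetic data therefore certify the *pipeline arithmetic*
(windowing, grouping, normalization, recovery of effects of the planted
form and size), not biological conclusions about any real proteome;
the published proteome-scale percentages depend on specific database
snapshots and are treated as provenance, not test targets.

## Problem sizes and numerics

Default test/driver scales — 2,000 proteins for positional-bias
recovery, 200 genes per charge group for occupancy recovery, 5,000
proteins for the bin-vs-baseline check, 1,000 random sequences for the
window oracle — were chosen so each estimate's sampling error sits well
inside its acceptance band (3 SE bounds, 10% relative error, and a
Bonferroni-adjusted z of 3.5 for ~80 simultaneous bin cells,
respectively). Integer-mode arithmetic is exact end-to-end; fractional
mode rounds per-residue charges to three decimals before summation.
Ratio-curve magnitudes with no positive-side windows are reported as
missing, distinct from 0. TSV outputs use fixed column order, UTF-8 and
'.' decimals so reruns are byte-identical under a fixed seed and config.

## Known limitations

* GO annotation matching is exact-ID only; no ontology-graph traversal.
* The score-based M:P thresholds are a package convention (±0.5 log2),
  not the published category boundaries; use label tables to reproduce
  published groupings.
* The metagene treats the profile's positions as codon units; data
  supplied in nucleotide coordinates must be converted upstream.
* Supercharged plants with |target| ≥ 16 cannot be recovered at an
  exact first-start offset (overlap arithmetic, see above).
* External predictors (nuclear-localization scoring) are out of scope;
  the package only exports the candidate FASTA inputs for them.
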