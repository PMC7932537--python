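# Methods

## Model and procedure

A substrate phage display experiment selects, from a library of randomized
hexapeptides displayed on phage coat protein PIII, those peptides a
protease cleaves: cleavage releases the phage from an affinity tag, so
uncleaved phage are removed by immunodepletion and survivors are
amplified, re-selected and sequenced.  The analysis assumes the protease's
catalytic cleft reads a P3–P1′ tetramer (true of MMPs, whose S3 and S1′
pockets dominate selectivity), so the unit of analysis is the *tetramer
cluster*: all distinct hexamers of a sample that contain a given tetramer.

**Clustering.** A hexamer has candidate tetramers at offsets 0, 1, 2.  The
naive library is clustered with multi-membership (a hexamer joins all of
its 1–3 distinct candidate clusters), because no selective pressure
distinguishes the registers.  Selections are clustered to a partition:
after building the multi-membership table, clusters are visited from least
to most abundant (ties lexicographic) and each multiply-assigned hexamer
is removed from the visited cluster unless that cluster is the hexamer's
most abundant candidate.  Abundance is the *static* initial
distinct-hexamer count; it is not recomputed during elimination, which
makes the procedure order-independent and equivalent to assigning each
hexamer directly to its most abundant candidate (ties broken by smallest
offset, then tetramer sequence — conventions of this package, logged in
the outputs).  Read counts are carried as metadata only; all statistics
use distinct-hexamer counts.

**Statistics.** Cluster probabilities are `P(t) = n_t / Σ nᵢ` within each
table (partitioned counts for selections, multi-membership counts for the
library).  Entropy and divergence use log base 2; `shannon_entropy`
exposes the base as a parameter for the per-position log₂₀ convention
used with residue-frequency specificity matrices.  RP(t) = P_S/P_NL;
clusters observed only in the selection receive a naive pseudocount of
one hexamer and are flagged and counted (with a deeply sequenced library
the case is rare, but the statistic must stay finite).  The selectome
threshold is the RP at which the cumulative K-L contribution, taken over
clusters in ascending RP order, first reaches zero (within 1e-12 to
absorb float cancellation).  Membership is strict (`RP > threshold`): the
threshold cluster itself closes the zero-sum region.  Two edge cases:
with no cluster above RP 1 there is no positive divergence mass and no
definable specificity (threshold `None`, empty selectome); with no
negative mass at all (e.g. a single-peak selection) the threshold is 1, so
every overrepresented cluster is in the selectome.

**Profiles.** Cluster members align on an eight-position P5…P3′ window
(offset 0 → P3…P3′, offset 1 → P4…P2′, offset 2 → P5…P1′).  Position
frequency matrices weight each distinct hexamer once and normalize each
column by its coverage (the number of hexamers reaching that position);
normalizing by total hexamers instead would shrink the outer positions'
frequencies by their coverage fraction — coverage normalization keeps
columns comparable.  Information content is `log₂ 20 − H(column)`.
RP/RP_Max decile groups use right-closed bins `((k−1)/10, k/10]`, with
exact zero joining group 1.

**Validation.** RP is validated against measured catalytic constants two
ways.  (1) Correlation: raw Pearson R over peptide-level pairs, then an
ordinary least-squares fit of bin-mean constant on bin-mean RP after
grouping records contiguously in ascending RP (equal record count per bin
by default; equal-width RP bins behind a flag).  Binning averages out the
P5/P4/P2′/P3′ context contribution, so the binned correlation should
exceed the raw one whenever a true signal is present — this is asserted
as a property in
expectation over seeded simulations.  (2) Classification: TP = RP above
threshold and constant > 0, TN = both below/zero, FP/FN the mismatches;
sensitivity, specificity, accuracy, FP rate, precision and MCC follow,
with a zero MCC denominator reported as 0 plus a flag.

**Cleavage-site annotation.** A site is the 1-based index of P1′ in a
protein; the P3–P1′ tetramer is residues `p1′−3 … p1′`.  Database-style
records supply a P4–P4′ octamer instead, whose characters 2–5 are the
tetramer.  Sites with P1′ before residue 4 are flagged unprojectable and
excluded from category fractions.  Categories: `selectome`
(RP > threshold), `sub_threshold` (0 < RP ≤ threshold), `absent` (RP = 0).
Isotopic enrichment (IE, log₂ treated/control reporter ratio of a labeled
neo-N-terminus) is summarized per enzyme by the sample (n−1) mean and
standard deviation; a site counts as enriched when its z-score is
strictly above 1.  Replicate channels are averaged on the log₂ scale;
per-site p-values are out of scope.  Cross-protease selectivity is an OLS
of RP/RP_Max (B) on RP/RP_Max (A) within the shared / unique-A / unique-B
groups defined by the IE criterion (or the RP criterion behind a flag).

## The simulator

The generator produces every pipeline input with the structure the
analysis assumes, and is the ground truth for parameter-recovery tests.

- **Landscape**: per-tetramer k_cat/K_M = `scale · exp(Σ position weights
  + ε)`, weights N(0, weight_sd) per position×residue, ε N(0, noise_sd).
  Defaults: scale 50 M⁻¹s⁻¹, weight_sd 1.5, noise_sd 0.5.  At these values
  roughly the top few percent of tetramers exceed the 3,289 M⁻¹s⁻¹ rate
  that is 99% cleaved under the default conditions, giving a protease of
  realistic breadth (tens of thousands of selectome clusters).
- **Context factor**: each hexamer's effective rate is the maximum over
  its three tetramer-site rates (one dominant scissile bond per
  substrate; a sum-of-sites mode exists behind a flag) times a per-hexamer
  log-normal factor of sd `context_sd` (default 0.5) standing in for the
  unpredictable P5/P4/P2′/P3′ contribution.
- **Selection round**: cleavage probability `1 − exp(−k·[E]·t)` (pseudo-
  first-order, [S] ≪ K_M; defaults 200 nM, 7,200 s, two rounds); cleaved
  counts binomial, uncleaved phage leak past immunodepletion with
  probability 1 − efficiency (default efficiency 0.99 — the leak supplies
  the low-RP background against which the threshold is defined);
  survivors are resampled multinomially to the sequencing depth.  The
  untreated control is the same process with cleavage probability 0.
- **Scale**: defaults are 1,000,000 distinct naive hexamers at 4,000,000
  reads and selection depth 1,000,000 (preserving the deep-library /
  shallower-selection ratio of real experiments).  The tetramer space
  itself cannot be scaled down: a singleton selection cluster has
  RP = 160,000 / (selection assignments), so selections much smaller than
  ~10⁶ hexamers push every observed cluster above RP 1 and the
  threshold loses its meaning.  The default scale is the smallest at
  which the method's intended regime (most observed clusters below RP 1,
  a minority of clusters holding most hexamer mass) appears; tests that
  do not need that regime run on much smaller inputs.
- **Kinetics emitter**: measured constant = effective rate ×
  log-normal measurement noise (sd 0.3), censored at an assay ceiling
  (default 12,792 M⁻¹s⁻¹) and reported as 0 below a detection floor
  (default 50 M⁻¹s⁻¹, a few percent cleavage over the assay window) —
  both censoring directions are features of real kinetic panels and the
  floor is what makes binary classification non-degenerate.
- **Planted proteomes**: random protein sequences with tetramers embedded
  at recorded P1′ positions, half drawn from the top 1% of the landscape
  (IE centered 3 log₂ units up), half uniform (IE near 0).

What the simulator does **not** emulate: phage propagation bias, codon-
level (NNK/NNN) library bias, PCR duplicates, paired-end artifacts, and
pooling of rounds for sequencing (only the final round is sequenced).
Passing tests therefore demonstrate correctness of the statistics under
the model's assumptions, not robustness to those experimental artifacts.

## Numerical and design choices

- One hexamer per read; frames searched forward 0, 1, 2 then reverse 0,
  1, 2, first valid insert wins; a stop or ambiguous residue inside the
  insert disqualifies that frame only.  Quality scores are ignored.
  Flank peptides are mandatory configuration: they are a property of the
  display vector, not of the method.
- The amino-acid alphabet is the 20 standard residues in alphabetical
  order everywhere (probability tables, PFM rows, peptide integer codes).
- Probability tables validate Σ P = 1 to 1e-9; K-L refuses unpseudocounted
  zero-reference clusters rather than returning infinity.
- The cumulative-divergence threshold scan sorts by (RP, contribution) so
  ties are deterministic.
- OLS and Pearson statistics come from `scipy.stats` closed forms;
  SEM = sd/√n per bin.
- All simulator randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawns; identical seeds give bit-identical
  outputs.

## Known limitations

- The finite-sample RP distribution of a *non-selective* protease is not
  exactly 1 everywhere: sampling noise and the partitioned-vs-multi-
  membership asymmetry between selection and library clustering produce a
  small spurious divergence.  The no-specificity outcome (threshold
  `None`) is exact at the distribution level and is tested there.
- Redundancy elimination with *static* abundances can differ from a
  dynamic-recount variant on adversarial toy inputs; the static rule is
  deterministic and order-independent, which we prioritize.
- Selectome size and threshold depend on sequencing depth and library
  complexity (see the scale note above); comparisons between proteases
  should use selections of comparable depth.
- PFM columns for outer window positions (P5, P4, P2′, P3′) are supported
  by only the subset of hexamers whose offset reaches them; at small
  cluster counts those columns are noisy.
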