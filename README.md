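# selectome

Quantitative protease-specificity profiling from substrate phage display
sequencing.

## The problem

Proteases from the same family — the matrix metalloproteinases MMP-2 and
MMP-9 are the canonical pair — cleave overlapping but not identical sets of
substrates, and single "consensus motifs" cannot capture either the breadth
of a protease's specificity or how strongly each motif contributes to
catalysis.  Substrate phage display coupled with deep sequencing can assay
millions of randomized hexapeptide substrates at once, but turning those
reads into a quantitative specificity profile needs a statistical
framework.  This package implements one, built around the **selectome**:
the set of substrate motifs that, only as a whole, is unique to a protease
and constitutes its proteolytic signature.

For proteases whose catalytic cleft reads a P3–P1′ tetramer (Schechter–
Berger numbering around the scissile P1–P1′ bond), every hexamer substrate
carries three candidate tetramers, each tetramer fits in at most 1,200
hexamer contexts, and there are 20⁴ = 160,000 possible tetramers.  Grouping
the distinct hexamers of a selection into *tetramer clusters* identifies
the cleavage register without experimental scissile-bond mapping, and the
number of hexamers per cluster measures that tetramer's contribution to
catalytic efficiency ("substrate fitness").

## The statistics

With cluster probabilities `P(t) = n_t / Σᵢ nᵢ` (n_t = distinct hexamers in
cluster *t*) for the selection (`P_S`) and the naive library (`P_NL`):

- **Shannon entropy** `H = −Σ P(t) log₂ P(t)` measures specificity breadth
  (uniform limit: log₂ 160,000 = 17.288 bits);
- **Relative probability** `RP(t) = P_S(t) / P_NL(t)` is the fitness
  statistic, from ≈1 (cleaved no better than background) to 160,000
  (a perfectly specific protease's single substrate);
- **Kullback–Leibler divergence**
  `D(P_S ‖ P_NL) = Σ P_S(t) log₂ RP(t)` measures how far selection moved
  the distribution;
- the **selectome threshold** is the RP value at which the cumulative K-L
  contribution (clusters in ascending RP order) crosses zero: clusters
  below it cancel to no net divergence, clusters above it carry all of it
  and form the selectome.

Around this core the package provides six-frame read translation and
flank-anchored hexamer extraction, control subtraction, P5–P3′ positional
frequency matrices and RP/RP_Max decile profiles, validation of RP against
measured catalytic constants (binned correlation and confusion-matrix
classification), selectome-based annotation of cleavage sites in proteins
(N-terminomics isotopic-enrichment evidence or P4–P4′ database octamers),
and a full phage-selection simulator so every analysis is testable against
a known ground truth.

## A worked example

`examples/01_simulate_and_profile.py` simulates a two-round selection at
200 nM enzyme for 2 h (conditions under which a substrate with
k_cat/K_M = 3,289 M⁻¹s⁻¹ is 99% cleaved per round) against a randomly drawn
position-weight specificity landscape, then derives the selectome:

```
naive library: 981,675 distinct hexamers
selection:     250,374 distinct hexamers survive

naive-library entropy:   17.249 bits (uniform max 17.288)
selection entropy:       15.044 bits
K-L divergence:          2.116 bits
selectome RP threshold:  1.90
selectome:               22,809 tetramer clusters of 53,483 observed
hexamers in selectome:   81.3%
```

The naive library clusters almost uniformly (17.25 of 17.29 bits);
selection concentrates the distribution (entropy drops, divergence is
positive), and the ~43% of observed clusters above the RP threshold hold
81% of the surviving hexamers — the selectome carries the specificity.
The other examples validate RP against simulated kinetics
(`02_kinetic_validation.py`: binning substrates by RP raises the Pearson
correlation from 0.54 to 0.97), classify planted cleavage sites in a toy
proteome (`03_annotate_cleavage_sites.py`) and compare two related
proteases' selectomes (`04_compare_two_proteases.py`).

A thin CLI mirrors the library for shell use:

```
selectome extract  --fastq reads.fq.gz --left-flank DLA --right-flank GAE --out hex.tsv
selectome stats    --selection sel.tsv --control ctrl.tsv --naive naive.tsv --out-prefix mmp
selectome profile  --clusters mmp.clusters.tsv --stats mmp.stats.tsv --deciles --out pfm/
selectome classify --kinetics kin.tsv --stats mmp.stats.tsv --threshold 4.5
```

Full-scale experimental count tables (hexamer TSVs from a real sequencing
run) enter through the same paths — `HexamerSet.from_tsv` or
`selectome stats` — so the workflow above applies unchanged to published
data.

## Layout

- `src/selectome/extract.py` — read translation, insert extraction, control subtraction
- `src/selectome/clustering.py` — tetramer clusters, redundancy elimination, combinatorics
- `src/selectome/stats.py` — entropy, RP, K-L divergence, selectome threshold
- `src/selectome/profiles.py` — P5–P3′ alignment, PFMs, RP/RP_Max deciles
- `src/selectome/validation.py` — kinetic correlation and binary classification
- `src/selectome/annotation.py` — cleavage-site projection, IE statistics, classification
- `src/selectome/simulate.py` — landscapes, libraries, selection rounds, fixtures
- `docs/methods.md` — models, parameter choices and limitations
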