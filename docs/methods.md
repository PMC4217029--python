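# Methods

## Motif model

The phospho-acceptor specificity of the kinase is modelled as an N×20
position weight matrix over offsets relative to the acceptor Ser/Thr
(offset 0). The matrix is estimated from aligned training windows by
Laplace-smoothed counting,

    p_o(a) = (count(a at o) + α) / (n_o + 20α),

with pseudocount α = 1 by default and padded positions excluded from the
counts at their offsets. The default window spans offsets −5…+4 (N = 10);
the width is configurable, and every constraint the screen uses lives in
−5…+1. Two kinds of positional structure sit on top of the
probabilities:

* **core constraints** (invariant): Arg at −5 and −3, S/T at 0. These are
  hard filters, not soft weights — a window failing them is rejected in
  both scanning modes.
* **preference** (soft): V, I or F at +1. In `core` mode it is recorded
  as a flag; in `strict` mode it is required. The hydrophobic set is
  exactly {V, I, F}; extending it is possible via configuration but off
  by default.

A window scores the summed log-odds `Σ_o ln(p_o(w_o)/q(w_o))` in natural
log units against a background composition `q` (uniform by default; a
helper derives `q` from the scanned sequences, which changes scores and
is therefore an explicit choice, not automatic). Padding (`-`) and
unknown residues (`X`) contribute zero to the sum and never satisfy a
constraint or preference.

**Likelihood.** The upstream motif package's "likelihood score" has no
published definition, so this package defines its own deterministic,
bounded, monotone surrogate: the raw score min–max normalised by the
matrix's exhaustive score range (the per-offset extreme log-odds sums,
attainable because the optimum of a per-position sum is per-position).
A degenerate matrix whose range is zero maps every window to 1.0.
Whether the conventional 0.7 cutoff transfers to this scale is
unknowable, so the cutoff is a free parameter defaulting to 0.7, with
comparators per criterion: strict `>` in criterion (b) ("above a score
of 0.7") and inclusive `>=` in criterion (c) ("a score of 0.7"),
matching the wording difference.

**Training set.** The five in-vivo substrate site classes that motivate
the motif are known by gene and position, but their full sequence
contexts are not distributable with this package, so the packaged
default training windows (`data/training_windows_synthetic.tsv`) are a
constructed stand-in that encodes the published consensus: every window
has Arg at −5/−3 and an S/T acceptor, and 10 of 11 carry a hydrophobic
+1. Any user-supplied window collection can replace them.

## Proteome scanning

Every S/T in every protein defines one candidate window, padded at the
termini; coordinates are 1-based to match conventional site numbering.
Hits are windows accepted by the constraint mode with likelihood at or
above the threshold, sorted by (protein id, position). Two invariants
follow directly and are enforced by tests: strict-mode hits are a subset
of core-mode hits, and raising the threshold never adds hits.

## Candidate criteria

The evidence gate (a chemical-sensitivity phenotype or a curated
interaction) precedes the site criteria, which are evaluated
a-then-b-then-c so exactly one branch label is assigned:

* (a) ≥4 predicted sites — no score or database condition, as stated;
* (b) exactly 3 sites ∧ (max likelihood > cutoff ∨ a predicted site is a
  known in vivo phosphosite). The published sentence admits two parses
  ("3 sites with at least one above …" vs "3 sites, at least one of
  which …"); both collapse to this predicate because the maximum
  likelihood and the database flag are per-gene aggregates;
* (c) 1–2 sites ∧ max likelihood ≥ cutoff ∧ a known in vivo phosphosite.

Sites are counted in core mode at threshold 0 by default, since the
original pipeline's pre-count cutoff is not stated. A `manual_include`
flag forces candidacy (branch `manual`) for genes added despite failing
the criteria, mirroring the asterisked entries of the candidate table.
GO Slim terms are taken from the input table, never computed; genes
without a term group under "Biological Process Unknown".

## SDL rubric

Growth is recorded as dilution spots grown (default series length 5
spots of 10-fold dilutions; the grading depends only on deficits
relative to the side-by-side control, not on the series length). A
*growth phenotype* at concentration c is ≥1 spot less growth than the
control on galactose with no such deficit on the dextrose counterpart —
the dextrose gate encodes the repressed-expression control of the assay
design, so baseline sickness is never called a phenotype. A *strong*
phenotype is zero growth. Grading applies the first matching rule of

    TOXIC → P5 → P4 → P3 → P2 → P1 → MINUS,

where TOXIC means the wild-type-kinase strain is already impaired on
galactose without inhibitor (the record is unscoreable), P5 is a
phenotype with no inhibitor, P4/P3 strong/plain phenotypes at 1 µM, and
P2/P1 strong/plain phenotypes at 2 µM given none at 1 µM. The published
rubric does not state a precedence; strongest-first is chosen because
the grade descriptions are nested severities (a P5 record typically also
satisfies the P3 test). Records missing galactose cells grade NA and are
excluded from tested counts.

A gene is an **SDL hit** if it carries any graded phenotype, or if it is
TOXIC but rescued by kinase co-overexpression — the decoy-substrate
signature; counting rescued-toxic genes is a config flag
(`count_rescued_toxic`, default on), which is what makes the packaged
table yield 20 hits rather than 19. A **substrate call** additionally
requires in vitro phosphorylation, where the weak-but-detectable "+/−"
level counts as positive (required to reconcile the printed 12/17 with
the per-gene symbols).

The packaged candidate-table transcription has 96 candidate rows; 5 are
unscoreable (N/A), so the computed denominator is 91 rather than the
printed 90 — the discrepancy is inherent to the printed table and the
package reports the computed value alongside the counts, which do
reproduce (10 toxic, 20 hits, 12/17 in vitro).

## Lipid mass arithmetic

Monoisotopic masses are summed from the NIST element table (via
pyteomics); the protonated adduct uses the proton mass 1.00728 Da, not
the hydrogen atom mass — this reproduces all five reference precursor
values to 4 d.p. from the packaged formulas (phytosphingosine C18H39NO3,
dihydrosphingosine C18H39NO2, their 1-phosphates C18H40NO6P/C18H40NO5P,
C18-phytoceramide C36H73NO4, C17-sphingosine internal standard
C17H35NO2 — standard lipid chemistry, packaged as data). LCB headgroup
fragments are the protonated precursor minus n×18.0106 per water loss;
for ceramides, amide cleavage regenerates the protonated LCB moiety
first, so phytoceramide and free phytosphingosine share the 282.3
fragment. The computed double-water-loss ion of dihydrosphingosine is
266.28; the commonly quoted 266.4 is a low-resolution readout and is not
asserted anywhere. Peak matching uses a relative (ppm) tolerance,
default 10 ppm, appropriate for a high-resolution analyzer;
assignment is nearest-in-ppm and deterministic. Internal-standard
quantitation is single-point with response factor 1 (no per-analyte
calibration is assumed); a linear standard-curve hook (slope, intercept)
exists and defaults to identity. Ceramide-synthase activity is product
amount divided by enzyme signal and reaction time.

## Synthetic data

Each generator draws from its own named pseudo-random stream derived
from the single seed, so adding a generator never shifts another's
output, and all outputs are byte-identical for a fixed seed.

* **Proteome** — residues i.i.d. from an average-proteome composition
  (Swiss-Prot statistics, packaged as constants; uniform fallback).
  Planted windows carry the invariant core, a single S/T (the acceptor),
  and a +1 drawn from {V,I,F} for strict-conforming sites or from the
  non-hydrophobic safe alphabet otherwise; all other planted positions
  avoid S, T and R. A repair pass mutates the acceptor of any accidental
  core-pattern window in the background (replacement never introduces R
  or S/T, so repairs cannot create new motifs). Consequence: a core-mode
  scan recovers exactly the planted sites — recovery tests are exact,
  not probabilistic. Default 20 strict + 30 core-only sites across 15
  proteins of 200–500 residues.
* **Evidence cohort** — half the genes are intended candidates cycling
  through branches a/b/c with gate evidence; the other half carry the
  same site profiles but no gate evidence, so every label is a
  deterministic function of the gate flag alone. Corruption toggles the
  gate with probability `flip_rate`, making the analytic label-recovery
  accuracy exactly 1 − flip_rate (a binomial proportion, used as the
  oracle in tests).
* **Growth matrices** — controls grow the full series everywhere;
  the construct's dextrose rows match control; galactose rows are set to
  the minimal pattern of the intended grade with rng jitter inside the
  grade's feasible region, so grading is a round trip by construction
  for all 8 grades. NA intent omits the galactose cells.
* **Peak lists** — one peak per target with Gaussian ppm error, plus
  noise peaks rejected within 5× the matching tolerance of any target,
  so specificity is exact and sensitivity follows the Gaussian interval
  probability (≈1 − 6·10⁻⁷ at 2 ppm error / 10 ppm tolerance).

What the generators do **not** emulate: real proteome composition
biases, disorder/topology context of sites, correlated evidence errors,
plate-to-plate growth variability, isotope envelopes and chromatography.
Passing recovery tests therefore certify the pipeline's internal logic
(each stage inverts its generator), not performance on real screens.

## Problem sizes and numerical choices

The default analysis and verification sizes — 200-protein scan-oracle
comparisons, 8 grades × 25 seeds rubric round trips, 1000-replicate peak
recovery — were chosen to make Monte-Carlo checks decisive at three
standard errors while keeping every suite fast on a single CPU.
Probability rows are validated to 1e-9; likelihoods are clipped to
[0, 1] (padded windows lie inside the matrix range because per-offset
maxima are nonnegative, so clipping is a safety net, not a correction);
ties in peak matching resolve to the first target in list order.

## Known limitations

* The likelihood scale is a surrogate; absolute threshold values are not
  comparable to the original motif package's scores.
* The packaged training windows are synthetic stand-ins; retraining on
  real site contexts will change scores (but not the constraint logic).
* The candidate-table denominator (91 scoreable vs 90 printed) cannot be
  reconciled from the table alone; counts, not fractions, are the
  contract.
* No spectral file parsing or peak integration: the lipid module starts
  from peak lists and areas.
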