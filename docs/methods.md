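# Methods

This note documents the models implemented in `dmcf`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the numerical conventions used throughout.

## Data model

A *search event* is (timestamp, physician y, patient p, visit v, term t).
Events grouped by (y, p, v) and ordered by timestamp form a *search
sequence*; additional visits of the same pair always produce additional
sequences, never merged.  Design choices:

- **Term normalization** (on by default, configurable): lowercase and
  whitespace collapse, so case variants ("HGB"/"hgb") share one vocabulary
  entry.  Raw logs mix case freely.
- **Visit boundaries** come from the log's visit id.  If a row has none, an
  inactivity timeout (default 240 minutes per (y, p) pair) splits that
  pair's events into session visits.
- **Timestamp ties** preserve input-file order (stable sort).
- **Repeated consecutive terms** are kept by default — a repeat is a
  legitimate self-transition — with a `collapse_repeats` switch.
- Length-1 sequences are kept: they contribute profile frequencies but no
  transitions.

## Dynamics component (foMC)

Transition counts are accumulated over adjacent pairs *within* a visit
sequence only, pooled across all physicians and patients; probabilities are
the row-normalized frequencies.  Deliberately *not* done: smoothing or
back-off (an unobserved transition scores exactly 0, and an unseen source
term yields an empty score map with a flag so the hybrid can lean on CF),
and higher-order chains.  The component is population-level by
construction: it carries no physician- or patient-specific state.

## Similarity profiles

Physicians and patients are bags of searched terms; terms are bags of the
patients they were searched on.  All profiles use raw training-set counts
(no tf-idf, no binarization), similarities are cosines, computed lazily
row-by-row from L2-normalized sparse matrices so the full pairwise matrix
is never materialized unless requested.  Conventions: a zero profile is
similar to nothing (including itself); neighbor queries exclude the target
entity and zero-similarity entities; ties at the k-th rank break by
ascending entity index, making every neighbor list deterministic.

## ypCF

Neighbor identification supports both orders. `simP2Y` ranks patients
first; candidate physicians must have searched, on a selected similar
patient, at least one term that was also searched *on the target patient by
anyone*.  `simY2P` ranks physicians first; candidate patients must share
with the target patient a term *that the same candidate physician* searched
on both.  The two pronoun readings differ deliberately (the anyone/same
distinction follows the most literal reading of each procedure's
description) and are isolated in `identify_simP2Y` / `identify_simY2P`.

Scoring conventions:

- f̄ for a (y, p) pair divides by the number of *distinct* observed terms.
- f̄ of a target pair never observed in training is 0, keeping scores
  finite; scores then reduce to the weighted centered-neighbor sum.
- The candidate universe is the terms occurring in the neighbor triplet
  set; any other term would score the constant f̄ and is not ranked.
- A term whose contributing similarity products sum to 0 gets no CF
  adjustment.

## TptCF

The similar-term set S_t is `sim_t ≥ β` (inclusive, so β = 1 keeps the
anchor; a 1e-9 slack absorbs float error on parallel profiles).  Per-patient
transition counts g pool all physicians and visits of that patient.  The
inner bracket is implemented exactly as specified: the numerator is
similarity-weighted, the denominator is the unweighted count of transitions
into the destination from S_t sources.  A consequence worth knowing: with a
singleton S_t the bracket is g/g = 1 for every destination reachable from
the anchor, i.e. the scorer degenerates to a flat score on the
patient-restricted Markov support rather than reproducing the Markov
ranking.  Patient weights are normalized over the similar-patient set, so
all scores lie in [0, 1].  S_p is the top-k_p patients by sim_p.

## Hybrid

Score scales differ (probabilities vs frequency-denominated CF values);
they are combined raw by default, matching the linear-combination
definition, with an optional per-component min-max rescale flag (off) for
experimentation.  The candidate universe is the union of the candidates of
the components with nonzero weight — hence α = 0 reproduces the pure
dynamics ranking exactly and α = 1 the pure CF ranking, a property the test
suite checks end to end.  Top-N lists break score ties by ascending term
index and are therefore prefixes of each other across N.

## CUTOFF evaluation

Events strictly before the cutoff train every component (transition counts,
profiles, similarities, triplet tables).  Sequence routing: fully
pre-cutoff → train only; straddling → pre-cutoff prefix trains, first
post-cutoff term is the single test label, later terms discarded; fully
post-cutoff → dropped.  A test case whose label never occurs in training is
kept and counted as a miss.  HR denominators are per test sequence.  Cutoffs
are specified as empirical quantiles of the event timestamps (an explicit
instant is also accepted); the empirical quantile is robust to the
heavy-tailed sequence spans the generator produces.  No multiple-comparison
correction is applied to grid searches — they are exploratory rankings, not
hypothesis tests.

## Synthetic generator

What it emulates: a handful of latent patient conditions with disjoint term
blocks and condition-specific first-order chains (one dominant successor
per term, mass `chain_dominance`); physician specialties concentrating
visits within a condition (`specialty_concentration`); short
shifted-geometric sequence lengths calibrated to a mean of 2.885 terms; a
uniform `noise_rate`; and within-visit inter-search gaps drawn
exponentially (mean `mean_gap_days`) so a few percent of sequences straddle
any mid-window cutoff — the property that gives the CUTOFF protocol a
usable test set.

Defaults (2,000 visits, 175 physicians, 1,000 patients, 500 terms, 5
conditions, dominance 0.8, concentration 0.9, noise 0.05, mean gap 8 days
over a 240-day window) are a roughly 12× scale-down of the log sizes the
method targets.  Patients and vocabulary are scaled slightly less than
proportionally so each chain row receives ~6-7 observed transitions: by a
Poisson argument this keeps the planted dynamics estimable from one
default corpus, which is the generator's purpose — making every downstream
component testable for recovery.  At the default sizes a 0.8-quantile
cutoff yields ≈ 120 test sequences.

What it does **not** emulate: clinical vocabulary (terms are symbolic),
comorbidity across conditions (blocks are disjoint apart from noise),
physician-specific search styles, drift over time, or the long-tailed
popularity distribution of real search terms.  Passing recovery tests
therefore shows the estimators are correct and well-calibrated under the
assumed cluster-plus-chain structure — not that the method attains any
particular accuracy on real clinical logs.

### Analytic expectations used in tests

An oracle knowing the generating chains hits at top-1 with probability
`s·[(1−ν)d + ν/T] + (1−s)·ν/T`, where ν is the noise rate, d the chain
dominance, T the vocabulary size and `s = 1 − ν(1 − 1/C)` the probability
that the previous term acts as a chain state (a noise term landing inside
the patient's own block still does).  The *fitted* Markov scorer is
additionally discounted by the probability that a row's arg-max is not the
true dominant successor, computed from a Poisson model of per-source
transition counts with a binomial dominant count and independent
near-uniform alternatives (ties counted as losses — slightly conservative).
Recovery tests compare measured hit rates against these expectations at 3
binomial standard errors.

## Numerical conventions

- Cosines are clipped to [0, 1] after sparse dot products.
- All orderings (vocabulary indices, neighbor lists, top-N lists, grid
  rows) are deterministic; identical corpus + configuration gives
  byte-identical evaluation results.
- Serialized artifacts (log TSV, transition triplets, similarity triplets)
  are versioned flat text files that round-trip exactly.

## Known limitations

- ypCF neighbor identification is O(|S_p| · patients-per-physician) per
  query; at very large k_p with dense logs an inverted index would be
  needed.
- The generator's disjoint term blocks make patient clustering easier than
  in real logs where conditions share vocabulary; cluster-recovery rates
  here are upper bounds on realistic behaviour.
- Grid searches refit nothing but still score every test case per
  configuration; the full default grid (thousands of points) is practical
  only on small corpora.
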