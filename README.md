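# dmcf — next-search-term recommendation for clinician EHR search logs

Physicians searching a patient's electronic health record issue short bursts
of queries during a visit ("EKG", "troponin", "echo", ...). `dmcf`
implements a hybrid recommender that suggests the *next* search term for a
physician *y* working on patient *p*, given the visit's search sequence so
far — together with the temporal evaluation protocol and synthetic-log
generator needed to study it end to end without access to protected
clinical data.

## The model

A visit's searches form a sequence T→(y, p, v) = {t₁ → t₂ → ⋯ → tₖ}.  A
candidate next term *t* is scored by a convex combination of two components:

    Score(t) = (1 − α) · Score_DYN(t) + α · Score_CF(t),      α ∈ [0, 1]

**Dynamics (foMC).** Score_DYN(t) = P(t | tₖ), the first-order Markov
transition probability estimated as the plain frequency ratio
h(tₖ → t) / Σₜ′ h(tₖ → t′) over all within-visit adjacent pairs in the
training log, pooled across physicians and patients.  No smoothing.

**Collaborative filtering.**  Physicians, patients and terms get frequency
profiles (**v** over terms, **u** over terms, **w** over patients) and cosine
similarities sim_y, sim_p, sim_t.  Two CF scorers are provided:

* **ypCF** — identifies similar patients S_p and similar physicians S_y
  (patient-first `simP2Y` or physician-first `simY2P`), then scores

      Score(t) = f̄(⟨y,p,·⟩) + Σ f̂(⟨y′,p′,t⟩)·sim_y(y,y′)·sim_p(p,p′)
                               / Σ sim_y(y,y′)·sim_p(p,p′)

  where f(⟨y,p,t⟩) counts how often y searched t on p in training and
  f̂ = f − f̄ is centered per (y, p) pair to damp volume bias.
* **TptCF** — aggregates, over similar patients p′ and terms t′ with
  sim_t(tₖ, t′) ≥ β, the per-patient transition counts g(t′ → t | p′),
  similarity-weighted in the numerator and normalized per destination.

**Evaluation (CUTOFF + HR@N).**  All sequences are split at one cutoff
instant: pre-cutoff events train every component; for each sequence
straddling the cutoff the first post-cutoff term is the held-out label.
HR@N is the fraction of test sequences whose label appears in the top-N
recommendations.

Because real EHR search logs are protected, the package ships a calibrated
synthetic generator (`dmcf.synthetic`): latent patient conditions and
physician specialties, condition-specific Markov chains with a dominant
successor per term, shifted-geometric sequence lengths (mean 2.885), and
full ground truth for recovery testing.

## Worked example

```python
from dmcf import (DmCF, HybridConfig, SyntheticConfig, generate_log,
                  make_cutoff_split, quantile_cutoff, run_evaluation)

corpus, truth = generate_log(SyntheticConfig(seed=1))
split = make_cutoff_split(corpus, quantile_cutoff(corpus, 0.8))
results = DmCF(split.train_corpus, HybridConfig(method="DmCF-ypCF", alpha=0.2)).fit()
print(results.summary())
```

```
DmCF recommender fit
============================================
method                      DmCF-ypCF
alpha (CF weight)           0.2
...
physicians                  175
patients                    823
terms                       498
sequences                   1682
search events               4606
mean sequence length        2.738
observed transitions        2924
distinct transition pairs   1283
============================================
```

Recommending for one held-out test case and evaluating two configurations:

```python
case = split.test_cases[0]
rec = results.recommend(case.physician_id, case.patient_id, list(case.prefix))
# rank 1: t0409 (score 0.800, dyn) — the Markov-dominant successor
# rank 2+: cf-sourced candidates from the similar (physician, patient) pair

for method in ("foMC", "DmCF-ypCF"):
    r = run_evaluation(split, HybridConfig(method=method, alpha=0.2), results=results)
    print(method, r.hr, r.n_test)
# foMC      {1: 0.627, 2: 0.644, 3: 0.644, 4: 0.644, 5: 0.653} 118
# DmCF-ypCF {1: 0.627, 2: 0.653, 3: 0.653, 4: 0.653, 5: 0.653} 118
```

HR@1 ≈ 0.63 against the generator's analytic one-guess ceiling of ≈ 0.70 —
the fitted chain recovers most, but not all, of the planted dominant
transitions from ~2,900 training transitions; blending in the CF component
(α = 0.2) lifts mid-list hit rates.

The same pipeline is scriptable from the shell:

```
dmcf simulate --seed 7 --out log.tsv --truth truth.json
dmcf evaluate --log log.tsv --cutoff-quantile 0.8 --cf DmCF-ypCF --alpha 0.2
dmcf grid --log log.tsv --config grid.yaml --out results.tsv
dmcf recommend --log log.tsv --physician y014 --patient p0724 --sequence "t0482,t0463"
```

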