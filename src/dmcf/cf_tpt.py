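"""Transition-involved patient-term-similarity collaborative filtering (TptCF).

TptCF scores a next term t by looking at what was searched, on patients
similar to the target patient, right after terms similar to the current last
term.  Per similar patient p', the inner quantity is

    sum_{t' in S_t} g(t' -> t | p') * sim_t(anchor, t')
    -----------------------------------------------------
    sum_{t'' in S_t} g(t'' -> t | p')

where g counts transitions into t on p' (pooled over physicians and visits)
and S_t is the set of terms whose similarity to the anchor (the last searched
term) is at least the threshold beta.  Note the asymmetry: the numerator is
similarity-weighted, the denominator is not.  Patient contributions are then
averaged with weights sim_p normalized over the similar-patient set, so every
score lies in [0, 1].
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .corpus import SearchCorpus
from .similarity import SimilarityIndex

__all__ = [
    "PatientTransitionStats",
    "SimilarTermSet",
    "similar_terms",
    "score_tptcf",
]


@dataclass
class SimilarTermSet:
    """Terms at least beta-similar to the anchor, with their similarities."""

    anchor: int
    members: dict[int, float]  # term index -> sim_t(anchor, term)
    beta: float
    anchor_known: bool = True


class PatientTransitionStats:
    """Per-patient within-visit transition counts g(t' -> t | p)."""

    def __init__(self, corpus: SearchCorpus):
        # patient -> dst term -> src term -> count
        self.incoming: dict[int, dict[int, dict[int, int]]] = defaultdict(
            lambda: defaultdict(dict)
        )
        self.n_transitions: dict[int, int] = defaultdict(int)
        for seq in corpus.sequences:
            pi = corpus.patients.index[seq.patient_id]
            ixs = [corpus.terms.index[t] for t in seq.terms]
            for a, b in zip(ixs, ixs[1:]):
                srcs = self.incoming[pi][b]
                srcs[a] = srcs.get(a, 0) + 1
                self.n_transitions[pi] += 1

    def g(self, src: int, dst: int, patient: int) -> int:
        return self.incoming.get(patient, {}).get(dst, {}).get(src, 0)


def similar_terms(
    sim_t: SimilarityIndex, t: int | None, beta: float
) -> SimilarTermSet:
    """All terms with sim_t(t, .) >= beta, the anchor included.

    The threshold is inclusive, so beta = 1 still keeps the anchor (and any
    term with an identical patient profile).  An unknown anchor yields a
    singleton set, flagged via ``anchor_known``.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    if t is None or not (0 <= t < sim_t.n):
        return SimilarTermSet(anchor=-1 if t is None else t, members={}, beta=beta,
                              anchor_known=False)
    row = sim_t.row(t)
    # tiny slack so parallel profiles (cosine 1 up to float error) survive beta = 1
    members = {int(j): float(row[j]) for j in (row >= beta - 1e-9).nonzero()[0]}
    members.setdefault(t, float(row[t]))
    return SimilarTermSet(anchor=t, members=members, beta=beta)


def score_tptcf(
    stats: PatientTransitionStats,
    similar_patients: list[tuple[int, float]],
    term_set: SimilarTermSet,
    ) -> dict[int, float]:
    """Evaluate the TptCF score for every candidate next term.

    Candidates are terms with at least one observed transition, on some
    similar patient, out of the similar-term set.  A patient with no such
    transitions into a term contributes 0 for that term.  With no similar
    patients (or all patient sims zero) every score is 0 and the map is
    empty.
    """
    weight_total = sum(s for _, s in similar_patients)
    if weight_total <= 0.0 or not term_set.members:
        return {}
    scores: dict[int, float] = defaultdict(float)
    for p2, sp_ in similar_patients:
        w = sp_ / weight_total
        if w == 0.0:
            continue
        for dst, srcs in stats.incoming.get(p2, {}).items():
            num = 0.0
            den = 0
            for src, c in srcs.items():
                sim = term_set.members.get(src)
                if sim is not None:
                    num += c * sim
                    den += c
            if den > 0:
                scores[dst] += w * (num / den)
    return dict(scores)
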