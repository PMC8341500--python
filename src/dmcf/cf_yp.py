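"""Physician-patient-similarity collaborative filtering (ypCF).

The scorer works from physician/patient neighbor sets and the table of
training triplet frequencies f(<y, p, t>) — how often physician y searched
term t on patient p.  Two neighbor-identification orders exist:

* ``simP2Y`` (patient-first): take the top-k_p patients most similar to the
  target patient; candidate physicians are those who searched, on at least
  one of those patients, a term that was also searched (by anyone) on the
  target patient; keep the top-k_y candidates by physician similarity.
* ``simY2P`` (physician-first): take the top-k_y physicians most similar to
  the target physician; candidate patients are those on whom one of these
  physicians searched a term that the same physician also searched on the
  target patient; keep the top-k_p candidates by patient similarity.

The score of a candidate term t is the target pair's mean triplet frequency
plus a similarity-weighted average of centered neighbor frequencies
f_hat = f - f_bar, the centering removing each neighbor pair's own search
volume so that heavy searchers do not dominate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .corpus import SearchCorpus
from .similarity import SimilarityIndex

__all__ = [
    "TripletTable",
    "NeighborSets",
    "identify_simP2Y",
    "identify_simY2P",
    "score_ypcf",
]


@dataclass
class NeighborSets:
    """Ordered similar-patient and similar-physician lists with their sims."""

    similar_patients: list[tuple[int, float]]
    similar_physicians: list[tuple[int, float]]
    method: str  # "simP2Y" or "simY2P"
    target_known: bool = True

    def to_tsv(self, path, corpus: SearchCorpus) -> None:
        """Dump both neighbor lists for inspection."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("kind\trank\tid\tsim\n")
            for kind, items, vocab in (
                ("patient", self.similar_patients, corpus.patients),
                ("physician", self.similar_physicians, corpus.physicians),
            ):
                for rank, (ix, sim) in enumerate(items, start=1):
                    fh.write(f"{kind}\t{rank}\t{vocab[ix]}\t{sim:.12g}\n")


class TripletTable:
    """Sparse <physician, patient, term> training frequencies and their indexes.

    Per observed (y, p) pair the table also carries the mean frequency
    f_bar over the pair's distinct observed terms, which both centers
    neighbor contributions and serves as the target pair's base score.
    """

    def __init__(self, corpus: SearchCorpus):
        self.pair_terms: dict[tuple[int, int], dict[int, int]] = defaultdict(dict)
        # terms searched on each patient by anyone
        self.patient_terms: dict[int, set[int]] = defaultdict(set)
        # physician -> term -> patients it was searched on
        self.physician_term_patients: dict[int, dict[int, set[int]]] = defaultdict(
            lambda: defaultdict(set)
        )
        # patient -> physician -> terms searched by that physician on them
        self.patient_physician_terms: dict[int, dict[int, set[int]]] = defaultdict(
            lambda: defaultdict(set)
        )
        for seq in corpus.sequences:
            yi = corpus.physicians.index[seq.physician_id]
            pi = corpus.patients.index[seq.patient_id]
            for t in seq.terms:
                ti = corpus.terms.index[t]
                d = self.pair_terms[(yi, pi)]
                d[ti] = d.get(ti, 0) + 1
                self.patient_terms[pi].add(ti)
                self.physician_term_patients[yi][ti].add(pi)
                self.patient_physician_terms[pi][yi].add(ti)
        self.pair_mean: dict[tuple[int, int], float] = {
            pair: sum(d.values()) / len(d) for pair, d in self.pair_terms.items()
        }

    def frequency(self, y: int, p: int, t: int) -> int:
        return self.pair_terms.get((y, p), {}).get(t, 0)

    def mean_frequency(self, y: int, p: int) -> float:
        """f_bar for the pair; 0 for a pair never observed in training."""
        return self.pair_mean.get((y, p), 0.0)


def identify_simP2Y(
    triplets: TripletTable,
    sim_p: SimilarityIndex,
    sim_y: SimilarityIndex,
    y: int | None,
    p: int | None,
    k_p: int,
    k_y: int,
) -> NeighborSets:
    """Patient-first neighbor identification."""
    if p is None or y is None or not (0 <= p < sim_p.n) or not (0 <= y < sim_y.n):
        return NeighborSets([], [], "simP2Y", target_known=False)
    s_p = sim_p.top_k(p, k_p)
    target_terms = triplets.patient_terms.get(p, set())
    candidates: set[int] = set()
    for p2, _ in s_p:
        for y2, terms in triplets.patient_physician_terms.get(p2, {}).items():
            if y2 != y and not terms.isdisjoint(target_terms):
                candidates.add(y2)
    s_y = sim_y.top_k(y, k_y, candidates=sorted(candidates)) if candidates else []
    return NeighborSets(s_p, s_y, "simP2Y")


def identify_simY2P(
    triplets: TripletTable,
    sim_p: SimilarityIndex,
    sim_y: SimilarityIndex,
    y: int | None,
    p: int | None,
    k_p: int,
    k_y: int,
) -> NeighborSets:
    """Physician-first neighbor identification."""
    if p is None or y is None or not (0 <= p < sim_p.n) or not (0 <= y < sim_y.n):
        return NeighborSets([], [], "simY2P", target_known=False)
    s_y = sim_y.top_k(y, k_y)
    candidates: set[int] = set()
    for y2, _ in s_y:
        shared = triplets.pair_terms.get((y2, p), {})
        for t in shared:
            candidates.update(triplets.physician_term_patients[y2].get(t, ()))
    candidates.discard(p)
    s_p = sim_p.top_k(p, k_p, candidates=sorted(candidates)) if candidates else []
    return NeighborSets(s_p, s_y, "simY2P")


def score_ypcf(
    triplets: TripletTable,
    neighbors: NeighborSets,
    y: int | None,
    p: int | None,
) -> dict[int, float]:
    """Score candidate terms with the centered-frequency CF formula.

    Candidates are the terms appearing in the neighbor triplet set
    {<y', p', t> : y' similar physician, p' similar patient, f > 0}; any
    other term would receive the constant base score and is excluded from
    ranking.  A term whose contributing similarity weights are all zero
    receives no CF adjustment.
    """
    num: dict[int, float] = defaultdict(float)
    den: dict[int, float] = defaultdict(float)
    for y2, sy in neighbors.similar_physicians:
        for p2, sp_ in neighbors.similar_patients:
            terms = triplets.pair_terms.get((y2, p2))
            if not terms:
                continue
            w = sy * sp_
            mean = triplets.pair_mean[(y2, p2)]
            for t, c in terms.items():
                num[t] += (c - mean) * w
                den[t] += w
    base = triplets.mean_frequency(y, p) if y is not None and p is not None else 0.0
    return {
        t: base + (num[t] / den[t] if den[t] > 0.0 else 0.0) for t in num
    }
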