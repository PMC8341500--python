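"""First-order Markov chain over search terms (the foMC dynamics scorer).

The transition probability from term ``t_i`` to ``t_j`` is the plain
frequency ratio

    P(t_j | t_i) = h(t_i -> t_j) / sum_k h(t_i -> t_k),

where ``h`` counts adjacent pairs within single visit sequences, pooled over
all physicians and patients.  No smoothing is applied: an unobserved
transition scores exactly 0.  Transitions are never counted across a visit
boundary, and self-transitions are counted when present.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import SearchCorpus, Vocabulary

__all__ = ["TransitionModel", "fit_transitions", "score_dyn"]

_SERIAL_HEADER = "# dmcf transition model v1"


@dataclass
class TransitionModel:
    """Sparse transition counts and the row-normalized chain they induce."""

    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    row_totals: dict[int, int] = field(default_factory=dict)
    vocabulary: Vocabulary = field(default_factory=Vocabulary)
    # outgoing adjacency: src index -> {dst index: count}
    _rows: dict[int, dict[int, int]] = field(default_factory=dict)

    @property
    def n_transitions(self) -> int:
        return sum(self.counts.values())

    def probability(self, src: str, dst: str) -> float:
        i = self.vocabulary.get(src)
        j = self.vocabulary.get(dst)
        if i is None or j is None:
            return 0.0
        total = self.row_totals.get(i, 0)
        if total == 0:
            return 0.0
        return self.counts.get((i, j), 0) / total

    def transition_row(self, src: str) -> dict[str, float]:
        """P(. | src) over terms with positive probability; empty if unseen."""
        i = self.vocabulary.get(src)
        if i is None:
            return {}
        total = self.row_totals.get(i, 0)
        if total == 0:
            return {}
        return {
            self.vocabulary[j]: c / total for j, c in self._rows[i].items()
        }

    def save(self, path: str | Path) -> None:
        """Write the model as a versioned ``src<TAB>dst<TAB>count`` triplet file."""
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(_SERIAL_HEADER + "\n")
            fh.write("src\tdst\tcount\n")
            for (i, j), c in sorted(self.counts.items()):
                fh.write(f"{self.vocabulary[i]}\t{self.vocabulary[j]}\t{c}\n")

    @classmethod
    def load(cls, path: str | Path) -> "TransitionModel":
        model = cls()
        with Path(path).open("r", encoding="utf-8") as fh:
            version = fh.readline().rstrip("\n")
            if version != _SERIAL_HEADER:
                raise ValueError(f"unrecognized transition-model file: {version!r}")
            fh.readline()  # column header
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                src, dst, c = line.split("\t")
                model._observe(model.vocabulary.add(src), model.vocabulary.add(dst), int(c))
        return model

    def _observe(self, i: int, j: int, n: int = 1) -> None:
        self.counts[(i, j)] = self.counts.get((i, j), 0) + n
        self.row_totals[i] = self.row_totals.get(i, 0) + n
        self._rows.setdefault(i, defaultdict(int))[j] += n


def fit_transitions(corpus: SearchCorpus) -> TransitionModel:
    """Count every adjacent within-visit term pair, pooled over all sequences.

    The resulting chain is shared across physicians and patients: the
    dynamics score deliberately captures population-level search patterns,
    not per-clinician ones.  An empty corpus yields an empty model.
    """
    model = TransitionModel(vocabulary=corpus.terms)
    for seq in corpus.sequences:
        ixs = [corpus.terms.index[t] for t in seq.terms]
        for a, b in zip(ixs, ixs[1:]):
            model._observe(a, b)
    return model


def score_dyn(model: TransitionModel, last_term: str) -> tuple[dict[str, float], bool]:
    """Dynamics scores: P(t | last_term) for every term with positive probability.

    Returns ``(scores, known)``.  ``known`` is False when ``last_term`` was
    never observed as a transition source (or is absent from the vocabulary),
    in which case the scores are empty and a hybrid caller can fall back to
    the collaborative-filtering component alone.
    """
    scores = model.transition_row(last_term)
    return scores, bool(scores)
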