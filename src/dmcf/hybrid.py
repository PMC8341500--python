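"""Blending the dynamics and collaborative-filtering scores into DmCF.

The hybrid score of a candidate term t is the linear combination

    Score(t) = (1 - alpha) * Score_DYN(t) + alpha * Score_CF(t),

with alpha in [0, 1] weighting the CF component.  The two components live on
different scales (the Markov score is a probability, the CF scores are
frequency-denominated); they are combined raw by default, with an optional
per-component min-max rescaling for experimentation.  The candidate universe
is the union of the components' candidates, restricted to components with
nonzero weight — so alpha = 0 reproduces the dynamics ranking exactly and
alpha = 1 the CF ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HybridConfig", "Recommendation", "score_dmcf", "recommend_top_n"]

METHODS = ("foMC", "ypCF", "TptCF", "DmCF-ypCF", "DmCF-TptCF")


@dataclass(frozen=True)
class HybridConfig:
    """A scoring configuration: method, CF weight and neighborhood sizes.

    ``method`` selects a pure scorer ("foMC", "ypCF", "TptCF") or a hybrid
    ("DmCF-ypCF", "DmCF-TptCF").  ``alpha`` is the CF weight and only affects
    the hybrids; ``sim_method`` picks the ypCF neighbor-identification order;
    ``beta`` is the TptCF similar-term threshold; ``n`` the recommendation
    list length.
    """

    method: str = "DmCF-ypCF"
    alpha: float = 0.2
    sim_method: str = "simP2Y"
    k_p: int = 1
    k_y: int = 1
    beta: float = 0.1
    n: int = 5
    rescale: bool = False
    exclude_searched: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.sim_method not in ("simP2Y", "simY2P"):
            raise ValueError(f"unknown sim_method {self.sim_method!r}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def cf_variant(self) -> str | None:
        if self.method in ("ypCF", "DmCF-ypCF"):
            return "ypCF"
        if self.method in ("TptCF", "DmCF-TptCF"):
            return "TptCF"
        return None

    @property
    def effective_alpha(self) -> float:
        """The CF weight actually applied: pure methods pin it to 0 or 1."""
        if self.method == "foMC":
            return 0.0
        if self.method in ("ypCF", "TptCF"):
            return 1.0
        return self.alpha


@dataclass
class Recommendation:
    """A ranked top-N list with per-term provenance ("dyn", "cf" or "both")."""

    terms: list[str]
    scores: list[float]
    provenance: list[str]
    empty: bool = False

    def __len__(self) -> int:
        return len(self.terms)

    def rank_of(self, term: str) -> int | None:
        """1-based rank of a term in the list, or None if absent."""
        try:
            return self.terms.index(term) + 1
        except ValueError:
            return None


def _minmax(scores: dict[int, float]) -> dict[int, float]:
    if not scores:
        return {}
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        return {t: 1.0 for t in scores}
    return {t: (s - lo) / (hi - lo) for t, s in scores.items()}


def score_dmcf(
    dyn: dict[int, float],
    cf: dict[int, float],
    alpha: float,
    rescale: bool = False,
) -> dict[int, float]:
    """Blend the two candidate score maps; missing keys count as 0.

    Terms unknown to both components are never candidates, and a component
    with zero weight contributes neither scores nor candidates.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if rescale:
        dyn, cf = _minmax(dyn), _minmax(cf)
    if alpha == 0.0:
        return dict(dyn)
    if alpha == 1.0:
        return dict(cf)
    out: dict[int, float] = {}
    for t in dyn.keys() | cf.keys():
        out[t] = (1.0 - alpha) * dyn.get(t, 0.0) + alpha * cf.get(t, 0.0)
    return out


def recommend_top_n(
    scores: dict[int, float],
    n: int,
    term_names: list[str] | None = None,
    dyn_candidates: set[int] | frozenset[int] = frozenset(),
    cf_candidates: set[int] | frozenset[int] = frozenset(),
    exclude: set[int] | frozenset[int] = frozenset(),
) -> Recommendation:
    """Top-``n`` terms by score, descending; ties broken by ascending term index.

    ``exclude`` optionally removes terms already searched in the current
    visit (off by default).  An empty score map yields an empty, flagged
    recommendation.
    """
    items = [(t, s) for t, s in scores.items() if t not in exclude]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    items = items[:n]

    def _prov(t: int) -> str:
        in_dyn, in_cf = t in dyn_candidates, t in cf_candidates
        if in_dyn and in_cf:
            return "both"
        if in_cf:
            return "cf"
        return "dyn"

    return Recommendation(
        terms=[term_names[t] if term_names else str(t) for t, _ in items],
        scores=[s for _, s in items],
        provenance=[_prov(t) for t, _ in items],
        empty=not items,
    )
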