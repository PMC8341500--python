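"""The DmCF model / results facade.

``DmCF`` is constructed from a training corpus (or a log file / DataFrame)
plus a :class:`~dmcf.hybrid.HybridConfig`; ``fit()`` estimates every
component the configured scorer needs — the shared first-order transition
chain, the physician/patient/term frequency profiles with their cosine
similarity indexes, the triplet-frequency table (ypCF) and the per-patient
transition statistics (TptCF) — and returns a :class:`DmCFResults` that
recommends next search terms.

Example
-------
>>> from dmcf import DmCF, HybridConfig
>>> res = DmCF.from_log("searches.tsv", HybridConfig(method="DmCF-ypCF", alpha=0.2)).fit()
>>> res.recommend("dr-17", "pt-204", ["ekg", "troponin"]).terms
"""

from __future__ import annotations

from functools import cached_property

import pandas as pd

from .cf_tpt import PatientTransitionStats, score_tptcf, similar_terms
from .cf_yp import TripletTable, identify_simP2Y, identify_simY2P, score_ypcf
from .corpus import (
    NormalizationConfig,
    SearchCorpus,
    corpus_from_frame,
    corpus_stats,
    load_log,
)
from .hybrid import HybridConfig, Recommendation, recommend_top_n, score_dmcf
from .markov import TransitionModel, fit_transitions
from .similarity import ProfileVectors, SimilarityIndex, build_profiles

__all__ = ["DmCF", "DmCFResults"]


class DmCF:
    """The hybrid dynamics / multi-collaborative-filtering recommender model."""

    def __init__(self, corpus: SearchCorpus, config: HybridConfig | None = None):
        self.corpus = corpus
        self.config = config or HybridConfig()

    @classmethod
    def from_log(
        cls,
        path,
        config: HybridConfig | None = None,
        normalization: NormalizationConfig | None = None,
    ) -> "DmCF":
        return cls(load_log(path, normalization), config)

    @classmethod
    def from_dataframe(
        cls,
        events: pd.DataFrame,
        config: HybridConfig | None = None,
        normalization: NormalizationConfig | None = None,
    ) -> "DmCF":
        return cls(corpus_from_frame(events, normalization), config)

    def fit(self) -> "DmCFResults":
        return DmCFResults(self)


class DmCFResults:
    """Fitted scorer components plus recommendation and reporting methods.

    Expensive components (similarity indexes, triplet table, per-patient
    transition stats) are built lazily on first use and cached, so a pure
    Markov configuration never pays for the CF machinery.
    """

    def __init__(self, model: DmCF):
        self.model = model
        self.corpus = model.corpus
        self.config = model.config
        self.transitions: TransitionModel = fit_transitions(self.corpus)

    @cached_property
    def profiles(self) -> ProfileVectors:
        return build_profiles(self.corpus)

    @cached_property
    def sim_y(self) -> SimilarityIndex:
        return SimilarityIndex(self.profiles.physician_profiles, "physician")

    @cached_property
    def sim_p(self) -> SimilarityIndex:
        return SimilarityIndex(self.profiles.patient_profiles, "patient")

    @cached_property
    def sim_t(self) -> SimilarityIndex:
        return SimilarityIndex(self.profiles.term_profiles, "term")

    @cached_property
    def triplets(self) -> TripletTable:
        return TripletTable(self.corpus)

    @cached_property
    def patient_transitions(self) -> PatientTransitionStats:
        return PatientTransitionStats(self.corpus)

    # -- scoring -----------------------------------------------------------

    def _dyn_scores(self, last_term: str | None) -> dict[int, float]:
        if last_term is None:
            return {}
        row = self.transitions.transition_row(last_term)
        tix = self.corpus.terms.index
        return {tix[t]: s for t, s in row.items()}

    def _cf_scores(
        self,
        y_ix: int | None,
        p_ix: int | None,
        last_ix: int | None,
        config: HybridConfig,
    ) -> dict[int, float]:
        variant = config.cf_variant
        if variant == "ypCF":
            identify = identify_simP2Y if config.sim_method == "simP2Y" else identify_simY2P
            neighbors = identify(
                self.triplets, self.sim_p, self.sim_y, y_ix, p_ix, config.k_p, config.k_y
            )
            return score_ypcf(self.triplets, neighbors, y_ix, p_ix)
        if variant == "TptCF":
            if p_ix is None or not (0 <= p_ix < self.sim_p.n):
                return {}
            s_p = self.sim_p.top_k(p_ix, config.k_p)
            s_t = similar_terms(self.sim_t, last_ix, config.beta)
            return score_tptcf(self.patient_transitions, s_p, s_t)
        return {}

    def recommend(
        self,
        physician_id: str,
        patient_id: str,
        sequence: list[str],
        config: HybridConfig | None = None,
        normalization: NormalizationConfig | None = None,
    ) -> Recommendation:
        """Rank next-search-term candidates for one in-progress visit.

        ``sequence`` is the visit's searches so far; only its last term
        feeds the dynamics and similar-term components.  Unknown physicians,
        patients or last terms degrade gracefully: the affected component
        contributes nothing.
        """
        config = config or self.config
        norm = normalization or NormalizationConfig()
        terms = [norm.normalize_term(t) for t in sequence]
        last = terms[-1] if terms else None
        last_ix = self.corpus.terms.get(last) if last is not None else None
        y_ix = self.corpus.physicians.get(physician_id)
        p_ix = self.corpus.patients.get(patient_id)

        alpha = config.effective_alpha
        dyn = self._dyn_scores(last) if alpha < 1.0 else {}
        cf = self._cf_scores(y_ix, p_ix, last_ix, config) if alpha > 0.0 else {}
        blended = score_dmcf(dyn, cf, alpha, rescale=config.rescale)
        exclude = (
            {ix for t in terms if (ix := self.corpus.terms.get(t)) is not None}
            if config.exclude_searched
            else frozenset()
        )
        return recommend_top_n(
            blended,
            config.n,
            term_names=self.corpus.terms.items,
            dyn_candidates=set(dyn),
            cf_candidates=set(cf),
            exclude=exclude,
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the training corpus and fitted components."""
        stats = corpus_stats(self.corpus)
        c = self.config
        lines = [
            "DmCF recommender fit",
            "=" * 44,
            f"{'method':<28}{c.method}",
            f"{'alpha (CF weight)':<28}{c.effective_alpha:g}",
            f"{'sim method':<28}{c.sim_method}",
            f"{'k_p / k_y':<28}{c.k_p} / {c.k_y}",
            f"{'beta (term-sim threshold)':<28}{c.beta:g}",
            "-" * 44,
            f"{'physicians':<28}{int(stats['n_physicians'])}",
            f"{'patients':<28}{int(stats['n_patients'])}",
            f"{'terms':<28}{int(stats['n_terms'])}",
            f"{'sequences':<28}{int(stats['n_sequences'])}",
            f"{'search events':<28}{int(stats['total_searches'])}",
            f"{'mean sequence length':<28}{stats['mean_sequence_length']:.3f}",
            f"{'observed transitions':<28}{self.transitions.n_transitions}",
            f"{'distinct transition pairs':<28}{len(self.transitions.counts)}",
            "=" * 44,
        ]
        return "\n".join(lines)
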