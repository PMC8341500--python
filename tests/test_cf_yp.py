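"""ypCF: neighbor identification orders and the centered-frequency score."""

import numpy as np
import pytest

from dmcf.cf_yp import (
    NeighborSets,
    TripletTable,
    identify_simP2Y,
    identify_simY2P,
    score_ypcf,
)
from dmcf.similarity import SimilarityIndex, build_profiles

from conftest import make_corpus, random_corpus


def indexes(corpus):
    prof = build_profiles(corpus)
    return (
        TripletTable(corpus),
        SimilarityIndex(prof.patient_profiles, "patient"),
        SimilarityIndex(prof.physician_profiles, "physician"),
    )


def eq9_oracle(corpus, s_y, s_p, y_ix, p_ix):
    """Literal evaluation of the centered-frequency CF score via dense loops."""
    f = {}
    for seq in corpus.sequences:
        yi = corpus.physicians.index[seq.physician_id]
        pi = corpus.patients.index[seq.patient_id]
        for t in seq.terms:
            ti = corpus.terms.index[t]
            f[(yi, pi, ti)] = f.get((yi, pi, ti), 0) + 1
    all_terms = range(len(corpus.terms))

    def fbar(y_, p_):
        observed = [t for t in all_terms if f.get((y_, p_, t), 0) > 0]
        if not observed:
            return 0.0
        return sum(f[(y_, p_, t)] for t in observed) / len(observed)

    candidates = {
        t
        for y2, _ in s_y
        for p2, _ in s_p
        for t in all_terms
        if f.get((y2, p2, t), 0) > 0
    }
    scores = {}
    for t in candidates:
        num = den = 0.0
        for y2, sy in s_y:
            for p2, sp in s_p:
                if f.get((y2, p2, t), 0) > 0:
                    num += (f[(y2, p2, t)] - fbar(y2, p2)) * sy * sp
                    den += sy * sp
        scores[t] = fbar(y_ix, p_ix) + (num / den if den > 0 else 0.0)
    return scores


class TestIdentification:
    def test_patient_first_selects_term_sharing_patient(self):
        corpus = make_corpus(
            [
                ("y1", "p1", "v1", ["a"]),
                ("y2", "p2", "v2", ["a", "a"]),  # p2 shares term a with p1
                ("y3", "p3", "v3", ["z"]),       # p3 shares nothing
            ]
        )
        triplets, sim_p, sim_y = indexes(corpus)
        ns = identify_simP2Y(
            triplets, sim_p, sim_y,
            corpus.physicians.index["y1"], corpus.patients.index["p1"], 1, 1,
        )
        assert [corpus.patients[i] for i, _ in ns.similar_patients] == ["p2"]
        assert [corpus.physicians[i] for i, _ in ns.similar_physicians] == ["y2"]

    def test_no_qualifying_physician_leaves_sy_empty(self):
        # only the target physician searched on the similar patient
        corpus = make_corpus(
            [("y1", "p1", "v1", ["a"]), ("y1", "p2", "v2", ["a"])]
        )
        triplets, sim_p, sim_y = indexes(corpus)
        ns = identify_simP2Y(
            triplets, sim_p, sim_y,
            corpus.physicians.index["y1"], corpus.patients.index["p1"], 2, 2,
        )
        assert ns.similar_patients and not ns.similar_physicians

    def _order_matters_corpus(self):
        return make_corpus(
            [
                ("y1", "p1", "v1", ["a"]),
                ("y1", "p4", "v2", ["q"]),
                ("y2", "p5", "v3", ["q"]),            # most physician-similar to y1
                ("y3", "p2", "v4", ["a", "a", "b"]),  # searched p1's term on p2
            ]
        )

    def test_identification_order_changes_the_physician_set(self):
        corpus = self._order_matters_corpus()
        triplets, sim_p, sim_y = indexes(corpus)
        y1 = corpus.physicians.index["y1"]
        p1 = corpus.patients.index["p1"]
        p2y = identify_simP2Y(triplets, sim_p, sim_y, y1, p1, 1, 1)
        y2p = identify_simY2P(triplets, sim_p, sim_y, y1, p1, 1, 1)
        assert [corpus.physicians[i] for i, _ in p2y.similar_physicians] == ["y3"]
        assert [corpus.physicians[i] for i, _ in y2p.similar_physicians] == ["y2"]

    def test_physician_first_empty_sy_implies_empty_sp(self):
        corpus = self._order_matters_corpus()
        triplets, sim_p, sim_y = indexes(corpus)
        y2p = identify_simY2P(
            triplets, sim_p, sim_y,
            corpus.physicians.index["y1"], corpus.patients.index["p1"], 1, 1,
        )
        # y2 never searched a term on p1, so no patient can qualify
        assert y2p.similar_patients == []

    def test_unknown_target_flags_and_empties(self):
        corpus = self._order_matters_corpus()
        triplets, sim_p, sim_y = indexes(corpus)
        for identify in (identify_simP2Y, identify_simY2P):
            ns = identify(triplets, sim_p, sim_y, None, 0, 1, 1)
            assert not ns.target_known
            assert ns.similar_patients == [] and ns.similar_physicians == []


class TestScore:
    def test_single_neighbor_worked_value(self):
        # neighbor pair: f(t)=3, f(u)=1 -> mean 2; target pair: one term once -> mean 1
        corpus = make_corpus(
            [
                ("y1", "p1", "v1", ["x"]),
                ("y2", "p2", "v2", ["t", "t", "t", "u"]),
            ]
        )
        triplets = TripletTable(corpus)
        ns = NeighborSets(
            [(corpus.patients.index["p2"], 1.0)],
            [(corpus.physicians.index["y2"], 1.0)],
            "simP2Y",
        )
        scores = score_ypcf(
            triplets, ns, corpus.physicians.index["y1"], corpus.patients.index["p1"]
        )
        assert scores[corpus.terms.index["t"]] == pytest.approx(2.0, abs=1e-12)
        assert scores[corpus.terms.index["u"]] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_neighbor_frequencies_reduce_to_base(self):
        corpus = make_corpus(
            [
                ("y1", "p1", "v1", ["x", "x"]),
                ("y2", "p2", "v2", ["t", "u", "w"]),  # uniform -> centered to 0
            ]
        )
        triplets = TripletTable(corpus)
        ns = NeighborSets(
            [(corpus.patients.index["p2"], 0.5)],
            [(corpus.physicians.index["y2"], 0.7)],
            "simP2Y",
        )
        scores = score_ypcf(
            triplets, ns, corpus.physicians.index["y1"], corpus.patients.index["p1"]
        )
        base = triplets.mean_frequency(
            corpus.physicians.index["y1"], corpus.patients.index["p1"]
        )
        assert base == 2.0
        assert all(v == pytest.approx(base, abs=1e-12) for v in scores.values())

    def test_unobserved_target_pair_scores_from_neighbors_only(self):
        corpus = make_corpus([("y2", "p2", "v1", ["t", "t", "u"])])
        triplets = TripletTable(corpus)
        ns = NeighborSets(
            [(corpus.patients.index["p2"], 1.0)],
            [(corpus.physicians.index["y2"], 1.0)],
            "simP2Y",
        )
        scores = score_ypcf(triplets, ns, None, None)
        assert scores[corpus.terms.index["t"]] == pytest.approx(0.5)
        assert scores[corpus.terms.index["u"]] == pytest.approx(-0.5)

    def test_empty_neighbor_sets_give_no_candidates(self):
        corpus = make_corpus([("y1", "p1", "v1", ["a"])])
        triplets = TripletTable(corpus)
        assert score_ypcf(triplets, NeighborSets([], [], "simP2Y"), 0, 0) == {}

    def test_zero_similarity_physician_is_inert(self):
        corpus = make_corpus(
            [
                ("y2", "p2", "v1", ["t", "t", "u"]),
                ("y3", "p2", "v2", ["w", "t"]),
            ]
        )
        triplets = TripletTable(corpus)
        p2 = corpus.patients.index["p2"]
        y2 = corpus.physicians.index["y2"]
        y3 = corpus.physicians.index["y3"]
        with_zero = score_ypcf(
            triplets, NeighborSets([(p2, 1.0)], [(y2, 0.8), (y3, 0.0)], "simP2Y"), 0, 0
        )
        without = score_ypcf(
            triplets, NeighborSets([(p2, 1.0)], [(y2, 0.8)], "simP2Y"), 0, 0
        )
        shared = set(without)
        assert all(abs(with_zero[t] - without[t]) < 1e-12 for t in shared)

    def test_centering_identity_per_pair(self):
        rng = np.random.default_rng(17)
        corpus = random_corpus(rng, n_sequences=20)
        triplets = TripletTable(corpus)
        for (y_, p_), terms in triplets.pair_terms.items():
            mean = triplets.pair_mean[(y_, p_)]
            assert abs(sum(c - mean for c in terms.values())) < 1e-9

    def test_doubling_frequencies_doubles_scores_and_keeps_ranking(self):
        corpus = make_corpus(
            [
                ("y1", "p1", "v1", ["x"]),
                ("y2", "p2", "v2", ["t", "t", "u"]),
            ]
        )
        doubled = make_corpus(
            [
                ("y1", "p1", "v1", ["x"]),
                ("y1", "p1", "v1b", ["x"]),
                ("y2", "p2", "v2", ["t", "t", "u"]),
                ("y2", "p2", "v2b", ["t", "t", "u"]),
            ]
        )
        ns1 = NeighborSets([(0, 1.0)], [(0, 1.0)], "simP2Y")
        s1 = score_ypcf(
            TripletTable(corpus),
            NeighborSets(
                [(corpus.patients.index["p2"], 1.0)],
                [(corpus.physicians.index["y2"], 1.0)],
                "simP2Y",
            ),
            corpus.physicians.index["y1"],
            corpus.patients.index["p1"],
        )
        s2 = score_ypcf(
            TripletTable(doubled),
            NeighborSets(
                [(doubled.patients.index["p2"], 1.0)],
                [(doubled.physicians.index["y2"], 1.0)],
                "simP2Y",
            ),
            doubled.physicians.index["y1"],
            doubled.patients.index["p1"],
        )
        for t_name in ("t", "u"):
            a = s1[corpus.terms.index[t_name]]
            b = s2[doubled.terms.index[t_name]]
            assert b == pytest.approx(2 * a, abs=1e-12)
        rank = lambda s, c: sorted(s, key=lambda t: (-s[t], t))
        assert [corpus.terms[t] for t in rank(s1, corpus)] == [
            doubled.terms[t] for t in rank(s2, doubled)
        ]

    def test_matches_literal_formula_on_random_corpora(self):
        rng = np.random.default_rng(71)
        for _ in range(30):
            corpus = random_corpus(
                rng,
                n_physicians=int(rng.integers(2, 5)),
                n_patients=int(rng.integers(2, 5)),
                n_terms=int(rng.integers(2, 5)),
                n_sequences=int(rng.integers(2, 12)),
            )
            triplets, sim_p, sim_y = indexes(corpus)
            y_ix = int(rng.integers(len(corpus.physicians)))
            p_ix = int(rng.integers(len(corpus.patients)))
            for identify in (identify_simP2Y, identify_simY2P):
                ns = identify(triplets, sim_p, sim_y, y_ix, p_ix, 2, 2)
                got = score_ypcf(triplets, ns, y_ix, p_ix)
                want = eq9_oracle(
                    corpus, ns.similar_physicians, ns.similar_patients, y_ix, p_ix
                )
                assert set(got) == set(want)
                for t in got:
                    assert abs(got[t] - want[t]) < 1e-10
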