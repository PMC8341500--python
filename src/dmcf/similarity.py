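"""Frequency profiles and cosine similarities for physicians, patients and terms.

Each physician ``y`` is a vector **v** of term search frequencies aggregated
over all of their patients; each patient ``p`` a vector **u** of term
frequencies aggregated over all physicians; each term ``t`` a vector **w** of
per-patient search frequencies aggregated over all physicians.  Entity
similarity is the cosine of the corresponding profile vectors — raw counts,
no tf-idf or binarization.  Entities with an all-zero profile have similarity
0 to everything (including themselves).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.preprocessing import normalize as _l2_normalize

from .corpus import SearchCorpus

__all__ = [
    "ProfileVectors",
    "SimilarityIndex",
    "build_profiles",
    "cosine",
    "top_k_neighbors",
]


@dataclass
class ProfileVectors:
    """Sparse count matrices: physicians x terms, patients x terms, terms x patients."""

    physician_profiles: sp.csr_matrix
    patient_profiles: sp.csr_matrix
    term_profiles: sp.csr_matrix


def build_profiles(corpus: SearchCorpus) -> ProfileVectors:
    """Count profiles from a (training) corpus.

    Every search event increments exactly one cell of each matrix, so all
    three grand totals equal the event count.
    """
    ys, ps, ts = [], [], []
    for seq in corpus.sequences:
        yi = corpus.physicians.index[seq.physician_id]
        pi = corpus.patients.index[seq.patient_id]
        for t in seq.terms:
            ys.append(yi)
            ps.append(pi)
            ts.append(corpus.terms.index[t])
    n_y, n_p, n_t = len(corpus.physicians), len(corpus.patients), len(corpus.terms)
    ones = np.ones(len(ts), dtype=np.int64)
    phys = sp.coo_matrix((ones, (ys, ts)), shape=(n_y, n_t)).tocsr()
    pat = sp.coo_matrix((ones, (ps, ts)), shape=(n_p, n_t)).tocsr()
    term = sp.coo_matrix((ones, (ts, ps)), shape=(n_t, n_p)).tocsr()
    return ProfileVectors(phys, pat, term)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two nonnegative vectors; 0 if either norm is 0."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


class SimilarityIndex:
    """Cosine similarities among rows of one profile matrix, computed on demand.

    Rows are L2-normalized once; a similarity row is then a single sparse
    mat-vec, which keeps memory linear in the profile size even when the
    full pairwise matrix would not fit.
    """

    def __init__(self, profiles: sp.spmatrix, kind: str):
        self.kind = kind
        self._normed = _l2_normalize(sp.csr_matrix(profiles, dtype=float), norm="l2")
        self.n = self._normed.shape[0]
        self._row_cache: dict[int, np.ndarray] = {}

    def row(self, i: int) -> np.ndarray:
        """Dense vector of similarities of entity ``i`` to every entity."""
        cached = self._row_cache.get(i)
        if cached is None:
            cached = np.clip(
                (self._normed @ self._normed[i].T).toarray().ravel(), 0.0, 1.0
            )
            if len(self._row_cache) > 4096:
                self._row_cache.clear()
            self._row_cache[i] = cached
        return cached

    def sim(self, i: int, j: int) -> float:
        return float(self.row(i)[j])

    def pairwise(self) -> np.ndarray:
        """Full dense pairwise similarity matrix (small problems only)."""
        return np.clip((self._normed @ self._normed.T).toarray(), 0.0, 1.0)

    def top_k(
        self, i: int, k: int, candidates: np.ndarray | list[int] | None = None
    ) -> list[tuple[int, float]]:
        """Up to ``k`` nearest neighbors of ``i`` by similarity, descending.

        The entity itself and zero-similarity entities are excluded; ties are
        broken by ascending entity index, so results are deterministic.  An
        optional ``candidates`` array restricts the ranking to a subset.
        """
        sims = self.row(i)
        if candidates is None:
            ixs = np.flatnonzero(sims)
        else:
            cand = np.asarray(candidates, dtype=int)
            ixs = cand[sims[cand] > 0.0]
        ixs = ixs[ixs != i]
        if ixs.size == 0 or k <= 0:
            return []
        order = np.lexsort((ixs, -sims[ixs]))[:k]
        chosen = ixs[order]
        return [(int(j), float(sims[j])) for j in chosen]

    def save(self, path, threshold: float = 0.0) -> None:
        """Dump nonzero pairwise similarities as ``i<TAB>j<TAB>sim`` triplets (i<j)."""
        mat = sp.triu(sp.csr_matrix(self._normed @ self._normed.T), k=1).tocoo()
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# dmcf similarity index v1 kind={self.kind}\n")
            fh.write("i\tj\tsim\n")
            order = np.lexsort((mat.col, mat.row))
            for r, c, v in zip(mat.row[order], mat.col[order], mat.data[order]):
                if v > threshold:
                    fh.write(f"{r}\t{c}\t{min(v, 1.0):.12g}\n")


def top_k_neighbors(index: SimilarityIndex, entity: int, k: int) -> list[tuple[int, float]]:
    """Module-level convenience wrapper around :meth:`SimilarityIndex.top_k`.

    Unknown entities (index out of range) yield an empty list.
    """
    if not 0 <= entity < index.n:
        import warnings

        warnings.warn(f"unknown {index.kind} entity {entity}; no neighbors")
        return []
    return index.top_k(entity, k)
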