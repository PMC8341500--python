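"""Temporal cutoff evaluation (CUTOFF protocol), HR@N and grid search.

All search sequences are split at one cutoff instant.  Events strictly
before the cutoff form the training corpus; for each sequence that straddles
the cutoff, the first post-cutoff term becomes that sequence's single test
label and later terms are discarded.  Sequences entirely before the cutoff
still train the models; sequences with no pre-cutoff term are dropped from
both training and testing.  Performance is Hit-Rate at N: the fraction of
test sequences whose held-out term appears among the top-N recommendations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import SearchCorpus, SearchSequence
from .hybrid import HybridConfig, Recommendation
from .model import DmCF, DmCFResults

__all__ = [
    "TestCase",
    "CutoffSplit",
    "EvalResult",
    "quantile_cutoff",
    "make_cutoff_split",
    "hit_rate_at_n",
    "run_evaluation",
    "grid_search",
    "default_grid",
    "expand_grid",
]


@dataclass(frozen=True)
class TestCase:
    """One held-out prediction task: the training prefix and its next term."""

    physician_id: str
    patient_id: str
    visit_id: str
    prefix: tuple[str, ...]
    truth: str


@dataclass
class CutoffSplit:
    cutoff_time: pd.Timestamp
    train_corpus: SearchCorpus
    test_cases: list[TestCase]

    @property
    def usable(self) -> bool:
        return len(self.test_cases) > 0


def quantile_cutoff(corpus: SearchCorpus, q: float) -> pd.Timestamp:
    """Cutoff instant at the empirical quantile ``q`` of all event times.

    The empirical quantile (rather than linear interpolation of the min/max
    range) guarantees that a fraction ``q`` of the searches falls before the
    cutoff regardless of how stragglers stretch the time range — mirroring
    how real cutoff dates are chosen to leave enough data on both sides.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"cutoff quantile must be in (0, 1), got {q}")
    stamps = [ts for seq in corpus.sequences for ts in seq.timestamps]
    if not stamps:
        raise ValueError("cannot place a cutoff in an empty corpus")
    return pd.Series(stamps).quantile(q, interpolation="nearest")


def make_cutoff_split(
    corpus: SearchCorpus, cutoff_time: pd.Timestamp | str
) -> CutoffSplit:
    """Route every sequence per the temporal-cutoff rules.

    Entirely pre-cutoff: train only.  Straddling: the pre-cutoff prefix
    trains, the first post-cutoff term is the test label, the rest of the
    sequence is discarded.  Entirely post-cutoff: dropped from both sides.
    """
    cutoff = pd.Timestamp(cutoff_time)
    train_seqs: list[SearchSequence] = []
    cases: list[TestCase] = []
    for seq in corpus.sequences:
        n_pre = sum(1 for ts in seq.timestamps if ts < cutoff)
        if n_pre == 0:
            continue
        if n_pre == len(seq):
            train_seqs.append(seq)
            continue
        train_seqs.append(
            SearchSequence(
                seq.physician_id,
                seq.patient_id,
                seq.visit_id,
                seq.terms[:n_pre],
                seq.timestamps[:n_pre],
            )
        )
        cases.append(
            TestCase(
                seq.physician_id,
                seq.patient_id,
                seq.visit_id,
                tuple(seq.terms[:n_pre]),
                seq.terms[n_pre],
            )
        )
    return CutoffSplit(cutoff, SearchCorpus.from_sequences(train_seqs), cases)


def hit_rate_at_n(recs: list[Recommendation], truths: list[str], n: int) -> float:
    """Fraction of cases whose true next term appears in the top-``n`` list."""
    if len(recs) != len(truths):
        raise ValueError("recommendation and truth lists must align")
    if not truths:
        raise ValueError("empty test set")
    hits = 0
    for rec, truth in zip(recs, truths):
        rank = rec.rank_of(truth)
        if rank is not None and rank <= n:
            hits += 1
    return hits / len(truths)


@dataclass
class EvalResult:
    """HR@1..N for one configuration on one cutoff split."""

    config: HybridConfig
    hr: dict[int, float]
    n_test: int
    ranks: tuple[int | None, ...] = field(default=(), repr=False)
    usable: bool = True

    def to_row(self) -> dict:
        c = self.config
        row = {
            "method": c.method,
            "sim": c.sim_method if c.cf_variant == "ypCF" else "-",
            "alpha": c.alpha if c.method.startswith("DmCF") else float("nan"),
            "k_p": c.k_p if c.cf_variant else np.nan,
            "k_y": c.k_y if c.cf_variant == "ypCF" else np.nan,
            "beta": c.beta if c.cf_variant == "TptCF" else float("nan"),
        }
        row.update({f"HR@{k}": v for k, v in sorted(self.hr.items())})
        row["n_test"] = self.n_test
        return row


def run_evaluation(
    split: CutoffSplit,
    config: HybridConfig,
    results: DmCFResults | None = None,
    max_n: int = 5,
) -> EvalResult:
    """Fit on the training corpus only and score every test case.

    A prefit ``results`` (from the same training corpus) may be supplied to
    share the similarity indexes across configurations of a grid.  Cases for
    which the scorer returns an empty list count as misses.
    """
    if not split.usable:
        return EvalResult(config, {k: 0.0 for k in range(1, max_n + 1)}, 0, usable=False)
    if results is None:
        results = DmCF(split.train_corpus, config).fit()
    rank_config = replace(config, n=max_n)
    ranks: list[int | None] = []
    for case in split.test_cases:
        rec = results.recommend(
            case.physician_id, case.patient_id, list(case.prefix), rank_config
        )
        ranks.append(rec.rank_of(case.truth))
    n_test = len(ranks)
    hr = {
        k: sum(1 for r in ranks if r is not None and r <= k) / n_test
        for k in range(1, max_n + 1)
    }
    return EvalResult(config, hr, n_test, ranks=tuple(ranks))


def grid_search(
    split: CutoffSplit,
    configs: list[HybridConfig],
    max_n: int = 5,
) -> pd.DataFrame:
    """Evaluate every configuration; flag per-method and overall best rows.

    Returns one row per configuration with HR@1..N plus boolean columns
    ``best_method_HR@k`` (best within its method) and ``best_overall_HR@k``.
    Fitted components are shared across configurations.
    """
    if not configs:
        raise ValueError("empty configuration grid")
    results = DmCF(split.train_corpus, configs[0]).fit()
    rows = [
        run_evaluation(split, cfg, results=results, max_n=max_n).to_row()
        for cfg in configs
    ]
    df = pd.DataFrame(rows)
    for k in range(1, max_n + 1):
        col = f"HR@{k}"
        df[f"best_method_{col}"] = df.groupby("method")[col].transform("max") == df[col]
        df[f"best_overall_{col}"] = df[col] == df[col].max()
    return df


def expand_grid(spec: dict) -> list[HybridConfig]:
    """Expand a flat grid description into configurations.

    ``spec`` maps ``methods`` to a list of method names and optionally
    ``alpha``, ``k_p``, ``k_y``, ``beta``, ``sim`` to value lists; for each
    method the cartesian product over the parameters that method actually
    uses is taken (so a foMC row is emitted once, not once per alpha).
    """
    methods = spec.get("methods", ["foMC"])
    alphas = spec.get("alpha", [0.2])
    k_ps = spec.get("k_p", [1])
    k_ys = spec.get("k_y", [1])
    betas = spec.get("beta", [0.1])
    sims = spec.get("sim", ["simP2Y"])
    configs: list[HybridConfig] = []
    for method in methods:
        use_alpha = alphas if method.startswith("DmCF") else [0.0]
        use_sim = sims if method in ("ypCF", "DmCF-ypCF") else ["simP2Y"]
        use_ky = k_ys if method in ("ypCF", "DmCF-ypCF") else [1]
        use_kp = k_ps if method != "foMC" else [1]
        use_beta = betas if method in ("TptCF", "DmCF-TptCF") else [0.1]
        for alpha, sim, k_p, k_y, beta in itertools.product(
            use_alpha, use_sim, use_kp, use_ky, use_beta
        ):
            configs.append(
                HybridConfig(
                    method=method, alpha=alpha, sim_method=sim,
                    k_p=k_p, k_y=k_y, beta=beta,
                )
            )
    return configs


def default_grid(
    alphas: tuple[float, ...] = tuple(round(a / 10, 1) for a in range(11)),
    k_ps: tuple[int, ...] = (1, 2, 3, 5, 10, 20, 50, 100, 200, 500),
    k_ys: tuple[int, ...] = (1, 2, 5, 10, 20, 100),
    betas: tuple[float, ...] = tuple(round(b / 10, 1) for b in range(1, 10)),
) -> list[HybridConfig]:
    """The full parameter grid over all five methods (large; trim for quick runs)."""
    configs: list[HybridConfig] = [HybridConfig(method="foMC")]
    for sim, k_p, k_y in itertools.product(("simP2Y", "simY2P"), k_ps, k_ys):
        configs.append(HybridConfig(method="ypCF", sim_method=sim, k_p=k_p, k_y=k_y))
    for k_p, beta in itertools.product(k_ps, betas):
        configs.append(HybridConfig(method="TptCF", k_p=k_p, beta=beta))
    for alpha, sim, k_p, k_y in itertools.product(
        (a for a in alphas if 0.0 < a < 1.0), ("simP2Y", "simY2P"), k_ps, k_ys
    ):
        configs.append(
            HybridConfig(method="DmCF-ypCF", alpha=alpha, sim_method=sim, k_p=k_p, k_y=k_y)
        )
    for alpha, k_p, beta in itertools.product(
        (a for a in alphas if 0.0 < a < 1.0), k_ps, betas
    ):
        configs.append(HybridConfig(method="DmCF-TptCF", alpha=alpha, k_p=k_p, beta=beta))
    return configs
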