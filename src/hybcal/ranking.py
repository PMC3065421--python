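"""Sample-independence validation of a protocol calibration.

A calibration is only trustworthy if the protocol ranking does not depend on
the biological samples used. This module stratifies genes by their
standardized differential-expression strength into Z/L/M/H quartiles, draws
many gene subsamples with random stratum proportions (emulating calibration
samples of very different character), ranks all protocols on every subsample
by the naive-Bayes log-likelihood, and summarizes the resulting rank
distribution. A stable winner certifies sample independence; a diffuse rank-1
distribution indicates that the calibration samples were unsuitable (for
example, strongly biased towards down-regulation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel_io import ExpressionSet, ValidationError
from . import measures

__all__ = [
    "StratifiedGenes",
    "RankDistribution",
    "STRATA",
    "stratify_genes",
    "draw_subsample",
    "rank_protocols",
    "recommend_protocol",
    "diagnose_instability",
    "write_rank_distribution",
    "write_recommendation",
    "plot_rank_distribution",
]

STRATA = ("Z", "L", "M", "H")


@dataclass
class StratifiedGenes:
    """Assignment of every gene to a Z/L/M/H stratum plus the statistic used.

    ``d`` is the standardized mean difference |mu1 - mu0| / sigma computed on
    the pooled data, so a single assignment serves all protocols.
    """

    stratum_of: pd.Series  # gene_id -> "Z"/"L"/"M"/"H"
    d: pd.Series  # gene_id -> stratification statistic

    def genes_in(self, stratum: str) -> list[str]:
        return list(self.stratum_of.index[self.stratum_of == stratum])

    @property
    def sizes(self) -> dict[str, int]:
        return {s: int((self.stratum_of == s).sum()) for s in STRATA}


@dataclass
class RankDistribution:
    """Frequency with which each protocol achieved each rank over subsamples.

    ``freq`` is a protocols x ranks frame; each row sums to 1 and, because
    every subsample assigns each rank exactly once, each column sums to 1 as
    well (the matrix is doubly stochastic).
    """

    freq: pd.DataFrame  # index: protocol K, columns: rank 1..P
    n_subsamples: int
    subset_size: int

    @property
    def protocols(self) -> list[str]:
        return list(self.freq.index)

    def rank1_share(self) -> pd.Series:
        return self.freq[1]


def stratify_genes(
    es_pooled: ExpressionSet, sigma_floor: float = measures.SIGMA_FLOOR
) -> StratifiedGenes:
    """Quartile stratification by standardized mean difference.

    Genes are sorted by (d, gene id) — the id breaks ties deterministically —
    and split into four equal-size blocks: Z holds the lowest quartile, H the
    highest.
    """
    if es_pooled.n_genes < 4:
        raise ValidationError("need at least 4 genes to form Z/L/M/H strata")
    mu0, mu1, sigma, _ = measures.fit_arrays(
        es_pooled.values, es_pooled.y, sigma_floor
    )
    d = np.abs(mu1 - mu0) / sigma
    order = sorted(range(es_pooled.n_genes), key=lambda i: (d[i], es_pooled.gene_ids[i]))
    blocks = np.array_split(np.array(order), 4)
    assign = pd.Series(index=pd.Index(es_pooled.gene_ids, name="gene_id"), dtype=object)
    for stratum, block in zip(STRATA, blocks):
        for i in block:
            assign.iloc[int(i)] = stratum
    return StratifiedGenes(
        stratum_of=assign,
        d=pd.Series(d, index=assign.index),
    )


def _stratum_counts(proportions: Sequence[float], size: int) -> list[int]:
    """Integer per-stratum counts summing to ``size`` (largest remainder)."""
    p = np.asarray(proportions, dtype=float)
    if p.size != 4 or np.any(p < 0):
        raise ValidationError("proportions must be 4 non-negative numbers")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValidationError("proportions must sum to 1")
    raw = p * size
    counts = np.floor(raw).astype(int)
    rem = size - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return [int(c) for c in counts]


def draw_subsample(
    strata: StratifiedGenes,
    proportions: Sequence[float],
    size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Sample ``size`` genes without replacement, stratum by stratum.

    Requested counts exceeding a stratum's population are truncated to the
    available genes, so the returned subset may be smaller than ``size`` for
    extreme proportions.
    """
    if size < 4:
        raise ValidationError("subsample size must be at least 4")
    counts = _stratum_counts(proportions, size)
    subset: list[str] = []
    for stratum, want in zip(STRATA, counts):
        pool = strata.genes_in(stratum)
        take = min(want, len(pool))
        if take:
            picked = rng.choice(len(pool), size=take, replace=False)
            subset.extend(pool[i] for i in sorted(picked))
    return subset


def _dirichlet_proportions(rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(np.ones(4))


def rank_protocols(
    es_per_protocol: Mapping[str, ExpressionSet],
    strata: StratifiedGenes,
    n_subsamples: int = 100,
    size: int | None = None,
    proportion_sampler: Callable[[np.random.Generator], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    sigma_floor: float = measures.SIGMA_FLOOR,
    eps: float = measures.POSTERIOR_EPS,
) -> RankDistribution:
    """Rank all protocols on many stratified random gene subsamples.

    For each subsample, stratum proportions are drawn (flat Dirichlet by
    default), one gene subset is drawn, and every protocol is scored by the
    naive-Bayes log-likelihood on that same subset (paired comparison); rank 1
    is best. Exact score ties — which arise when protocol datasets are
    identical — are broken by a per-subsample random permutation so that tied
    protocols share ranks evenly over subsamples.
    """
    if len(es_per_protocol) < 2:
        raise ValidationError("need at least 2 protocols to rank")
    rng = np.random.default_rng() if rng is None else rng
    sampler = proportion_sampler or _dirichlet_proportions
    protocols = list(es_per_protocol)
    gene_sets = {tuple(es.gene_ids) for es in es_per_protocol.values()}
    if len(gene_sets) != 1:
        raise ValidationError("gene ids differ across protocols")
    gene_pos = {g: i for i, g in enumerate(next(iter(es_per_protocol.values())).gene_ids)}
    if size is None:
        size = max(4, len(gene_pos) // 4)
    counts = np.zeros((len(protocols), len(protocols)), dtype=int)
    for _ in range(n_subsamples):
        props = sampler(rng)
        subset = draw_subsample(strata, props, size, rng)
        idx = np.array([gene_pos[g] for g in subset], dtype=int)
        scores = np.array(
            [
                measures.loglik_nb_fit(
                    es_per_protocol[k].values[idx],
                    es_per_protocol[k].y,
                    sigma_floor,
                    eps,
                )
                for k in protocols
            ]
        )
        tie_key = rng.permutation(len(protocols))
        order = sorted(range(len(protocols)), key=lambda i: (-scores[i], tie_key[i]))
        for rank_minus_1, i in enumerate(order):
            counts[i, rank_minus_1] += 1
    freq = pd.DataFrame(
        counts / n_subsamples,
        index=pd.Index(protocols, name="protocol"),
        columns=pd.RangeIndex(1, len(protocols) + 1, name="rank"),
    )
    return RankDistribution(freq=freq, n_subsamples=n_subsamples, subset_size=size)


def recommend_protocol(
    rd: RankDistribution,
    temperature_of: Mapping[str, float],
    top_share_threshold: float = 0.5,
    adjacency_window: float = 2.0,
) -> tuple[str, bool]:
    """Recommend a protocol from the rank-1 shares with the high-temperature
    tie-break.

    Protocols whose rank-1 frequency is at least ``top_share_threshold`` times
    the maximum rank-1 frequency are the *winners*. Among overlapping winners
    the highest hybridization temperature is recommended, to minimize
    cross-hybridization potential. The result is flagged *stable* when the
    winners are temperature-adjacent (their temperatures span at most
    ``adjacency_window`` degrees Celsius, i.e. neighbours on a typical 1-2
    degree protocol grid).
    """
    shares = rd.rank1_share()
    if shares.empty:
        raise ValidationError("empty rank distribution")
    missing = [k for k in shares.index if k not in temperature_of]
    if missing:
        raise ValidationError(f"temperatures missing for protocols: {missing}")
    top = shares.max()
    winners = [k for k in shares.index if shares[k] >= top_share_threshold * top]
    winner = max(winners, key=lambda k: temperature_of[k])
    temps = [temperature_of[k] for k in winners]
    stable = (max(temps) - min(temps)) <= adjacency_window
    return winner, stable


def diagnose_instability(
    rd: RankDistribution, entropy_threshold_bits: float = 1.5
) -> dict:
    """Entropy-based diagnosis of an uncertain rank-1 distribution.

    Returns the Shannon entropy (bits) of the rank-1 shares, a ``biased_flag``
    raised when it exceeds the threshold, and a narrative hint: a diffuse
    winner distribution indicates that a reliable calibration cannot be based
    on the samples used (e.g. samples biased towards one regulation
    direction).
    """
    shares = rd.rank1_share().to_numpy()
    nz = shares[shares > 0]
    entropy = float(-(nz * np.log2(nz)).sum()) + 0.0  # avoid negative zero
    flag = entropy > entropy_threshold_bits
    message = (
        "rank-1 distribution is diffuse: the calibration samples may be "
        "biased (e.g. towards down-regulation) and a reliable temperature "
        "calibration cannot be based on them"
        if flag
        else "rank-1 distribution is concentrated; calibration appears sample-independent"
    )
    return {
        "rank1_entropy_bits": entropy,
        "biased_flag": flag,
        "message": message,
    }


def write_rank_distribution(rd: RankDistribution, path) -> None:
    rd.freq.to_csv(path, sep="\t", lineterminator="\n")


def write_recommendation(
    winner: str, stable: bool, rd: RankDistribution, path
) -> None:
    payload = {
        "winner": winner,
        "stable": bool(stable),
        "rank1_shares": {k: float(v) for k, v in rd.rank1_share().items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_rank_distribution(rd: RankDistribution, path=None):
    """Minimal pie-chart panel of per-protocol rank frequencies (one pie per
    protocol). Requires matplotlib; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(rd.protocols)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.4))
    axes = np.atleast_1d(axes)
    for ax, k in zip(axes, rd.protocols):
        row = rd.freq.loc[k]
        ax.pie(row.to_numpy(), labels=[str(r) for r in row.index], normalize=True)
        ax.set_title(str(k))
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig
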