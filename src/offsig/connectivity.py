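"""Compound-class enrichment near the top of a ranked perturbagen list.

A connectivity-map-style query returns perturbagens ranked by similarity to
a transcriptional signature (rank 1 = strongest match).  Whether a compound
class (e.g. the HDAC inhibitors) concentrates near the top is quantified by
its top-K count/fraction, with significance from a bootstrap null — classes
of the same size resampled uniformly without replacement from the ranked
library — cross-checked by the closed-form hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RankedPerturbagens:
    """Ordered perturbagen ids (rank 1 first) with class annotations."""

    ids: list[str]
    classes: dict[str, list[str]] = field(default_factory=dict)
    scores: np.ndarray | None = None  # optional per-item connectivity score

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("perturbagen ids must be unique")
        self._rank = {pid: i + 1 for i, pid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def members(self, class_name: str) -> list[str]:
        present = [
            pid for pid, labels in self.classes.items()
            if class_name in labels and pid in self._rank
        ]
        if not present:
            raise KeyError(f"class {class_name!r} has no members in the list")
        return present

    def ranks_of(self, class_name: str) -> np.ndarray:
        return np.array(sorted(self._rank[p] for p in self.members(class_name)))


@dataclass
class EnrichmentResult:
    class_name: str
    m: int                 # class size present in the list
    k: int                 # top-K cutoff
    count: int             # |class ∩ top-K|
    fraction: float        # count / m
    bootstrap_p: float
    hypergeom_p: float
    b: int                 # bootstrap replicates
    seed: int


def topk_statistic(
    ranked: RankedPerturbagens, class_name: str, k: int = 250
) -> tuple[int, float]:
    """Count and fraction of class members ranked in the top K."""
    ranks = ranked.ranks_of(class_name)
    count = int((ranks <= k).sum())
    return count, count / len(ranks)


def hypergeometric_tail(n: int, k: int, m: int, observed: int) -> float:
    """P(X ≥ observed) for X ~ Hypergeometric(N=n, K=k, m draws).

    The null probability that a uniformly drawn size-m class has at least
    ``observed`` members in the top k of an n-item list.
    """
    if not (0 <= observed <= min(m, k) <= n) or m > n:
        raise ValueError(
            f"inconsistent counts: N={n}, K={k}, m={m}, observed={observed}"
        )
    # stable upper tail via the survival function (log-space internally)
    return float(stats.hypergeom.sf(observed - 1, n, k, m))


def bootstrap_class_enrichment(
    ranked: RankedPerturbagens,
    class_name: str,
    k: int = 250,
    b: int = 10_000,
    seed: int = 0,
    chunk: int = 2_000,
) -> EnrichmentResult:
    """Bootstrap p for the top-K concentration of a compound class.

    Null replicates draw m perturbagen ids uniformly without replacement
    from the N-item list and recompute the top-K count; the add-one
    estimator p = (1 + #{null ≥ observed}) / (B + 1) keeps p ≥ 1/(B+1).
    Sampling uses vectorized random-key selection, chunked over replicates.
    """
    import warnings

    count, fraction = topk_statistic(ranked, class_name, k)
    m, n = len(ranked.ranks_of(class_name)), ranked.n
    if m >= n:
        raise ValueError("class covers the whole list; null undefined")
    if b < 100:
        warnings.warn(f"B={b} gives p resolution of only {1/(b+1):.3g}")
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < b:
        nb = min(chunk, b - done)
        keys = rng.random((nb, n))
        pick = np.argpartition(keys, m - 1, axis=1)[:, :m]  # uniform m-subsets
        null_counts = (pick < k).sum(axis=1)  # position < k  <=>  rank <= k
        exceed += int((null_counts >= count).sum())
        done += nb
    p_boot = (1 + exceed) / (b + 1)
    p_hyper = hypergeometric_tail(n, k, m, count)
    return EnrichmentResult(class_name, m, k, count, fraction,
                            p_boot, p_hyper, b, seed)


def read_ranked_list(path, class_path=None) -> RankedPerturbagens:
    """Read `rank,perturbagen_id[,score]` TSV plus optional class-map TSV."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("rank")
    classes: dict[str, list[str]] = {}
    if class_path is not None:
        cm = pd.read_csv(class_path, sep="\t")
        for pid, sub in cm.groupby("perturbagen_id"):
            classes[pid] = sub["class"].tolist()
    scores = df["score"].to_numpy(float) if "score" in df.columns else None
    return RankedPerturbagens(df["perturbagen_id"].astype(str).tolist(),
                              classes, scores)


def rank_score_table(
    ranked: RankedPerturbagens, class_name: str
) -> pd.DataFrame:
    """Rank positions of class members, as a fraction of the library size."""
    ranks = ranked.ranks_of(class_name)
    return pd.DataFrame({
        "rank": ranks,
        "rank_fraction": ranks / ranked.n,
        "class": class_name,
    })
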