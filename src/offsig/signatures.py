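"""Two-group gene signatures, ssGSEA, and rank-based per-cell scoring.

A transcriptional "On/Off" signature contrasts two sample groups (e.g.
knockdown vs control): genes are first filtered by a two-sided Student
t-test (pooled variance, P ≤ 0.05), then ranked by the signal-to-noise
ratio SNR = (μ_A − μ_B)/(σ_A + σ_B) with the GSEA standard-deviation floor,
and the top-k positive / bottom-k negative genes become the up/down marker
lists.  Samples are scored against gene sets by single-sample GSEA
(rank-weighted ECDF difference); single cells are scored by a Mann–Whitney
U statistic on clipped ranks (UCell-style) with a leukemic-population flag
at score ≥ 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Genes × samples expression (log scale assumed) with group labels."""

    values: pd.DataFrame           # index = gene ids, columns = sample ids
    groups: pd.Series              # sample id -> group label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    def two_groups(self) -> tuple[np.ndarray, np.ndarray, str, str]:
        levels = sorted(self.groups.unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups, got {levels}")
        a, b = levels
        xa = self.values.loc[:, self.groups == a].to_numpy(float)
        xb = self.values.loc[:, self.groups == b].to_numpy(float)
        if xa.shape[1] < 2 or xb.shape[1] < 2:
            raise ValueError("each group needs >= 2 samples")
        return xa, xb, a, b


@dataclass
class GeneSignature:
    up: list[str]
    down: list[str]
    scores: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    k: int = 100

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists overlap")


def ttest_filter(expr: ExpressionMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sided pooled-variance Student t; keep = (p ≤ alpha).

    Genes with zero pooled variance get a missing p, keep=False and a
    degenerate flag.  Welch's correction is available via ``equal_var`` in
    :func:`scipy.stats.ttest_ind` should unequal variances matter; the
    classical Student form is the default here.
    """
    xa, xb, *_ = expr.two_groups()
    res = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    degenerate = (var_a + var_b) == 0
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    return pd.DataFrame({
        "t": t, "p": p,
        "keep": ~degenerate & (p <= alpha),
        "degenerate": degenerate,
    }, index=expr.values.index)


def snr_rank(
    expr: ExpressionMatrix, sigma_floor_frac: float = 0.2,
    sigma_floor_abs: float = 0.2,
) -> pd.Series:
    """Signal-to-noise ratio per gene, sorted descending.

    SNR = (μ_A − μ_B) / (σ_A + σ_B), each per-group σ floored at
    max(``sigma_floor_frac`` × |μ|, ``sigma_floor_abs``) — the GSEA
    convention, which keeps near-constant genes from dominating the ranking.
    Group A is the lexicographically first group label.
    """
    xa, xb, *_ = expr.two_groups()
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a = np.maximum(xa.std(axis=1, ddof=1),
                      np.maximum(sigma_floor_frac * np.abs(mu_a),
                                 sigma_floor_abs))
    sd_b = np.maximum(xb.std(axis=1, ddof=1),
                      np.maximum(sigma_floor_frac * np.abs(mu_b),
                                 sigma_floor_abs))
    snr = pd.Series((mu_a - mu_b) / (sd_a + sd_b), index=expr.values.index,
                    name="snr")
    return snr.sort_values(ascending=False, kind="mergesort")


def build_signature(
    de: pd.DataFrame, snr: pd.Series, k: int = 100,
    apply_filter: bool = True,
) -> GeneSignature:
    """Top-k/bottom-k SNR genes among the t-test-kept genes.

    up = k highest SNR > 0, down = k lowest SNR < 0 (fewer if supply is
    short).  Ties broken deterministically by gene id.  ``apply_filter=False``
    ranks all genes regardless of the t-test gate.
    """
    genes = de.index.intersection(snr.index)
    s = snr.loc[genes]
    if apply_filter:
        s = s[de.loc[genes, "keep"].fillna(False)]
    if s.empty:
        warnings.warn("no genes pass the filter; empty signature")
        return GeneSignature([], [], pd.Series(dtype=float), k)
    order = s.to_frame().assign(gene=s.index).sort_values(
        ["snr", "gene"], ascending=[False, True])
    up = order[order["snr"] > 0].head(k)["gene"].tolist()
    down_order = s.to_frame().assign(gene=s.index).sort_values(
        ["snr", "gene"], ascending=[True, True])
    down = down_order[down_order["snr"] < 0].head(k)["gene"].tolist()
    return GeneSignature(up, down, s.loc[up + down], k)


def ssgsea(
    sample_values: pd.Series, gene_set, alpha_weight: float = 0.25,
    normalize: bool = False,
) -> float:
    """Single-sample GSEA enrichment score for one expression vector.

    Genes are ranked by value descending (gene-id tie-break); the score is
    the sum over all rank positions of the difference between the
    |value|^``alpha_weight``-weighted cumulative in-set fraction and the
    cumulative out-of-set fraction.  ``normalize=True`` divides by the
    number of genes for cross-sample comparability.
    """
    sv = pd.Series(sample_values).astype(float)
    order = sv.to_frame("v").assign(gene=sv.index).sort_values(
        ["v", "gene"], ascending=[False, True])
    genes = order["gene"].to_numpy()
    vals = order["v"].to_numpy()
    in_set = np.isin(genes, list(gene_set))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the expression vector")
    if n_in == len(genes):
        raise ValueError("gene set covers every gene; score undefined")
    w = np.abs(vals) ** alpha_weight
    w_in = np.where(in_set, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_set) / (len(genes) - n_in)
    es = float(np.sum(p_in - p_out))
    return es / len(genes) if normalize else es


def ssgsea_matrix(
    expr: pd.DataFrame, gene_sets: dict, alpha_weight: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA scores for every gene set × sample of an expression frame."""
    out = {}
    for name, members in gene_sets.items():
        out[name] = {
            s: ssgsea(expr[s], members, alpha_weight, normalize)
            for s in expr.columns
        }
    return pd.DataFrame(out).T


def cell_signature_score(
    cell_ranks, signature, r_max: int = 1500, threshold: float = 0.2,
) -> tuple[float, bool]:
    """Rank-based (UCell-style) signature score for one cell.

    ``cell_ranks`` maps gene -> 1-based expression rank within the cell.
    Signature genes missing from the rank universe get rank ``r_max + 1``;
    ranks are clipped at ``r_max + 1``.  With n signature genes,
    U' = Σ clipped ranks − n(n+1)/2 and score = max(0, 1 − U'/(n·r_max)),
    flagged as leukemic population (LP) when score ≥ ``threshold``.
    """
    sig = list(signature)
    n = len(sig)
    if n == 0:
        raise ValueError("empty signature")
    ranks = pd.Series(cell_ranks).astype(float)
    r = np.minimum(ranks.reindex(sig).fillna(r_max + 1).to_numpy(),
                   r_max + 1)
    u = r.sum() - n * (n + 1) / 2.0
    score = max(0.0, 1.0 - u / (n * r_max))
    return float(score), bool(score >= threshold)


def score_cells(
    ranks: pd.DataFrame, signature, r_max: int = 1500, threshold: float = 0.2,
) -> pd.DataFrame:
    """Vectorized :func:`cell_signature_score` over a genes × cells rank frame."""
    sig = list(signature)
    n = len(sig)
    if n == 0:
        raise ValueError("empty signature")
    r = ranks.reindex(sig).fillna(r_max + 1).clip(upper=r_max + 1)
    u = r.sum(axis=0) - n * (n + 1) / 2.0
    score = (1.0 - u / (n * r_max)).clip(lower=0.0)
    return pd.DataFrame({"score": score, "lp": score >= threshold})


def rank_cells(expr: pd.DataFrame) -> pd.DataFrame:
    """1-based descending-expression ranks per cell (average ties)."""
    return expr.rank(axis=0, ascending=False, method="average")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{i}: GMT line needs >= 3 tab-separated fields"
                )
            name, _desc, *members = fields
            uniq = list(dict.fromkeys(m for m in members if m))
            if len(uniq) < len([m for m in members if m]):
                warnings.warn(f"{path}:{i}: duplicate members in {name!r}")
            sets[name] = uniq
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes × samples TSV, first column gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)
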