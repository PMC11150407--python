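"""RIME (ChIP-MS) interactor calling: spectral-count gate and LFQ route.

Chromatin-complex partners of a bait protein are called from
MaxQuant-style proteinGroups tables two ways.  The spectral route keeps a
protein when its MS/MS spectral count reaches a minimum (default 5) in
every bait replicate while the matched IgG control fails that criterion.
The LFQ route log2-transforms intensities, imputes missing values from a
downshifted per-column normal (missingness in LFQ is intensity-dependent),
runs a two-sample t-test with a permutation-based FDR, and calls a protein
significant when p < 0.05, |log2 fold change| ≥ 2 toward the bait, and it
was identified with ≥ 2 peptides.  Hit lists from several samples are
intersected and overlapped with annotated gene sets.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import hypergeometric_tail

FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "site": "Only identified by site",
}


class RimeConfigError(ValueError):
    """Missing flag / replicate columns in the protein table."""


def filter_quant_table(
    table: pd.DataFrame, flag_columns: dict | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop reverse hits, contaminants and only-identified-by-site rows.

    Flag columns follow MaxQuant semantics: a '+' (or truthy) entry marks
    the row.  Returns the filtered table and a per-reason removal log.
    """
    cols = dict(FLAG_COLUMNS)
    cols.update(flag_columns or {})
    missing = [c for c in cols.values() if c not in table.columns]
    if missing:
        raise RimeConfigError(f"missing flag column(s): {missing}")
    keep = pd.Series(True, index=table.index)
    log: dict[str, int] = {}
    for reason, col in cols.items():
        flagged = table[col].fillna("").astype(str).str.strip().isin(
            {"+", "True", "true", "1"})
        log[reason] = int((flagged & keep).sum())
        keep &= ~flagged
    return table[keep].copy(), log


def _condition_columns(table: pd.DataFrame, prefix: str, condition: str):
    cols = [c for c in table.columns
            if c.startswith(f"{prefix} {condition}")]
    if not cols:
        raise RimeConfigError(
            f"no '{prefix} {condition}*' replicate columns found"
        )
    return cols


def spec_hit_call(
    table: pd.DataFrame,
    min_spec: int = 5,
    igg_max_spec: int | None = None,
    sample_condition: str = "sample",
    igg_condition: str = "IgG",
    spec_prefix: str = "MS/MS count",
    igg_rule: str = "all_below",
    igg_ratio: float = 2.0,
    mode: str = "each",
) -> pd.DataFrame:
    """Spectral-count interactor calling against the IgG control.

    A protein is a hit when SPEC ≥ ``min_spec`` in every bait replicate
    (``mode='each'``; ``mode='mean'`` applies the threshold to the replicate
    mean) and the IgG control fails: either SPEC < ``igg_max_spec``
    (default: ``min_spec``) in every IgG replicate
    (``igg_rule='all_below'``, default — IgG-positive proteins are classic
    pulldown background) or mean bait SPEC ≥ ``igg_ratio`` × mean IgG SPEC
    (``igg_rule='mean_ratio'``).  With the IgG threshold pinned, raising
    ``min_spec`` can only remove hits.  Hits are ordered by descending mean
    bait SPEC.
    """
    if igg_max_spec is None:
        igg_max_spec = min_spec
    s_cols = _condition_columns(table, spec_prefix, sample_condition)
    g_cols = _condition_columns(table, spec_prefix, igg_condition)
    s = table[s_cols].to_numpy(float)
    g = table[g_cols].to_numpy(float)
    if mode == "each":
        sample_ok = (s >= min_spec).all(axis=1)
    elif mode == "mean":
        sample_ok = s.mean(axis=1) >= min_spec
    else:
        raise ValueError("mode must be 'each' or 'mean'")
    if igg_rule == "all_below":
        igg_ok = (g < igg_max_spec).all(axis=1)
    elif igg_rule == "mean_ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            igg_ok = s.mean(axis=1) >= igg_ratio * np.maximum(
                g.mean(axis=1), 1e-12)
    else:
        raise ValueError("igg_rule must be 'all_below' or 'mean_ratio'")
    out = table[sample_ok & igg_ok].copy()
    out["mean_spec"] = out[s_cols].mean(axis=1)
    return out.sort_values(
        ["mean_spec", out.columns[0]], ascending=[False, True]
    ).reset_index(drop=True)


def lfq_impute(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing log2 intensities from a downshifted per-column normal.

    Per sample column with observed mean μ and sd σ, missing entries are
    drawn from Normal(μ − ``downshift``·σ, (``width``·σ)²) — the standard
    treatment for intensity-dependent (MNAR) dropout, placing imputed
    values near the detection limit.  Returns the completed matrix and the
    boolean imputed mask.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy().astype(float)
    mask = matrix.isna()
    for col in out.columns:
        obs = out[col].dropna()
        if obs.empty:
            raise ValueError(f"column {col!r} has no observed intensities")
        miss = mask[col]
        if miss.any():
            mu, sd = obs.mean(), obs.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                sd = 0.0
            draws = rng.normal(mu - downshift * sd, width * sd,
                               size=int(miss.sum()))
            out.loc[miss, col] = draws
    return out, mask


def _t_stats(x: np.ndarray, ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Pooled two-sample t per row for column splits ga/gb (vectorized)."""
    a, b = x[:, ga], x[:, gb]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(
            sp2 * (1 / na + 1 / nb))


def lfq_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    peptides: pd.Series | None = None,
    sample_group: str | None = None,
    b: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    min_log2fc: float = 2.0,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Two-sample t with permutation FDR and the interactor gate.

    ``groups`` labels each column with two levels; ``sample_group`` names
    the bait level (default: the lexicographically first level) and fold
    change is sample − control.  The null is built by relabeling columns
    (identity excluded): all distinct relabelings when there are ≤ ``b`` of
    them, otherwise ``b`` random ones.  q is the plug-in permutation FDR —
    the average number of null |t| values at or above each observed |t|,
    divided by the observed count at that threshold, monotonized.
    ``significant`` requires p < ``alpha``, log2 fold change ≥
    ``min_log2fc`` toward the sample, and ≥ ``min_peptides`` peptides.
    """
    groups = pd.Series(groups).reindex(matrix.columns)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if sample_group is None:
        sample_group = levels[0]
    if sample_group not in levels:
        raise ValueError(f"sample_group {sample_group!r} not in {levels}")
    control_group = levels[1] if sample_group == levels[0] else levels[0]
    ga = np.where((groups == sample_group).to_numpy())[0]
    gb = np.where((groups == control_group).to_numpy())[0]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 columns")
    x = matrix.to_numpy(float)
    n_cols = x.shape[1]
    t_obs = _t_stats(x, ga, gb)
    dof = len(ga) + len(gb) - 2
    p = 2 * stats.t.sf(np.abs(t_obs), dof)

    all_splits = list(combinations(range(n_cols), len(ga)))
    # each split and its complement give the same |t|; halve the catalogue
    # and drop the observed labeling (and its complement) from the null
    observed_split = tuple(sorted(ga))
    observed_comp = tuple(sorted(gb))
    unique_splits = []
    seen = set()
    for s in all_splits:
        comp = tuple(sorted(set(range(n_cols)) - set(s)))
        if s in (observed_split, observed_comp):
            continue
        if comp not in seen:
            seen.add(s)
            unique_splits.append(s)
    if len(unique_splits) < 2:
        raise ValueError("fewer than 2 distinct relabelings")
    rng = np.random.default_rng(seed)
    if len(unique_splits) <= b:
        splits = unique_splits
    else:
        idx = rng.choice(len(unique_splits), size=b, replace=False)
        splits = [unique_splits[i] for i in idx]

    abs_obs = np.abs(t_obs)
    finite = np.isfinite(abs_obs)
    null_exceed = np.zeros_like(abs_obs)
    n_perm = 0
    for s in splits:
        sa = np.array(s)
        sb = np.array(sorted(set(range(n_cols)) - set(s)))
        t_null = np.abs(_t_stats(x, sa, sb))
        t_null = t_null[np.isfinite(t_null)]
        null_exceed += np.searchsorted(-np.sort(-t_null), -abs_obs,
                                       side="right")
        n_perm += 1
    mean_null = null_exceed / n_perm
    obs_sorted = -np.sort(-abs_obs[finite])
    n_ge_obs = np.searchsorted(-obs_sorted, -abs_obs, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = mean_null / np.maximum(n_ge_obs, 1)
    # monotonize: q_i = min of plug-in estimates over thresholds at or
    # above |t_i| (suffix minimum in descending-|t| order)
    order = np.argsort(-abs_obs)
    e = np.clip(q[order], 0, 1)
    e = np.where(np.isfinite(e), e, 1.0)
    q_sorted = np.minimum.accumulate(e[::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted

    log2fc = x[:, ga].mean(axis=1) - x[:, gb].mean(axis=1)
    res = pd.DataFrame({
        "log2fc": log2fc, "t": t_obs, "p": p, "q": q_mono,
    }, index=matrix.index)
    sig = (res["p"] < alpha) & (res["log2fc"] >= min_log2fc)
    if peptides is not None:
        sig &= pd.Series(peptides).reindex(matrix.index) >= min_peptides
    res["significant"] = sig.fillna(False)
    return res


def intersect_hits(
    lists, key: str = "gene_symbol", spec_col: str = "mean_spec"
) -> pd.DataFrame:
    """Proteins common to every hit list, ordered by descending mean SPEC.

    ``lists`` is a sequence of hit DataFrames sharing the ``key`` column;
    the intersection is an exact set operation, so it is associative and
    order-invariant by construction.
    """
    lists = list(lists)
    if not lists or any(df.empty for df in lists):
        raise ValueError("intersection needs non-empty hit lists")
    common = set(lists[0][key])
    for df in lists[1:]:
        common &= set(df[key])
    rows = []
    for sym in common:
        specs = [df.loc[df[key] == sym, spec_col].mean()
                 for df in lists if spec_col in df.columns]
        rows.append({key: sym,
                     "mean_spec": float(np.mean(specs)) if specs else np.nan})
    out = pd.DataFrame(rows, columns=[key, "mean_spec"])
    return out.sort_values(["mean_spec", key],
                           ascending=[False, True]).reset_index(drop=True)


def gene_set_overlap(
    proteins, gene_sets: dict, background: int
) -> pd.DataFrame:
    """Per gene set: overlap members, count and hypergeometric enrichment p.

    ``background`` is the assumed universe size (e.g. detectable proteome);
    it must cover the union of the protein set and every gene set tested.
    """
    prot = set(proteins)
    if not prot:
        raise ValueError("empty protein set")
    rows = []
    for name, members in gene_sets.items():
        mem = set(members)
        if background < len(prot | mem):
            raise ValueError(
                f"background {background} smaller than the union for {name!r}"
            )
        ov = sorted(prot & mem)
        pval = hypergeometric_tail(background, len(mem), len(prot), len(ov))
        rows.append({"gene_set": name, "overlap_n": len(ov),
                     "set_size": len(mem), "protein_n": len(prot),
                     "p_hypergeom": pval, "overlap": ";".join(ov)})
    return pd.DataFrame(rows).sort_values(
        ["p_hypergeom", "gene_set"]).reset_index(drop=True)
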