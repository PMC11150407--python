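"""Plate-based viability screen scoring: POC / ΔPOC, hit gating, spatial QC.

A 384-well screen measures luminescence (ATP content) per well.  Each plate
carries DMSO vehicle wells and etoposide positive-control wells; compounds are
plated in duplicate.  Viability is expressed as percent of control
(POC = 100 * L_well / mean vehicle L on the same plate) and its complement,
the normalized percent cell death ΔPOC = 100 * (L̄_vehicle - L̄_compound) /
L̄_vehicle computed on duplicate-averaged luminescence.  Each compound is
tested against pooled vehicle wells with a one-way ANOVA on a two-level
linear model, p-values are Benjamini–Hochberg adjusted, and hits are gated on
adjusted p and a ΔPOC percentile limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ROWS_384 = [chr(ord("A") + i) for i in range(16)]
N_COLS_384 = 24

REQUIRED_COLUMNS = [
    "plate_id", "row", "col", "compound_id", "role",
    "luminescence", "cell_line", "replicate",
]

ROLES = {"sample", "vehicle", "positive"}


class ScreenConfigError(ValueError):
    """A required column or configuration item is missing."""


class ScreenValidationError(ValueError):
    """A well record violates the 384-well grid or role invariants."""


class DegeneratePlateError(ValueError):
    """Plate cannot be normalized (e.g. vehicle mean luminescence of zero)."""


@dataclass
class PlateSet:
    """Well-level screen data with per-plate indexing.

    ``wells`` is a DataFrame with the canonical columns
    ``plate_id,row,col,compound_id,role,luminescence,cell_line,replicate``.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ScreenConfigError(f"missing required columns: {missing}")
        _validate_wells(self.wells)

    @property
    def plate_ids(self) -> list:
        return sorted(self.wells["plate_id"].unique())

    def plate(self, plate_id) -> pd.DataFrame:
        return self.wells[self.wells["plate_id"] == plate_id]

    def vehicle_means(self) -> pd.Series:
        """Mean vehicle luminescence per (plate, cell line)."""
        veh = self.wells[self.wells["role"] == "vehicle"]
        return veh.groupby(["plate_id", "cell_line"])["luminescence"].mean()


def _validate_wells(df: pd.DataFrame) -> None:
    bad_row = ~df["row"].isin(ROWS_384)
    bad_col = (df["col"] < 1) | (df["col"] > N_COLS_384)
    if bad_row.any() or bad_col.any():
        idx = df.index[bad_row | bad_col][:5].tolist()
        raise ScreenValidationError(
            f"wells outside the 384-well grid at rows {idx}"
        )
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        raise ScreenValidationError(
            f"unknown roles: {sorted(df.loc[bad_role, 'role'].unique())}"
        )
    veh = df["role"] == "vehicle"
    veh_named = veh & df["compound_id"].fillna("").astype(str).str.len().gt(0)
    if veh_named.any():
        raise ScreenValidationError(
            "vehicle wells must carry an empty compound_id"
        )
    if (df["luminescence"] < 0).any():
        raise ScreenValidationError("negative luminescence")
    counts = df[veh].groupby("plate_id").size()
    for pid in df["plate_id"].unique():
        if counts.get(pid, 0) < 2:
            raise ScreenValidationError(
                f"plate {pid!r} has fewer than 2 vehicle wells"
            )


def read_screen_table(
    path, dialect: Mapping[str, str] | None = None, sep: str | None = None
) -> PlateSet:
    """Read a well-level CSV/TSV into a :class:`PlateSet`.

    ``dialect`` maps canonical column names to the file's column names.
    Separator is sniffed from the extension unless given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    dialect = dict(dialect or {})
    rename = {v: k for k, v in dialect.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenConfigError(
            f"screen table {path} is missing column(s) {missing}; "
            "map them via the dialect option"
        )
    df = df[REQUIRED_COLUMNS].copy()
    df["compound_id"] = df["compound_id"].fillna("").astype(str)
    df["col"] = df["col"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    df["luminescence"] = df["luminescence"].astype(float)
    return PlateSet(df)


def write_screen_table(plates: PlateSet, path, sep: str = ",") -> None:
    plates.wells.to_csv(path, sep=sep, index=False)


def poc_per_well(plates: PlateSet) -> pd.DataFrame:
    """Percent-of-control per well: 100 * L / mean(vehicle L on same plate).

    Vehicle wells of a plate average to exactly 100.  Raises
    :class:`DegeneratePlateError` when a plate's vehicle mean is zero.
    """
    df = plates.wells.copy()
    vm = plates.vehicle_means().rename("vehicle_mean")
    if (vm <= 0).any():
        bad = vm[vm <= 0].index.tolist()
        raise DegeneratePlateError(
            f"vehicle mean luminescence not positive on plate(s) {bad}"
        )
    df = df.join(vm, on=["plate_id", "cell_line"])
    if df["vehicle_mean"].isna().any():
        bad = df.loc[df["vehicle_mean"].isna(), ["plate_id", "cell_line"]]
        raise DegeneratePlateError(
            "no vehicle wells for plate/cell-line pairs:\n"
            f"{bad.drop_duplicates().to_string(index=False)}"
        )
    df["poc"] = 100.0 * df["luminescence"] / df["vehicle_mean"]
    return df


def delta_poc(
    plates: PlateSet, compound: str, cell_line: str | None = None
) -> float:
    """ΔPOC = 100 * (L̄_vehicle − L̄_compound) / L̄_vehicle.

    Duplicate wells are averaged before the formula; vehicle reference is the
    mean of vehicle wells on the compound's plate(s).
    """
    df = plates.wells
    sel = (df["compound_id"] == compound) & (df["role"] == "sample")
    if cell_line is not None:
        sel &= df["cell_line"] == cell_line
    wells = df[sel]
    if wells.empty:
        raise KeyError(
            f"no wells for compound {compound!r}"
            + (f" in cell line {cell_line!r}" if cell_line else "")
        )
    plate_ids = wells["plate_id"].unique()
    veh = df[(df["role"] == "vehicle") & df["plate_id"].isin(plate_ids)]
    if cell_line is not None:
        veh = veh[veh["cell_line"] == cell_line]
    vbar = veh["luminescence"].mean()
    if not vbar > 0:
        raise DegeneratePlateError("vehicle mean luminescence not positive")
    cbar = wells["luminescence"].mean()
    return 100.0 * (vbar - cbar) / vbar


def compound_anova(
    plates: PlateSet,
    compound: str,
    cell_line: str | None = None,
    vehicle_wells: pd.DataFrame | None = None,
) -> float:
    """One-way ANOVA p for compound vs vehicle luminescence.

    Fits the two-level group factor as a linear model; the F-test on that
    model equals the pooled-variance two-sided t-test (F = t²).  Returns NaN
    when within-group variance vanishes in both groups.
    """
    df = plates.wells
    sel = (df["compound_id"] == compound) & (df["role"] == "sample")
    if cell_line is not None:
        sel &= df["cell_line"] == cell_line
    y1 = df.loc[sel, "luminescence"].to_numpy(float)
    if vehicle_wells is None:
        plate_ids = df.loc[sel, "plate_id"].unique()
        vsel = (df["role"] == "vehicle") & df["plate_id"].isin(plate_ids)
        if cell_line is not None:
            vsel &= df["cell_line"] == cell_line
        y0 = df.loc[vsel, "luminescence"].to_numpy(float)
    else:
        y0 = vehicle_wells["luminescence"].to_numpy(float)
    if len(y1) < 2 or len(y0) < 2:
        raise ScreenValidationError(
            "ANOVA needs >= 2 compound and >= 2 vehicle wells"
        )
    return _anova_two_group(y1, y0)


def _anova_two_group(y1: np.ndarray, y0: np.ndarray) -> float:
    n1, n0 = len(y1), len(y0)
    ss_within = ((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum()
    if ss_within == 0.0:
        return float("nan")
    grand = np.concatenate([y1, y0]).mean()
    ss_between = n1 * (y1.mean() - grand) ** 2 + n0 * (y0.mean() - grand) ** 2
    df_b, df_w = 1, n1 + n0 - 2
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(stats.f.sf(f, df_b, df_w))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ScreenValidationError("p-values must lie in [0, 1]")
    if vals.size:
        out[ok] = multipletests(vals, method="fdr_bh")[1]
    return out


def screen_stats(
    plates: PlateSet,
    alpha: float = 0.05,
    reduce: str = "mean",
) -> pd.DataFrame:
    """Per compound × cell line ΔPOC, ANOVA p and BH-adjusted p.

    Vectorized over the whole screen: duplicate wells are averaged per
    compound, the vehicle reference is pooled over the compound's plate(s),
    and the ANOVA is computed through the algebraically equivalent pooled
    two-sample formulation.  ``reduce`` ('mean' or 'max') controls how a
    compound's screen-level ΔPOC is summarized across cell lines in
    :func:`select_hits`.
    """
    df = plates.wells
    samples = df[df["role"] == "sample"]
    veh = df[df["role"] == "vehicle"]

    vstats = veh.groupby(["plate_id", "cell_line"])["luminescence"].agg(
        v_mean="mean", v_ss=lambda x: ((x - x.mean()) ** 2).sum(), v_n="count"
    )
    g = samples.groupby(["compound_id", "cell_line", "plate_id"])
    cstats = g["luminescence"].agg(
        c_mean="mean", c_ss=lambda x: ((x - x.mean()) ** 2).sum(), c_n="count"
    ).reset_index()
    # compounds normally live on one plate; pool vehicle over their plates
    merged = cstats.join(vstats, on=["plate_id", "cell_line"])
    agg = merged.groupby(["compound_id", "cell_line"]).agg(
        mean_lum_compound=("c_mean", "mean"),
        mean_lum_vehicle=("v_mean", "mean"),
        c_ss=("c_ss", "sum"),
        c_n=("c_n", "sum"),
        v_ss=("v_ss", "sum"),
        v_n=("v_n", "sum"),
    ).reset_index()

    agg["poc"] = 100.0 * agg["mean_lum_compound"] / agg["mean_lum_vehicle"]
    agg["delta_poc"] = 100.0 - agg["poc"]

    # pooled two-sample t == one-way ANOVA F on the two-level linear model
    n1 = agg["c_n"].to_numpy(float)
    n0 = agg["v_n"].to_numpy(float)
    ss_w = agg["c_ss"].to_numpy(float) + agg["v_ss"].to_numpy(float)
    dof = n1 + n0 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ss_w / dof
        t = (agg["mean_lum_compound"] - agg["mean_lum_vehicle"]).to_numpy(
            float
        ) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
        p = stats.f.sf(t**2, 1, dof)
    p = np.where((ss_w == 0) | (n1 < 2) | (n0 < 2), np.nan, p)
    agg["p_anova"] = p
    agg["adj_p"] = bh_adjust(agg["p_anova"])
    agg["reduce"] = reduce
    return agg.drop(columns=["c_ss", "c_n", "v_ss", "v_n"])


def select_hits(
    stats_df: pd.DataFrame,
    alpha: float = 0.05,
    percentile: float = 95.0,
    percentile_over: str = "all",
    reduce: str = "mean",
) -> pd.DataFrame:
    """Gate hits on adjusted p and the ΔPOC percentile limit.

    A compound is a hit iff its (cross-cell-line ``reduce``d) ΔPOC reaches
    the ``percentile``-th percentile of the reference ΔPOC distribution —
    either over all screened compounds (default) or only over the compounds
    with ``adj_p <= alpha`` (``percentile_over='significant'``) — and its
    worst adjusted p is ≤ alpha.  Hits are returned sorted by ΔPOC
    descending, ties broken by compound id.
    """
    if stats_df.empty:
        return stats_df.assign(is_hit=pd.Series(dtype=bool)).iloc[0:0]
    if percentile_over not in {"all", "significant"}:
        raise ValueError("percentile_over must be 'all' or 'significant'")
    red = "max" if reduce == "max" else "mean"
    per_comp = stats_df.groupby("compound_id").agg(
        delta_poc=("delta_poc", red), adj_p=("adj_p", "max")
    ).reset_index()
    sig = per_comp["adj_p"] <= alpha
    ref = per_comp.loc[sig if percentile_over == "significant" else slice(None),
                       "delta_poc"]
    if ref.empty:
        return per_comp.iloc[0:0].assign(is_hit=pd.Series(dtype=bool))
    # linear-interpolation (type-7) percentile
    limit = float(np.percentile(ref.to_numpy(float), percentile))
    hit = sig & (per_comp["delta_poc"] >= limit)
    hits = per_comp[hit].copy()
    hits["is_hit"] = True
    hits["delta_poc_limit"] = limit
    return hits.sort_values(
        ["delta_poc", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)


def spatial_bias_report(plates: PlateSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-plate spatial diagnostics on sample-well POC.

    Kruskal–Wallis across rows and across columns, edge-vs-interior median
    POC difference; p-values BH-adjusted across plates, a plate flagged when
    any adjusted p ≤ ``alpha``.  Degenerate plates (constant POC or a single
    row/column) are marked not-computable and never flagged.
    """
    poc = poc_per_well(plates)
    poc = poc[poc["role"] == "sample"]
    rows = []
    for (pid, line), sub in poc.groupby(["plate_id", "cell_line"]):
        rec = {"plate_id": pid, "cell_line": line,
               "p_rows": np.nan, "p_cols": np.nan,
               "edge_effect": np.nan, "computable": False}
        row_groups = [g["poc"].to_numpy() for _, g in sub.groupby("row")]
        col_groups = [g["poc"].to_numpy() for _, g in sub.groupby("col")]
        edge = (sub["row"].isin([ROWS_384[0], ROWS_384[-1]])
                | sub["col"].isin([1, N_COLS_384]))
        if (len(row_groups) >= 2 and len(col_groups) >= 2
                and sub["poc"].nunique() > 1):
            try:
                rec["p_rows"] = stats.kruskal(*row_groups).pvalue
                rec["p_cols"] = stats.kruskal(*col_groups).pvalue
                rec["computable"] = True
            except ValueError:  # all values identical within the test
                pass
            if edge.any() and (~edge).any():
                rec["edge_effect"] = (sub.loc[edge, "poc"].median()
                                      - sub.loc[~edge, "poc"].median())
        rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(flagged=pd.Series(dtype=bool))
    out["adj_p_rows"] = bh_adjust(out["p_rows"])
    out["adj_p_cols"] = bh_adjust(out["p_cols"])
    out["flagged"] = out["computable"] & (
        (out["adj_p_rows"] <= alpha) | (out["adj_p_cols"] <= alpha)
    )
    return out


def positive_control_qc(plates: PlateSet) -> pd.DataFrame:
    """Z'-style separation of vehicle vs positive-control wells per plate."""
    df = plates.wells
    rows = []
    for (pid, line), sub in df.groupby(["plate_id", "cell_line"]):
        veh = sub.loc[sub["role"] == "vehicle", "luminescence"]
        pos = sub.loc[sub["role"] == "positive", "luminescence"]
        if len(veh) < 2 or len(pos) < 2:
            continue
        sep = abs(veh.mean() - pos.mean())
        z = 1 - 3 * (veh.std(ddof=1) + pos.std(ddof=1)) / sep if sep else np.nan
        rows.append({"plate_id": pid, "cell_line": line, "z_prime": z,
                     "vehicle_mean": veh.mean(), "positive_mean": pos.mean()})
    return pd.DataFrame(rows)
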