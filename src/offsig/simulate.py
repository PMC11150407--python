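"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed, and
emits data in the same dialects the readers consume plus a separate truth
table (planted property and effect size per entity) — truth never leaks
into the data files themselves.

The defaults mirror the screen and assay designs the pipeline targets: a
384-well duplicate-well screen (24 DMSO vehicle + 8 etoposide positive
wells and 176 duplicate compounds per plate, lognormal plate baselines),
two-group expression with planted up/down marker genes, a connectivity-map
scale ranked library with a top-enriched class, two-replicate bait-vs-IgG
proteomics with intensity-dependent (MNAR) dropout, and 4PL dose–response
curves over a six-log micromolar dilution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dose import DoseResponseCurve, four_pl
from .screen import N_COLS_384, ROWS_384, PlateSet
from .signatures import ExpressionMatrix

VEHICLE_WELLS_PER_PLATE = 24
POSITIVE_WELLS_PER_PLATE = 8
COMPOUNDS_PER_PLATE = (16 * 24 - VEHICLE_WELLS_PER_PLATE
                       - POSITIVE_WELLS_PER_PLATE) // 2  # duplicates


class LayoutError(ValueError):
    """Requested design exceeds plate capacity."""


def gen_screen(
    n_compounds: int = 5292,
    n_plates: int | None = None,
    active_fraction: float = 0.05,
    active_delta_poc: float = 95.0,
    noise_cv: float = 0.05,
    spatial_bias: float | None = None,
    baseline: float = 10_000.0,
    baseline_cv: float = 0.15,
    positive_delta_poc: float = 90.0,
    cell_line: str = "CL1",
    seed: int = 0,
) -> tuple[PlateSet, pd.DataFrame]:
    """Duplicate-well 384-plate luminescence screen with planted actives.

    Vehicle luminescence is lognormal around a per-plate baseline; a
    planted active's mean is scaled by (1 − active_delta_poc/100);
    multiplicative well noise has the given CV.  ``spatial_bias`` adds that
    many POC points (as luminescence fraction of baseline) to edge wells of
    every plate.  Returns the :class:`PlateSet` and a truth table with one
    row per compound.
    """
    rng = np.random.default_rng(seed)
    need = int(np.ceil(n_compounds / COMPOUNDS_PER_PLATE))
    if n_plates is None:
        n_plates = need
    elif n_plates < need:
        raise LayoutError(
            f"{n_compounds} duplicate compounds need {need} plates "
            f"(capacity {COMPOUNDS_PER_PLATE}/plate), got {n_plates}"
        )
    compounds = [f"CPD{i:05d}" for i in range(n_compounds)]
    n_active = int(round(active_fraction * n_compounds))
    active = np.zeros(n_compounds, dtype=bool)
    active[rng.choice(n_compounds, size=n_active, replace=False)] = True

    sigma = np.sqrt(np.log1p(noise_cv**2))  # lognormal with given CV
    records = []
    all_wells = [(r, c) for r in ROWS_384 for c in range(1, N_COLS_384 + 1)]
    for p in range(n_plates):
        pid = f"P{p + 1:03d}"
        plate_base = baseline * rng.lognormal(
            -0.5 * np.log1p(baseline_cv**2) ** 1,
            np.sqrt(np.log1p(baseline_cv**2)))
        start = p * COMPOUNDS_PER_PLATE
        plate_compounds = compounds[start:start + COMPOUNDS_PER_PLATE]
        roles = (["vehicle"] * VEHICLE_WELLS_PER_PLATE
                 + ["positive"] * POSITIVE_WELLS_PER_PLATE
                 + [c for c in plate_compounds for _ in (1, 2)])
        order = rng.permutation(len(all_wells))
        for slot, item in enumerate(roles):
            row, col = all_wells[order[slot]]
            if item == "vehicle":
                mean, cid, role = plate_base, "", "vehicle"
            elif item == "positive":
                mean = plate_base * (1 - positive_delta_poc / 100)
                cid, role = "", "positive"
            else:
                cid, role = item, "sample"
                idx = int(cid[3:])
                eff = active_delta_poc if active[idx] else 0.0
                mean = plate_base * (1 - eff / 100)
            lum = mean * rng.lognormal(-0.5 * sigma**2, sigma)
            if spatial_bias and (row in (ROWS_384[0], ROWS_384[-1])
                                 or col in (1, N_COLS_384)):
                lum += plate_base * spatial_bias / 100.0
            records.append((pid, row, col, cid, role, lum, cell_line, 1))
    wells = pd.DataFrame(records, columns=[
        "plate_id", "row", "col", "compound_id", "role", "luminescence",
        "cell_line", "replicate"])
    truth = pd.DataFrame({
        "entity_id": compounds,
        "planted": np.where(active, "active", "inert"),
        "effect": np.where(active, active_delta_poc, 0.0),
    })
    return PlateSet(wells), truth


def gen_expression(
    n_genes: int = 2000,
    n_per_group: int = 16,
    n_up: int = 100,
    n_down: int = 100,
    effect_sd_units: float = 2.0,
    group_labels: tuple[str, str] = ("A_on", "B_off"),
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group expression with planted up/down signature genes.

    Background is Normal(0, 1); the first ``n_up`` genes are shifted up and
    the next ``n_down`` shifted down by ``effect_sd_units`` standard
    deviations in group A.  Gene order is shuffled so planted genes are not
    positionally identifiable.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per_group))
    shift = np.zeros(n_genes)
    shift[:n_up] = effect_sd_units
    shift[n_up:n_up + n_down] = -effect_sd_units
    x[:, :n_per_group] += shift[:, None]
    perm = rng.permutation(n_genes)
    x = x[perm]
    shift = shift[perm]
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = ([f"{group_labels[0]}_{i + 1}" for i in range(n_per_group)]
               + [f"{group_labels[1]}_{i + 1}" for i in range(n_per_group)])
    groups = pd.Series([group_labels[0]] * n_per_group
                       + [group_labels[1]] * n_per_group, index=samples)
    values = pd.DataFrame(x, index=genes, columns=samples)
    truth = pd.DataFrame({
        "entity_id": genes,
        "planted": np.where(shift > 0, "up",
                            np.where(shift < 0, "down", "null")),
        "effect": shift,
    })
    return ExpressionMatrix(values, groups), truth


def gen_ranked_list(
    n: int = 2836,
    class_size: int = 32,
    enrichment_strength: float = 0.0,
    class_name: str = "CLASS",
    seed: int = 0,
):
    """Ranked perturbagen list with one class enriched toward the top.

    Class members' ranks are drawn without replacement with probability
    proportional to exp(−strength × rank / N): strength 0 is uniform (the
    null), large strength concentrates the class in the top ranks.
    """
    from .connectivity import RankedPerturbagens

    if class_size >= n:
        raise ValueError("class_size must be < n")
    rng = np.random.default_rng(seed)
    ids = [f"PRT{i:05d}" for i in range(n)]
    ranks = np.arange(n)
    w = np.exp(-enrichment_strength * ranks / n)
    member_pos = rng.choice(n, size=class_size, replace=False,
                            p=w / w.sum())
    members = {ids[i] for i in member_pos}
    classes = {pid: [class_name] for pid in members}
    truth = pd.DataFrame({
        "entity_id": ids,
        "planted": [class_name if pid in members else "background"
                    for pid in ids],
        "effect": enrichment_strength,
    })
    return RankedPerturbagens(ids, classes), truth


def gen_proteomics(
    n_proteins: int = 1000,
    n_interactors: int = 50,
    n_replicates: int = 2,
    spec_lambda_bait: float = 12.0,
    spec_lambda_background: float = 1.0,
    lfq_effect: float = 3.0,
    lfq_base_mean: float = 25.0,
    lfq_base_sd: float = 1.0,
    lfq_sd: float = 0.4,
    missing_rate_mnar: float = 0.2,
    mnar_steepness: float = 2.0,
    seed: int = 0,
    interactor_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MaxQuant-style protein table with planted bait interactors.

    ``interactor_seed`` fixes which proteins are interactors independently
    of the noise seed, so several samples can share the same planted
    complex (as biological replicates of one pulldown would).

    Spectral counts are Poisson (interactors high in the bait pulldown, at
    background rate in IgG); log2 LFQ intensities are normal with a planted
    ``lfq_effect`` shift for interactors in the bait columns.  Missingness
    is logistic in intensity (lower intensity → more likely missing) with
    overall rate tuned by ``missing_rate_mnar``.  A few decoy/contaminant
    rows carry MaxQuant '+' flags so table filtering is exercised.
    """
    rng = np.random.default_rng(seed)
    prot = [f"PROT{i:04d}" for i in range(n_proteins)]
    genes = [f"GENE{i:04d}" for i in range(n_proteins)]
    pick_rng = (np.random.default_rng(interactor_seed)
                if interactor_seed is not None else rng)
    inter = np.zeros(n_proteins, dtype=bool)
    inter[pick_rng.choice(n_proteins, size=n_interactors,
                          replace=False)] = True

    lam_sample = np.where(inter, spec_lambda_bait, spec_lambda_background)
    lam_igg = np.full(n_proteins, spec_lambda_background)
    table = {
        "Majority protein IDs": prot,
        "Gene names": genes,
        "Peptides": rng.integers(2, 30, size=n_proteins),
        "Unique peptides": rng.integers(1, 15, size=n_proteins),
        "Reverse": [""] * n_proteins,
        "Potential contaminant": [""] * n_proteins,
        "Only identified by site": [""] * n_proteins,
    }
    for r in range(1, n_replicates + 1):
        table[f"MS/MS count sample_{r}"] = rng.poisson(lam_sample)
        table[f"MS/MS count IgG_{r}"] = rng.poisson(lam_igg)
    base = rng.normal(lfq_base_mean, lfq_base_sd, size=n_proteins)
    for r in range(1, n_replicates + 1):
        s = base + np.where(inter, lfq_effect, 0.0) + rng.normal(
            0, lfq_sd, n_proteins)
        g = base + rng.normal(0, lfq_sd, n_proteins)
        for cond, vals in (("sample", s), ("IgG", g)):
            # logistic MNAR: dropout odds grow as intensity falls
            z = mnar_steepness * (np.median(base) - vals) + np.log(
                missing_rate_mnar / (1 - missing_rate_mnar))
            drop = rng.random(n_proteins) < 1 / (1 + np.exp(-z))
            col = np.where(drop, np.nan, 2.0**vals)
            table[f"LFQ intensity {cond}_{r}"] = col
    df = pd.DataFrame(table)
    # planted QC rows exercising the flag filter
    flagged = df.sample(n=min(3, n_proteins), random_state=int(
        rng.integers(0, 2**31)))
    for i, col in zip(flagged.index, ["Reverse", "Potential contaminant",
                                      "Only identified by site"]):
        df.loc[i, col] = "+"
        inter[df.index.get_loc(i) if isinstance(i, str) else i] = False
    truth = pd.DataFrame({
        "entity_id": genes,
        "planted": np.where(inter, "interactor", "background"),
        "effect": np.where(inter, lfq_effect, 0.0),
    })
    return df, truth


def gen_dose_response(
    params: tuple[float, float, float, float] = (0.0, 100.0, 0.5, 1.0),
    concentrations=None,
    noise_sd: float = 0.0,
    n_rep: int = 1,
    compound_id: str = "CPD",
    subject_id: str = "CELL",
    seed: int = 0,
) -> DoseResponseCurve:
    """4PL viability curve: exact mean response plus i.i.d. normal noise.

    ``params`` is (bottom, top, ic50 μM, hill).  The default dose series is
    a half-log dilution from 0.03 to 10 μM (the six-point low-micromolar
    design typical of viability assays); replicates are averaged per dose.
    """
    bottom, top, ic50, hill = params
    if concentrations is None:
        concentrations = 10.0 ** np.arange(-1.5, 1.01, 0.5)  # 0.03–10 μM
    x = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    mean = four_pl(x, bottom, top, ic50, hill)
    y = mean[None, :] + rng.normal(0, noise_sd, size=(n_rep, len(x)))
    return DoseResponseCurve(compound_id, subject_id, x, y.mean(axis=0))
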