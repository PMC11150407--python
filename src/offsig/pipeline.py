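"""End-to-end orchestration: screen → hits → clusters, signature →
enrichment, RIME → intersection → gene-set overlap, from one YAML config.

Stages communicate through documented TSV files so any stage can be re-run
independently; outputs are byte-stable for identical config + inputs +
seeds, and the run report records per-stage row counts, parameters and
output digests.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chem, connectivity, rime, screen, signatures

_DEFAULTS = {
    "alpha": 0.05,
    "percentile": 95.0,
    "percentile_over": "all",
    "k_top": 250,
    "bootstrap_b": 10_000,
    "signature_k": 100,
    "r_max": 1500,
    "lp_threshold": 0.2,
    "min_spec": 5,
    "cut_height": None,
    "seed": 0,
}

_STAGES = ("screen", "clustering", "signature", "connectivity", "rime")

_KNOWN_KEYS = set(_DEFAULTS) | {
    "stages", "inputs", "output_dir",
}

_INPUT_KEYS = {
    "screen_table", "smiles_table", "expression_table", "expression_groups",
    "ranked_list", "class_map", "class_name", "protein_tables", "gene_sets",
    "background",
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    stages: list[str]
    inputs: dict
    output_dir: Path
    params: dict = field(default_factory=dict)

    def param(self, name):
        return self.params.get(name, _DEFAULTS[name])

    def echo(self) -> dict:
        full = dict(_DEFAULTS)
        full.update(self.params)
        def _str(v):
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, list):
                return [_str(x) for x in v]
            return v

        return {"stages": self.stages,
                "inputs": {k: _str(v) for k, v in self.inputs.items()},
                "output_dir": str(self.output_dir), **full}


def validate_config(path) -> PipelineConfig:
    """Parse and schema-check a YAML/JSON pipeline config.

    Unknown keys are rejected by name; defaults are materialized so the
    echoed config is complete.  Referenced input files must exist.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    stages = raw.get("stages", list(_STAGES))
    bad = [s for s in stages if s not in _STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s): {bad}")
    inputs = raw.get("inputs", {})
    unknown_in = set(inputs) - _INPUT_KEYS
    if unknown_in:
        raise ConfigError(f"unknown input key(s): {sorted(unknown_in)}")
    base = Path(path).parent
    resolved = {}
    for key, val in inputs.items():
        if key in {"class_name", "background"}:
            resolved[key] = val
            continue
        if key == "protein_tables":
            paths = [base / v if not Path(v).is_absolute() else Path(v)
                     for v in val]
            for p in paths:
                if not p.exists():
                    raise ConfigError(f"input file not found: {p}")
            resolved[key] = paths
            continue
        p = base / val if not Path(val).is_absolute() else Path(val)
        if not p.exists():
            raise ConfigError(f"input file not found: {p}")
        resolved[key] = p
    params = {k: raw[k] for k in _DEFAULTS if k in raw}
    out_dir = Path(raw.get("output_dir", "offsig_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    return PipelineConfig(stages, resolved, out_dir, params)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: PipelineConfig, log=sys.stderr) -> dict:
    """Execute the enabled stages in dependency order; return the run report.

    Any stage failure raises :class:`StageError` tagged with the stage
    name; outputs written before the failure are retained.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report = {"stages": {}, "params": config.echo()}
    state: dict = {}

    def emit(stage, name, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        report["stages"][stage]["outputs"][name] = {
            "rows": int(len(df)), "sha256": _digest(path)}
        return path

    for stage in _STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        report["stages"][stage] = {"outputs": {}}
        print(f"[offsig:{stage}] starting", file=log)
        try:
            if stage == "screen":
                plates = screen.read_screen_table(
                    config.inputs["screen_table"])
                stats_df = screen.screen_stats(
                    plates, alpha=config.param("alpha"))
                hits = screen.select_hits(
                    stats_df, alpha=config.param("alpha"),
                    percentile=config.param("percentile"),
                    percentile_over=config.param("percentile_over"))
                qc = screen.spatial_bias_report(plates)
                for pid, vm in plates.vehicle_means().items():
                    print(f"[offsig:screen] vehicle mean {pid}: {vm:.1f}",
                          file=log)
                emit(stage, "screen_stats.tsv", stats_df)
                emit(stage, "hits.tsv", hits)
                emit(stage, "plate_qc.tsv", qc)
                state["hits"] = hits
            elif stage == "clustering":
                if "hits" not in state and "smiles_table" not in config.inputs:
                    raise StageError(
                        "clustering needs the screen stage or a smiles_table"
                    )
                smi = pd.read_csv(config.inputs["smiles_table"], sep="\t")
                if "hits" in state:
                    smi = smi[smi["compound_id"].isin(
                        state["hits"]["compound_id"])]
                fps = chem.fingerprint_compounds(
                    dict(zip(smi["compound_id"], smi["smiles"])))
                sim = chem.similarity_matrix(fps)
                z, labels = chem.cluster_hits(
                    sim, cut_height=config.param("cut_height"))
                merge = pd.DataFrame(
                    z, columns=["left", "right", "height", "size"])
                emit(stage, "merge_table.tsv", merge)
                lab = pd.DataFrame({"compound_id": sim.index,
                                    "cluster": labels if labels is not None
                                    else range(1, len(sim) + 1)})
                emit(stage, "clusters.tsv", lab)
            elif stage == "signature":
                expr = signatures.read_expression_tsv(
                    config.inputs["expression_table"])
                grp = pd.read_csv(config.inputs["expression_groups"],
                                  sep="\t", index_col=0).iloc[:, 0]
                mat = signatures.ExpressionMatrix(expr, grp)
                de = signatures.ttest_filter(mat, alpha=config.param("alpha"))
                snr = signatures.snr_rank(mat)
                sig = signatures.build_signature(
                    de, snr, k=config.param("signature_k"))
                emit(stage, "signature_up.tsv", pd.DataFrame(
                    {"gene": sig.up, "snr": sig.scores.loc[sig.up].values}))
                emit(stage, "signature_down.tsv", pd.DataFrame(
                    {"gene": sig.down,
                     "snr": sig.scores.loc[sig.down].values}))
                state["signature"] = sig
            elif stage == "connectivity":
                ranked = connectivity.read_ranked_list(
                    config.inputs["ranked_list"],
                    config.inputs.get("class_map"))
                res = connectivity.bootstrap_class_enrichment(
                    ranked, config.inputs["class_name"],
                    k=config.param("k_top"), b=config.param("bootstrap_b"),
                    seed=config.param("seed"))
                emit(stage, "enrichment.tsv", pd.DataFrame([vars(res)]))
                emit(stage, "rank_scores.tsv", connectivity.rank_score_table(
                    ranked, config.inputs["class_name"]))
            elif stage == "rime":
                hit_lists = []
                for p in config.inputs["protein_tables"]:
                    tbl = pd.read_csv(p, sep="\t")
                    filtered, _rm = rime.filter_quant_table(tbl)
                    hits = rime.spec_hit_call(
                        filtered, min_spec=config.param("min_spec"))
                    hits = hits.rename(
                        columns={"Gene names": "gene_symbol"})
                    hit_lists.append(hits)
                    emit(stage, f"rime_hits_{Path(p).stem}.tsv", hits)
                common = rime.intersect_hits(hit_lists)
                emit(stage, "intersection.tsv", common)
                if "gene_sets" in config.inputs:
                    sets = signatures.read_gmt(config.inputs["gene_sets"])
                    bg = config.inputs.get("background", 20_000)
                    ov = rime.gene_set_overlap(
                        common["gene_symbol"], sets, bg)
                    emit(stage, "geneset_overlap.tsv", ov)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        report["stages"][stage]["seconds"] = round(dt, 3)
        print(f"[offsig:{stage}] done in {dt:.2f}s", file=log)

    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
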