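"""End-to-end pipeline stages tying the modules together.

Each stage is a plain function over in-memory objects; the CLI and the
numbered analysis scripts are thin wrappers around these.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import autocm, cohort, graphs, stats
from .config import PipelineConfig

__all__ = ["map_from_cohort", "run_full", "map_summary"]


def _select(table: pd.DataFrame, timepoint: str, subset: str,
            threshold_pct: float) -> pd.DataFrame:
    if subset != "all":
        split = stats.split_responders(table, threshold_pct=threshold_pct)
        keep = split.responders if subset == "responders" else split.non_responders
        table = table[table["patient_id"].isin(keep)]
    sel = table[table["timepoint"] == timepoint]
    if len(sel) < 2:
        raise ValueError(f"fewer than 2 patients in {subset}/{timepoint}")
    return sel


def map_from_cohort(
    table: pd.DataFrame,
    timepoint: str = "before",
    subset: str = "all",
    config: PipelineConfig | None = None,
):
    """normalize → train → distance → MST → MRG → hubs for one stratum.

    Returns (model, distance matrix, MST graph, MRG graph, hub set).
    """
    cfg = config or PipelineConfig()
    sel = _select(table, timepoint, subset, cfg.responder_threshold_pct)
    panel = [c for c in cohort.PANEL_VARIABLES if c in sel.columns]
    X = autocm.normalize(sel[panel])
    model = autocm.train(
        X, C=cfg.autocm_C, tol=cfg.autocm_tol, max_epochs=cfg.autocm_max_epochs
    )
    d = autocm.to_distance(model)
    mst = graphs.minimum_spanning_tree(d)
    mrg = graphs.maximally_regular_graph(mst, d, max_extra=cfg.max_extra)
    hubs = graphs.find_hubs(mrg, cfg.hub_degree_threshold)
    return model, d, mst, mrg, hubs


def map_summary(mrg, hubs) -> dict:
    return {"n_edges": mrg.number_of_edges(), "n_hubs": len(hubs),
            "hubs": sorted(map(str, hubs))}


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_full(config: PipelineConfig, out_dir) -> dict:
    """The whole study pipeline on a synthetic study-emulation cohort:
    summary tables for all / responders / non-responders, six
    connectivity maps ({all, responders, non_responders} × {before,
    after}), and map deltas.  Writes all artifacts under ``out_dir`` and
    returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.default_study_spec(seed=config.seed)
    spec.n_patients = config.n_patients
    spec.n_female = config.n_female
    spec.n_male = config.n_male
    spec.effect_noise_sd = config.effect_noise_sd
    if (config.n_patients, config.n_female, config.n_male) != (40, 29, 11):
        spec.responder_sex_counts = None
        spec.responder_fraction = config.responder_fraction
    table = cohort.generate_cohort(spec)
    cohort.write_cohort_csv(table, out / "cohort.csv")

    for subset in ("all", "responders", "non_responders"):
        rows = stats.build_summary_table(
            table, subset=subset, alpha=config.alpha,
            threshold_pct=config.responder_threshold_pct,
        )
        stats.summary_table_to_frame(rows).to_csv(
            out / f"summary_{subset}.csv", index=False, float_format="%.6g"
        )

    summaries = {}
    for subset in ("all", "responders", "non_responders"):
        for timepoint in ("before", "after"):
            key = f"{subset}_{timepoint}"
            model, d, mst, mrg, hubs = map_from_cohort(
                table, timepoint=timepoint, subset=subset, config=config
            )
            d.to_csv(out / f"distance_{key}.csv", float_format="%.6g")
            graphs.export_graph(mrg, out / f"map_{key}.csv", format="csv")
            graphs.export_graph(mrg, out / f"map_{key}.graphml", format="graphml")
            summaries[key] = map_summary(mrg, hubs)

    deltas = {}
    for subset in ("all", "responders", "non_responders"):
        s1 = summaries[f"{subset}_before"]
        s2 = summaries[f"{subset}_after"]
        deltas[f"{subset}_before_to_after"] = asdict(
            graphs.compare_counts(
                s1["n_edges"], s1["n_hubs"], s2["n_edges"], s2["n_hubs"]
            )
        )

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_patients": config.n_patients,
        "maps": summaries,
        "deltas": deltas,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
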