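"""Auto-CM semantic connectivity maps and their before/after deltas.

For each stratum x timepoint (all / responders / non-responders x
before / after) this trains the Auto-Contractive Map on the normalized
24-variable panel, filters the weight-derived distances through the MST,
extends to the Maximally Regular Graph, and reports edge and hub counts.
Graph files (edge-list CSV + GraphML) and a manifest of counts and
percent deltas land in results/maps/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from osteomap import cohort, graphs, pipeline
from osteomap.config import PipelineConfig

OUT = Path(__file__).resolve().parent.parent / "results"
MAPS = OUT / "maps"
MAPS.mkdir(parents=True, exist_ok=True)

table = cohort.read_cohort_csv(OUT / "cohort.csv")
cfg = PipelineConfig()

summaries = {}
for subset in ("all", "responders", "non_responders"):
    for timepoint in ("before", "after"):
        key = f"{subset}_{timepoint}"
        model, d, mst, mrg, hubs = pipeline.map_from_cohort(
            table, timepoint=timepoint, subset=subset, config=cfg
        )
        d.to_csv(MAPS / f"distance_{key}.csv", float_format="%.6g")
        graphs.export_graph(mrg, MAPS / f"map_{key}.csv", format="csv")
        graphs.export_graph(mrg, MAPS / f"map_{key}.graphml", format="graphml")
        summaries[key] = pipeline.map_summary(mrg, hubs)
        print(f"{key}: MST {mst.number_of_edges()} edges, "
              f"MRG {mrg.number_of_edges()} edges, {len(hubs)} hubs "
              f"(epochs {model.epochs_run}, converged {model.converged})")

deltas = {}
for subset in ("all", "responders", "non_responders"):
    s1, s2 = summaries[f"{subset}_before"], summaries[f"{subset}_after"]
    delta = graphs.compare_counts(s1["n_edges"], s1["n_hubs"],
                                  s2["n_edges"], s2["n_hubs"])
    deltas[f"{subset}_before_to_after"] = asdict(delta)
    print(f"{subset} before->after: edges {delta.edge_change_pct:+d}%  "
          f"hubs {delta.hub_change_pct:+d}%")

(MAPS / "manifest.json").write_text(
    json.dumps({"maps": summaries, "deltas": deltas}, indent=2, sort_keys=True)
)
print(f"wrote {MAPS / 'manifest.json'}")
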