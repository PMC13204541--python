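"""End-to-end pipeline: simulate/load -> views -> metrics -> comparisons -> report.

A run is fully specified by one configuration mapping (YAML on disk):

.. code-block:: yaml

    seed: 1
    simulate:            # or  manifest: path/to/manifest.tsv
      n_wt: 8
      n_ko: 12
      zero_prob: 0.3
      planted_edges: [[3, 17, 2.0]]
    threshold: 0.001
    fdr_q: 0.05
    null_model: {n_null: 100, swaps_per_edge: 10}
    circuits: [fear, tle]

All randomness flows from the one seed, every output embeds the
resolved configuration, and a rerun with an identical config is
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circuits import circuit_compare
from .connectome import (EXTRACTION_THRESHOLD, Connectome, export_chord_table,
                         hemisphere_view, normalize, read_count_matrix, threshold)
from .diffusivity import compare_regions, records_to_frame
from .groupstats import compare_network_params, edgewise_compare, region_streamline_compare
from .io import read_manifest, write_matrix_tsv, write_table
from .netmetrics import compute_metrics
from .parcellation import load_region_table
from .simulate import CohortStudy, PlantedEdge, PlantedRegion, SimulationConfig, simulate_cohort

__all__ = ["run_pipeline", "cohort_from_config", "metrics_table"]

VIEW_MODES = ("whole", "ipsilateral-L", "ipsilateral-R", "contralateral-LR")


def cohort_from_config(config: dict) -> CohortStudy:
    """Build the cohort a config describes: simulated or loaded from a manifest."""
    seed = int(config.get("seed", 0))
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("seed", seed)
        sim["planted_edges"] = tuple(
            PlantedEdge(int(a), int(b), float(e)) for a, b, e in sim.get("planted_edges", ()))
        sim["planted_regions"] = tuple(
            PlantedRegion(int(r), s, float(e)) for r, s, e in sim.get("planted_regions", ()))
        return simulate_cohort(SimulationConfig(**sim))
    if "manifest" in config:
        table = load_region_table(config.get("region_table"))
        manifest = read_manifest(config["manifest"])
        base = Path(config["manifest"]).parent
        connectomes = []
        for row in manifest.itertuples():
            p = Path(row.matrix_path)
            if not p.is_absolute():
                p = base / p
            connectomes.append(read_count_matrix(p, table, animal_id=row.animal_id,
                                                 group=row.group))
        return CohortStudy(connectomes=connectomes, diffusivity=[], config=None,
                           table=table)
    raise ValueError("config must contain a 'simulate' block or a 'manifest' path")


def metrics_table(cohort: CohortStudy, t: float = EXTRACTION_THRESHOLD,
                  n_null: int | None = None, swaps_per_edge: int = 10,
                  seed: int = 0) -> pd.DataFrame:
    """Tidy per-animal metric table over the standard graph views.

    Small-worldness (the expensive stochastic measure) is included when
    ``n_null`` is set; its null-model seed is derived deterministically
    from ``seed`` and the animal/view position.
    """
    rows = []
    table = cohort.table
    for a_idx, c in enumerate(cohort.connectomes):
        for v_idx, mode in enumerate(VIEW_MODES):
            if mode == "whole":
                view = threshold(normalize(c.counts, c.labels, provenance="whole"), t)
            else:
                view = hemisphere_view(c, table, mode, t)
            sw_seed = (seed * 1_000_003 + a_idx * 101 + v_idx) % (2**31)
            m = compute_metrics(view, n_null=n_null, swaps_per_edge=swaps_per_edge,
                                seed=sw_seed)
            for name, value in m.to_dict().items():
                rows.append({"animal_id": c.animal_id, "group": c.group,
                             "provenance": mode, "metric": name, "value": value})
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir, force: bool = False) -> Path:
    """Run the full analysis a config describes and write the report bundle.

    Writes per-animal adjacency TSVs and chord tables, the tidy metric
    table, signed p-matrices and edgewise tables for both hemisphere
    modes, region streamline comparisons, network-parameter tests,
    circuit comparisons, diffusivity region maps (when present), and a
    run manifest with the resolved config.  Refuses to overwrite a
    non-empty output directory unless ``force`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    cohort = cohort_from_config(config)

    out.mkdir(parents=True, exist_ok=True)
    (out / "adjacency").mkdir(exist_ok=True)
    (out / "chord").mkdir(exist_ok=True)

    seed = int(config.get("seed", 0))
    t = float(config.get("threshold", EXTRACTION_THRESHOLD))
    q = float(config.get("fdr_q", 0.05))
    null_cfg = config.get("null_model", {}) or {}
    n_null = null_cfg.get("n_null")
    swaps = int(null_cfg.get("swaps_per_edge", 10))

    manifest_rows = []
    for c in cohort.connectomes:
        mpath = out / "adjacency" / f"{c.animal_id}.tsv"
        write_matrix_tsv(mpath, c.counts, c.labels)
        chord = export_chord_table(threshold(normalize(c.counts, c.labels), t))
        chord.to_csv(out / "chord" / f"{c.animal_id}.csv", index=False,
                     float_format="%.12g")
        manifest_rows.append({"animal_id": c.animal_id, "group": c.group,
                              "matrix_path": f"adjacency/{c.animal_id}.tsv"})
    write_table(pd.DataFrame(manifest_rows), out / "manifest.tsv")

    metrics = metrics_table(cohort, t=t, n_null=n_null, swaps_per_edge=swaps, seed=seed)
    write_table(metrics, out / "metrics.tsv")
    write_table(compare_network_params(metrics), out / "network_params_tests.tsv")

    for mode in ("ipsilateral", "contralateral"):
        res = edgewise_compare(cohort, mode=mode, q=q)
        write_table(res.table, out / f"edgewise_{mode}.tsv")
        write_matrix_tsv(out / f"signed_p_{mode}.tsv",
                         res.matrix.values.to_numpy(), res.matrix.labels)

    write_table(region_streamline_compare(cohort, q=q), out / "region_streamlines.tsv")

    for name in config.get("circuits", ["fear", "tle"]):
        for side in ("ipsilateral", "contralateral"):
            write_table(circuit_compare(cohort, name, side=side, q=q),
                        out / f"circuit_{name}_{side}.tsv")

    if cohort.diffusivity:
        frame = records_to_frame(cohort.diffusivity)
        write_table(frame, out / "diffusivity_records.tsv")
        maps = pd.concat([compare_regions(frame, scalar=s, q=q)
                          for s in ("FA", "MD", "AD", "RD")], ignore_index=True)
        write_table(maps, out / "diffusivity_region_maps.tsv")

    run_manifest = {
        "hdbn_version": __version__,
        "seed": seed,
        "threshold": t,
        "fdr_q": q,
        "null_model": {"n_null": n_null, "swaps_per_edge": swaps},
        "config": _jsonable(config),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
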