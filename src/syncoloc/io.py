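"""Plain-text readers and writers: CSV tables, JSON metrics, YAML configs.

Coordinates are written both as 0-based pixel indices (origin top-left)
and in nm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import PunctaSet
from .pairing import Metric, SynapseTable


def puncta_to_frame(ps: PunctaSet) -> pd.DataFrame:
    rows = []
    for p in ps.puncta:
        x_nm, y_nm = p.max_pos_nm
        rows.append({
            "id": p.id,
            "x_px": x_nm / ps.pixel_size_nm,
            "y_px": y_nm / ps.pixel_size_nm,
            "x_nm": x_nm,
            "y_nm": y_nm,
            "area_um2": p.area_um2,
            "peak": p.peak_intensity,
            "eq_diam_nm": p.equivalent_diameter_nm,
        })
    return pd.DataFrame(rows, columns=["id", "x_px", "y_px", "x_nm", "y_nm",
                                       "area_um2", "peak", "eq_diam_nm"])


def write_puncta_csv(ps: PunctaSet, path) -> None:
    puncta_to_frame(ps).to_csv(path, index=False)


def read_points_csv(path) -> np.ndarray:
    """Read a point set as (n, 2) array of (x_nm, y_nm)."""
    df = pd.read_csv(path)
    return df[["x_nm", "y_nm"]].to_numpy(dtype=float)


def synapse_table_to_frame(table: SynapseTable) -> pd.DataFrame:
    rows = [{
        "pre_id": p.pre_id,
        "post_id": p.post_id,
        "distance_nm": p.distance_nm,
        "input_label": p.input_label,
        "pre_multi": p.pre_multi,
        "post_multi": p.post_multi,
    } for p in table.pairs]
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "distance_nm",
                                       "input_label", "pre_multi",
                                       "post_multi"])


def write_synapse_table_csv(table: SynapseTable, path) -> None:
    synapse_table_to_frame(table).to_csv(path, index=False)


def write_assignments_csv(table: SynapseTable, path) -> None:
    rows = [{
        "receptor_id": a.receptor_id,
        "compartment": a.compartment,
        "synapse_index": a.synapse_index,
        "distance_to_marker_nm": a.distance_to_marker_nm,
    } for a in table.assignments]
    pd.DataFrame(rows, columns=["receptor_id", "compartment",
                                "synapse_index",
                                "distance_to_marker_nm"]).to_csv(path,
                                                                 index=False)


def metrics_to_dict(metrics: dict[str, Metric]) -> dict:
    return {name: {"value": m.value, "numerator": m.numerator,
                   "denominator": m.denominator}
            for name, m in metrics.items()}


def write_metrics_json(metrics: dict[str, Metric], path) -> None:
    Path(path).write_text(json.dumps(metrics_to_dict(metrics), indent=2)
                          + "\n")


def write_fit_json(fit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def write_ground_truth(outdir, gt, images=None) -> None:
    """Dump a synthetic field: truth CSVs, resolved config, optional TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for channel, pts in gt.points.items():
        amps = gt.amplitudes[channel]
        for i, ((x, y), a) in enumerate(zip(pts, amps)):
            rows.append({"channel": channel, "id": i, "x_nm": x, "y_nm": y,
                         "amplitude": a})
    pd.DataFrame(rows, columns=["channel", "id", "x_nm", "y_nm",
                                "amplitude"]).to_csv(
        outdir / "points.csv", index=False)
    pd.DataFrame(gt.pairing, columns=["pre_id", "post_id",
                                      "offset_nm"]).to_csv(
        outdir / "pairing.csv", index=False)
    assign = pd.DataFrame(gt.receptor_assignment,
                          columns=["receptor_id", "synapse_id",
                                   "compartment"])
    assign.to_csv(outdir / "receptor_assignment.csv", index=False)
    pd.DataFrame({"synapse_id": range(len(gt.input_labels)),
                  "input_label": gt.input_labels}).to_csv(
        outdir / "input_labels.csv", index=False)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(gt.config.to_dict(), sort_keys=False))
    if images:
        for name, img in images.items():
            img.to_tiff(outdir / f"{name}.tif")


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
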