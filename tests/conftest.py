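import numpy as np
import pandas as pd
import pytest

from birdcal import simulate
from birdcal.io import DETECTION_COLUMNS


def detection_frame(rows):
    """Build a canonical detection frame from compact per-row dicts."""
    defaults = {
        "dataset_id": "ds1",
        "recorder_id": "rec1",
        "species": "species a",
        "score": 0.9,
        "timestamp_utc": "2022-06-01T06:00:00",
        "local_offset_minutes": 0,
        "source_file": "rec1_20220601.wav",
        "start_offset_s": 0.0,
        "end_offset_s": 3.0,
    }
    filled = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("detection_id", f"d{i:04d}")
        filled.append(r)
    df = pd.DataFrame(filled, columns=DETECTION_COLUMNS)
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"])
    df["local_offset_minutes"] = df["local_offset_minutes"].astype("int64")
    for c in ("score", "start_offset_s", "end_offset_s"):
        df[c] = df[c].astype(float)
    return df


def labeled_frame(scores, labels):
    """Minimal labeled-detections frame for precision computations."""
    return pd.DataFrame(
        {
            "detection_id": [f"d{i}" for i in range(len(scores))],
            "score": np.asarray(scores, dtype=float),
            "label": [
                "true_positive" if l in ("tp", "true_positive") else "false_positive"
                for l in labels
            ],
        }
    )


@pytest.fixture(scope="session")
def ladder_stream():
    """One precision_ladder simulation with ground truth (seed 0)."""
    cfg = simulate.scenario_preset("precision_ladder", seed=0)
    detections, truth = simulate.simulate_detections(cfg)
    return cfg, detections, truth


@pytest.fixture(scope="session")
def triptych_stream():
    """One diel_triptych simulation with ground truth (seed 0)."""
    cfg = simulate.scenario_preset("diel_triptych", seed=0)
    detections, truth = simulate.simulate_detections(cfg)
    return cfg, detections, truth
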