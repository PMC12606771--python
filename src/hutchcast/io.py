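"""CSV sensor dialect, checkpoints, and run manifests.

CSV dialect: header ``timestamp,Tin,RHin,CO2,WS,Tout,RHout``, ISO-8601
timestamps at a constant step, empty field = missing. Checkpoints bundle
the weight arrays with the embedded model configuration so a load
reconstructs the exact forward function.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelConfig, PatchCrossFormer
from .synthetic import CHANNELS, RawSeriesTable


def write_series_csv(table: RawSeriesTable, path) -> None:
    frame = table.frame.copy()
    frame.index = frame.index.strftime("%Y-%m-%dT%H:%M:%S")
    frame.index.name = "timestamp"
    frame.to_csv(path, na_rep="")


def read_series_csv(path) -> RawSeriesTable:
    """Read the sensor CSV dialect, validating header and timestamp grid."""
    frame = pd.read_csv(path)
    if "timestamp" not in frame.columns:
        raise ValueError("CSV must have a 'timestamp' column")
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise ValueError(f"CSV lacks required channel columns: {missing}")
    extra = [c for c in frame.columns if c not in CHANNELS + ["timestamp"]]
    if extra:
        warnings.warn(f"ignoring extra columns: {extra}")
    ts = pd.to_datetime(frame["timestamp"])
    diffs = ts.diff().iloc[1:]
    bad = diffs[diffs <= pd.Timedelta(0)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"timestamps not strictly increasing at row {row} ({ts.iloc[row]})"
        )
    irregular = diffs[diffs != diffs.iloc[0]] if len(diffs) else diffs
    if len(irregular):
        row = irregular.index[0]
        raise ValueError(
            f"irregular timestamp step at row {row} ({ts.iloc[row]})"
        )
    step = int(diffs.iloc[0].total_seconds() // 60) if len(diffs) else 1
    out = frame[CHANNELS].astype(float)
    out.index = pd.DatetimeIndex(ts, name="timestamp")
    return RawSeriesTable(out, step)


def save_checkpoint(model: PatchCrossFormer, path) -> None:
    """Serialize weights plus the embedded ModelConfig (npz, runtime artifact)."""
    state = model.state_dict()
    np.savez(
        path,
        __config__=np.frombuffer(
            json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
        ),
        **state,
    )


def load_checkpoint(path) -> PatchCrossFormer:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode())
        )
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = PatchCrossFormer(cfg)
    model.load_state_dict(state)
    return model


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run exactly."""

    command: str
    config: dict
    seed: int
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    version: str = "0.1.0"

    def write(self, path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2))
        tmp.replace(path)  # atomic publish

    @classmethod
    def start(cls, command: str, config: dict, seed: int,
              inputs: dict[str, str] | None = None) -> "RunManifest":
        return cls(
            command=command, config=config, seed=seed,
            inputs=inputs or {},
            started=datetime.now(timezone.utc).isoformat(),
        )
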