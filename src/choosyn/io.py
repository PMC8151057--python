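"""Plain-text input/output: signal CSV, event lists, JSON manifests."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import EmgRecording
from .simulator import GroundTruthSet, SimulatedRecording

__all__ = [
    "write_signal_csv",
    "read_signal_csv",
    "write_events",
    "read_events",
    "read_recording",
    "write_recording",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_manifest",
]


def write_signal_csv(path: str | Path, signal: np.ndarray,
                     muscle_names: list[str]) -> None:
    """Rows = samples, columns = muscles, header = muscle names."""
    pd.DataFrame(signal, columns=list(muscle_names)).to_csv(path, index=False)


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_events(path: str | Path, events: np.ndarray) -> None:
    """One 0-based cycle-start sample index per line."""
    Path(path).write_text("\n".join(str(int(e)) for e in events) + "\n")


def read_events(path: str | Path) -> np.ndarray:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.array([int(ln) for ln in lines])


def write_recording(signal_path: str | Path, events_path: str | Path,
                    rec: SimulatedRecording | EmgRecording,
                    muscle_names: list[str] | None = None) -> None:
    if muscle_names is None:
        muscle_names = list(getattr(rec, "muscle_names", ())) or [
            f"M{i + 1}" for i in range(rec.signal.shape[1])]
    write_signal_csv(signal_path, rec.signal, muscle_names)
    write_events(events_path, np.asarray(rec.events))


def read_recording(signal_path: str | Path,
                   events_path: str | Path) -> EmgRecording:
    signal, names = read_signal_csv(signal_path)
    return EmgRecording(signal=signal, muscle_names=names,
                        events=read_events(events_path))


def write_ground_truth_json(path: str | Path, truth: GroundTruthSet) -> None:
    payload = {
        "true_n": truth.true_n,
        "cycle_length": truth.cycle_length,
        "n_cycles": truth.n_cycles,
        "seed": truth.seed,
        "weights": truth.weights.tolist(),
        "coefficients": truth.coefficients.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path: str | Path) -> GroundTruthSet:
    d = json.loads(Path(path).read_text())
    return GroundTruthSet(weights=np.array(d["weights"]),
                          coefficients=np.array(d["coefficients"]),
                          true_n=d["true_n"], cycle_length=d["cycle_length"],
                          n_cycles=d["n_cycles"], seed=d["seed"])


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(_plain(manifest), indent=2))


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
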