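"""File formats: delimited pattern files, JSON model documents, text reports.

Pattern files are UTF-8 comma-separated text, one pattern per row, with an
optional final integer label column (0/1) and an optional header row
(auto-detected).  Models are single JSON documents carrying a schema version.
Every generated artifact gets a JSON manifest beside it recording the seed
and parameters that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .coding import NoResponse
from .mismatch import MismatchResult
from .network import NetworkModel, model_from_dict, model_to_dict
from .neuron import NeuronKind, SpikeTrain
from .training import Evaluation, PatternSet

__all__ = [
    "read_patterns",
    "write_patterns",
    "read_model",
    "write_model",
    "write_manifest",
    "write_spike_train",
    "training_report",
    "evaluation_table",
    "sweep_table",
]


def _looks_like_header(line: str, delimiter: str) -> bool:
    for token in line.strip().split(delimiter):
        try:
            float(token)
        except ValueError:
            return True
    return False


def read_patterns(
    path: str | Path, delimiter: str = ",", labeled: bool | None = None
) -> PatternSet:
    """Read a delimited pattern file.

    ``labeled=None`` auto-detects a final 0/1 integer label column; pass
    True/False to force the interpretation.  Unlabeled files get all-negative
    labels (the caller is expected to know what it loaded).
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path} contains no patterns")
    if _looks_like_header(lines[0], delimiter):
        lines = lines[1:]
    rows = [[float(tok) for tok in ln.split(delimiter)] for ln in lines]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: rows have inconsistent sample counts")
    data = np.asarray(rows, dtype=float)

    if labeled is None:
        last = data[:, -1]
        labeled = width > 1 and np.all(np.isin(last, (0.0, 1.0)))
    if labeled:
        return PatternSet(data[:, :-1], data[:, -1].astype(int))
    return PatternSet(data, np.zeros(data.shape[0], dtype=int))


def write_patterns(
    path: str | Path, ts: PatternSet, delimiter: str = ",", header: bool = True
) -> None:
    path = Path(path)
    n = ts.n_samples
    lines = []
    if header:
        lines.append(delimiter.join([f"s{i}" for i in range(n)] + ["label"]))
    for row, label in zip(ts.patterns, ts.labels):
        lines.append(delimiter.join(f"{x:.6g}" for x in row) + f"{delimiter}{label}")
    path.write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> NetworkModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def write_model(path: str | Path, model: NetworkModel) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def write_manifest(path: str | Path, **fields) -> None:
    """Record seed / parameter provenance for a generated artifact."""
    Path(path).write_text(json.dumps(fields, indent=2, default=str) + "\n")


def write_spike_train(path: str | Path, train: SpikeTrain, neuron_id: int = 0) -> None:
    """Two-column delimited spike list: time_ms, neuron_id."""
    lines = ["time_ms,neuron_id"]
    lines += [f"{t:.6g},{neuron_id}" for t in train.times]
    Path(path).write_text("\n".join(lines) + "\n")


def training_report(model: NetworkModel) -> str:
    """Plain-text summary of a fitted model."""
    kinds = model.neuron_map
    n_ts = sum(k == NeuronKind.TONIC_SPIKING for k in kinds)
    n_iis = len(kinds) - n_ts
    ts_w = [w for w, k in zip(model.w1, kinds) if k == NeuronKind.TONIC_SPIKING]
    iis_w = [w for w, k in zip(model.w1, kinds) if k == NeuronKind.INHIBITION_INDUCED]
    lines = [
        f"network size: {model.n_inputs}-1",
        f"tonic spiking neurons: {n_ts}",
        f"inhibition-induced neurons: {n_iis}",
    ]
    if ts_w:
        lines.append(f"TS weight range: {min(ts_w):.2f} .. {max(ts_w):.2f}")
    if iis_w:
        lines.append(f"IIS weight range: {min(iis_w):.2f} .. {max(iis_w):.2f}")
    lines += [
        f"w2: {model.w2}",
        f"Cref: {model.c_ref}",
        f"input gain: {model.input_gain:.6g}",
    ]
    if model.code_mode is not None:
        lines.append(
            f"response mode: [{model.code_mode.dt1:.1f}, {model.code_mode.dt2:.1f}] ms"
        )
    if model.se_threshold is not None:
        lines.append(f"SE threshold: {model.se_threshold:.1f} ms^2")
    return "\n".join(lines)


def evaluation_table(ev: Evaluation, labels: Sequence[int]) -> str:
    """Per-pattern evaluation table: id, dt1, dt2, SE, predicted, label."""
    lines = ["pattern,dt1_ms,dt2_ms,se,predicted,label"]
    for i, (s, label) in enumerate(zip(ev.scored, labels), start=1):
        if isinstance(s.code, NoResponse):
            dt1 = dt2 = se = "NA"
        else:
            dt1, dt2 = f"{s.code.dt1:.1f}", f"{s.code.dt2:.1f}"
            se = f"{s.se:.1f}"
        lines.append(f"{i},{dt1},{dt2},{se},{int(s.predicted)},{int(label)}")
    c = ev.confusion
    lines.append("")
    lines.append(f"# TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn} ACC={ev.accuracy:.4f}")
    if ev.max_sampling_hz is not None:
        lines.append(f"# max sampling frequency: {ev.max_sampling_hz:.1f} Hz")
    return "\n".join(lines)


def sweep_table(results: Sequence[MismatchResult]) -> str:
    """Mismatch sweep as a delimited table (percent, mean, min, max)."""
    lines = ["percent,mean_acc,min_acc,max_acc"]
    for r in results:
        lines.append(
            f"{r.percent:g},{r.mean_acc:.4f},{r.min_acc:.4f},{r.max_acc:.4f}"
        )
    return "\n".join(lines)
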