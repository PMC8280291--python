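"""Evaluation surfaces: the architecture-comparison grid, per-group
metrics, and true-vs-predicted histogram exports.

All reports are pandas DataFrames written as CSV with fixed column order,
so re-runs diff cleanly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .cv import BIN_CENTERS
from .inverse import (
    ModelSpec,
    SequenceRegressor,
    TrainConfig,
    build_model,
    dominant_bin_accuracy,
    round_half_away_from_zero,
    train,
)
from .simulate import DatasetSplit, GROUP_IDS, corpus_arrays, group_has_block, group_pattern, split_corpus

GRID_COLUMNS = [
    "cell", "bidirectional", "n_layers",
    "train_loss", "train_acc", "val_loss", "val_acc",
    "stopped_epoch", "error",
]

GROUP_COLUMNS = [
    "group_id", "pattern", "block",
    "train_loss", "train_acc", "train_n",
    "val_loss", "val_acc", "val_n",
]


def run_network_grid(
    corpus,
    specs: list[ModelSpec],
    cfg: TrainConfig = TrainConfig(),
    split_seed: int = 0,
) -> pd.DataFrame:
    """Train every spec on the same train/test split and tabulate final
    metrics.  A failing spec annotates its row (column ``error``) instead
    of aborting the grid.  The best row — max validation accuracy, ties by
    min validation loss — is flagged in a ``best`` column."""
    if not specs:
        raise ValueError("need at least one model spec")
    split = split_corpus(list(corpus), seed=split_seed)
    rows = []
    for spec in specs:
        row = {
            "cell": spec.cell,
            "bidirectional": spec.bidirectional,
            "n_layers": spec.n_layers,
            "train_loss": np.nan, "train_acc": np.nan,
            "val_loss": np.nan, "val_acc": np.nan,
            "stopped_epoch": 0, "error": "",
        }
        try:
            model = build_model(spec, seed=cfg.seed)
            res = train(model, split, cfg)
            row.update(
                train_loss=res.final_training_loss,
                train_acc=res.final_training_accuracy,
                val_loss=res.final_validation_loss,
                val_acc=res.final_validation_accuracy,
                stopped_epoch=res.stopped_epoch,
            )
        except Exception as exc:  # noqa: BLE001 - annotate, keep going
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    report = pd.DataFrame(rows, columns=GRID_COLUMNS)
    ok = report["error"] == ""
    report["best"] = False
    if ok.any():
        ranked = report[ok].sort_values(
            ["val_acc", "val_loss"], ascending=[False, True], kind="stable"
        )
        report.loc[ranked.index[0], "best"] = True
    return report


def _partition_metrics(model: SequenceRegressor, sets) -> tuple[float, float, int]:
    w, y, _ = corpus_arrays(sets)
    pred = model.predict(w)
    loss, _ = nn.mse_loss(pred.astype(nn.F32), y.astype(nn.F32))
    return loss, dominant_bin_accuracy(pred, y), len(sets)


def evaluate_by_group(model: SequenceRegressor, split: DatasetSplit) -> pd.DataFrame:
    """MSE loss and dominant-bin accuracy per (pattern, block) group, on
    the training and held-out partitions separately.  Groups absent from a
    partition get NaN metrics and a zero count, never fabricated values."""
    rows = []
    for gid in GROUP_IDS:
        row = {
            "group_id": gid,
            "pattern": group_pattern(gid),
            "block": group_has_block(gid),
        }
        for name, sets in (("train", split.train), ("val", split.test)):
            subset = [s for s in sets if s.group_id == gid]
            if subset:
                loss, acc, n = _partition_metrics(model, subset)
            else:
                loss, acc, n = np.nan, np.nan, 0
            row[f"{name}_loss"] = loss
            row[f"{name}_acc"] = acc
            row[f"{name}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows, columns=GROUP_COLUMNS)


def export_prediction_pairs(model: SequenceRegressor, sets, out_dir) -> list[Path]:
    """For each labeled set write two CSVs: the 28-row true/predicted
    histogram pair and the 251-sample waveform.  Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(sets):
        raw = model.predict(s.waveform)[0]
        pred = np.clip(round_half_away_from_zero(raw), 0, None).astype(int)
        hist_path = out / f"set_{i:04d}_histogram.csv"
        pd.DataFrame(
            {
                "bin_center_m_per_s": BIN_CENTERS,
                "true_count": s.label,
                "predicted_count": pred,
            }
        ).to_csv(hist_path, index=False)
        wave_path = out / f"set_{i:04d}_waveform.csv"
        pd.DataFrame(
            {
                "time_ms": np.round(np.arange(len(s.waveform)) * 0.1, 1),
                "amplitude_mv": s.waveform,
            }
        ).to_csv(wave_path, index=False)
        paths.extend([hist_path, wave_path])
    return paths
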