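"""Delimited-text interchange for every pipeline stage.

All tabular artifacts are TSV with header rows; the missingness mask mirrors
the check-mark table of the study design (rows = mice, columns = regions,
cells "ok"/"-" written as the Unicode check mark / dash, with "true/false"
and "1/0" also accepted on read).  Signals are written one file per
(mouse, session) — a TSV with one column per region, or a flat .npy when
binary output is requested — with a JSON sidecar carrying mouse id, session,
sampling rate, region order and class label.  Completion models round-trip
through JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .completion import CompletionHyperparams, CompletionModel
from .errors import DataError

CHECK = "✓"
DASH = "-"

_TRUE = {CHECK, "true", "True", "1", "ok"}
_FALSE = {DASH, "false", "False", "0"}


# -- mask -------------------------------------------------------------------

def write_mask(mask: pd.DataFrame, path: str | Path) -> None:
    encoded = mask.map(lambda v: CHECK if v else DASH)
    encoded.to_csv(path, sep="\t", index_label="mouse")


def read_mask(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col="mouse", dtype=str)

    def decode(v: str, row: str, col: str) -> bool:
        v = str(v).strip()
        if v in _TRUE:
            return True
        if v in _FALSE:
            return False
        raise DataError(
            f"mask cell ({row!r}, {col!r}) has unrecognized value {v!r}"
        )

    decoded = pd.DataFrame(
        [
            [decode(raw.loc[i, c], i, c) for c in raw.columns]
            for i in raw.index
        ],
        index=raw.index, columns=raw.columns,
    )
    for mouse, row in decoded.iterrows():
        if not row.any():
            raise DataError(f"mouse with no observed regions: {mouse!r}")
    for region in decoded.columns:
        if not decoded[region].any():
            raise DataError(f"region observed for no mouse: {region!r}")
    return decoded


# -- labels -----------------------------------------------------------------

def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"mouse": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mouse", "label"} <= set(table.columns):
        raise DataError(f"labels file {path} needs columns mouse, label")
    return dict(zip(table["mouse"], table["label"]))


# -- feature tables / matrices ---------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    meta = {"mouse", "session", "window", "region"}
    if not meta <= set(table.columns):
        raise DataError(
            f"feature table {path} missing columns {sorted(meta - set(table.columns))}"
        )
    value_cols = [c for c in table.columns if c not in meta]
    for col in value_cols:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any() or coerced.isna().any():
            row = int(np.argmax((coerced.isna()).to_numpy()))
            raise DataError(
                f"non-numeric or empty cell at row {row}, column {col!r}"
            )
        table[col] = coerced
    return table

def write_matrix(X: np.ndarray, columns: list[str], path: str | Path,
                 row_meta: pd.DataFrame | None = None) -> None:
    frame = pd.DataFrame(X, columns=columns)
    if row_meta is not None:
        frame = pd.concat([row_meta.reset_index(drop=True), frame], axis=1)
    frame.to_csv(path, sep="\t", index=False)


# -- signals ----------------------------------------------------------------

def write_signals(cohort, out_dir: str | Path, fmt: str = "tsv") -> list[Path]:
    """One file per (mouse, session) with a JSON sidecar; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for mouse in cohort.mouse_ids:
        regions = [r for r in cohort.regions if cohort.mask.loc[mouse, r]]
        for session in range(cohort.config.sessions_per_mouse):
            arr = np.column_stack(
                [cohort.signals[(mouse, session, r)] for r in regions]
            )
            stem = out_dir / f"{mouse}_s{session}"
            if fmt == "npy":
                path = stem.with_suffix(".npy")
                np.save(path, arr)
            else:
                path = stem.with_suffix(".tsv")
                np.savetxt(path, arr, delimiter="\t", fmt="%.6g",
                           header="\t".join(regions), comments="")
            sidecar = {
                "mouse_id": mouse,
                "session": session,
                "fs": cohort.fs,
                "regions": regions,
                "label": cohort.labels[mouse],
            }
            stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
            written.append(path)
    return written


def read_signals(in_dir: str | Path) -> tuple[dict, dict, float]:
    """Read a signals directory; returns (signals, labels, fs)."""
    in_dir = Path(in_dir)
    signals: dict[tuple[str, int, str], np.ndarray] = {}
    labels: dict[str, str] = {}
    fs = None
    sidecars = sorted(in_dir.glob("*.json"))
    if not sidecars:
        raise DataError(f"no signal sidecars found in {in_dir}")
    for sidecar in sidecars:
        meta = json.loads(sidecar.read_text())
        fs = meta["fs"]
        labels[meta["mouse_id"]] = meta["label"]
        npy = sidecar.with_suffix(".npy")
        tsv = sidecar.with_suffix(".tsv")
        if npy.exists():
            arr = np.load(npy)
        elif tsv.exists():
            arr = np.loadtxt(tsv, delimiter="\t", skiprows=1, ndmin=2)
        else:
            raise DataError(f"no signal file next to sidecar {sidecar}")
        for k, region in enumerate(meta["regions"]):
            signals[(meta["mouse_id"], meta["session"], region)] = arr[:, k]
    return signals, labels, float(fs)


# -- completion model -------------------------------------------------------

def write_completion_model(model: CompletionModel, path: str | Path) -> None:
    payload = {
        "P": model.P.tolist(),
        "Q": model.Q.tolist(),
        "b_row": model.b_row.tolist(),
        "b_col": model.b_col.tolist(),
        "mu": model.mu,
        "hyper": vars(model.hyper),
        "history": list(model.history),
    }
    Path(path).write_text(json.dumps(payload))


def read_completion_model(path: str | Path) -> CompletionModel:
    payload = json.loads(Path(path).read_text())
    return CompletionModel(
        P=np.asarray(payload["P"], dtype=float),
        Q=np.asarray(payload["Q"], dtype=float),
        b_row=np.asarray(payload["b_row"], dtype=float),
        b_col=np.asarray(payload["b_col"], dtype=float),
        mu=float(payload["mu"]),
        hyper=CompletionHyperparams(**payload["hyper"]),
        history=list(payload["history"]),
    )
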