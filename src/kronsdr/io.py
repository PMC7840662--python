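"""Delimited-text readers/writers and fit serialisation.

Two CSV layouts are supported for matrix-valued predictors:

* **long**: columns ``sample_id, row_index, col_index, value`` with 1-based
  ``row_index`` (variable/marker) and ``col_index`` (time/channel); every
  sample must supply the full p x T grid (no imputation).
* **wide**: one row per sample, columns ``sample_id`` then ``v{i}_t{j}``.

Responses live in a second CSV with columns ``sample_id, y`` and are
joined on ``sample_id``.  Vectorisation is column-major over the p x T
matrix (time-major stacking); indices are 1-based in files, 0-based in
memory.  Fits are serialised to JSON with matrices as nested lists plus
shape metadata.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .dataset import MatrixDataset
from .kpfc import SDRFit
from .kron import KroneckerMean, SubspaceBasis

LONG_COLUMNS = ["sample_id", "row_index", "col_index", "value"]


def load_dataset(predictors_path, response_path, layout: str = "long") -> MatrixDataset:
    """Load a :class:`MatrixDataset` from CSV files."""
    resp = pd.read_csv(response_path, float_precision="round_trip")
    if "sample_id" not in resp.columns or "y" not in resp.columns:
        raise ValueError("response file must have columns sample_id, y")
    resp["sample_id"] = resp["sample_id"].astype(str)
    if layout == "long":
        X, ids = _read_long(predictors_path)
    elif layout == "wide":
        X, ids = _read_wide(predictors_path)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    resp = resp.set_index("sample_id")
    missing = [s for s in ids if s not in resp.index]
    if missing:
        raise ValueError(f"samples without responses: {missing}")
    y = resp.loc[list(ids), "y"].to_numpy()
    return MatrixDataset(X, y)


def _read_long(path):
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != LONG_COLUMNS:
        raise ValueError(f"long layout requires columns {LONG_COLUMNS}")
    df["sample_id"] = df["sample_id"].astype(str)
    dup = df.duplicated(subset=["sample_id", "row_index", "col_index"])
    if dup.any():
        offender = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate cell for sample {offender['sample_id']!r} at "
            f"({offender['row_index']}, {offender['col_index']})"
        )
    p = int(df["row_index"].max())
    T = int(df["col_index"].max())
    ids = list(dict.fromkeys(df["sample_id"]))
    X = np.full((len(ids), p, T), np.nan)
    pos = {s: i for i, s in enumerate(ids)}
    X[df["sample_id"].map(pos), df["row_index"] - 1, df["col_index"] - 1] = df["value"]
    bad = np.isnan(X).any(axis=(1, 2))
    if bad.any():
        names = [ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"missing cells for samples: {names}")
    return X, ids


def _wide_columns(p: int, T: int) -> list[str]:
    # column-major (time-major) order, matching the internal vec convention
    return [f"v{i}_t{j}" for j in range(1, T + 1) for i in range(1, p + 1)]


def _read_wide(path):
    df = pd.read_csv(path, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValueError("wide layout requires a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in wide file")
    cells = [c for c in df.columns if c != "sample_id"]
    p = max(int(c.split("_")[0][1:]) for c in cells)
    T = max(int(c.split("_")[1][1:]) for c in cells)
    expected = _wide_columns(p, T)
    if set(cells) != set(expected):
        raise ValueError("wide file does not contain a complete v{i}_t{j} grid")
    V = df[expected].to_numpy(dtype=float)
    X = V.reshape(len(df), T, p).transpose(0, 2, 1)
    return X, list(df["sample_id"])


def save_dataset(data: MatrixDataset, predictors_path, response_path,
                 layout: str = "wide", sample_ids=None) -> None:
    ids = sample_ids or [f"s{i + 1}" for i in range(data.n)]
    if layout == "wide":
        V = data.X.transpose(0, 2, 1).reshape(data.n, -1)
        df = pd.DataFrame(V, columns=_wide_columns(data.p, data.T))
        df.insert(0, "sample_id", ids)
    elif layout == "long":
        rec = [
            (ids[i], j + 1, t + 1, data.X[i, j, t])
            for i in range(data.n) for j in range(data.p) for t in range(data.T)
        ]
        df = pd.DataFrame(rec, columns=LONG_COLUMNS)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    # %.17g guarantees float64 values survive the text round trip exactly
    df.to_csv(predictors_path, index=False, float_format="%.17g")
    pd.DataFrame({"sample_id": ids, "y": data.y}).to_csv(
        response_path, index=False, float_format="%.17g"
    )


def _enc(M) -> dict | None:
    if M is None:
        return None
    M = np.asarray(M)
    return {"shape": list(M.shape), "data": M.tolist()}


def _dec(obj) -> np.ndarray | None:
    if obj is None:
        return None
    return np.asarray(obj["data"], dtype=float).reshape(obj["shape"])


def save_fit(fit: SDRFit, path) -> None:
    doc = {
        "variant": fit.variant,
        "dims": list(fit.dims),
        "d1": fit.d1,
        "d2": fit.d2,
        "Gamma1": _enc(fit.Gamma1),
        "Gamma2": _enc(fit.Gamma2),
        "gamma": _enc(fit.gamma),
        "alpha": _enc(fit.mean.alpha) if fit.mean is not None else None,
        "beta": _enc(fit.mean.beta) if fit.mean is not None else None,
        "mean_product": _enc(fit.mean_product),
        "Delta": _enc(fit.Delta),
        "fmsdr": _enc(fit.fmsdr.matrix),
        "Xbar": _enc(fit.Xbar),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_fit(path) -> SDRFit:
    with open(path) as fh:
        doc = json.load(fh)
    alpha = _dec(doc["alpha"])
    mean = KroneckerMean(alpha, _dec(doc["beta"])) if alpha is not None else None
    return SDRFit(
        Gamma1=_dec(doc["Gamma1"]), Gamma2=_dec(doc["Gamma2"]),
        gamma=_dec(doc["gamma"]), mean=mean,
        mean_product=_dec(doc["mean_product"]), Delta=_dec(doc["Delta"]),
        fmsdr=SubspaceBasis(_dec(doc["fmsdr"])), variant=doc["variant"],
        Xbar=_dec(doc["Xbar"]), dims=tuple(doc["dims"]),
        d1=doc["d1"], d2=doc["d2"],
    )
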