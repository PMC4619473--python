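"""Tabular readers/writers and model-configuration parsing.

Data tables are delimited text (comma-separated, header required) with
numeric feature columns and one integer label column; labels are remapped
to contiguous ``0..M-1`` with the map recorded.  Model configurations are
YAML or JSON mappings with a ``model`` block (structure, coupling,
hyperparameters), a ``class_prob`` block and a ``loss`` matrix.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .models import ClassProbPosterior, GaussianPosterior, LossMatrix

__all__ = [
    "read_labeled_table",
    "write_report",
    "read_report",
    "load_config",
    "build_model",
]


def read_labeled_table(path, label_column: str = "label"):
    """Read a labeled feature table.

    Returns ``(X, labels, label_map)`` where ``label_map`` maps original
    label values to the contiguous indices used internally; row order is
    preserved.
    """
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    if df.isna().any().any():
        bad = df.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(f"missing value at row {row}, column {col!r} in {path}")
    features = df.drop(columns=[label_column])
    try:
        X = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature values in {path}: {exc}") from exc
    raw = df[label_column].to_numpy()
    if not np.issubdtype(raw.dtype, np.integer):
        if not np.all(raw == raw.astype(int)):
            raise ValueError("labels must be integers")
        raw = raw.astype(int)
    uniques = np.unique(raw)
    if uniques.shape[0] < 2:
        raise ValueError("need at least two classes in the label column")
    label_map = {int(v): i for i, v in enumerate(uniques)}
    labels = np.array([label_map[int(v)] for v in raw])
    return X, labels, label_map


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path) -> None:
    """Write a report (dataclass or mapping) as JSON; lossless round trip."""
    payload = _jsonable(report)
    pathlib.Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(pathlib.Path(path).read_text())


def load_config(path) -> dict:
    text = pathlib.Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _as_S(entry, dim: int) -> np.ndarray:
    """Accept a full matrix or a scalar meaning scalar * identity."""
    arr = np.asarray(entry, dtype=float)
    if arr.ndim == 0:
        return float(arr) * np.eye(dim)
    return arr


def build_model(config: dict):
    """Build ``(class_prob, prior, loss)`` from a configuration mapping.

    ``prior`` is a :class:`GaussianPosterior` for Gaussian configs or the
    Dirichlet parameter matrix for discrete configs.  Every propriety
    violation raises with a message naming the offending hyperparameter.
    """
    loss = LossMatrix(np.asarray(config["loss"], dtype=float))
    cp = config["class_prob"]
    mode = cp["mode"]
    if mode == "known":
        class_prob = ClassProbPosterior("known", c=np.asarray(cp["c"], float))
    else:
        class_prob = ClassProbPosterior(mode, alpha=np.asarray(cp["alpha"], float))
    model = config["model"]
    if model.get("kind") == "discrete":
        alpha = np.asarray(model["alpha"], dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("discrete prior parameters alpha must all be positive")
        return class_prob, alpha, loss
    structure = model["structure"]
    coupling = model.get("coupling", "independent")
    m = np.asarray(model["m"], dtype=float)
    dim = m.shape[1]
    if structure == "known":
        prior = GaussianPosterior(
            structure="known",
            coupling="independent",
            nu=np.asarray(model["nu"], float),
            m=m,
            sigma=np.asarray(model["sigma"], float),
        )
    else:
        raw_S = np.asarray(model["S"], dtype=float)
        if coupling == "homoscedastic":
            kappa = float(np.asarray(model["kappa"]).reshape(-1)[0])
            S = _as_S(raw_S, dim)
        else:
            kappa = np.asarray(model["kappa"], dtype=float)
            if raw_S.ndim <= 1:  # one scalar, or one scalar per class
                scalars = np.broadcast_to(raw_S, (m.shape[0],))
                S = np.stack([s * np.eye(dim) for s in scalars])
            elif raw_S.ndim == 2:
                S = np.broadcast_to(raw_S, (m.shape[0], dim, dim)).copy()
            else:
                S = raw_S
        prior = GaussianPosterior(
            structure=structure, coupling=coupling,
            nu=np.asarray(model["nu"], float), m=m, kappa=kappa, S=S,
        )
    return class_prob, prior, loss
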