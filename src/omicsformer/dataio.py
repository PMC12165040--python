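"""Delimited omics-matrix I/O, sample alignment and model serialization.

Matrices are plain delimited text: one header row of feature IDs and a
leading sample-ID column (or the transpose).  Missing entries are carried
internally as NaN and written back out as ``"NA"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_MODEL_FORMAT_VERSION = 1


@dataclass
class OmicsMatrix:
    """One omics layer: an n-samples x d-features real matrix with IDs.

    Missing entries are NaN in ``values``; ``missing_mask`` mirrors them.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_name: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample IDs x {len(self.feature_ids)} feature IDs"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} ID: {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values.copy(), list(self.sample_ids), list(self.feature_ids), self.omics_name
        )

    def subset_samples(self, ids: list[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return OmicsMatrix(self.values[idx], list(ids), list(self.feature_ids), self.omics_name)

    def subset_features(self, keep: list[str]) -> "OmicsMatrix":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in keep]
        return OmicsMatrix(self.values[:, idx], list(self.sample_ids), list(keep), self.omics_name)


@dataclass
class MultiOmicsDataset:
    """Sample-aligned collection of omics layers plus optional labels."""

    layers: list[OmicsMatrix]
    labels: np.ndarray | None = None
    split_tags: np.ndarray | None = None
    alignment_dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("dataset needs at least one layer")
        ref = self.layers[0].sample_ids
        for layer in self.layers[1:]:
            if layer.sample_ids != ref:
                raise ValueError(
                    f"layer {layer.omics_name!r} sample IDs differ from {self.layers[0].omics_name!r}"
                )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(ref):
                raise ValueError("labels length does not match sample count")
            if self.labels.min() < 0:
                raise ValueError("class labels must be non-negative integers")

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.layers[0].n_samples

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return int(self.labels.max()) + 1

    def layer(self, name: str) -> OmicsMatrix:
        for lay in self.layers:
            if lay.omics_name == name:
                return lay
        raise KeyError(f"no omics layer named {name!r}")

    def subset_samples(self, index: np.ndarray) -> "MultiOmicsDataset":
        """Restrict to a boolean mask or integer index over samples."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ids = [self.sample_ids[i] for i in index]
        layers = [lay.subset_samples(ids) for lay in self.layers]
        labels = self.labels[index] if self.labels is not None else None
        return MultiOmicsDataset(layers, labels)

    def copy(self) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            [lay.copy() for lay in self.layers],
            None if self.labels is None else self.labels.copy(),
        )


def _first_duplicate(ids) -> str | None:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path,
    orientation: str = "samples-in-rows",
    omics_name: str | None = None,
    delimiter: str | None = None,
) -> OmicsMatrix:
    """Read a delimited matrix with a header row and leading ID column.

    ``orientation`` is ``"samples-in-rows"`` (default) or
    ``"features-in-rows"`` for transposed files.  Empty fields, ``NA`` and
    ``NaN`` become missing entries.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "features-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    raw = df.to_numpy()
    missing_tokens = {"", "NA", "NaN", "nan", "na"}
    stripped = np.char.strip(raw.astype(str))
    is_missing = np.isin(stripped, sorted(missing_tokens))
    numeric = pd.to_numeric(pd.Series(stripped.ravel()), errors="coerce").to_numpy()
    values = numeric.astype(float).reshape(raw.shape)
    bad = np.isnan(values) & ~is_missing
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-numeric cell {stripped[i, j]!r} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r} in {path}"
        )
    values[is_missing] = np.nan
    return OmicsMatrix(
        values,
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        omics_name or path.stem,
    )


def write_matrix(matrix: OmicsMatrix, path, delimiter: str | None = None) -> None:
    """Write a matrix as delimited text; missing entries become ``NA``."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids)
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.12g")


def read_labels(path, delimiter: str | None = None) -> dict[str, int]:
    """Read a two-column (sample_id, class) labels file into a mapping."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("labels file needs two columns: sample_id, class")
    sample_col, class_col = df.columns[:2]
    dup = _first_duplicate(list(df[sample_col]))
    if dup is not None:
        raise ValueError(f"duplicate sample ID in labels file: {dup!r}")
    return {str(s): int(c) for s, c in zip(df[sample_col], df[class_col])}


def write_labels(labels: dict[str, int], path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    pd.DataFrame(
        {"sample_id": list(labels), "class": [labels[s] for s in labels]}
    ).to_csv(path, sep=sep, index=False)


def align_samples(
    layers: list[OmicsMatrix], labels: dict[str, int] | None = None
) -> MultiOmicsDataset:
    """Restrict layers to their shared sample IDs in lexicographic order.

    The returned dataset records the IDs dropped from each layer in
    ``alignment_dropped`` (layer name -> sorted list).  Lexicographic
    ordering makes downstream runs deterministic regardless of file order.
    """
    if not layers:
        raise ValueError("need at least one layer")
    common = set(layers[0].sample_ids)
    for lay in layers[1:]:
        common &= set(lay.sample_ids)
    if not common:
        raise ValueError("sample-ID intersection across layers is empty")
    if labels is not None:
        missing = common - set(labels)
        if missing:
            raise ValueError(f"labels missing for samples: {sorted(missing)[:5]}")
    order = sorted(common)
    dropped = {
        lay.omics_name: sorted(set(lay.sample_ids) - common) for lay in layers
    }
    aligned = [lay.subset_samples(order) for lay in layers]
    y = np.array([labels[s] for s in order], dtype=int) if labels is not None else None
    ds = MultiOmicsDataset(aligned, y)
    ds.alignment_dropped = dropped
    return ds


# --- model serialization ----------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a fitted model (Omicsformer or blood-panel risk model).

    Single ``.npz`` archive holding every parameter array plus a JSON
    header with the format version and a config snapshot.
    """
    arrays, config = model._to_arrays()
    header = {
        "format_version": _MODEL_FORMAT_VERSION,
        "model_class": type(model).__name__,
        "config": config,
    }
    payload = dict(arrays)
    payload["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    )
    # write through a file object so np.savez never appends a suffix
    with open(Path(path), "wb") as fh:
        np.savez(fh, **payload)


def load_model(path):
    """Load a model written by :func:`save_model`; dispatches on class."""
    try:
        with np.load(Path(path)) as npz:
            if "__header__" not in npz:
                raise ValueError(f"{path}: not a model file (missing header)")
            header = json.loads(bytes(npz["__header__"].tobytes()).decode("utf-8"))
            arrays = {k: npz[k] for k in npz.files if k != "__header__"}
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    version = header.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version} not supported (expected {_MODEL_FORMAT_VERSION})"
        )
    cls_name = header["model_class"]
    if cls_name == "OmicsformerModel":
        from .model import OmicsformerModel

        return OmicsformerModel._from_arrays(arrays, header["config"])
    if cls_name == "RiskModel":
        from .blood_risk import RiskModel

        return RiskModel._from_arrays(arrays, header["config"])
    raise ValueError(f"unknown model class {cls_name!r} in {path}")
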