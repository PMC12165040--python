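"""Feature filtering, minimum-fraction imputation, log2 and standardization.

The pipeline order is fixed: **filter -> impute -> log2 -> center/scale**.
Filters mirror common quality rules for quantified omics layers:

* protein layers keep features with coefficient of variation (CV) < 0.3
  *and* missing fraction < 0.25;
* other layers keep features with missing fraction < 0.20, so that every
  retained missing cell falls under the single imputation rule;
* missing cells are imputed as ``factor x`` the minimum positive observed
  value of the whole layer (default factor 1/83, a limit-of-detection
  style small fraction of the observed floor);
* designated layers are log2-transformed, then every feature is centered
  and scaled to unit variance using training-set statistics.

Non-positive observed values are treated as missing for the purposes of
the minimum-positive computation and log2 safety.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import MultiOmicsDataset, OmicsMatrix

DEFAULT_IMPUTE_FACTOR = 1.0 / 83.0


@dataclass
class PreprocessRecipe:
    """Thresholds and switches for the preprocessing pipeline.

    ``protein_layers`` names the layers subject to the CV filter;
    ``log2_layers`` the layers to log2-transform (typically metabolomic
    and proteomic abundances, not a clinical blood panel).
    """

    cv_max: float = 0.3
    missing_max_protein: float = 0.25
    missing_max_other: float = 0.20
    impute_factor: float = DEFAULT_IMPUTE_FACTOR
    protein_layers: frozenset = frozenset()
    log2_layers: frozenset = frozenset()
    scale: bool = True

    def __post_init__(self) -> None:
        for name in ("cv_max", "missing_max_protein", "missing_max_other"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.impute_factor <= 0:
            raise ValueError("impute_factor must be positive")
        self.protein_layers = frozenset(self.protein_layers)
        self.log2_layers = frozenset(self.log2_layers)


@dataclass
class ScalingStats:
    """Per-feature mean/sd learned on training data, keyed by feature ID."""

    mean: np.ndarray
    std: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("scaling stats require strictly positive stds")


def feature_cv(column: np.ndarray) -> float:
    """Coefficient of variation of one feature: sample sd / mean.

    Computed over non-missing entries on the raw (pre-log) scale.
    Requires at least two observed values and a non-zero mean.
    """
    col = np.asarray(column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size < 2:
        raise ValueError("CV undefined: fewer than 2 observed values")
    mean = obs.mean()
    if mean == 0:
        raise ValueError("CV undefined: zero mean")
    return float(obs.std(ddof=1) / mean)


def filter_features(
    matrix: OmicsMatrix, recipe: PreprocessRecipe
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Apply the retention filters; returns survivors plus a drop report.

    The report has columns (feature_id, reason).  All thresholds are
    strict ``<`` comparisons, so a feature at exactly the missing-fraction
    threshold is dropped.
    """
    if matrix.n_features == 0:
        raise ValueError("empty matrix")
    is_protein = matrix.omics_name in recipe.protein_layers
    miss_max = recipe.missing_max_protein if is_protein else recipe.missing_max_other
    miss_frac = matrix.missing_mask.mean(axis=0)

    keep, dropped = [], []
    for j, fid in enumerate(matrix.feature_ids):
        if miss_frac[j] >= miss_max:
            dropped.append((fid, f"missing_fraction={miss_frac[j]:.3f}>={miss_max}"))
            continue
        if is_protein:
            try:
                cv = feature_cv(matrix.values[:, j])
            except ValueError:
                dropped.append((fid, "cv_undefined"))
                continue
            if not cv < recipe.cv_max:
                dropped.append((fid, f"cv={cv:.3f}>={recipe.cv_max}"))
                continue
        keep.append(fid)
    if not keep:
        raise ValueError(f"all features dropped from layer {matrix.omics_name!r}")
    report = pd.DataFrame(dropped, columns=["feature_id", "reason"])
    return matrix.subset_features(keep), report


def impute_min_fraction(
    matrix: OmicsMatrix, factor: float = DEFAULT_IMPUTE_FACTOR
) -> OmicsMatrix:
    """Replace missing entries with ``factor x`` the layer's minimum
    positive observed value.

    Non-positive observed entries are treated as missing too, so the
    output is strictly positive and safe to log-transform.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = matrix.copy()
    vals = out.values
    fill_mask = np.isnan(vals) | (vals <= 0)
    positive = vals[~np.isnan(vals) & (vals > 0)]
    if positive.size == 0:
        raise ValueError(f"layer {matrix.omics_name!r} has no positive entries")
    if fill_mask.any():
        vals[fill_mask] = factor * positive.min()
    return out


def transform_scale(
    matrix: OmicsMatrix,
    recipe: PreprocessRecipe,
    stats: ScalingStats | None = None,
) -> tuple[OmicsMatrix, ScalingStats]:
    """log2 (if the layer is designated) then center/unit-variance scale.

    With ``stats`` given (test data), the stored training means/sds are
    applied; otherwise stats are fitted on the matrix itself and returned.
    Constant features cannot be scaled and raise when fitting.
    """
    out = matrix.copy()
    vals = out.values
    if np.isnan(vals).any():
        raise ValueError("transform_scale expects a complete (imputed) matrix")
    if matrix.omics_name in recipe.log2_layers:
        if np.any(vals <= 0):
            i, j = map(int, np.argwhere(vals <= 0)[0])
            raise ValueError(
                f"log2 undefined for non-positive entry at sample "
                f"{matrix.sample_ids[i]!r}, feature {matrix.feature_ids[j]!r}"
            )
        vals = np.log2(vals)
    if not recipe.scale:
        out.values = vals
        return out, stats if stats is not None else ScalingStats(
            np.zeros(vals.shape[1]), np.ones(vals.shape[1]), list(matrix.feature_ids)
        )
    if stats is None:
        mean = vals.mean(axis=0)
        std = vals.std(axis=0, ddof=1)
        if np.any(std <= 0):
            j = int(np.argwhere(std <= 0)[0])
            raise ValueError(
                f"constant feature {matrix.feature_ids[j]!r} cannot be scaled; "
                "remove it before scaling"
            )
        stats = ScalingStats(mean, std, list(matrix.feature_ids))
    else:
        if stats.feature_ids != matrix.feature_ids:
            raise ValueError("scaling stats feature IDs do not match matrix")
    out.values = (vals - stats.mean) / stats.std
    return out, stats


@dataclass
class PreprocessResult:
    dataset: MultiOmicsDataset
    stats: dict
    reports: dict = field(default_factory=dict)


def preprocess_dataset(
    dataset: MultiOmicsDataset,
    recipe: PreprocessRecipe,
    stats: dict | None = None,
) -> PreprocessResult:
    """Run filter -> impute -> log2 -> scale on every layer.

    When ``stats`` (per-layer ScalingStats + surviving feature lists from a
    training run) is supplied, filtering is replaced by restriction to the
    training survivors and the stored scaling statistics are applied —
    the mode used for held-out data.
    """
    new_layers, out_stats, reports = [], {}, {}
    for layer in dataset.layers:
        name = layer.omics_name
        if stats is None:
            filtered, report = filter_features(layer, recipe)
            reports[name] = report
            layer_stats = None
        else:
            filtered = layer.subset_features(stats[name].feature_ids)
            layer_stats = stats[name]
        # drop constant complete features before scaling (cannot be standardized)
        if layer_stats is None and recipe.scale:
            imputed_probe = impute_min_fraction(filtered, recipe.impute_factor)
            probe = (
                np.log2(imputed_probe.values)
                if name in recipe.log2_layers
                else imputed_probe.values
            )
            keep = [
                fid
                for fid, sd in zip(filtered.feature_ids, probe.std(axis=0, ddof=1))
                if sd > 0
            ]
            if not keep:
                raise ValueError(f"all features constant in layer {name!r}")
            filtered = filtered.subset_features(keep)
        imputed = impute_min_fraction(filtered, recipe.impute_factor)
        scaled, layer_stats = transform_scale(imputed, recipe, layer_stats)
        new_layers.append(scaled)
        out_stats[name] = layer_stats
    out = MultiOmicsDataset(new_layers, dataset.labels)
    return PreprocessResult(out, out_stats, reports)
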