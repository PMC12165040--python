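"""Synthetic cohorts with planted structure for offline end-to-end testing.

Three generators, all pure functions of their spec (seed included):

* ``generate_multiomics_cohort`` — a cohort of n samples in k latent
  groups across v omics layers.  Background features are Gaussian around
  a positive baseline; each informative feature's group mean is shifted
  by +/- delta (in noise-sd units) according to a per-group sign pattern;
  entries go missing completely at random at rate m.
* ``generate_blood_panel`` — a 25-parameter Gaussian-mixture panel whose
  k group means sit equally spaced along the all-ones direction
  (adjacent pairs ``separation`` within-group sds apart), so group order
  encodes increasing overall magnitude.
* ``generate_longitudinal`` — dated pre-onset blood records drifting
  from a low-risk toward a high-risk centroid as onset approaches:
  a record at time-to-onset t is drawn from the high-risk component with
  probability lambda(t) = exp(-t / tau).

Defaults mirror the study conditions the package is designed around:
160 samples in groups of 80/41/39, four omics layers, a 25-parameter
panel, and a 100-patient 5-year retrospective record set.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .dataio import MultiOmicsDataset, OmicsMatrix
from .preprocess import PreprocessRecipe
from .trajectory import LongitudinalRecord

PANEL_WIDTH = 25
PANEL_FEATURES = [f"BP{i + 1:02d}" for i in range(PANEL_WIDTH)]
_PANEL_BASELINE = 10.0

DEFAULT_LAYERS = {
    "transcriptome": 2000,
    "proteome": 800,
    "metabolome_blood": 400,
    "metabolome_urine": 300,
}


@dataclass
class CohortSpec:
    """Study conditions for the multi-omics cohort generator."""

    group_sizes: tuple = (80, 41, 39)
    layer_features: dict = field(default_factory=lambda: dict(DEFAULT_LAYERS))
    informative_per_layer: int = 40
    effect_size: float = 1.5
    noise_sd: float = 1.0
    baseline: float = 12.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 1:
            raise ValueError("every group needs at least one sample")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.informative_per_layer < 0:
            raise ValueError("informative_per_layer must be >= 0")
        if any(self.informative_per_layer > d for d in self.layer_features.values()):
            raise ValueError("more informative features than features in a layer")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))


@dataclass
class DriftSpec:
    """Study conditions for the longitudinal pre-onset record generator."""

    n_patients: int = 100
    records_per_year: int = 2
    years: float = 5.0
    tau: float = 3.0
    low_centroid: np.ndarray | None = None
    high_centroid: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.n_patients < 1 or self.records_per_year < 1:
            raise ValueError("need at least one patient and one record per year")
        if self.low_centroid is None:
            self.low_centroid = panel_group_means(separation=6.0, k=3)[0]
        if self.high_centroid is None:
            self.high_centroid = panel_group_means(separation=6.0, k=3)[2]
        self.low_centroid = np.asarray(self.low_centroid, dtype=float)
        self.high_centroid = np.asarray(self.high_centroid, dtype=float)
        if self.low_centroid.shape != (PANEL_WIDTH,) or self.high_centroid.shape != (
            PANEL_WIDTH,
        ):
            raise ValueError(f"centroids must have {PANEL_WIDTH} panel parameters")


def cohort_recipe() -> PreprocessRecipe:
    """The preprocessing recipe matched to the synthetic cohort's scale.

    The generator emits Gaussian intensities around a positive baseline —
    the shape abundance data takes *after* log transformation — so no
    second log2 is applied.  Missing cells are imputed at the layer's
    minimum observed positive value (factor 1.0, standard minimum-value
    imputation for log-scale matrices); the small-fraction 1/83 default
    is meant for raw-scale abundances spanning orders of magnitude, where
    a fraction of the observed floor approximates a detection limit.
    The proteome layer carries the CV retention filter.
    """
    return PreprocessRecipe(
        protein_layers={"proteome"},
        log2_layers=set(),
        impute_factor=1.0,
    )


def _group_labels(group_sizes) -> np.ndarray:
    return np.repeat(np.arange(len(group_sizes)), group_sizes)


def _sign_patterns(
    rng: np.random.Generator, k: int, s: int, max_tries: int = 1000
) -> np.ndarray:
    """k x s matrix of +/-1 group sign patterns.

    Every feature's pattern is non-constant across groups (a feature that
    shifts all groups equally carries no group information), and every
    pair of groups differs on at least s/2 features, which guarantees
    identifiability at moderate effect sizes.
    """
    if s == 0:
        return np.zeros((k, 0))
    # with a single +/-1 feature and k > 2 groups, not every pair can
    # differ; enforce only non-constancy in that degenerate case
    pair_min = s / 2 if s >= 2 or k <= 2 else 0
    for _ in range(max_tries):
        signs = rng.choice([-1.0, 1.0], size=(k, s))
        for j in range(s):
            while np.all(signs[:, j] == signs[0, j]):
                signs[:, j] = rng.choice([-1.0, 1.0], size=k)
        ok = all(
            np.sum(signs[a] != signs[b]) >= pair_min
            for a in range(k)
            for b in range(a + 1, k)
        )
        if ok:
            return signs
    raise RuntimeError("could not draw sufficiently distinct sign patterns")


def generate_multiomics_cohort(
    spec: CohortSpec,
) -> tuple[MultiOmicsDataset, dict]:
    """Generate the cohort; returns (dataset-with-labels, truth registry).

    The registry maps layer name -> {"features": planted feature IDs,
    "signs": k x s sign matrix}; it never leaks into the data itself.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = _group_labels(spec.group_sizes)
    k = len(spec.group_sizes)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    layers, truth = [], {}
    for name, d in spec.layer_features.items():
        values = rng.normal(spec.baseline, spec.noise_sd, size=(n, d))
        s = spec.informative_per_layer
        info_idx = rng.choice(d, size=s, replace=False) if s else np.array([], dtype=int)
        signs = _sign_patterns(rng, k, s)
        for col, j in enumerate(info_idx):
            shift = spec.effect_size * spec.noise_sd * signs[labels, col]
            values[:, j] += shift
        if spec.missing_rate > 0:
            mask = rng.random(size=(n, d)) < spec.missing_rate
            values[mask] = np.nan
        feature_ids = [f"{name[:3].upper()}_{j + 1:05d}" for j in range(d)]
        layers.append(OmicsMatrix(values, sample_ids, feature_ids, name))
        truth[name] = {
            "features": [feature_ids[j] for j in info_idx],
            "signs": signs,
        }
    return MultiOmicsDataset(layers, labels), truth


def panel_group_means(separation: float, k: int = 3) -> np.ndarray:
    """k x 25 matrix of group means: equally spaced along ones/sqrt(25),
    adjacent groups ``separation`` apart, increasing overall magnitude."""
    u = np.ones(PANEL_WIDTH) / np.sqrt(PANEL_WIDTH)
    return np.stack(
        [_PANEL_BASELINE + g * separation * u for g in range(k)], axis=0
    )


def generate_blood_panel(
    n: int = 160,
    group_sizes: tuple = (80, 41, 39),
    separation: float = 6.0,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[OmicsMatrix, np.ndarray]:
    """25-column Gaussian-mixture blood panel; returns (panel, true labels).

    Group index increases with overall panel magnitude, so the planted
    risk ordering is recoverable from decoded centroid means.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if sum(group_sizes) != n:
        raise ValueError(f"group sizes {group_sizes} do not sum to n={n}")
    rng = np.random.default_rng(seed)
    labels = _group_labels(group_sizes)
    means = panel_group_means(separation * noise_sd, k=len(group_sizes))
    values = means[labels] + rng.normal(0.0, noise_sd, size=(n, PANEL_WIDTH))
    sample_ids = [f"B{i + 1:04d}" for i in range(n)]
    return OmicsMatrix(values, sample_ids, list(PANEL_FEATURES), "blood_panel"), labels


def generate_longitudinal(spec: DriftSpec) -> list[LongitudinalRecord]:
    """Dated pre-onset records drifting toward the high-risk centroid.

    Every record strictly precedes its patient's onset date; the
    high-risk mixture weight at time-to-onset t (years) is exp(-t/tau).
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    base_onset = _dt.date(2020, 1, 1)
    n_records = int(round(spec.records_per_year * spec.years))
    for p in range(spec.n_patients):
        pid = f"P{p + 1:04d}"
        onset = base_onset + _dt.timedelta(days=int(rng.integers(0, 365)))
        times = rng.uniform(0.0, spec.years, size=n_records)
        for t in times:
            lam = float(np.exp(-t / spec.tau))
            centroid = spec.high_centroid if rng.random() < lam else spec.low_centroid
            panel = centroid + rng.normal(0.0, spec.noise_sd, size=PANEL_WIDTH)
            # at least one day before onset
            days_before = max(1, int(round(t * 365.25)))
            records.append(
                LongitudinalRecord(
                    patient_id=pid,
                    record_date=onset - _dt.timedelta(days=days_before),
                    panel=panel,
                    onset_date=onset,
                )
            )
    return records
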