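"""Deep clustering of routine blood panels into ordered risk groups.

A single self-attention block maps the standardized 25-parameter panel
into a latent space; an affine decoder reconstructs the panel and the
pair is trained as an autoencoder.  K-means on the latent embeddings
yields k clusters whose within-cluster mean latent vectors become risk
centroids.  Clusters are ranked into risk levels 1 (low) .. k (high) by
the mean of their decoded, standardized panel values — the high-risk
group is the one whose blood indices run largest overall.  New records
are standardized with the stored training statistics, embedded, and
assigned the risk level of the nearest centroid by Euclidean distance
(ties break toward the lower risk level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._autograd import Adam, affine_backward, attention_backward, attention_forward, init_matrix
from .dataio import OmicsMatrix
from .model import Affine, AttentionBlockParams, self_attention
from .preprocess import ScalingStats


@dataclass
class BloodRiskConfig:
    """Autoencoder and clustering settings for the blood-panel model."""

    k: int = 3
    latent_dim: int = 8
    epochs: int = 300
    learning_rate: float = 1e-3
    n_init: int = 50
    seed: int = 0
    scale_mode: str = "sqrt"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class RiskModel:
    """Fitted blood-panel risk model: encoder, decoder, scaling stats,
    latent centroids and the cluster -> risk-level ordering."""

    block: AttentionBlockParams
    decoder: Affine
    stats: ScalingStats
    medians: np.ndarray
    centroids: np.ndarray
    risk_order: np.ndarray  # risk_order[cluster_index] = level in 1..k
    k: int
    feature_ids: list[str]
    history: list = field(default_factory=list)
    cluster_labels: np.ndarray | None = None
    # standardized training panel; new records are embedded jointly with
    # it so their latent coordinates share the training attention context
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k >= 2:
            d = _pairwise_sq_dists(self.centroids, self.centroids)
            np.fill_diagonal(d, np.inf)
            if d.min() == 0:
                raise ValueError("centroids must be pairwise distinct")
        if sorted(self.risk_order.tolist()) != list(range(1, self.k + 1)):
            raise ValueError("risk_order must be a permutation of 1..k")

    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (values - self.stats.mean) / self.stats.std

    def encode(self, standardized: np.ndarray) -> np.ndarray:
        """Latent embedding of an already-standardized record batch.

        With a stored training reference, the records are embedded
        jointly with it and the record rows are returned (attention is
        permutation-equivariant, so each record's embedding does not
        depend on row order).
        """
        if self.reference is None:
            return self_attention(standardized, self.block)
        X = np.concatenate([self.reference, standardized], axis=0)
        return self_attention(X, self.block)[-standardized.shape[0]:]

    def _to_arrays(self):
        arrays = {
            "W_Q": self.block.W_Q,
            "W_K": self.block.W_K,
            "W_V": self.block.W_V,
            "dec_W": self.decoder.W,
            "dec_b": self.decoder.b,
            "mean": self.stats.mean,
            "std": self.stats.std,
            "medians": self.medians,
            "centroids": self.centroids,
            "risk_order": self.risk_order,
        }
        if self.reference is not None:
            arrays["reference"] = self.reference
        config = {
            "k": self.k,
            "feature_ids": self.feature_ids,
            "scale_mode": self.block.scale_mode,
        }
        return arrays, config

    @classmethod
    def _from_arrays(cls, arrays, config):
        block = AttentionBlockParams(
            arrays["W_Q"],
            arrays["W_K"],
            arrays["W_V"],
            scale_dim=arrays["W_Q"].shape[1],
            scale_mode=config["scale_mode"],
        )
        return cls(
            block=block,
            decoder=Affine(arrays["dec_W"], arrays["dec_b"]),
            stats=ScalingStats(arrays["mean"], arrays["std"], list(config["feature_ids"])),
            medians=arrays["medians"],
            centroids=arrays["centroids"],
            risk_order=np.asarray(arrays["risk_order"], dtype=int),
            k=int(config["k"]),
            feature_ids=list(config["feature_ids"]),
            reference=arrays.get("reference"),
        )


@dataclass
class RiskAssignment:
    sample_id: str
    latent: np.ndarray
    distances: np.ndarray
    risk_level: int


def _pairwise_sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)


def fit_blood_autoencoder(
    B: np.ndarray, config: BloodRiskConfig
) -> tuple[AttentionBlockParams, Affine, list[float]]:
    """Train the attention autoencoder on a standardized, complete panel.

    Minimizes ||B - g(H_B)||_F^2 by full-batch Adam; returns the encoder
    block, decoder and the per-epoch loss trajectory (entry 0 is the
    initial loss).
    """
    B = np.asarray(B, dtype=float)
    if np.isnan(B).any():
        raise ValueError("autoencoder input must be complete (no missing values)")
    d = B.shape[1]
    rng = np.random.default_rng(config.seed)
    dh = config.latent_dim
    block = AttentionBlockParams(
        init_matrix(rng, d, dh),
        init_matrix(rng, d, dh),
        init_matrix(rng, d, dh),
        scale_dim=dh,
        scale_mode=config.scale_mode,
    )
    decoder = Affine(init_matrix(rng, dh, d), np.zeros(d))
    params = [block.W_Q, block.W_K, block.W_V, decoder.W, decoder.b]
    opt = Adam(params, lr=config.learning_rate)
    trajectory = []
    for epoch in range(config.epochs):
        H, cache = attention_forward(B, block.W_Q, block.W_K, block.W_V, block.scale)
        B_hat = H @ decoder.W + decoder.b
        loss = float(np.sum((B_hat - B) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite autoencoder loss at epoch {epoch}")
        trajectory.append(loss)
        dBhat = 2.0 * (B_hat - B)
        dH, dWd, dbd = affine_backward(dBhat, H, decoder.W)
        _, dWQ, dWK, dWV = attention_backward(dH, cache, block.W_Q, block.W_K, block.W_V)
        opt.step([dWQ, dWK, dWV, dWd, dbd])
    H, _ = attention_forward(B, block.W_Q, block.W_K, block.W_V, block.scale)
    trajectory.append(float(np.sum((H @ decoder.W + decoder.b - B) ** 2)))
    return block, decoder, trajectory


def cluster_latent(H: np.ndarray, k: int, seed: int, n_init: int = 50) -> np.ndarray:
    """K-means over latent embeddings; labels in 1..k, deterministic
    given the seed (best of ``n_init`` seeded restarts by inertia)."""
    H = np.asarray(H, dtype=float)
    if H.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {H.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**32))
    return km.fit_predict(H) + 1


def order_risk_levels(centroids: np.ndarray, decoder: Affine) -> np.ndarray:
    """Rank clusters into risk levels by decoded panel magnitude.

    Each centroid is decoded back to the standardized panel space; the
    mean over the 25 parameters orders the clusters, largest mean ->
    highest risk level.  Exact ties break by cluster index.
    """
    decoded = centroids @ decoder.W + decoder.b
    magnitude = decoded.mean(axis=1)
    order = np.argsort(magnitude, kind="stable")  # ascending; stable = index tie-break
    risk_order = np.empty(len(magnitude), dtype=int)
    risk_order[order] = np.arange(1, len(magnitude) + 1)
    return risk_order


def build_risk_model(
    B: OmicsMatrix, config: BloodRiskConfig | None = None, max_reseeds: int = 5
) -> RiskModel:
    """Full blood-risk pipeline on a raw panel matrix.

    Median-imputes missing fields, standardizes, fits the autoencoder,
    clusters the latent space, computes within-cluster mean centroids and
    orders them into risk levels.  An empty cluster triggers a re-run
    with the next seed (logged via warning).
    """
    config = config or BloodRiskConfig()
    values = np.asarray(B.values, dtype=float)
    medians = np.nanmedian(values, axis=0)
    if np.isnan(medians).any():
        raise ValueError("a panel parameter is missing in every sample")
    filled = np.where(np.isnan(values), medians, values)
    mean = filled.mean(axis=0)
    std = filled.std(axis=0, ddof=1)
    if np.any(std <= 0):
        raise ValueError("constant panel parameter cannot be standardized")
    stats = ScalingStats(mean, std, list(B.feature_ids))
    Bs = (filled - mean) / std

    for attempt in range(max_reseeds):
        seed = config.seed + attempt
        cfg = BloodRiskConfig(
            k=config.k,
            latent_dim=config.latent_dim,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            n_init=config.n_init,
            seed=seed,
            scale_mode=config.scale_mode,
        )
        block, decoder, history = fit_blood_autoencoder(Bs, cfg)
        H = self_attention(Bs, block)
        labels = cluster_latent(H, cfg.k, seed=seed, n_init=cfg.n_init)
        sizes = np.array([(labels == c).sum() for c in range(1, cfg.k + 1)])
        if sizes.min() > 0:
            break
        warnings.warn(f"empty cluster with seed {seed}; retrying with seed {seed + 1}")
    else:
        raise RuntimeError("clustering produced an empty cluster for every seed tried")

    centroids = np.stack([H[labels == c].mean(axis=0) for c in range(1, cfg.k + 1)])
    risk_order = order_risk_levels(centroids, decoder)
    return RiskModel(
        block=block,
        decoder=decoder,
        stats=stats,
        medians=medians,
        centroids=centroids,
        risk_order=risk_order,
        k=cfg.k,
        feature_ids=list(B.feature_ids),
        history=history,
        cluster_labels=labels,
        reference=Bs,
    )


def assign_risk(records: OmicsMatrix, model: RiskModel) -> list[RiskAssignment]:
    """Assign each record the risk level of its nearest latent centroid.

    Records are standardized with the model's stored training statistics
    and embedded as one batch.  Missing panel fields are imputed with the
    stored training medians (with a per-record warning); an all-missing
    record is an error.  Exact distance ties break toward the lower risk
    level.
    """
    if records.feature_ids != model.feature_ids:
        try:
            records = records.subset_features(model.feature_ids)
        except KeyError as exc:
            raise ValueError(
                "record features do not match the panel schema of the model"
            ) from exc
    values = np.asarray(records.values, dtype=float)
    missing = np.isnan(values)
    for i in np.flatnonzero(missing.all(axis=1)):
        raise ValueError(f"record {records.sample_ids[i]!r} has no observed panel fields")
    for i in np.flatnonzero(missing.any(axis=1)):
        warnings.warn(
            f"record {records.sample_ids[i]!r}: "
            f"{int(missing[i].sum())} missing fields imputed with training medians"
        )
    filled = np.where(missing, model.medians, values)
    H = model.encode(model.standardize(filled))
    dists = np.sqrt(_pairwise_sq_dists(H, model.centroids))
    out = []
    for i, sid in enumerate(records.sample_ids):
        d = dists[i]
        # candidates at the minimal distance; tie -> lowest risk level
        at_min = np.flatnonzero(d == d.min())
        cluster = at_min[np.argmin(model.risk_order[at_min])]
        out.append(
            RiskAssignment(
                sample_id=sid,
                latent=H[i],
                distances=d,
                risk_level=int(model.risk_order[cluster]),
            )
        )
    return out
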