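"""The Can-EWS recurrent classifier: construction, training, risk scoring.

Two variants share one architecture — three stacked GRU layers of 24 units
with dropout 0.3 and a 2-unit softmax head.  V1 consumes the five hourly
vital-sign channels; V2 additionally consumes their five consecutive-
difference (delta) channels, ten features in all.  The softmax event-class
probability, scaled to 0–100, is the risk score.

Feature channels are standardized to zero mean / unit variance using
statistics computed on the training windows only; the frozen parameters
travel with the model and are applied verbatim at validation, test and
deployment time.

Training minimises binary cross-entropy with Adam (default parameters).
Epoch count, batch size and early stopping are exposed in the config; with
the same seed, data and thread configuration, training and scoring are
bit-reproducible (same-platform contract).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cohort import PatientStay
from .nn import Adam, GRUClassifier, cross_entropy
from .preprocessing import (
    CleaningRanges,
    EventWindowSpec,
    build_feature_windows,
    compute_deltas,
    resample_hourly,
    stack_windows,
)

__all__ = [
    "ModelConfig",
    "CanEWSModel",
    "RiskSeries",
    "build_model",
    "train",
    "predict_risk",
    "score_stay",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    The architecture (3 GRU layers × 24 units, dropout 0.3, Adam, binary
    cross-entropy, 2-unit softmax) is fixed by design; epochs, batch size
    and early stopping are ordinary training knobs.
    """

    variant: str = "V2"
    lookback: int = 24
    n_recurrent_layers: int = 3
    units_per_layer: int = 24
    dropout_rate: float = 0.3
    learning_rate: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 128
    patience: int = 5
    class_weight: str | None = None  # None or "balanced"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("V1", "V2"):
            raise ValueError("variant must be 'V1' or 'V2'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lookback < 1 or self.units_per_layer < 1:
            raise ValueError("lookback and units_per_layer must be >= 1")

    @property
    def n_features(self) -> int:
        return 5 if self.variant == "V1" else 10


@dataclass
class RiskSeries:
    """Hourly risk scores (0–100) for one stay."""

    patient_id: str
    reference_times: pd.DatetimeIndex
    scores: np.ndarray

    def __post_init__(self):
        if len(self.reference_times) != len(self.scores):
            raise ValueError("times and scores must align")
        if len(self.scores) and not (
            (self.scores >= 0).all() and (self.scores <= 100).all()
        ):
            raise ValueError("risk scores must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "reference_time": self.reference_times,
                "risk_score": self.scores,
            }
        )


@dataclass
class CanEWSModel:
    """A (possibly trained) Can-EWS classifier with its frozen preprocessing."""

    config: ModelConfig
    net: GRUClassifier
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)

    @property
    def is_trained(self) -> bool:
        return self.feature_mean is not None

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if not self.is_trained:
            raise ValueError("model has no standardization parameters; train first")
        if X.shape[-1] != self.config.n_features:
            raise ValueError(
                f"expected {self.config.n_features} features for variant "
                f"{self.config.variant}, got {X.shape[-1]}"
            )
        return (X - self.feature_mean) / self.feature_sd


def build_model(config: ModelConfig) -> CanEWSModel:
    """Construct an untrained model; same seed → identical initial weights."""
    net = GRUClassifier(
        input_dim=config.n_features,
        hidden=config.units_per_layer,
        n_layers=config.n_recurrent_layers,
        dropout=config.dropout_rate,
        seed=config.seed,
    )
    return CanEWSModel(config=config, net=net)


def _as_arrays(windows) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(windows, tuple):
        X, y = windows
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    X, y, _ = stack_windows(list(windows))
    return X, y


def train(
    model: CanEWSModel,
    windows,
    val_windows=None,
) -> CanEWSModel:
    """Fit the model in place on training windows; returns the model.

    ``windows`` is either a list of :class:`FeatureWindow` or an ``(X, y)``
    pair.  Standardization statistics are computed here, on the training
    windows only.  Early stopping monitors validation loss when validation
    windows are supplied, otherwise training loss; the best parameters are
    restored at the end.
    """
    cfg = model.config
    X, y = _as_arrays(windows)
    if len(X) == 0:
        raise ValueError("no training windows")
    if X.shape[2] != cfg.n_features:
        raise ValueError(
            f"windows have {X.shape[2]} features but variant {cfg.variant} "
            f"expects {cfg.n_features}"
        )
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"training set contains a single class ({classes.tolist()})")

    mean = X.reshape(-1, X.shape[2]).mean(axis=0)
    sd = X.reshape(-1, X.shape[2]).std(axis=0)
    sd[sd < 1e-8] = 1.0  # constant channel: leave centred at zero
    model.feature_mean, model.feature_sd = mean, sd
    Xs = (X - mean) / sd

    weights = None
    if cfg.class_weight == "balanced":
        per_class = len(y) / (2.0 * np.bincount(y, minlength=2))
        weights = per_class[y]

    val = None
    if val_windows is not None:
        Xv, yv = _as_arrays(val_windows)
        val = (model.standardize(Xv), yv)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.net.params, lr=cfg.learning_rate)
    n = len(Xs)
    best_loss, best_params, since_best = np.inf, None, 0
    model.history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            bw = weights[idx] if weights is not None else None
            probs, cache = model.net.forward(Xs[idx], training=True, rng=rng)
            loss = cross_entropy(probs, y[idx], bw)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "check inputs and learning rate"
                )
            grads = model.net.backward(cache, y[idx], bw)
            opt.step(model.net.params, grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        record = {"epoch": epoch, "train_loss": epoch_loss}
        if val is not None:
            pv = model.net.predict_proba(val[0])
            probs2 = np.column_stack([1 - pv, pv])
            record["val_loss"] = cross_entropy(probs2, val[1])
        model.history.append(record)
        monitored = record.get("val_loss", epoch_loss)
        if monitored < best_loss - 1e-6:
            best_loss = monitored
            best_params = {k: v.copy() for k, v in model.net.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_params is not None:
        model.net.params = best_params
    return model


def predict_risk(model: CanEWSModel, windows) -> np.ndarray:
    """Risk score in [0, 100] per window: softmax event probability × 100."""
    if not model.is_trained:
        raise ValueError("model is not trained")
    if isinstance(windows, np.ndarray):
        X = windows
    elif isinstance(windows, tuple):
        X = np.asarray(windows[0], dtype=float)
    else:
        X, _, _ = stack_windows(list(windows))
    return 100.0 * model.net.predict_proba(model.standardize(X))


def score_stay(
    model: CanEWSModel,
    stay: PatientStay,
    ranges: CleaningRanges | None = None,
    spec: EventWindowSpec | None = None,
) -> RiskSeries:
    """Run the full preprocessing chain and score every eligible hour."""
    grid = resample_hourly(stay, ranges)
    if model.config.variant == "V2":
        grid = compute_deltas(grid)
    windows = build_feature_windows(
        grid,
        stay.outcome,
        lookback=model.config.lookback,
        variant=model.config.variant,
        spec=spec,
    )
    if not windows:
        warnings.warn(
            f"{stay.patient_id}: stay shorter than lookback "
            f"({model.config.lookback} h); no scores emitted",
            stacklevel=2,
        )
        return RiskSeries(stay.patient_id, pd.DatetimeIndex([]), np.array([]))
    X, _, index = stack_windows(windows)
    scores = predict_risk(model, X)
    return RiskSeries(
        stay.patient_id, pd.DatetimeIndex(index["reference_time"]), scores
    )


def save_model(model: CanEWSModel, path) -> None:
    """Serialize weights, config, and standardization parameters to one file."""
    if not model.is_trained:
        raise ValueError("refusing to save an untrained model")
    payload = {f"param::{k}": v for k, v in model.net.params.items()}
    payload["feature_mean"] = model.feature_mean
    payload["feature_sd"] = model.feature_sd
    payload["meta"] = np.frombuffer(
        json.dumps(
            {
                "format_version": _FORMAT_VERSION,
                "config": asdict(model.config),
                "history": model.history,
            }
        ).encode(),
        dtype=np.uint8,
    )
    np.savez_compressed(path, **payload)


def load_model(path, expected_variant: str | None = None) -> CanEWSModel:
    """Load a model saved by :func:`save_model`; predictions round-trip."""
    with np.load(path) as archive:
        if "meta" not in archive:
            raise ValueError("not a Can-EWS model file (missing metadata block)")
        meta = json.loads(archive["meta"].tobytes().decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta.get('format_version')!r}"
            )
        if "feature_mean" not in archive or "feature_sd" not in archive:
            raise ValueError("model file lacks standardization parameters")
        config = ModelConfig(**meta["config"])
        if expected_variant is not None and config.variant != expected_variant:
            raise ValueError(
                f"model variant is {config.variant}, expected {expected_variant}"
            )
        model = build_model(config)
        model.net.params = {
            k.removeprefix("param::"): archive[k]
            for k in archive.files
            if k.startswith("param::")
        }
        model.feature_mean = archive["feature_mean"]
        model.feature_sd = archive["feature_sd"]
        model.history = meta["history"]
    return model
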