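"""Per-(SS class, angle) fully-connected regressors with a periodic-MAE loss.

Each of the twelve (3 SS classes x 4 angle types) regressors is a
fully-connected network with three sigmoid hidden layers of 150 units and a
single linear output that predicts the angle in degrees directly.  Training
uses plain SGD with momentum 0.9 from a scaled-uniform ("glorot") init; the
learning rate starts at 0.01 and is halved whenever the monitored loss fails
to improve for three consecutive epochs, stopping once it would fall below
1e-15.  The loss is the mean periodic absolute error

    AE(P, A) = min(D, |360 - D|),  D = |P - A|,

averaged over residues whose target angle is defined (chain termini are
excluded).  Training is fully deterministic given the schedule seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import (
    Ahiw,
    FeatureMatrix,
    NormalizationStats,
    apply_normalization,
    build_feature_matrix,
    fit_normalization,
    ProteinRecord,
)
from .geometry import ANGLE_NAMES, AngleTable, wrap_angle
from .ss_router import SS3_CLASSES, map_ss8_to_ss3

__all__ = [
    "DEFAULT_SETTINGS",
    "FcnnConfig",
    "TrainingSchedule",
    "Fcnn",
    "ModelBundle",
    "EmptyClassError",
    "periodic_mae_loss",
    "train_model",
    "train_bundle",
    "predict_angles",
    "train_pooled_models",
    "predict_angles_pooled",
    "class_angle_rows",
]

#: best AHIW setting per (SS3 class, angle type)
DEFAULT_SETTINGS: dict[tuple[str, str], str] = {
    ("helix", "phi"): "YYR9", ("helix", "psi"): "YYR9",
    ("helix", "theta"): "YYR9", ("helix", "tau"): "YYR9",
    ("sheet", "phi"): "YYR9", ("sheet", "psi"): "YYZ9",
    ("sheet", "theta"): "YYR9", ("sheet", "tau"): "YYR9",
    ("coil", "phi"): "YYR5", ("coil", "psi"): "YYR9",
    ("coil", "theta"): "YYR5", ("coil", "tau"): "YYR9",
}


class EmptyClassError(ValueError):
    """An SS class has no training residues, so its model cannot be trained."""


@dataclass
class FcnnConfig:
    """Network shape: hidden sigmoid layers and one linear output unit."""

    hidden_layers: tuple[int, ...] = (150, 150, 150)


@dataclass
class TrainingSchedule:
    """SGD-with-momentum schedule with patience-based learning-rate halving."""

    lr_initial: float = 0.01
    momentum: float = 0.9
    lr_factor: float = 0.5
    patience: int = 3
    lr_floor: float = 1e-15
    batch_size: int = 16
    max_epochs: int = 300
    seed: int = 0
    monitor: str = "val"      # "val" | "train": which loss drives lr halving
    restore_best: bool = True


def periodic_mae_loss(predicted, actual, defined=None) -> float:
    """Mean of min(D, |360-D|), D = |P-A|, over entries whose target is defined."""
    p = np.asarray(predicted, float).ravel()
    a = np.asarray(actual, float).ravel()
    if p.shape != a.shape:
        raise ValueError("predicted and actual must have equal lengths")
    mask = np.isfinite(a) & np.isfinite(p)
    if defined is not None:
        mask &= np.asarray(defined, bool).ravel()
    if not mask.any():
        raise ValueError("no defined entries to average the loss over")
    d = np.mod(np.abs(p[mask] - a[mask]), 360.0)
    ae = np.minimum(d, np.abs(360.0 - d))
    return float(ae.mean())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Fcnn:
    """Feed-forward regressor: sigmoid hidden layers, one linear output unit.

    Weights are float32; ``predict`` returns float64 degrees (unwrapped).
    """

    def __init__(self, input_width: int, hidden_layers=(150, 150, 150), rng=None):
        self.input_width = int(input_width)
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        sizes = [self.input_width, *self.hidden_layers, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        rng = rng if rng is not None else np.random.default_rng()
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            W = rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)
            self.weights.append(W)
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _sigmoid(a @ W + b)
            acts.append(a)
        acts.append(a @ self.weights[-1] + self.biases[-1])
        return acts

    def predict(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_width:
            raise ValueError(
                f"input width mismatch: got {X.shape}, model expects (*, {self.input_width})"
            )
        return self._forward(X)[-1][:, 0].astype(np.float64)

    def state(self) -> dict[str, np.ndarray]:
        d = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            d[f"W{i}"] = W
            d[f"b{i}"] = b
        return d

    @classmethod
    def from_state(cls, state: dict[str, np.ndarray]) -> "Fcnn":
        n_layers = sum(1 for k in state if k.startswith("W"))
        weights = [np.asarray(state[f"W{i}"], np.float32) for i in range(n_layers)]
        biases = [np.asarray(state[f"b{i}"], np.float32) for i in range(n_layers)]
        m = cls.__new__(cls)
        m.input_width = weights[0].shape[0]
        m.hidden_layers = tuple(W.shape[1] for W in weights[:-1])
        m.weights = weights
        m.biases = biases
        return m


def train_model(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: FcnnConfig | None = None,
    sched: TrainingSchedule | None = None,
) -> tuple[Fcnn, dict]:
    """Train one regressor; returns (model, history).

    ``train`` and ``val`` are (X, y) pairs with y in degrees; rows whose
    target is NaN are dropped.  The history records per-epoch train/val loss
    and the learning rate; the same seed reproduces it bit-identically.
    """
    config = config or FcnnConfig()
    sched = sched or TrainingSchedule()
    Xtr, ytr = train
    Xval, yval = val
    keep = np.isfinite(np.asarray(ytr, float))
    Xtr = np.ascontiguousarray(np.asarray(Xtr, float)[keep], dtype=np.float32)
    ytr = np.asarray(ytr, float)[keep].astype(np.float32)
    keepv = np.isfinite(np.asarray(yval, float))
    Xval = np.ascontiguousarray(np.asarray(Xval, float)[keepv], dtype=np.float32)
    yval = np.asarray(yval, float)[keepv]
    if Xtr.shape[0] == 0:
        raise EmptyClassError("training subset is empty")
    if Xval.shape[0] == 0:
        raise EmptyClassError("validation subset is empty")

    rng = np.random.default_rng(np.random.SeedSequence(sched.seed))
    model = Fcnn(Xtr.shape[1], config.hidden_layers, rng=rng)
    velocity_W = [np.zeros_like(W) for W in model.weights]
    velocity_b = [np.zeros_like(b) for b in model.biases]

    n = Xtr.shape[0]
    lr = sched.lr_initial
    best = np.inf
    best_state = {k: v.copy() for k, v in model.state().items()}
    prev_monitored = np.inf
    stagnant = 0
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    halt_reason = "max_epochs"
    mom = np.float32(sched.momentum)

    for epoch in range(sched.max_epochs):
        perm = rng.permutation(n)
        for lo in range(0, n, sched.batch_size):
            idx = perm[lo : lo + sched.batch_size]
            Xb = Xtr[idx]
            yb = ytr[idx]
            acts = model._forward(Xb)
            pred = acts[-1][:, 0]
            # subgradient of mean periodic AE: sign of the wrapped residual
            resid = wrap_angle(pred.astype(np.float64) - yb.astype(np.float64))
            delta = (np.sign(resid) / len(yb)).astype(np.float32)[:, None]
            lr32 = np.float32(lr)
            for layer in range(len(model.weights) - 1, -1, -1):
                a_prev = acts[layer]
                gW = a_prev.T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    a_cur = acts[layer]
                    delta = (delta @ model.weights[layer].T) * (a_cur * (1.0 - a_cur))
                velocity_W[layer] = mom * velocity_W[layer] - lr32 * gW
                velocity_b[layer] = mom * velocity_b[layer] - lr32 * gb
                model.weights[layer] += velocity_W[layer]
                model.biases[layer] += velocity_b[layer]
        train_loss = periodic_mae_loss(model.predict(Xtr), ytr.astype(np.float64))
        val_loss = periodic_mae_loss(model.predict(Xval), yval)
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        monitored = val_loss if sched.monitor == "val" else train_loss
        if monitored < best:
            best = monitored
            best_state = {k: v.copy() for k, v in model.state().items()}
        # an epoch is stagnant when it fails to improve on its predecessor;
        # "patience" consecutive stagnant epochs halve the learning rate
        if monitored < prev_monitored:
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= sched.patience:
                new_lr = lr * sched.lr_factor
                stagnant = 0
                if new_lr < sched.lr_floor:
                    halt_reason = "lr_floor"
                    break
                lr = new_lr
        prev_monitored = monitored
    history["halt_reason"] = halt_reason
    if sched.restore_best:
        restored = Fcnn.from_state(best_state)
        restored.hidden_layers = model.hidden_layers
        model = restored
    return model, history


def class_angle_rows(
    records: list[ProteinRecord],
    setting: Ahiw,
    angle: str,
    ss3_class: str | None = None,
    matrix: FeatureMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (un-normalized) feature rows and angle targets for one (class, angle).

    Rows are restricted to ``ss3_class`` when given (predicted labels); targets
    keep NaN at undefined positions so the trainer can drop them.
    """
    if matrix is None:
        matrix = build_feature_matrix(records, setting)
    targets = AngleTable.concatenate([r.angles for r in records]).angle(angle)
    if ss3_class is None:
        return matrix.X, targets
    idx = np.flatnonzero(matrix.ss3 == ss3_class)
    return matrix.X[idx], targets[idx]


@dataclass
class ModelBundle:
    """Trained regressors keyed by (SS3 class, angle) with their settings and stats."""

    models: dict[tuple[str, str], Fcnn] = field(default_factory=dict)
    settings: dict[tuple[str, str], Ahiw] = field(default_factory=dict)
    stats: dict[tuple[str, str], NormalizationStats] = field(default_factory=dict)
    histories: dict[tuple[str, str], dict] = field(default_factory=dict)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    call_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "settings": {f"{c}.{a}": s.name for (c, a), s in self.settings.items()},
            "schedule": asdict(self.schedule),
            "stats_mode": {f"{c}.{a}": st.mode for (c, a), st in self.stats.items()},
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for (c, a), m in self.models.items():
            for k, v in m.state().items():
                arrays[f"{c}.{a}.{k}"] = v
        for (c, a), st in self.stats.items():
            arrays[f"{c}.{a}.stats_lo"] = st.lo
            arrays[f"{c}.{a}.stats_hi"] = st.hi
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        data = np.load(directory / "weights.npz")
        bundle = cls(schedule=TrainingSchedule(**meta["schedule"]))
        for key, name in meta["settings"].items():
            c, a = key.split(".")
            bundle.settings[(c, a)] = Ahiw.parse(name)
            state = {
                k.split(".", 2)[2]: data[k]
                for k in data.files
                if k.startswith(f"{c}.{a}.") and not k.split(".", 2)[2].startswith("stats")
            }
            bundle.models[(c, a)] = Fcnn.from_state(state)
            bundle.stats[(c, a)] = NormalizationStats(
                meta["stats_mode"][key],
                data[f"{c}.{a}.stats_lo"],
                data[f"{c}.{a}.stats_hi"],
                fitted_on=f"{c}",
            )
        return bundle


def train_bundle(
    train_records: list[ProteinRecord],
    val_records: list[ProteinRecord],
    settings: dict[tuple[str, str], str | Ahiw] | None = None,
    sched: TrainingSchedule | None = None,
    config: FcnnConfig | None = None,
    classes: tuple[str, ...] = SS3_CLASSES,
    angles: tuple[str, ...] = ANGLE_NAMES,
) -> ModelBundle:
    """Train one regressor per requested (SS class, angle) pair.

    Normalization statistics are fitted on each class's own training residues
    under that model's setting.  Raises EmptyClassError naming the class if a
    requested class has no training rows.
    """
    sched = sched or TrainingSchedule()
    raw = dict(settings or DEFAULT_SETTINGS)
    parsed = {
        k: (v if isinstance(v, Ahiw) else Ahiw.parse(v)) for k, v in raw.items()
    }
    bundle = ModelBundle(schedule=sched)
    # one windowed matrix per distinct setting, shared by all (class, angle) pairs
    cache_tr: dict[str, FeatureMatrix] = {}
    cache_va: dict[str, FeatureMatrix] = {}
    for ci, cls_name in enumerate(classes):
        for ai, angle in enumerate(angles):
            setting = parsed[(cls_name, angle)]
            if setting.name not in cache_tr:
                cache_tr[setting.name] = build_feature_matrix(train_records, setting)
                cache_va[setting.name] = build_feature_matrix(val_records, setting)
            Xtr, ytr = class_angle_rows(
                train_records, setting, angle, cls_name, matrix=cache_tr[setting.name]
            )
            Xva, yva = class_angle_rows(
                val_records, setting, angle, cls_name, matrix=cache_va[setting.name]
            )
            if Xtr.shape[0] == 0:
                raise EmptyClassError(f"no training residues for class {cls_name!r}")
            stats = fit_normalization(Xtr, setting.encoding, fitted_on=cls_name)
            Xtr_n = apply_normalization(Xtr, stats)
            Xva_n = apply_normalization(Xva, stats)
            model_seed = int(
                np.random.SeedSequence([sched.seed, ci, ai]).generate_state(1)[0] % (2**31)
            )
            model_sched = TrainingSchedule(**{**asdict(sched), "seed": model_seed})
            try:
                model, hist = train_model((Xtr_n, ytr), (Xva_n, yva), config, model_sched)
            except EmptyClassError as e:
                raise EmptyClassError(f"class {cls_name!r}, angle {angle!r}: {e}") from e
            key = (cls_name, angle)
            bundle.models[key] = model
            bundle.settings[key] = setting
            bundle.stats[key] = stats
            bundle.histories[key] = hist
            bundle.call_counts[key] = 0
    return bundle


def train_pooled_models(
    train_records: list[ProteinRecord],
    val_records: list[ProteinRecord],
    setting: str | Ahiw = "YYR9",
    sched: TrainingSchedule | None = None,
    config: FcnnConfig | None = None,
    angles: tuple[str, ...] = ANGLE_NAMES,
) -> dict[str, tuple[Fcnn, NormalizationStats]]:
    """Class-agnostic baseline: one regressor per angle over all residues.

    Same capacity, loss and schedule as the routed models; used to measure the
    benefit of secondary-structure-specific specialization.
    """
    sched = sched or TrainingSchedule()
    setting = setting if isinstance(setting, Ahiw) else Ahiw.parse(setting)
    mtr = build_feature_matrix(train_records, setting)
    mva = build_feature_matrix(val_records, setting)
    out = {}
    for ai, angle in enumerate(angles):
        Xtr, ytr = class_angle_rows(train_records, setting, angle, matrix=mtr)
        Xva, yva = class_angle_rows(val_records, setting, angle, matrix=mva)
        stats = fit_normalization(Xtr, setting.encoding, fitted_on="pooled")
        seed = int(np.random.SeedSequence([sched.seed, 99, ai]).generate_state(1)[0] % (2**31))
        model_sched = TrainingSchedule(**{**asdict(sched), "seed": seed})
        model, _ = train_model(
            (apply_normalization(Xtr, stats), ytr),
            (apply_normalization(Xva, stats), yva),
            config,
            model_sched,
        )
        out[angle] = (model, stats)
    return out


def predict_angles_pooled(
    pooled: dict[str, tuple[Fcnn, NormalizationStats]],
    record: ProteinRecord,
    setting: str | Ahiw = "YYR9",
) -> AngleTable:
    """Predictions of the class-agnostic baseline for one protein."""
    setting = setting if isinstance(setting, Ahiw) else Ahiw.parse(setting)
    m = build_feature_matrix([record], setting)
    L = len(record)
    out = {}
    bounds = {
        "phi": np.arange(L) >= 1,
        "psi": np.arange(L) <= L - 2,
        "theta": (np.arange(L) >= 1) & (np.arange(L) <= L - 2),
        "tau": (np.arange(L) >= 1) & (np.arange(L) <= L - 3),
    }
    for angle, (model, stats) in pooled.items():
        pred = wrap_angle(model.predict(apply_normalization(m.X, stats)))
        if angle == "theta":
            pred = np.clip(pred, 0.0, 180.0)
        pred = np.where(bounds[angle], pred, np.nan)
        out[angle] = pred
    return AngleTable(
        out["phi"], out["psi"], out["theta"], out["tau"],
        sequence=record.sequence, protein_id=record.protein_id,
    )


def predict_angles(bundle: ModelBundle, record: ProteinRecord) -> AngleTable:
    """Predict all four angles for one protein, routing each residue by its
    predicted SS3 class.

    Raw model outputs are wrapped to (-180, 180]; theta is additionally clamped
    to [0, 180].  Termini where an angle has no defining atom quadruple are NaN.
    """
    L = len(record)
    ss3 = np.array([map_ss8_to_ss3(s) for s in record.ss8_pred])
    out = {a: np.full(L, np.nan) for a in ANGLE_NAMES}
    defined = {
        "phi": np.arange(L) >= 1,
        "psi": np.arange(L) <= L - 2,
        "theta": (np.arange(L) >= 1) & (np.arange(L) <= L - 2),
        "tau": (np.arange(L) >= 1) & (np.arange(L) <= L - 3),
    }
    matrices: dict[str, FeatureMatrix] = {}
    for (cls_name, angle), model in bundle.models.items():
        setting = bundle.settings[(cls_name, angle)]
        if setting.name not in matrices:
            matrices[setting.name] = build_feature_matrix([record], setting)
        m = matrices[setting.name]
        rows = np.flatnonzero((ss3 == cls_name) & defined[angle])
        if len(rows) == 0:
            continue
        X = apply_normalization(m.X[rows], bundle.stats[(cls_name, angle)])
        try:
            pred = model.predict(X)
        except ValueError as e:
            raise ValueError(f"model ({cls_name}, {angle}): {e}") from e
        pred = wrap_angle(pred)
        if angle == "theta":
            pred = np.clip(pred, 0.0, 180.0)
        out[angle][rows] = pred
        bundle.call_counts[(cls_name, angle)] = (
            bundle.call_counts.get((cls_name, angle), 0) + len(rows)
        )
    return AngleTable(
        out["phi"], out["psi"], out["theta"], out["tau"],
        sequence=record.sequence, protein_id=record.protein_id,
    )
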