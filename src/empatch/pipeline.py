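"""Preprocessing, cross-validation and model training for the biomarker data.

The learning problem: each weekly on-diet measurement session yields a
6-channel × T raw-signal window from the sensor twin; the model jointly
predicts the diet group (CON / HFFD / HFFSD, softmax head) and the
continuous health degree in [0, 1] (regression head). Preprocessing is
Z-score standardisation fitted on each fold's training split only, and
model selection uses stratified fivefold cross-validation that balances
class counts and, within class, the degree distribution (degree-sorted
round-robin dealing). Folds are grouped by animal by default so that no rat
contributes to both a training and a validation split.

Classical baselines (KNN, SVM, decision tree, random forest, XGBoost) run on
per-channel steady-state features through scikit-learn / xgboost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sensors
from .cohort import ANALYTE_COLUMNS, CHRONIC_GROUPS
from .nn import MTLConfig, MTLNet, train_network

CLASS_TO_INDEX = {g: i for i, g in enumerate(CHRONIC_GROUPS)}


# ---------------------------------------------------------------------------
# feature windows

@dataclass
class WindowSet:
    """Standardisable model inputs: raw 6×T windows plus labels."""

    x: np.ndarray  # (N, 6, T) raw sensor signals
    y_class: np.ndarray  # (N,) int in {0,1,2}
    y_degree: np.ndarray  # (N,) float in [0,1]
    subject_ids: np.ndarray  # (N,) str
    channels: tuple = ANALYTE_COLUMNS

    def __len__(self) -> int:
        return self.x.shape[0]


def build_windows(
    panels: pd.DataFrame,
    params: dict | None = None,
    T: int = 60,
    sample_rate_hz: float = 1.0,
    seed: int = 0,
    include_baseline_week: bool = False,
) -> WindowSet:
    """Render panel concentrations into raw sensor windows.

    Each panel becomes one 6-channel × T window of forward-model signals
    (steady state + noise + slow drift; the 5-min settling period is assumed
    already elapsed, so no transient). The pre-diet week-0 visit is excluded
    by default: before the intervention the groups are exchangeable by
    construction, so it carries no class signal.
    """
    params = params or sensors.device_channel_params()
    df = panels
    if not include_baseline_week and "week" in df.columns:
        df = df[(df["week"].isna()) | (df["week"] > 0)]
    df = df.reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError("no panels left to window")
    rng = np.random.default_rng(seed)
    t = np.arange(T) / sample_rate_hz
    x = np.empty((n, 6, T), dtype=np.float32)
    for ci, col in enumerate(ANALYTE_COLUMNS):
        ch = col.split("_")[0] if col != "ph" else "ph"
        p = params[ch]
        conc = df[col].to_numpy(dtype=float)
        lo, hi = p.linear_range
        conc_eff = np.clip(conc, lo, hi)  # sensor saturation
        if p.modality == sensors.AMPEROMETRIC:
            base = p.intercept + p.slope * conc_eff
        elif p.modality == sensors.POTENTIOMETRIC:
            base = p.intercept + p.slope * np.log10(conc_eff / p.ref_conc)
        else:
            base = p.intercept + p.ph_sign * p.slope * conc_eff
        sig = base[:, None] + p.drift_rate * t[None, :] / 60.0
        if p.noise_sd > 0:
            sig = sig + rng.normal(0.0, p.noise_sd, size=(n, T))
        x[:, ci, :] = sig
    groups = df["group"].astype(str)
    y_class = np.array([CLASS_TO_INDEX[g] for g in groups], dtype=np.int64)
    subjects = df["sample_id"].str.rsplit("-", n=1).str[0].to_numpy(dtype=object)
    return WindowSet(
        x=x, y_class=y_class,
        y_degree=df["degree"].to_numpy(dtype=float),
        subject_ids=subjects,
    )


def steady_features(ws: WindowSet) -> np.ndarray:
    """Per-sample 6-vector of per-channel window means (baseline parity mode)."""
    return ws.x.mean(axis=2).astype(np.float64)


# ---------------------------------------------------------------------------
# Z-score standardisation

def zscore_fit_transform(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Standardise columns to mean 0, SD 1 (ddof=0) using train statistics.

    ``apply_to`` is transformed with the *training* mean/SD only, never its
    own. Raises on a constant training feature, naming its index.
    """
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant feature(s) in training data: {const.tolist()}")
    out_train = (train - mean) / sd
    out_apply = None
    if apply_to is not None:
        out_apply = (np.asarray(apply_to, dtype=float) - mean) / sd
    return out_train, out_apply, mean, sd


def channel_stats(x_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/SD over all training samples and timepoints (float64)."""
    mean = x_train.mean(axis=(0, 2), dtype=np.float64)
    sd = x_train.astype(np.float64).std(axis=(0, 2), ddof=0)
    if np.any(sd == 0):
        bad = [ANALYTE_COLUMNS[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant channel(s) in training data: {bad}")
    return mean, sd


def standardize_windows(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    xs = (x.astype(np.float64) - mean[None, :, None]) / sd[None, :, None]
    return xs.astype(np.float32)


# ---------------------------------------------------------------------------
# stratified fivefold assignment

@dataclass
class FoldAssignment:
    k: int
    assignments: np.ndarray  # (N,) fold index per sample
    stratification_report: pd.DataFrame

    def train_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def val_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


def make_stratified_folds(
    class_labels: np.ndarray,
    degree_labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    subject_ids: np.ndarray | None = None,
) -> FoldAssignment:
    """Class-stratified folds that also balance the degree distribution.

    Within each class, samples (or animals, when ``subject_ids`` is given —
    the leakage-safe default used by the pipeline) are ordered by degree,
    ties broken by a seeded shuffle, and dealt round-robin to the k folds
    from a seeded starting offset. This keeps per-fold class counts within
    one unit of balance and spreads every degree quantile across folds.
    """
    class_labels = np.asarray(class_labels)
    degree_labels = np.asarray(degree_labels, dtype=float)
    n = class_labels.size
    rng = np.random.default_rng(seed)
    assignments = np.full(n, -1, dtype=int)

    if subject_ids is not None:
        subject_ids = np.asarray(subject_ids, dtype=object)
        units: dict = {}
        for i in range(n):
            units.setdefault(subject_ids[i], []).append(i)
        unit_keys = list(units)
        unit_class = {u: class_labels[units[u][0]] for u in unit_keys}
        for u in unit_keys:
            if not all(class_labels[i] == unit_class[u] for i in units[u]):
                raise ValueError(f"subject {u} spans multiple classes")
        unit_degree = {u: float(np.mean(degree_labels[units[u]])) for u in unit_keys}
        deal_units, deal_class, deal_degree = unit_keys, unit_class, unit_degree
    else:
        deal_units = list(range(n))
        deal_class = {i: class_labels[i] for i in deal_units}
        deal_degree = {i: float(degree_labels[i]) for i in deal_units}
        units = {i: [i] for i in deal_units}

    for cls in np.unique(class_labels):
        members = [u for u in deal_units if deal_class[u] == cls]
        if len(members) < k:
            raise ValueError(
                f"class {cls!r} has {len(members)} unit(s), fewer than k={k}"
            )
        members = [members[j] for j in rng.permutation(len(members))]  # tie break
        members.sort(key=lambda u: deal_degree[u])  # stable: keeps shuffle for ties
        offset = int(rng.integers(k))
        for pos, u in enumerate(members):
            assignments[units[u]] = (pos + offset) % k

    report_rows = []
    for f in range(k):
        mask = assignments == f
        row = {"fold": f, "n": int(mask.sum())}
        for cls in np.unique(class_labels):
            row[f"class_{cls}"] = int(np.sum(mask & (class_labels == cls)))
        qs = np.quantile(degree_labels, [0.25, 0.5, 0.75])
        for qi, q in enumerate(qs):
            row[f"degree_le_q{qi + 1}"] = float(np.mean(degree_labels[mask] <= q))
        report_rows.append(row)
    report = pd.DataFrame(report_rows)

    counts = {
        cls: np.bincount(assignments[class_labels == cls], minlength=k)
        for cls in np.unique(class_labels)
    }
    for cls, cnt in counts.items():
        if subject_ids is None and cnt.max() - cnt.min() > 1:
            raise AssertionError(f"fold imbalance for class {cls!r}: {cnt}")
    return FoldAssignment(k=k, assignments=assignments, stratification_report=report)


# ---------------------------------------------------------------------------
# multi-task training

@dataclass
class TrainedMTL:
    """A trained fold model with its train-split preprocessing statistics."""

    net: MTLNet
    config: MTLConfig
    fold: int
    channel_mean: np.ndarray
    channel_sd: np.ndarray
    degree_mean: float
    degree_sd: float
    stats_provenance: str
    history: pd.DataFrame = field(repr=False, default=None)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **{f"w{i}": w for i, w in enumerate(self.net.get_weights())},
                 channel_mean=self.channel_mean, channel_sd=self.channel_sd,
                 degree_stats=np.array([self.degree_mean, self.degree_sd]))
        sidecar = {
            "fold": self.fold,
            "stats_provenance": self.stats_provenance,
            "config": {
                "conv_channels": list(self.config.conv_channels),
                "cls_hidden": list(self.config.cls_hidden),
                "reg_hidden": list(self.config.reg_hidden),
                "kernel": self.config.kernel,
                "n_input_channels": self.config.n_input_channels,
                "n_classes": self.config.n_classes,
                "loss_weight_lambda": self.config.loss_weight_lambda,
                "lr": self.config.lr,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "seed": self.config.seed,
                "dtype": self.config.dtype,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedMTL":
        path = Path(path)
        side = json.loads(path.with_suffix(".json").read_text())
        config = MTLConfig(**{**side["config"],
                              "conv_channels": tuple(side["config"]["conv_channels"]),
                              "cls_hidden": tuple(side["config"]["cls_hidden"]),
                              "reg_hidden": tuple(side["config"]["reg_hidden"])})
        net = MTLNet(config)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        weights = [data[f"w{i}"] for i in range(len(net.get_weights()))]
        net.set_weights(weights)
        net.trained = True
        dm, ds = data["degree_stats"]
        return cls(
            net=net, config=config, fold=side["fold"],
            channel_mean=data["channel_mean"], channel_sd=data["channel_sd"],
            degree_mean=float(dm), degree_sd=float(ds),
            stats_provenance=side["stats_provenance"],
        )


def train_mtl(
    ws: WindowSet,
    folds: FoldAssignment,
    config: MTLConfig | None = None,
) -> tuple[list[TrainedMTL], pd.DataFrame, pd.DataFrame]:
    """Fivefold cross-validated joint training.

    Returns (models, per-fold metrics with a fold-mean row, per-epoch
    history). Standardisation statistics — per-channel signal mean/SD and
    the degree target's mean/SD — are computed on each fold's training
    split only and stored on the fold's model, tagged with their
    provenance, so inference always reuses train-split statistics.
    """
    config = config or MTLConfig()
    models: list[TrainedMTL] = []
    metric_rows = []
    history_rows = []
    for f in range(folds.k):
        tr, va = folds.train_idx(f), folds.val_idx(f)
        mean, sd = channel_stats(ws.x[tr])
        x_tr = standardize_windows(ws.x[tr], mean, sd)
        x_va = standardize_windows(ws.x[va], mean, sd)
        dmean = float(ws.y_degree[tr].mean())
        dsd = float(ws.y_degree[tr].std(ddof=0))
        if dsd == 0:
            raise ValueError("degree target constant on the training split")
        yd_tr = (ws.y_degree[tr] - dmean) / dsd
        yd_va = (ws.y_degree[va] - dmean) / dsd

        fold_cfg = MTLConfig(**{**config.__dict__, "seed": config.seed + f,
                                "extra": dict(config.extra)})
        net = MTLNet(fold_cfg)
        hist = train_network(
            net, x_tr, ws.y_class[tr], yd_tr, fold_cfg,
            x_val=x_va, y_class_val=ws.y_class[va], y_degree_val=yd_va,
        )
        model = TrainedMTL(
            net=net, config=fold_cfg, fold=f, channel_mean=mean, channel_sd=sd,
            degree_mean=dmean, degree_sd=dsd,
            stats_provenance=f"train-split of fold {f}",
            history=pd.DataFrame(hist).assign(fold=f),
        )
        models.append(model)
        history_rows.append(model.history)

        proba, degree = predict(model, ws.x[va])
        acc = float(np.mean(proba.argmax(axis=1) == ws.y_class[va]))
        resid = degree - ws.y_degree[va]
        var = float(np.var(ws.y_degree[va]))
        r2 = float(1.0 - np.mean(resid**2) / var) if var > 0 else np.nan
        metric_rows.append({"fold": f, "val_accuracy": acc, "val_r2": r2,
                            "n_train": tr.size, "n_val": va.size})

    metrics = pd.DataFrame(metric_rows)
    mean_row = {"fold": "mean",
                "val_accuracy": metrics["val_accuracy"].mean(),
                "val_r2": metrics["val_r2"].mean(),
                "n_train": metrics["n_train"].mean(),
                "n_val": metrics["n_val"].mean()}
    metrics = pd.concat([metrics, pd.DataFrame([mean_row])], ignore_index=True)
    return models, metrics, pd.concat(history_rows, ignore_index=True)


def predict(model: TrainedMTL, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and degree estimates for raw (unstandardised) windows.

    Applies the model's stored train-split statistics; degree estimates are
    mapped back to the original scale and clipped to [0, 1] at report time.
    """
    x = np.asarray(x)
    if x.ndim != 3 or x.shape[1] != model.config.n_input_channels:
        raise ValueError(
            f"expected (N, {model.config.n_input_channels}, T) windows, got {x.shape}"
        )
    xs = standardize_windows(x, model.channel_mean, model.channel_sd)
    logits, reg = model.net.forward(xs)
    from .nn import softmax

    proba = softmax(logits.astype(np.float64))
    degree = np.clip(reg.astype(np.float64) * model.degree_sd + model.degree_mean,
                     0.0, 1.0)
    return proba, degree


def predict_logits(model: TrainedMTL, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw class logits and unclipped degree estimates (attribution surface)."""
    xs = standardize_windows(np.asarray(x), model.channel_mean, model.channel_sd)
    logits, reg = model.net.forward(xs)
    return (logits.astype(np.float64),
            reg.astype(np.float64) * model.degree_sd + model.degree_mean)


def embed(model: TrainedMTL, x: np.ndarray) -> np.ndarray:
    """Penultimate shared feature vectors for raw windows."""
    if not model.net.trained:
        raise RuntimeError("model is untrained")
    xs = standardize_windows(np.asarray(x), model.channel_mean, model.channel_sd)
    return model.net.embed(xs).astype(np.float64)


# ---------------------------------------------------------------------------
# classical baselines

def train_baselines(
    features: np.ndarray,
    y_class: np.ndarray,
    y_degree: np.ndarray,
    folds: FoldAssignment,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold-mean accuracy and R² for the five classical reference models.

    A comparison harness over scikit-learn / xgboost estimators on flattened
    per-sample feature vectors, using the same folds as the network.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
    from sklearn.svm import SVC, SVR
    from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
    from xgboost import XGBClassifier, XGBRegressor

    zoo = {
        "KNN": (KNeighborsClassifier(n_neighbors=5),
                KNeighborsRegressor(n_neighbors=5)),
        "SVM": (SVC(kernel="rbf", random_state=seed), SVR(kernel="rbf")),
        "DT": (DecisionTreeClassifier(random_state=seed),
               DecisionTreeRegressor(random_state=seed)),
        "RF": (RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
               RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)),
        "XGBoost": (XGBClassifier(random_state=seed, n_jobs=1, verbosity=0),
                    XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)),
    }
    rows = []
    for name, (clf, reg) in zoo.items():
        accs, r2s = [], []
        for f in range(folds.k):
            tr, va = folds.train_idx(f), folds.val_idx(f)
            try:
                x_tr, x_va, _, _ = zscore_fit_transform(features[tr], features[va])
                clf.fit(x_tr, y_class[tr])
                accs.append(float(np.mean(clf.predict(x_va) == y_class[va])))
                reg.fit(x_tr, y_degree[tr])
                pred = reg.predict(x_va)
                var = np.var(y_degree[va])
                r2s.append(float(1 - np.mean((pred - y_degree[va]) ** 2) / var))
            except Exception as exc:  # surface which model failed
                raise RuntimeError(f"baseline {name} failed on fold {f}: {exc}") from exc
        rows.append({"model": name,
                     "accuracy": float(np.mean(accs)),
                     "r2": float(np.mean(r2s))})
    return pd.DataFrame(rows)
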