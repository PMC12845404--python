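"""Training protocol, regression metrics and bootstrap confidence intervals.

The training loop follows the study protocol: Adam on mean-squared error,
learning rate 1e-3, batch size 32, at most 500 epochs, reduce-on-plateau
scheduling and early stopping with patience 20, always returning the
parameters of the best-validation epoch.

Metrics are MAE, RMSE, MAPE (percent; zero labels excluded and counted) and
R^2; uncertainty is a percentile bootstrap over prediction-label pairs,
reported as mean +/- half the 2.5--97.5 percentile spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .apyieldnet import APYieldNet, APYieldNetConfig, DataScaler


@dataclass
class TrainConfig:
    max_epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.05  # L2 coupling into Adam; small-sample regime
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    early_stopping_patience: int = 20
    seed: int = 0

    def validate(self):
        if self.early_stopping_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class TrainingError(RuntimeError):
    pass


def train(model_cfg: APYieldNetConfig, train_cfg: TrainConfig,
          train_records, val_records) -> tuple[APYieldNet, TrainHistory]:
    """Fit APYieldNet, returning the best-validation-epoch parameters."""
    if not train_records or not val_records:
        raise ValueError("train and validation sets must be non-empty")
    train_cfg.validate()
    model = APYieldNet(model_cfg)
    model.scaler = DataScaler.fit(train_records)
    sc = model.scaler

    tt, tc, ty, ta, tl = model.batch_from_records(train_records)
    vt, vc, vy, va, vl = model.batch_from_records(val_records)
    tz = (tl - sc.y_mean) / sc.y_std
    vz = (vl - sc.y_mean) / sc.y_std

    rng = nn.seeded_rng(train_cfg.seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate,
                  weight_decay=train_cfg.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, factor=train_cfg.scheduler_factor,
                                 patience=train_cfg.scheduler_patience,
                                 min_lr=train_cfg.min_lr)
    hist = TrainHistory()
    best_loss, best_state, bad = np.inf, None, 0
    n = len(train_records)

    for epoch in range(train_cfg.max_epochs):
        model.train()
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(tt[idx], tc[idx], ty[idx], ta[idx])
            loss = nn.mse_loss(pred, tz[idx])
            if not np.isfinite(loss.item()):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(idx)
        model.eval()
        vp = model.forward(vt, vc, vy, va).data
        vloss = float(np.mean((vp - vz) ** 2))
        if not np.isfinite(vloss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        hist.train_loss.append(ep_loss / n)
        hist.val_loss.append(vloss)
        hist.lr.append(opt.lr)
        # plateau detection follows the (smooth) training loss; with the
        # small validation sets typical here a val-monitored scheduler
        # collapses the learning rate on noise long before convergence
        sched.step(ep_loss / n)
        if vloss < best_loss - 1e-12:
            best_loss, bad = vloss, 0
            best_state = model.get_state()
            hist.best_epoch = epoch
        else:
            bad += 1
            if bad >= train_cfg.early_stopping_patience:
                break
    hist.stopped_epoch = len(hist.val_loss) - 1
    if best_state is not None:
        model.set_state(best_state)
    model.eval()
    return model, hist


# ---------------------------------------------------------------------------
# metrics

UNDEFINED = "undefined"  # explicit marker for degenerate R^2


@dataclass
class MetricReport:
    mae: float
    rmse: float
    mape: float | str
    r2: float | str
    mape_excluded: int = 0
    bootstrap: dict | None = None  # per-metric {"mean", "ci_half"}
    n_boot: int = 0

    def as_dict(self) -> dict:
        out = {}
        for name in ("mae", "rmse", "mape", "r2"):
            entry = {"point": getattr(self, name)}
            if self.bootstrap and name in self.bootstrap:
                entry.update(self.bootstrap[name])
            out[name] = entry
        if self.mape_excluded:
            out["mape"]["excluded_zero_labels"] = self.mape_excluded
        return out


def _point_metrics(preds: np.ndarray, labels: np.ndarray):
    err = preds - labels
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    nz = labels != 0
    excluded = int(np.sum(~nz))
    mape = (float(100.0 * np.mean(np.abs(err[nz] / labels[nz])))
            if nz.any() else UNDEFINED)
    sstot = float(np.sum((labels - labels.mean()) ** 2))
    r2 = (1.0 - float(np.sum(err ** 2)) / sstot) if sstot > 0 else UNDEFINED
    return mae, rmse, mape, r2, excluded


def evaluate(preds, labels) -> MetricReport:
    """Point MAE/RMSE/MAPE/R^2 (MAPE in percent, zero labels excluded)."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if preds.shape != labels.shape or preds.size < 2:
        raise ValueError("need equal-length prediction/label vectors, n >= 2")
    mae, rmse, mape, r2, excl = _point_metrics(preds, labels)
    return MetricReport(mae=mae, rmse=rmse, mape=mape, r2=r2,
                        mape_excluded=excl)


def bootstrap_ci(preds, labels, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> MetricReport:
    """Percentile bootstrap over (pred, label) pairs.

    Each replicate resamples n pairs with replacement and recomputes every
    metric; the report carries the replicate mean and half the central
    ``level`` percentile spread.  Replicates with constant labels have no
    R^2 and are skipped for that metric (count logged).
    """
    report = evaluate(preds, labels)
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = preds.size
    rng = np.random.default_rng(seed)
    samples = {"mae": [], "rmse": [], "mape": [], "r2": []}
    r2_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        mae, rmse, mape, r2, _ = _point_metrics(preds[idx], labels[idx])
        samples["mae"].append(mae)
        samples["rmse"].append(rmse)
        if mape != UNDEFINED:
            samples["mape"].append(mape)
        if r2 == UNDEFINED:
            r2_skipped += 1
        else:
            samples["r2"].append(r2)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    boot = {}
    for name, vals in samples.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        qlo, qhi = np.percentile(arr, [lo_q, hi_q])
        boot[name] = {"boot_mean": float(arr.mean()),
                      "ci_half": float((qhi - qlo) / 2)}
    if r2_skipped:
        boot.setdefault("r2", {})["replicates_skipped"] = r2_skipped
    report.bootstrap = boot
    report.n_boot = n_boot
    return report


def mean_baseline_mae(train_labels, test_labels) -> float:
    """MAE of predicting the training-set mean everywhere (sanity floor)."""
    mu = float(np.mean(train_labels))
    return float(np.mean(np.abs(np.asarray(test_labels, dtype=float) - mu)))
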