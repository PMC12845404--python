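"""Workflow orchestration and command-line interface.

``run_pipeline`` executes the full prediction workflow on one configuration:
assemble (or simulate) the county-year dataset, augment the training years,
train the regression network, evaluate with bootstrap confidence intervals
on the held-out year, predict the orchard/sampling-area yields and apply the
proportional correction.  Every artifact lands in the output directory with
a manifest (config hash, seed, package versions) sufficient to re-derive it.

The ``apyield`` console script exposes the individual stages::

    apyield simulate | assemble | augment | train | predict | eval
            | correct | run | blocks-selftest
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import yaml

from . import __version__
from .apyieldnet import APYieldNet, APYieldNetConfig
from .augment import AugmentationConfig, augment_pipeline
from .correction import CorrectionScenario, correct_scenario
from .features import read_dataset, temporal_split, write_dataset
from .synthdata import SyntheticConfig, generate_county_dataset
from .training import TrainConfig, bootstrap_ci, train

log = logging.getLogger("apyield")
logging.basicConfig(stream=sys.stderr,
                    format="%(levelname)s %(name)s: %(message)s")


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "apyield_out"
    test_year: int = 2023
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    augmentation: AugmentationConfig = dataclasses.field(
        default_factory=AugmentationConfig)
    model: APYieldNetConfig = dataclasses.field(default_factory=APYieldNetConfig)
    training: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    augment_enabled: bool = True
    # correction inputs (kg/mu); None disables the correction stage
    correction_pred_sample: float | None = None
    correction_true_sample: float | None = None
    correction_pred_orchard: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, target in (("synthetic", cfg.synthetic),
                                ("augmentation", cfg.augmentation),
                                ("model", cfg.model),
                                ("training", cfg.training)):
            for k, v in (raw.get(section) or {}).items():
                if not hasattr(target, k):
                    raise ValueError(f"unknown key {section}.{k}")
                setattr(target, k, v)
        for k in ("seed", "out_dir", "test_year", "augment_enabled",
                  "correction_pred_sample", "correction_true_sample",
                  "correction_pred_orchard"):
            if k in raw:
                setattr(cfg, k, raw[k])
        cfg.propagate_seed()
        return cfg

    def propagate_seed(self):
        self.synthetic.seed = self.seed
        self.augmentation.seed = self.seed
        self.model.seed = self.seed
        self.training.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(model: APYieldNet, path):
    """Binary parameter file + JSON sidecar with config and scaling stats."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             *[p.data for p in model.parameters()])
    sidecar = {"config": dataclasses.asdict(model.cfg),
               "scaler": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in dataclasses.asdict(model.scaler).items()},
               "version": __version__}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> APYieldNet:
    from .apyieldnet import DataScaler
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = APYieldNetConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in sidecar["config"].items()})
    model = APYieldNet(cfg)
    sc = sidecar["scaler"]
    model.scaler = DataScaler(
        y_mean=sc["y_mean"], y_std=sc["y_std"],
        area_mean=sc["area_mean"], area_std=sc["area_std"],
        stat_mean=np.asarray(sc["stat_mean"]),
        stat_std=np.asarray(sc["stat_std"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.set_state([data[k] for k in data.files])
    model.eval()
    return model


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.propagate_seed()
    artifacts: dict[str, str] = {}

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("simulate")
        records, _ = generate_county_dataset(cfg.synthetic)
        write_dataset(records, out / "features.csv", out / "labels.csv")
        (out / "synthetic.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(cfg.synthetic)))
        artifacts["dataset"] = str(out / "labels.csv")

        _stage("split")
        split = temporal_split(records, cfg.test_year, seed=cfg.seed)
        train_recs = [records[i] for i in split.train_ids]
        val_recs = [records[i] for i in split.val_ids]
        test_recs = [records[i] for i in split.test_ids]

        _stage("augment")
        if cfg.augment_enabled:
            train_aug = augment_pipeline(train_recs, cfg.augmentation)
        else:
            train_aug = train_recs
        write_dataset(train_aug, out / "augmented_features.csv",
                      out / "augmented_labels.csv")
        artifacts["augmented"] = str(out / "augmented_labels.csv")

        _stage("train")
        model, hist = train(cfg.model, cfg.training, train_aug, val_recs)
        save_checkpoint(model, out / "checkpoint")
        artifacts["checkpoint"] = str(out / "checkpoint.npz")
        (out / "history.csv").write_text(
            "epoch,train_loss,val_loss,lr\n" + "\n".join(
                f"{i},{t},{v},{l}" for i, (t, v, l) in enumerate(
                    zip(hist.train_loss, hist.val_loss, hist.lr))))

        _stage("evaluate")
        preds = model.predict_records(test_recs)
        labels = np.array([r.yield_label for r in test_recs])
        report = bootstrap_ci(preds, labels, seed=cfg.seed)
        (out / "metrics.json").write_text(
            json.dumps(report.as_dict(), indent=2, sort_keys=True))
        artifacts["metrics"] = str(out / "metrics.json")

        _stage("correct")
        if cfg.correction_pred_sample is not None:
            sc = CorrectionScenario(
                y_pre_sample=cfg.correction_pred_sample,
                y_true_sample=cfg.correction_true_sample,
                y_pre=cfg.correction_pred_orchard)
            corr = correct_scenario(sc)
            (out / "correction.json").write_text(json.dumps(corr, indent=2))
            artifacts["correction"] = str(out / "correction.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {"config": cfg.to_dict(), "config_hash": _config_hash(cfg),
                "seed": cfg.seed, "version": __version__,
                "artifacts": artifacts}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


# ---------------------------------------------------------------------------
# CLI

@click.group()
@click.version_option(__version__)
def main():
    """Apple-orchard yield prediction from multispectral time series."""


@main.command()
@click.option("--counties", default=22, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", default="simulated", show_default=True)
def simulate(counties, seed, out_dir):
    """Generate a synthetic county-year dataset with known ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(n_counties=counties, seed=seed)
    records, _ = generate_county_dataset(cfg)
    write_dataset(records, out / "features.csv", out / "labels.csv")
    (out / "synthetic.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(cfg)))
    click.echo(f"wrote {len(records)} county-year records to {out}")


@main.command()
@click.option("--features", "features_path", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True)
def assemble(features_path, labels_path, out_path):
    """Validate a long-form CSV pair and write the assembled dataset."""
    records = read_dataset(features_path, labels_path)
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    write_dataset(records, out.with_suffix(".features.csv"),
                  out.with_suffix(".labels.csv"))
    click.echo(f"assembled {len(records)} records")


@main.command()
@click.option("--features", "features_path", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_prefix", required=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--n-samples", default=0, show_default=True,
              help="VAE sampling budget")
def augment(features_path, labels_path, out_prefix, seed, n_samples):
    """Run the three-stage augmentation on a dataset."""
    records = read_dataset(features_path, labels_path)
    cfg = AugmentationConfig(seed=seed, n_samples=n_samples)
    out_records = augment_pipeline(records, cfg)
    out = Path(out_prefix)
    write_dataset(out_records, out.with_suffix(".features.csv"),
                  out.with_suffix(".labels.csv"))
    click.echo(f"{len(records)} -> {len(out_records)} records")


@main.command(name="train")
@click.option("--features", "features_path", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True))
@click.option("--test-year", default=2023, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", default="ckpt", show_default=True)
@click.option("--max-epochs", default=500, show_default=True)
def train_cmd(features_path, labels_path, test_year, seed, out_dir, max_epochs):
    """Train the yield network with the standard protocol."""
    records = read_dataset(features_path, labels_path)
    split = temporal_split(records, test_year, seed=seed)
    model, hist = train(APYieldNetConfig(seed=seed),
                        TrainConfig(seed=seed, max_epochs=max_epochs),
                        [records[i] for i in split.train_ids],
                        [records[i] for i in split.val_ids])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(model, out / "checkpoint")
    click.echo(f"best val loss {min(hist.val_loss):.4f} "
               f"at epoch {hist.best_epoch}; checkpoint in {out}")


@main.command()
@click.option("--model", "model_path", required=True)
@click.option("--features", "features_path", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True)
def predict(model_path, features_path, labels_path, out_path):
    """Predict kg/mu yields for every record in a dataset."""
    model = load_checkpoint(Path(model_path))
    records = read_dataset(features_path, labels_path)
    preds = model.predict_records(records)
    with open(out_path, "w") as fh:
        fh.write("county,year,predicted_yield_kg_per_mu\n")
        for r, p in zip(records, preds):
            fh.write(f"{r.county},{r.year},{p}\n")
    click.echo(f"wrote {len(records)} predictions")


@main.command(name="eval")
@click.option("--preds", "preds_path", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_path", required=True, type=click.Path(exists=True))
@click.option("--seed", default=0, show_default=True)
def eval_cmd(preds_path, labels_path, seed):
    """MAE/RMSE/MAPE/R^2 with 1000-rep bootstrap CIs (JSON to stdout)."""
    import pandas as pd
    preds = pd.read_csv(preds_path)["predicted_yield_kg_per_mu"].to_numpy()
    labels = pd.read_csv(labels_path)["yield_kg_per_mu"].to_numpy()
    report = bootstrap_ci(preds, labels, seed=seed)
    click.echo(json.dumps(report.as_dict(), indent=2, sort_keys=True))


@main.command()
@click.option("--pred-sample", type=float, default=None,
              help="model-predicted sampling-area yield (kg/mu)")
@click.option("--true-sample", type=float, default=None,
              help="ground-estimated sampling-area yield (kg/mu)")
@click.option("--pred-orchard", type=float, default=None,
              help="model-predicted whole-orchard yield (kg/mu)")
@click.option("--batch", "batch_path", type=click.Path(exists=True),
              default=None, help="CSV with columns pred_sample, true_sample,"
              " pred_orchard (overrides the single-scenario options)")
@click.option("--alpha-precision", type=click.Choice(["rounded", "full"]),
              default="rounded", show_default=True)
def correct(pred_sample, true_sample, pred_orchard, batch_path,
            alpha_precision):
    """Proportional correction: alpha and the corrected orchard yield."""
    import pandas as pd
    if batch_path is not None:
        table = pd.read_csv(batch_path)
        rows = []
        for _, row in table.iterrows():
            sc = CorrectionScenario(y_pre_sample=row["pred_sample"],
                                    y_true_sample=row["true_sample"],
                                    y_pre=row["pred_orchard"])
            rows.append(correct_scenario(sc, alpha_precision))
        click.echo(pd.DataFrame(rows).to_csv(index=False), nl=False)
        return
    if None in (pred_sample, true_sample, pred_orchard):
        raise click.UsageError("provide --batch or all three yields")
    sc = CorrectionScenario(y_pre_sample=pred_sample,
                            y_true_sample=true_sample, y_pre=pred_orchard)
    click.echo(json.dumps(correct_scenario(sc, alpha_precision)))


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML run configuration")
@click.option("--seed", default=None, type=int)
@click.option("--out", "out_dir", default=None)
def run(config_path, seed, out_dir):
    """Full pipeline: simulate/assemble -> augment -> train -> eval -> correct."""
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg.seed = seed
        cfg.propagate_seed()
    if out_dir is not None:
        cfg.out_dir = out_dir
    artifacts = run_pipeline(cfg)
    click.echo(json.dumps(artifacts, indent=2))


@main.command(name="blocks-selftest")
@click.option("--seed", default=0, show_default=True)
def blocks_selftest(seed):
    """Identity/contract self-checks of the detection feature blocks."""
    from . import nn as _nn
    from .detectblocks import FMA, FSPPF, IAFM, SS2D, channel_shuffle, fma_modulate
    from .synthdata import generate_feature_maps
    rng = _nn.seeded_rng(seed)
    x = generate_feature_maps(2, 4, 6, 6, seed=seed)
    checks = {}
    fma = FMA(4, 6, 6).identity_config()
    checks["fma_identity_max_err"] = float(
        np.abs(fma_modulate(x, fma, gate_override=1.0) - x).max())
    checks["channel_shuffle_involution"] = bool(
        np.array_equal(channel_shuffle(channel_shuffle(x, 2), 2), x))
    from .autodiff import Tensor
    ia = IAFM(4, 4, rng)
    checks["iafm_out_shape_ok"] = ia(Tensor(x), Tensor(x)).shape == x.shape
    ss = SS2D(4, 4, rng)
    checks["ss2d_shape_ok"] = ss(Tensor(x)).shape == x.shape
    ok = (checks["fma_identity_max_err"] < 1e-5 and
          all(v for k, v in checks.items() if k != "fma_identity_max_err"))
    click.echo(json.dumps({"ok": ok, **checks}))
    if not ok:
        raise SystemExit(1)
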