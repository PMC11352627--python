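"""Training loop, metrics and cross-validation driver.

Optimisation follows the method's protocol: AdamW, batch size 256,
initial learning rate 1e-3 decayed by a factor 0.9 every 20 epochs
(StepLR). Epoch count and early stopping are open choices: default 100
epochs with patience-20 early stopping on a held-out validation slice of
the training portion.

Metrics are MSE, RMSE (= √MSE of the same residual vector, an identity
asserted on every report), Pearson and Spearman correlation, overall and
optionally stratified by tissue and by cell line, all on the raw score
scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ModelConfig, TrainConfig
from .data_io import DatasetBundle, kfold, split_train_test
from .model import FeatureStore, SynergyModel, assemble_batch, mse_loss
from .nn import AdamW

__all__ = [
    "step_lr",
    "MetricsReport",
    "evaluate",
    "train",
    "TrainResult",
    "cross_validate",
]


def step_lr(epoch: int, lr0: float = 1e-3, gamma: float = 0.9,
            step_size: int = 20) -> float:
    """Step-decay schedule: lr0 · gamma^⌊epoch / step_size⌋."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return lr0 * gamma ** (epoch // step_size)


@dataclass
class MetricsReport:
    mse: float
    rmse: float
    pcc: float | None
    scc: float | None
    n: int
    per_stratum: dict = field(default_factory=dict)

    def __post_init__(self):
        assert abs(self.rmse**2 - self.mse) < 1e-9 * max(1.0, self.mse)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    residual = pred - truth
    mse = float(np.mean(residual**2))
    if len(pred) < 2 or np.std(pred) == 0 or np.std(truth) == 0:
        pcc = scc = None  # undefined for constant input, not NaN
    else:
        pcc = float(stats.pearsonr(pred, truth).statistic)
        scc = float(stats.spearmanr(pred, truth).statistic)
    return {"mse": mse, "rmse": float(np.sqrt(mse)), "pcc": pcc, "scc": scc,
            "n": int(len(pred))}


def evaluate(pred, truth, strata: dict | None = None) -> MetricsReport:
    """Four regression metrics overall and per stratum.

    ``strata`` maps a stratification name (e.g. "tissue", "cell_line") to
    one label per example.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if len(pred) < 2:
        raise ValueError("need at least two examples")
    report = MetricsReport(**_metrics(pred, truth))
    for name, labels in (strata or {}).items():
        labels = np.asarray(labels)
        if labels.shape != pred.shape:
            raise ValueError(f"stratum {name!r} labels length mismatch")
        report.per_stratum[name] = {
            str(lab): _metrics(pred[labels == lab], truth[labels == lab])
            for lab in np.unique(labels)
        }
    return report


@dataclass
class TrainResult:
    model: SynergyModel
    store: FeatureStore
    history: list[dict]
    best_epoch: int
    best_val_mse: float


def _augment_orderings(examples):
    out = list(examples)
    out += [dataclasses.replace(e, drug_a=e.drug_b, drug_b=e.drug_a)
            for e in examples]
    return out


def train(model: SynergyModel, bundle: DatasetBundle, config: TrainConfig,
          store: FeatureStore | None = None, examples=None,
          checkpoint_path=None) -> TrainResult:
    """Train ``model`` on ``bundle`` (or an explicit example subset).

    Fully reproducible per (model seed, train seed); keeps the best
    validation-MSE weights and restores them at the end; aborts on a
    non-finite loss with the offending epoch/batch identified.
    """
    store = store or FeatureStore(bundle.drugs, model.config)
    examples = list(examples if examples is not None else bundle.examples)
    cell_matrix, cell_row = bundle.cell_matrix()

    if config.val_fraction > 0 and len(examples) >= 10:
        train_ex, val_ex = split_train_test(
            examples, 1.0 - config.val_fraction, seed=config.seed + 1)
    else:
        train_ex, val_ex = examples, []
    if model.config.order_augment:
        train_ex = _augment_orderings(train_ex)

    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.lr0,
                weight_decay=config.weight_decay)
    history: list[dict] = []
    best = {"epoch": -1, "val_mse": np.inf, "state": model.state_dict()}
    stale = 0
    model.train()
    for epoch in range(config.epochs):
        opt.lr = step_lr(epoch, config.lr0, config.gamma, config.step_size)
        order = rng.permutation(len(train_ex))
        losses = []
        for start in range(0, len(train_ex), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = assemble_batch([train_ex[i] for i in idx], store,
                                   cell_matrix, cell_row)
            opt.zero_grad()
            pred = model.forward(batch, store)
            loss = mse_loss(pred, batch.y)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, "
                    f"batch starting at {start}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        record = {"epoch": epoch, "lr": opt.lr,
                  "train_mse": float(np.mean(losses))}
        if val_ex:
            val_pred = model.predict(val_ex, store, cell_matrix, cell_row)
            val_mse = float(np.mean(
                (val_pred - np.array([e.score for e in val_ex]))**2))
            record["val_mse"] = val_mse
            if val_mse < best["val_mse"] - 1e-12:
                best = {"epoch": epoch, "val_mse": val_mse,
                        "state": model.state_dict()}
                stale = 0
            else:
                stale += 1
        history.append(record)
        if val_ex and stale > config.patience:
            break
    if val_ex and best["epoch"] >= 0:
        model.load_state_dict(best["state"])
    model.eval()
    if checkpoint_path is not None:
        model.save(checkpoint_path)
    return TrainResult(model=model, store=store, history=history,
                       best_epoch=best["epoch"],
                       best_val_mse=float(best["val_mse"]))


def _strata_for(examples, bundle: DatasetBundle) -> dict:
    tissues = [bundle.cells[e.cell_line].tissue or "unknown" for e in examples]
    return {"tissue": tissues,
            "cell_line": [e.cell_line for e in examples]}


def evaluate_model(model: SynergyModel, bundle: DatasetBundle, examples,
                   store: FeatureStore | None = None) -> MetricsReport:
    store = store or FeatureStore(bundle.drugs, model.config)
    cell_matrix, cell_row = bundle.cell_matrix()
    pred = model.predict(examples, store, cell_matrix, cell_row)
    truth = np.array([e.score for e in examples])
    return evaluate(pred, truth, strata=_strata_for(examples, bundle))


def cross_validate(bundle: DatasetBundle, k: int, model_config: ModelConfig,
                   train_config: TrainConfig) -> dict:
    """k-fold CV: k independent models, per-fold metrics, mean ± sd summary."""
    store: FeatureStore | None = None
    reports: list[MetricsReport] = []
    for fold, (train_ex, val_ex) in enumerate(
            kfold(bundle.examples, k, seed=train_config.seed)):
        cfg = dataclasses.replace(model_config,
                                  seed=model_config.seed + fold)
        model = SynergyModel(cfg, bundle.expr_width, bundle.mut_width,
                             len(bundle.cells))
        tc = dataclasses.replace(train_config, seed=train_config.seed + fold)
        result = train(model, bundle, tc, store=store, examples=train_ex)
        store = result.store
        reports.append(evaluate_model(model, bundle, val_ex, store=store))
    summary = {}
    for name in ("mse", "rmse", "pcc", "scc"):
        values = [getattr(r, name) for r in reports]
        if any(v is None for v in values):
            summary[name] = None
            continue
        arr = np.asarray(values, dtype=np.float64)
        summary[name] = {"mean": float(arr.mean()), "sd": float(arr.std())}
    return {"folds": [r.to_dict() for r in reports], "summary": summary}
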