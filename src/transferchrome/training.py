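"""Losses, SGD training loops and AUC evaluation.

Two protocols are supported:

* **single** — train, validate and test on one (labeled) cell line,
  minimizing the binary cross-entropy of the label head only.
* **cross** — train on a labeled source cell line plus half of an unlabeled
  target cell line, evaluate on the held-out target half.  Each batch mixes
  source (domain 1) and target (domain 0) genes; the label loss is computed
  on source genes only, while the domain loss is computed on all genes and
  back-propagates into the feature extractor through the gradient reversal
  layer with strength lambda.  The training objective is
  sum_i L_y^i - lambda * sum_i L_d^i.

Optimization is SGD (lr 0.001, momentum 0.85, weight decay 0.001 by
default).  Single mode early-stops on validation AUC (patience epochs
without improvement) and restores the best epoch.  Cross mode runs its
full epoch budget and by default returns the final parameters: with no
target labels, source-validation AUC cannot sense domain alignment, so
stopping on it would return a model from before the adversarial phase
has acted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

from . import autodiff as ad
from .data import CellLineDataset
from .model import ModelConfig, TransferChromeModel

EPS_CLAMP = 1e-7


@dataclass
class TrainConfig:
    """Optimizer and protocol hyperparameters."""

    learning_rate: float = 0.001
    momentum: float = 0.85
    weight_decay: float = 0.001
    max_epochs: int = 200
    early_stop_patience: int = 10
    batch_size: int = 64
    seed: int = 0
    mode: str = "single"
    lambda_grl: float = 1.0
    target_train_fraction: float = 0.5
    source_valid_fraction: float = 0.1
    lambda_schedule: str = "ramp"  # 2/(1+exp(-10 p)) - 1, or "constant"
    clip_grad_norm: float | None = 5.0
    # the domain head trains faster than the body so it keeps tracking the
    # shifting feature distribution; a lagging head emits wild adversarial
    # gradients that destabilize the extractor
    domain_head_lr_mult: float = 5.0
    # which parameters a cross-mode run returns: the final epoch (standard
    # for adversarial adaptation, where no target-label signal exists to
    # validate on) or the best source-validation epoch
    cross_restore: str = "final"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if not (0 < self.target_train_fraction < 1):
            raise ValueError("target_train_fraction must be in (0, 1)")
        if self.mode not in ("single", "cross"):
            raise ValueError("mode must be 'single' or 'cross'")
        if self.lambda_schedule not in ("constant", "ramp"):
            raise ValueError("lambda_schedule must be 'constant' or 'ramp'")
        if self.cross_restore not in ("final", "best_val"):
            raise ValueError("cross_restore must be 'final' or 'best_val'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainReport:
    """Per-epoch training history and final evaluation."""

    mode: str
    label_loss: list[float] = field(default_factory=list)
    domain_loss: list[float] = field(default_factory=list)
    domain_accuracy: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    test_auc: float = float("nan")
    n_epochs_run: int = 0

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_metrics_csv(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("epoch,L_y,L_d,val_auc\n")
            for e in range(self.n_epochs_run):
                ld = self.domain_loss[e] if e < len(self.domain_loss) else ""
                fh.write(f"{e},{self.label_loss[e]},{ld},{self.val_auc[e]}\n")


def cross_entropy(y: int, y_hat: float, eps: float = EPS_CLAMP) -> float:
    """Binary cross-entropy -[y log p + (1-y) log(1-p)], p clamped to
    [eps, 1-eps]."""
    if y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {y!r}")
    p = min(max(float(y_hat), eps), 1.0 - eps)
    return -(y * np.log(p) + (1 - y) * np.log(1.0 - p))


def adversarial_objective(
    label_losses, domain_losses, lam: float
) -> float:
    """Reporting-side scalar of the adversarial objective
    sum L_y - lambda * sum L_d."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return float(np.sum(label_losses) - lam * np.sum(domain_losses))


def evaluate_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outranks a random
    negative, with ties counted one half.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D vectors of equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos + n_neg != y.size:
        raise ValueError("labels must be 0/1")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def predict(model: TransferChromeModel, dataset: CellLineDataset) -> np.ndarray:
    """Evaluation-mode P(label=1) for every gene, in dataset order."""
    if len(dataset) == 0:
        return np.zeros(0)
    return model.predict_proba(dataset.signals())


def _lambda_at(tcfg: TrainConfig, epoch: int) -> float:
    if tcfg.lambda_schedule == "constant":
        return tcfg.lambda_grl
    p = epoch / max(tcfg.max_epochs - 1, 1)
    return tcfg.lambda_grl * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)


def _auc_or_nan(labels, scores) -> float:
    try:
        return evaluate_auc(labels, scores)
    except ValueError:
        return float("nan")


def train_single(
    train: CellLineDataset,
    valid: CellLineDataset,
    test: CellLineDataset,
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> tuple[TransferChromeModel, TrainReport]:
    """Single-cell-line protocol: supervised training of the label head."""
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig(mode="single")
    x_train, y_train = train.signals(), train.labels()
    x_valid, y_valid = valid.signals(), valid.labels()
    x_test, y_test = test.signals(), test.labels()

    model = TransferChromeModel(mcfg, seed=tcfg.seed)
    opt = ad.SGD(model.parameters(), tcfg.learning_rate, tcfg.momentum,
                 tcfg.weight_decay, clip_norm=tcfg.clip_grad_norm)
    rng = np.random.default_rng(tcfg.seed)
    report = TrainReport(mode="single")
    best_auc, best_state, patience = -np.inf, model.state(), 0

    n = len(train)
    for epoch in range(tcfg.max_epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = perm[start : start + tcfg.batch_size]
            opt.zero_grad()
            feats = model.extract_features(x_train[idx], rng=rng)
            loss = ad.bce_with_logits(model.label_logit(feats), y_train[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        report.label_loss.append(float(np.mean(losses)))
        val_auc = _auc_or_nan(y_valid, model.predict_proba(x_valid))
        report.val_auc.append(val_auc)
        report.n_epochs_run = epoch + 1
        if val_auc > best_auc:
            best_auc, best_state, patience = val_auc, model.state(), 0
            report.best_epoch = epoch
        else:
            patience += 1
            if patience >= tcfg.early_stop_patience:
                break

    model.load_state(best_state)
    report.test_auc = _auc_or_nan(y_test, model.predict_proba(x_test))
    return model, report


def split_target_halves(
    target: CellLineDataset, tcfg: TrainConfig
) -> tuple[CellLineDataset, CellLineDataset]:
    """Seeded split of the target cell line into an (unlabeled) training
    half and a held-out test half."""
    n = len(target)
    if n == 0:
        raise ValueError("empty target dataset")
    perm = np.random.default_rng(tcfg.seed + 1).permutation(n)
    n_train = int(round(n * tcfg.target_train_fraction))
    return (
        target.subset(perm[:n_train], suffix="/train-half"),
        target.subset(perm[n_train:], suffix="/test-half"),
    )


def train_cross(
    source: CellLineDataset,
    target: CellLineDataset,
    mcfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
) -> tuple[TransferChromeModel, TrainReport, CellLineDataset]:
    """Cross-cell-line protocol with domain-adversarial training.

    The source is fully labeled; the target's labels are treated as unknown
    during training.  Returns the trained model, the report (test AUC is
    measured on the held-out target half, which must carry labels for
    evaluation), and that held-out half.
    """
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig(mode="cross")

    target_train, target_test = split_target_halves(target, tcfg)

    # hold out a slice of the source for early stopping on label AUC
    n_src = len(source)
    perm = np.random.default_rng(tcfg.seed + 2).permutation(n_src)
    n_val = max(int(round(n_src * tcfg.source_valid_fraction)), 2)
    src_valid = source.subset(perm[:n_val], suffix="/valid")
    src_train = source.subset(perm[n_val:], suffix="/train")

    x_src, y_src = src_train.signals(), src_train.labels()
    x_tgt = target_train.signals()
    x_val, y_val = src_valid.signals(), src_valid.labels()

    # pooled training arrays; domain 1 = source, 0 = target
    x_all = np.concatenate([x_src, x_tgt])
    d_all = np.concatenate([np.ones(len(x_src)), np.zeros(len(x_tgt))])
    y_all = np.concatenate([y_src.astype(np.float64), np.zeros(len(x_tgt))])
    label_mask = d_all.copy()  # label loss on source genes only

    model = TransferChromeModel(mcfg, seed=tcfg.seed)
    head_params = [p for fc in model.domain_fc for p in fc.parameters()]
    head_ids = {id(p) for p in head_params}
    body_params = [p for p in model.parameters() if id(p) not in head_ids]
    opt = ad.SGD(body_params, tcfg.learning_rate, tcfg.momentum,
                 tcfg.weight_decay, clip_norm=tcfg.clip_grad_norm)
    opt_head = ad.SGD(head_params,
                      tcfg.learning_rate * tcfg.domain_head_lr_mult,
                      tcfg.momentum, tcfg.weight_decay,
                      clip_norm=tcfg.clip_grad_norm)
    rng = np.random.default_rng(tcfg.seed)
    report = TrainReport(mode="cross")
    best_auc, best_state = -np.inf, model.state()

    n = len(x_all)
    for epoch in range(tcfg.max_epochs):
        lam = _lambda_at(tcfg, epoch)
        perm = rng.permutation(n)
        lab_losses, dom_losses, dom_correct, dom_total = [], [], 0, 0
        for start in range(0, n, tcfg.batch_size):
            idx = perm[start : start + tcfg.batch_size]
            opt.zero_grad()
            opt_head.zero_grad()
            feats = model.extract_features(x_all[idx], rng=rng)
            dom_logit = model.domain_logit(feats, lam)
            loss_d = ad.bce_with_logits(dom_logit, d_all[idx])
            if label_mask[idx].sum() > 0:
                lab_logit = model.label_logit(feats)
                loss_y = ad.bce_with_logits(lab_logit, y_all[idx],
                                            weights=label_mask[idx])
                total = ad.add(loss_y, loss_d)
                lab_losses.append(float(loss_y.data))
            else:  # pure-target batch: only the domain branch contributes
                total = loss_d
            total.backward()
            opt.step()
            opt_head.step()
            dom_losses.append(float(loss_d.data))
            dom_correct += int(((dom_logit.data > 0) == (d_all[idx] > 0.5)).sum())
            dom_total += len(idx)
        report.label_loss.append(float(np.mean(lab_losses)))
        report.domain_loss.append(float(np.mean(dom_losses)))
        report.domain_accuracy.append(dom_correct / dom_total)
        val_auc = _auc_or_nan(y_val, model.predict_proba(x_val))
        report.val_auc.append(val_auc)
        report.n_epochs_run = epoch + 1
        if val_auc > best_auc:
            best_auc, best_state = val_auc, model.state()
            report.best_epoch = epoch

    # source-validation AUC is blind to target-domain alignment, so the
    # adversarial protocol runs its full epoch budget and, by default,
    # returns the final parameters; "best_val" restores the best
    # source-validation epoch instead
    if tcfg.cross_restore == "best_val":
        model.load_state(best_state)
    try:
        report.test_auc = _auc_or_nan(
            target_test.labels(), model.predict_proba(target_test.signals())
        )
    except ValueError:  # unlabeled held-out half: no evaluation possible
        report.test_auc = float("nan")
    return model, report, target_test
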