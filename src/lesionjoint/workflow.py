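"""Training protocol, cross-validation, ablations and model explanation.

The training loop mirrors the study protocol: Adam (default moments),
initial learning rate 1e-4, batch size 2, plateau-halving schedule
(patience 10 epochs, factor 0.5), training-time augmentation only, and
stratified k-fold cross-validation whose per-fold reports are averaged
into the final table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .joint_model import JointModel, ModelConfig
from .metrics import aggregate_folds, cls_metrics, seg_metrics
from .nn import tensor as T
from .nn.optim import Adam
from .nn.tensor import Tensor
from .objectives import (LossWeights, bce_loss, cam_maps, cross_task_loss,
                         dice_loss, total_loss)
from .synthetic_data import CaseSample, augment


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 2
    epochs: int = 200
    lr0: float = 1e-4
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    augment_p: float = 0.5
    seed: int = 0
    monitor: str = "train"        # plateau rule watches train or val loss
    scale_profile: str = "full"
    loss_weights: LossWeights = dataclasses.field(default_factory=LossWeights)

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Desk-scale training profile.

        The desk budget is a few hundred optimizer steps (vs thousands in
        the full protocol), so the initial learning rate is raised to
        3e-3; everything else keeps the protocol defaults.
        """
        defaults = dict(lr0=3e-3, scale_profile="desk")
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.plateau_patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("factor must be in (0, 1)")


@dataclasses.dataclass
class FoldSplit:
    assignments: dict           # case_id -> fold index
    k: int
    seed: int

    def fold_cases(self, fold: int) -> list[str]:
        return sorted(cid for cid, f in self.assignments.items() if f == fold)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"k": self.k, "seed": self.seed, "assignments": self.assignments},
            sort_keys=True, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FoldSplit":
        d = json.loads(Path(path).read_text())
        return cls(assignments=d["assignments"], k=d["k"], seed=d["seed"])

    def digest(self) -> str:
        payload = json.dumps({"k": self.k, "assignments": self.assignments},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class SchedulerState:
    lr: float
    best_loss: float = float("inf")
    stale_count: int = 0


def lr_schedule_step(state: SchedulerState, epoch_loss: float,
                     cfg: TrainConfig) -> SchedulerState:
    """Halve the learning rate after ``patience`` epochs without improvement."""
    if not np.isfinite(epoch_loss):
        raise ValueError("non-finite epoch loss")
    if epoch_loss < state.best_loss:
        return SchedulerState(lr=state.lr, best_loss=epoch_loss, stale_count=0)
    stale = state.stale_count + 1
    if stale >= cfg.plateau_patience:
        return SchedulerState(lr=state.lr * cfg.plateau_factor,
                              best_loss=state.best_loss, stale_count=0)
    return SchedulerState(lr=state.lr, best_loss=state.best_loss,
                          stale_count=stale)


def make_folds(cases, k: int = 5, seed: int = 0,
               group_key: dict | None = None) -> FoldSplit:
    """Stratified-by-label k-fold partition, deterministic given seed.

    Fold membership depends only on the sorted case ids, never on input
    order. ``group_key`` (case_id -> group) keeps all members of a group
    — e.g. longitudinal sessions of one patient — in the same fold.
    """
    ids_labels = _as_id_label_pairs(cases)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids_labels) < k:
        raise ValueError("fewer cases than folds")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    if group_key:
        units = {}
        for cid, label in ids_labels:
            units.setdefault(group_key.get(cid, cid), []).append((cid, label))
        unit_items = sorted(units.items())
    else:
        unit_items = [(cid, [(cid, label)]) for cid, label in
                      sorted(ids_labels)]
    # stratify by the (majority) label of each unit
    by_label: dict[int, list] = {}
    for key, members in unit_items:
        maj = int(round(np.mean([lb for _, lb in members])))
        by_label.setdefault(maj, []).append((key, members))
    next_fold = 0
    for label in sorted(by_label):
        items = by_label[label]
        order = rng.permutation(len(items))
        for pos in order:
            _, members = items[pos]
            for cid, _ in members:
                assignments[cid] = next_fold % k
            next_fold += 1
    return FoldSplit(assignments=assignments, k=k, seed=seed)


def _as_id_label_pairs(cases):
    if isinstance(cases, pd.DataFrame):
        return list(zip(cases["case_id"].astype(str), cases["label"]))
    return [(c.case_id, c.label) for c in cases]


def _augment_seed(master: int, epoch: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(epoch, index))
    return int(ss.generate_state(1)[0] % (2**31))


def _batch_arrays(samples: list[CaseSample]):
    vols = np.stack([s.volume for s in samples])[:, None].astype(np.float32)
    masks = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
    labels = np.array([s.label for s in samples], dtype=np.float32)
    return vols, masks, labels


def compute_losses(model: JointModel, vols: np.ndarray, masks: np.ndarray,
                   labels: np.ndarray, weights: LossWeights):
    """Forward pass + the three loss components on one batch."""
    state = model(Tensor(vols))
    l_seg = dice_loss(state.prob_map, Tensor(masks))
    l_cls = bce_loss(state.cls.probs[:, 1], labels)
    if weights.beta[2] > 0:
        V = cam_maps(state.cls, labels.astype(int))
        l_cross = cross_task_loss(state.seg_maps, V, weights.eta)
    else:
        l_cross = Tensor(0.0)
    loss = total_loss(l_seg, l_cls, l_cross, weights.beta)
    return loss, l_seg, l_cls, l_cross, state


def train_fold(train_cases: list[CaseSample], val_cases: list[CaseSample],
               model_cfg: ModelConfig, train_cfg: TrainConfig,
               log_path: str | Path | None = None,
               step_log_path: str | Path | None = None):
    """Train one model; returns (model-with-best-weights, training log).

    Augmentation applies to training cases only; the best checkpoint is
    selected by validation total loss (training loss if no validation
    cases are supplied). Fully deterministic given the seeds. The returned
    log has one row per epoch; ``step_log_path`` additionally captures
    every optimizer step (step, loss components, lr).
    """
    train_ids = {c.case_id for c in train_cases}
    if train_ids & {c.case_id for c in val_cases}:
        raise ValueError("train/val overlap")
    model = JointModel(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr0)
    sched = SchedulerState(lr=train_cfg.lr0)
    weights = train_cfg.loss_weights
    rng = np.random.default_rng(train_cfg.seed)
    rows = []
    step_rows = []
    global_step = 0
    best_val = float("inf")
    best_state = model.state_dict()
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(train_cases))
        comps = np.zeros(4)
        n_batches = 0
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            batch = [
                augment(train_cases[i], train_cfg.augment_p,
                        _augment_seed(train_cfg.seed, epoch, int(i)))
                for i in idx
            ]
            vols, masks, labels = _batch_arrays(batch)
            loss, l_seg, l_cls, l_cross, _ = compute_losses(
                model, vols, masks, labels, weights)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            model.zero_grad()
            loss.backward()
            opt.lr = sched.lr
            opt.step()
            comps += [l_seg.item(), l_cls.item(), l_cross.item(), loss.item()]
            n_batches += 1
            step_rows.append({"epoch": epoch, "step": global_step,
                              "L_seg": l_seg.item(), "L_cls": l_cls.item(),
                              "L_cross": l_cross.item(),
                              "L_total": loss.item(), "lr": sched.lr})
            global_step += 1
        comps /= max(n_batches, 1)
        val_loss = np.nan
        if val_cases:
            val_loss = _validation_loss(model, val_cases, train_cfg, weights)
        monitor = comps[3] if train_cfg.monitor == "train" or not val_cases \
            else val_loss
        sched = lr_schedule_step(sched, float(monitor), train_cfg)
        select = val_loss if val_cases else comps[3]
        if select < best_val:
            best_val = select
            best_state = model.state_dict()
        rows.append({"epoch": epoch, "L_seg": comps[0], "L_cls": comps[1],
                     "L_cross": comps[2], "L_total": comps[3],
                     "val_loss": val_loss, "lr": sched.lr})
    model.load_state_dict(best_state)
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    if step_log_path is not None:
        pd.DataFrame(step_rows).to_csv(step_log_path, index=False)
    return model, log


def _validation_loss(model, val_cases, train_cfg, weights) -> float:
    total = 0.0
    n = 0
    with T.no_grad():
        for start in range(0, len(val_cases), train_cfg.batch_size):
            batch = val_cases[start:start + train_cfg.batch_size]
            vols, masks, labels = _batch_arrays(batch)
            loss, *_ = compute_losses(model, vols, masks, labels, weights)
            total += loss.item()
            n += 1
    return total / max(n, 1)


def evaluate_cases(model: JointModel, cases: list[CaseSample],
                   threshold: float | None = None):
    """Per-case segmentation metrics and fold-level classification metrics."""
    thr = model.cfg.binarize_threshold if threshold is None else threshold
    per_case = []
    labels, probs = [], []
    for case in cases:
        prob_map, _, cls_probs = model.predict(case.volume)
        pred_mask = (prob_map >= thr).astype(np.uint8)
        row = {"case_id": case.case_id, "label": case.label,
               "p_pos": float(cls_probs[1])}
        row.update(seg_metrics(pred_mask, case.mask))
        per_case.append(row)
        labels.append(case.label)
        probs.append(float(cls_probs[1]))
    per_case = pd.DataFrame(per_case)
    report = {m: float(per_case[m].mean(skipna=True))
              for m in ("DSC", "PPV", "TPR", "VD")}
    report.update(cls_metrics(np.array(labels), np.array(probs), thr))
    return per_case, report


def run_cross_validation(cases: list[CaseSample], split: FoldSplit,
                         model_cfg: ModelConfig, train_cfg: TrainConfig,
                         out_dir: str | Path | None = None):
    """Train k models on the split; aggregate held-out metrics.

    Returns dict with per-fold reports, the per-case frame and the
    mean/sd summary (fractions; use metrics.to_percent for tables).
    """
    by_id = {c.case_id: c for c in cases}
    missing = set(split.assignments) - set(by_id)
    if missing:
        raise ValueError(f"split references unknown cases: {sorted(missing)}")
    fold_reports = []
    case_frames = []
    for fold in range(split.k):
        val_ids = set(split.fold_cases(fold))
        train_cases = [by_id[cid] for cid in sorted(set(by_id) - val_ids)]
        val_cases = [by_id[cid] for cid in sorted(val_ids)]
        fold_seed = int(np.random.SeedSequence(
            entropy=train_cfg.seed, spawn_key=(fold,)).generate_state(1)[0]
            % (2**31))
        fold_cfg = dataclasses.replace(train_cfg, seed=fold_seed)
        step_path = None
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            step_path = Path(out_dir) / f"fold{fold}_step_log.csv"
        model, log = train_fold(train_cases, val_cases, model_cfg, fold_cfg,
                                step_log_path=step_path)
        per_case, report = evaluate_cases(model, val_cases)
        per_case["fold"] = fold
        report["fold"] = fold
        fold_reports.append(report)
        case_frames.append(per_case)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            log.to_csv(out / f"fold{fold}_train_log.csv", index=False)
            model.save(out / f"fold{fold}_model.npz")
    summary = aggregate_folds(
        [{k: v for k, v in r.items() if k != "fold"} for r in fold_reports])
    per_case_all = pd.concat(case_frames, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        per_case_all.to_csv(out / "per_case_metrics.csv", index=False)
        pd.DataFrame(fold_reports).to_csv(out / "per_fold_metrics.csv",
                                          index=False)
        summary.to_csv(out / "summary_metrics.csv")
        # table-ready percent scaling (DSC (%) ... AUC (%))
        (100.0 * summary).to_csv(out / "summary_metrics_percent.csv")
        import platform

        cfg_json = model_cfg.to_json()
        record = {
            "split_digest": split.digest(),
            "seed": train_cfg.seed,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
            "model_config": json.loads(cfg_json),
            "train_config": {
                "batch_size": train_cfg.batch_size, "epochs": train_cfg.epochs,
                "lr0": train_cfg.lr0, "patience": train_cfg.plateau_patience,
                "factor": train_cfg.plateau_factor,
                "augment_p": train_cfg.augment_p,
                "beta": list(train_cfg.loss_weights.beta),
                "eta": list(train_cfg.loss_weights.eta),
            },
            "environment": {"python": platform.python_version(),
                            "numpy": np.__version__,
                            "platform": platform.platform()},
        }
        (out / "run_record.json").write_text(json.dumps(record, indent=1,
                                                        sort_keys=True))
    return {"folds": fold_reports, "per_case": per_case_all,
            "summary": summary}


#: named ablation switches -> (ModelConfig overrides, beta overrides)
ABLATION_VARIANTS = {
    "joint": ({}, None),
    "only seg": ({"lgm_variant": "off"}, (1.0, 0.0, 0.0)),
    "only cls": ({"lgm_variant": "off"}, (0.0, 0.8, 0.0)),
    "w/o share": ({"share_variant": "off"}, None),
    "only local": ({"share_variant": "only_local"}, None),
    "only global": ({"share_variant": "only_global"}, None),
    "w/o LGM": ({"lgm_variant": "off"}, None),
    "dot product": ({"lgm_variant": "dot_product"}, None),
    "concat": ({"lgm_variant": "concat"}, None),
    "dot add": ({"lgm_variant": "dot_add"}, None),
    "w/o cross loss": ({}, (1.0, 0.8, 0.0)),
}


def ablation_suite(cases: list[CaseSample], split: FoldSplit,
                   model_cfg: ModelConfig, train_cfg: TrainConfig,
                   variants: list[str] | None = None,
                   out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run cross-validation per ablation variant with shared seeds/split."""
    names = list(ABLATION_VARIANTS) if variants is None else list(variants)
    unknown = [n for n in names if n not in ABLATION_VARIANTS]
    if unknown:
        raise ValueError(f"unknown ablation variant(s): {unknown}")
    rows = []
    for name in names:
        cfg_over, beta_over = ABLATION_VARIANTS[name]
        m_cfg = dataclasses.replace(model_cfg, **cfg_over)
        t_cfg = train_cfg
        if beta_over is not None:
            t_cfg = dataclasses.replace(
                train_cfg,
                loss_weights=dataclasses.replace(train_cfg.loss_weights,
                                                 beta=beta_over))
        sub_dir = None
        if out_dir is not None:
            sub_dir = Path(out_dir) / name.replace("/", "_").replace(" ", "_")
        result = run_cross_validation(cases, split, m_cfg, t_cfg, sub_dir)
        row = {"variant": name, "split_digest": split.digest()}
        row.update({m: result["summary"].loc["mean", m]
                    for m in result["summary"].columns})
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "ablation_table.csv", index=False)
    return table


def explain(model: JointModel, case: CaseSample) -> dict:
    """CAM and Grad-CAM lesion localization maps for the predicted class.

    Returns per-stage maps rectified, min-max normalized to [0, 1] and
    trilinearly upsampled to the input resolution.
    """
    x = Tensor(case.volume[None, None].astype(np.float32))
    state = model(x)
    c = int(np.argmax(state.cls.probs.data[0]))
    # CAM: weighted sums of stage features by the class's FC weights
    cams = cam_maps(state.cls, c, normalize=False)
    # Grad-CAM: channel weights = spatially averaged gradients of the logit
    logit = state.cls.logits[0, c]
    model.zero_grad()
    logit.backward()
    out = {"predicted_class": c, "cam": [], "grad_cam": []}
    full = model.cfg.input_size
    for V, F in zip(cams, state.cls.stage_features):
        out["cam"].append(_postprocess_map(V.data[0, 0], full))
        g = F.grad
        alpha = g.mean(axis=(2, 3, 4), keepdims=True)   # (1, C, 1, 1, 1)
        gmap = np.maximum((alpha * F.data).sum(axis=1)[0], 0.0)
        out["grad_cam"].append(_postprocess_map(gmap, full))
    return out


def _postprocess_map(vol: np.ndarray, target: tuple) -> np.ndarray:
    from .preprocess import resize_volume

    vol = np.maximum(vol, 0.0)
    rng_ = vol.max() - vol.min()
    vol = (vol - vol.min()) / rng_ if rng_ > 0 else np.zeros_like(vol)
    return resize_volume(vol.astype(np.float32), target, "linear")
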