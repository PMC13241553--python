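"""Training orchestration: Monte Carlo splits, gating, voting, cascade.

Model evaluation uses Monte Carlo cross-validation with an 80/20
train-validation split, repeated until every subject has appeared in a
validation set at least once.  Per fold, a principal network is trained,
validation cases are predicted, cases with mean DSC >= 0.7 against the
ground truth are retained to train the refinement network, and per-fold
cascade predictions are fused by majority voting before anatomical
post-processing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .labels import DEFAULT_SCHEME
from .metrics import MaskPair, dsc
from .nn import (Adam, NetworkConfig, PrincipalNet, RefinementNet, Tensor,
                 boundary_weight_map, combined_loss, deep_supervision_loss,
                 downsample_labels, one_hot, softmax_channels)
from .phantom import PhantomSubject
from .postprocess import PostprocessConfig, postprocess
from .volume import LabelMap, Volume, normalize_intensity

logger = logging.getLogger(__name__)

__all__ = ["FoldSplit", "EnsembleSet", "TrainConfig", "make_mc_splits",
           "gate_for_refinement", "majority_vote", "mean_foreground_dsc",
           "run_training", "TrainResult", "predict_cascade"]


@dataclass(frozen=True)
class FoldSplit:
    run: int
    train: Tuple[str, ...]
    validation: Tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.validation):
            raise ValueError("train and validation sets overlap")


@dataclass
class EnsembleSet:
    """Per-model hard predictions for one subject, fused by voting."""

    predictions: List[LabelMap]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.predictions:
            raise ValueError("ensemble must contain at least one prediction")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("voting threshold must be in (0, 1]")
        shapes = {p.data.shape for p in self.predictions}
        if len(shapes) > 1:
            raise ValueError(f"ensemble predictions differ in shape: {shapes}")


def make_mc_splits(subject_ids: Sequence[str], ratio: float = 0.8,
                   seed: int = 0, max_runs: int = 20) -> List[FoldSplit]:
    """Repeated random 80/20 splits until full validation coverage.

    Stops at the first run after which every subject has been in a
    validation set at least once; raises if ``max_runs`` is exhausted
    before coverage is achieved.
    """
    ids = list(subject_ids)
    if len(ids) < 5:
        raise ValueError(f"need at least 5 subjects, got {len(ids)}")
    if not 0.0 < ratio < 1.0:
        raise ValueError("split ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = max(1, min(len(ids) - 1, round(ratio * len(ids))))
    splits: List[FoldSplit] = []
    uncovered = set(ids)
    for run in range(max_runs):
        perm = list(rng.permutation(ids))
        splits.append(FoldSplit(run=run, train=tuple(perm[:n_train]),
                                validation=tuple(perm[n_train:]), seed=seed))
        uncovered -= set(perm[n_train:])
        if not uncovered:
            return splits
    raise RuntimeError(
        f"validation coverage not achieved within {max_runs} runs; "
        f"uncovered subjects: {sorted(uncovered)}")


def mean_foreground_dsc(pred: LabelMap, gt: LabelMap) -> float:
    """Unweighted mean DSC over foreground labels present in the GT."""
    vals = []
    for lid in range(1, gt.scheme.num_classes):
        if (gt.data == lid).any():
            vals.append(dsc(MaskPair(pred.data == lid, gt.data == lid,
                                     spacing=gt.spacing)))
    if not vals:
        raise ValueError("ground truth has no foreground labels")
    return float(np.mean(vals))


def gate_for_refinement(subject_dsc: Dict[str, float],
                        threshold: float = 0.7) -> List[str]:
    """Subjects whose mean DSC meets the gate (inclusive at the boundary)."""
    retained = [sid for sid, val in subject_dsc.items() if val >= threshold]
    if not retained:
        logger.warning(
            "refinement gate retained no subjects (all mean DSC < %.2f)",
            threshold)
    return retained


def majority_vote(ensemble: EnsembleSet) -> LabelMap:
    """Per-voxel fusion: class kept iff its vote fraction strictly
    exceeds the threshold, otherwise background.

    With threshold 0.5 at most one class can qualify per voxel, so the
    rule is well defined; for lower thresholds the qualifying class with
    the most votes wins (ties -> lowest class id).
    """
    preds = ensemble.predictions
    stack = np.stack([p.data for p in preds])
    m = len(preds)
    num_classes = preds[0].scheme.num_classes
    counts = np.zeros((num_classes,) + preds[0].data.shape, dtype=np.int16)
    for c in range(num_classes):
        counts[c] = (stack == c).sum(axis=0)
    counts[0] = 0                       # background never "wins" a vote
    best = counts.argmax(axis=0)        # ties -> lowest class id
    frac = np.take_along_axis(counts, best[None], axis=0)[0] / m
    out = np.where(frac > ensemble.threshold, best, 0).astype(np.uint8)
    return preds[0].replace(data=out)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for the cascade training run (implementation
    choices; the study's full-resolution settings are not published)."""

    epochs_principal: int = 10
    epochs_refinement: int = 6
    lr: float = 5e-3
    gate_threshold: float = 0.7
    vote_threshold: float = 0.5
    boundary_w_max: float = 5.0
    boundary_tau: float = 2.0
    ce_weight: float = 0.5
    ce_fg_weight: float = 10.0
    split_ratio: float = 0.8
    max_runs: int = 20
    n_folds: Optional[int] = 3       # cap on MC runs actually trained
    seed: int = 0
    use_refinement: bool = True
    normalize: bool = True


@dataclass
class FoldResult:
    split: FoldSplit
    principal: PrincipalNet
    refinement: Optional[RefinementNet]
    loss_history: List[float]
    refinement_loss_history: List[float]
    validation_dsc: Dict[str, float]
    retained: List[str]


@dataclass
class TrainResult:
    folds: List[FoldResult]
    net_cfg: NetworkConfig
    train_cfg: TrainConfig
    logs: List[dict] = field(default_factory=list)


def _prep_image(vol: Volume, normalize: bool) -> np.ndarray:
    if normalize:
        vol = normalize_intensity(vol)
    return np.asarray(vol.data, dtype=np.float32)


def _train_principal(net: PrincipalNet, samples, cfg: TrainConfig,
                     net_cfg: NetworkConfig, logs: List[dict],
                     fold: int) -> List[float]:
    opt = Adam(net.parameters(), lr=cfg.lr)
    history = []
    for epoch in range(cfg.epochs_principal):
        total = 0.0
        for img, target in samples:
            toh = one_hot(target, net_cfg.num_classes)
            taux = one_hot(downsample_labels(target), net_cfg.num_classes)
            opt.zero_grad()
            main, aux = net(Tensor(img[None]))
            l_main = combined_loss(softmax_channels(main), toh,
                                   ce_weight=cfg.ce_weight,
                                   ce_fg_weight=cfg.ce_fg_weight)
            l_aux = (combined_loss(softmax_channels(aux), taux,
                                   ce_weight=cfg.ce_weight,
                                   ce_fg_weight=cfg.ce_fg_weight)
                     if aux is not None else None)
            loss = deep_supervision_loss(l_main, l_aux,
                                         net_cfg.aux_loss_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"principal training diverged (non-finite loss) at "
                    f"fold {fold}, epoch {epoch}")
            loss.backward()
            opt.step()
            total += float(loss.data)
        mean_loss = total / len(samples)
        history.append(mean_loss)
        logs.append({"stage": "principal", "fold": fold, "epoch": epoch,
                     "loss": mean_loss})
        logger.info("fold %d principal epoch %d loss %.4f",
                    fold, epoch, mean_loss)
    return history


def _train_refinement(net: RefinementNet, samples, cfg: TrainConfig,
                      net_cfg: NetworkConfig, logs: List[dict],
                      fold: int) -> List[float]:
    opt = Adam(net.parameters(), lr=cfg.lr)
    history = []
    for epoch in range(cfg.epochs_refinement):
        total = 0.0
        for img, probs, target in samples:
            toh = one_hot(target, net_cfg.num_classes)
            wmap = boundary_weight_map(target, cfg.boundary_w_max,
                                       cfg.boundary_tau)
            opt.zero_grad()
            x = Tensor(np.concatenate([img[None], probs], axis=0))
            scores = net(x)
            loss = combined_loss(softmax_channels(scores), toh,
                                 weights=wmap, ce_weight=cfg.ce_weight,
                                 ce_fg_weight=cfg.ce_fg_weight)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"refinement training diverged (non-finite loss) at "
                    f"fold {fold}, epoch {epoch}")
            loss.backward()
            opt.step()
            total += float(loss.data)
        mean_loss = total / len(samples)
        history.append(mean_loss)
        logs.append({"stage": "refinement", "fold": fold, "epoch": epoch,
                     "loss": mean_loss})
        logger.info("fold %d refinement epoch %d loss %.4f",
                    fold, epoch, mean_loss)
    return history


def run_training(cohort: Sequence[PhantomSubject],
                 net_cfg: Optional[NetworkConfig] = None,
                 train_cfg: Optional[TrainConfig] = None,
                 out_dir: Optional[Path] = None) -> TrainResult:
    """Train the full cascade on a cohort with union ground truths.

    Per Monte Carlo fold: train the principal network, predict the
    validation subjects, gate by mean DSC, and train the refinement
    network on the retained (image, prediction) pairs against the union
    GT with a boundary-weighted Dice loss.
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    from .labels import merge_union_gt

    by_id = {s.subject_id: s for s in cohort}
    targets: Dict[str, np.ndarray] = {}
    images: Dict[str, np.ndarray] = {}
    for s in cohort:
        merged, _ = merge_union_gt(s.reader1, s.reader2)
        targets[s.subject_id] = merged.data
        images[s.subject_id] = _prep_image(s.volume, train_cfg.normalize)

    splits = make_mc_splits(sorted(by_id), ratio=train_cfg.split_ratio,
                            seed=train_cfg.seed, max_runs=train_cfg.max_runs)
    if train_cfg.n_folds is not None:
        splits = splits[:train_cfg.n_folds]

    logs: List[dict] = []
    folds: List[FoldResult] = []
    for split in splits:
        t0 = time.time()
        pnet = PrincipalNet(dataclasses.replace(
            net_cfg, seed=net_cfg.seed + split.run))
        samples = [(images[sid], targets[sid]) for sid in split.train]
        history = _train_principal(pnet, samples, train_cfg, net_cfg, logs,
                                   split.run)

        val_dsc: Dict[str, float] = {}
        val_probs: Dict[str, np.ndarray] = {}
        scheme = cohort[0].gt.scheme
        for sid in split.validation:
            probs = pnet.predict_probs(images[sid])
            val_probs[sid] = probs
            pred = LabelMap(probs.argmax(axis=0).astype(np.uint8),
                            spacing=by_id[sid].gt.spacing, scheme=scheme)
            gt_map = by_id[sid].gt.replace(data=targets[sid])
            val_dsc[sid] = mean_foreground_dsc(pred, gt_map)

        retained = gate_for_refinement(val_dsc, train_cfg.gate_threshold)
        rnet = None
        rhistory: List[float] = []
        if train_cfg.use_refinement and retained:
            rnet = RefinementNet(dataclasses.replace(
                net_cfg, in_channels=1 + net_cfg.num_classes,
                seed=net_cfg.seed + split.run))
            rsamples = [(images[sid], val_probs[sid], targets[sid])
                        for sid in retained]
            rhistory = _train_refinement(rnet, rsamples, train_cfg, net_cfg,
                                         logs, split.run)

        folds.append(FoldResult(split, pnet, rnet, history, rhistory,
                                val_dsc, retained))
        logger.info("fold %d done in %.1fs (retained %d/%d)", split.run,
                    time.time() - t0, len(retained), len(split.validation))

    result = TrainResult(folds, net_cfg, train_cfg, logs)
    if out_dir is not None:
        _save_run(result, Path(out_dir))
    return result


def _save_run(result: TrainResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    folds_meta = []
    for fr in result.folds:
        np.savez(out_dir / f"fold{fr.split.run}_principal.npz",
                 **fr.principal.state_dict())
        if fr.refinement is not None:
            np.savez(out_dir / f"fold{fr.split.run}_refinement.npz",
                     **fr.refinement.state_dict())
        folds_meta.append({
            "run": fr.split.run, "train": list(fr.split.train),
            "validation": list(fr.split.validation),
            "validation_dsc": fr.validation_dsc, "retained": fr.retained,
        })
    (out_dir / "folds.json").write_text(json.dumps(folds_meta, indent=2))
    (out_dir / "config.json").write_text(json.dumps({
        "network": dataclasses.asdict(result.net_cfg),
        "training": dataclasses.asdict(result.train_cfg),
    }, indent=2))
    import csv
    with open(out_dir / "loss_log.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["stage", "fold", "epoch",
                                                "loss"])
        writer.writeheader()
        writer.writerows(result.logs)


def predict_cascade(result: TrainResult, volume: Volume,
                    pp_cfg: Optional[PostprocessConfig] = None,
                    apply_postprocess: bool = True,
                    scheme=DEFAULT_SCHEME) -> LabelMap:
    """Full inference: per-fold principal -> refinement, majority vote
    across folds, then anatomical post-processing."""
    img = _prep_image(volume, result.train_cfg.normalize)
    preds = []
    for fr in result.folds:
        probs = fr.principal.predict_probs(img)
        if fr.refinement is not None:
            probs = fr.refinement.predict_probs(img, probs)
        preds.append(LabelMap(probs.argmax(axis=0).astype(np.uint8),
                              spacing=volume.spacing, scheme=scheme,
                              subject_id=volume.subject_id))
    voted = majority_vote(EnsembleSet(preds,
                                      result.train_cfg.vote_threshold))
    if not apply_postprocess:
        return voted
    out, _ = postprocess(voted, pp_cfg or PostprocessConfig())
    return out
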