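"""End-to-end experiment pipeline: simulate -> preprocess -> (pretrain) ->
train -> evaluate -> explain -> report.

One :class:`RunConfig` drives every stage; all randomness fans out from its
master seed, and the written ``manifest.json`` is sufficient to reproduce a
run bit-for-bit.  The pipeline operates on an in-memory phantom cohort and
writes per-fold predictions, the operating-point metrics, the rater /
augmented-rater comparison (with paired bootstrap significance), the kappa
table, and saliency localization scores for example cases.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    TARGET_SENSITIVITY,
    augment_ratings,
    bootstrap_wilcoxon,
    calibrate_to_sensitivity,
    cohens_kappa,
    confusion_metrics,
    ratings_to_calls,
    roc_auc,
    threshold_scores,
    youden_threshold,
)
from .model import EncoderConfig, build_cae, build_classifier
from .preprocess import VolumeStandardizer
from .synthetic import PhantomConfig, RaterModel, generate_cohort, generate_raters
from .training import (
    SplitPlan,
    TrainConfig,
    make_splits,
    predict_scores,
    pretrain_cae,
    train_classifier,
)
from .xai import localization_score, smoothgrad, threshold_heatmap

PRESETS: dict[str, dict] = {
    # a couple of minutes on one CPU; exercises every stage
    "smoke": dict(
        phantom=dict(shape=(32, 32, 16), n_labeled=24, n_unlabeled=8),
        encoder=dict(stages=2, channels=(4, 8), fc=(8, 4), dropout=0.0,
                     input_pool=(4, 4, 2)),
        train=dict(epochs=4, batch_size=4),
        pretrain_epochs=2, n_explain=2, bootstrap_m=50, bootstrap_n=24,
    ),
    # the package's standard desk-scale study
    "desk": dict(
        phantom=dict(shape=(64, 64, 32), n_labeled=200, n_unlabeled=60),
        encoder=dict(stages=2, channels=(6, 12), fc=(16, 8), dropout=0.0,
                     input_pool=(8, 8, 4)),
        train=dict(epochs=25, batch_size=5),
        pretrain_epochs=5, n_explain=5, bootstrap_m=200, bootstrap_n=200,
    ),
    # clinical-scale shapes (192x192x50), for architecture checks only
    "clinical-shape": dict(
        phantom=dict(shape=(192, 192, 50), n_labeled=4, n_unlabeled=2),
        encoder=dict(stages=5, channels=(8, 16, 32, 64, 128), fc=(64, 16),
                     dropout=0.25, input_pool=None),
        train=dict(epochs=1, batch_size=2),
        pretrain_epochs=0, n_explain=1, bootstrap_m=50, bootstrap_n=4,
    ),
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; JSON-serializable for the manifest."""

    seed: int = 0
    preset: str = "desk"
    equivariant: bool = True
    pretrain: bool = False
    alpha: float = 1.0
    target_sensitivity: float = TARGET_SENSITIVITY
    significance_level: float = 0.05
    n_folds: int = 4
    ratios: tuple[float, float, float] = (0.56, 0.19, 0.25)
    stratify: bool = True
    raters: dict = field(default_factory=lambda: {
        "senior1": dict(sensitivity=0.44, specificity=0.88, indeterminable_rate=0.09),
        "senior2": dict(sensitivity=0.42, specificity=0.86, indeterminable_rate=0.09),
        "junior1": dict(sensitivity=0.34, specificity=0.90, indeterminable_rate=0.20),
        "junior2": dict(sensitivity=0.38, specificity=0.86, indeterminable_rate=0.20),
    })
    heatmap_threshold: float = 0.3
    overrides: dict = field(default_factory=dict)

    def resolve(self) -> dict:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        cfg = json.loads(json.dumps(PRESETS[self.preset]))
        for key, val in self.overrides.items():
            section, _, name = key.partition(".")
            if name:
                cfg.setdefault(section, {})[name] = val
            else:
                cfg[key] = val
        return cfg


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path, quiet: bool = False) -> dict:
    """Execute the full pipeline; returns the results dict it also writes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.resolve()
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ("phantom", "split", "train", "raters", "bootstrap", "xai"),
                 ss.spawn(6))}
    log_path = out / "run.log.jsonl"
    t_start = time.time()

    def log(stage: str, **info):
        rec = {"stage": stage, "t": round(time.time() - t_start, 2), **_jsonable(info)}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
        if not quiet:
            print(f"[{rec['t']:8.1f}s] {stage} " +
                  " ".join(f"{k}={v}" for k, v in info.items()))

    # -- simulate -----------------------------------------------------------
    phantom_cfg = PhantomConfig(**cfg["phantom"], seed=seeds["phantom"])
    cohort = generate_cohort(phantom_cfg)
    lab = cohort.labeled_index
    X = cohort.volumes[lab]
    y = cohort.labels
    ids = cohort.table["patient_id"].to_numpy()[lab]
    contrasts = cohort.table["flair_lesion_contrast"].to_numpy()[lab]
    log("simulate", n_labeled=len(lab), n_unlabeled=len(cohort.table) - len(lab),
        prevalence=float(y.mean()))

    # -- pretrain (optional) ------------------------------------------------
    encoder_state = None
    enc_cfg = EncoderConfig(**cfg["encoder"], equivariant=config.equivariant)
    if config.pretrain and cfg["pretrain_epochs"] > 0:
        std_all = VolumeStandardizer().fit(cohort.volumes)
        cae = build_cae(enc_cfg, X.shape[2:], seed=seeds["train"])
        tc = TrainConfig(**cfg["train"], class_weighted=False)
        tc.epochs = cfg["pretrain_epochs"]
        hist = pretrain_cae(cae, std_all.transform(cohort.volumes), tc,
                            seed=seeds["train"])
        encoder_state = cae.state_dict()
        log("pretrain", n=cohort.volumes.shape[0],
            final_mse=hist["train_loss"][-1])

    # -- cross-validated training -------------------------------------------
    plan: SplitPlan = make_splits(np.arange(len(y)), seed=seeds["split"],
                                  ratios=config.ratios, n_folds=config.n_folds,
                                  labels=y, stratify=config.stratify)
    pred_rows = []
    fold_aucs = []
    fold_nets = []
    for f, fold in enumerate(plan):
        tr, va, te = fold["train"], fold["val"], fold["test"]
        std = VolumeStandardizer().fit(X[tr])
        net = build_classifier(enc_cfg, X.shape[2:], seed=seeds["train"] + f)
        if encoder_state is not None:
            from .model import load_encoder
            load_encoder(net, encoder_state)
        tc = TrainConfig(**cfg["train"], alpha=config.alpha)
        train_classifier(net, std.transform(X[tr]), y[tr], tc,
                         X_val=std.transform(X[va]), y_val=y[va],
                         seed=seeds["train"] + 100 + f)
        val_scores = predict_scores(net, std.transform(X[va]))
        test_scores = predict_scores(net, std.transform(X[te]))
        thr_youden = youden_threshold(val_scores, y[va])
        thr_calib = calibrate_to_sensitivity(val_scores, y[va],
                                             config.target_sensitivity)
        auc = roc_auc(test_scores, y[te]) if len(np.unique(y[te])) == 2 else float("nan")
        fold_aucs.append(auc)
        fold_nets.append((net, std, te))
        for i, s in zip(te, test_scores):
            pred_rows.append({"patient_id": ids[i], "fold": f, "score": float(s),
                              "label": int(y[i]),
                              "call_youden": int(s >= thr_youden),
                              "call_calibrated": int(s >= thr_calib)})
        log("train_fold", fold=f, test_auc=auc, thr_youden=thr_youden,
            thr_calibrated=thr_calib)

    preds = pd.DataFrame(pred_rows).sort_values("patient_id").reset_index(drop=True)
    preds.to_csv(out / "predictions.csv", index=False)

    # -- evaluation on the pooled disjoint test sets ------------------------
    order = {pid: k for k, pid in enumerate(preds["patient_id"])}
    test_ids = preds["patient_id"].to_numpy()
    y_test = preds["label"].to_numpy()
    dl_scores = preds["score"].to_numpy()
    dl_calls = preds["call_calibrated"].to_numpy()
    metrics = {
        "dl_auc_mean": float(np.nanmean(fold_aucs)),
        "dl_auc_std": float(np.nanstd(fold_aucs)),
        "dl_auc_pooled": roc_auc(dl_scores, y_test),
        "youden": confusion_metrics(preds["call_youden"], y_test).to_dict(),
        "calibrated": confusion_metrics(dl_calls, y_test).to_dict(),
    }

    # synthetic raters on the pooled test patients
    idx_test = np.array([np.flatnonzero(ids == pid)[0] for pid in test_ids])
    rater_rows, kappa_rows, rating_frames = [], [], []
    rater_calls = {}
    for k, (name, rparams) in enumerate(sorted(config.raters.items())):
        rm = RaterModel(**rparams, seed=seeds["raters"] + k)
        ratings = generate_raters(y_test, contrasts[idx_test], rm,
                                  patient_ids=test_ids, rater_id=name)
        rating_frames.append(ratings)
        r = ratings["rating"].to_numpy()
        plain_calls = ratings_to_calls(r)
        aug_calls = augment_ratings(r, dl_calls)
        rater_calls[name] = plain_calls
        rater_calls[f"{name} + DL"] = aug_calls
        boot = bootstrap_wilcoxon(aug_calls, plain_calls, y_test,
                                  metric="balanced_accuracy",
                                  n_subset=cfg["bootstrap_n"], m_init=cfg["bootstrap_m"],
                                  alpha_level=config.significance_level,
                                  seed=seeds["bootstrap"] + k)
        rater_rows.append({"rater": name, **confusion_metrics(plain_calls, y_test).to_dict()})
        rater_rows.append({"rater": f"{name} + DL",
                           **confusion_metrics(aug_calls, y_test).to_dict(),
                           "p_vs_human": boot.p_value, "significant": boot.significant,
                           "bootstrap_m": boot.m})
        log("evaluate_rater", rater=name, p=boot.p_value, m=boot.m)
    pd.concat(rating_frames).to_csv(out / "ratings.csv", index=False)
    rater_table = pd.DataFrame(rater_rows).drop(columns=["threshold", "auc"])
    rater_table.to_csv(out / "rater_table.csv", index=False)

    names = sorted(rater_calls)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            kappa_rows.append({"rater_a": a, "rater_b": b,
                               "kappa": cohens_kappa(rater_calls[a], rater_calls[b])})
    kappa_table = pd.DataFrame(kappa_rows)
    kappa_table.to_csv(out / "kappa_table.csv", index=False)

    # -- explain ------------------------------------------------------------
    xai_rows = []
    best_fold = int(np.nanargmax(fold_aucs))
    net, std, te = fold_nets[best_fold]
    lesioned = [i for i in te if cohort.lesion_masks[lab[i]].any()][:cfg["n_explain"]]
    for i in lesioned:
        xin = std.transform(X[[i]])[0]
        sal = smoothgrad(net, xin, n=8, sigma=0.1, seed=seeds["xai"] + int(i))
        mask = threshold_heatmap(sal, config.heatmap_threshold)
        rep = localization_score(mask[0], mask[1], cohort.lesion_masks[lab[i]])
        xai_rows.append({"patient_id": ids[i], **asdict(rep)})
        log("explain", patient=ids[i], well_localized=rep.well_localized)
    xai_table = pd.DataFrame(xai_rows)
    xai_table.to_csv(out / "xai_localization.csv", index=False)
    if len(xai_table):
        metrics["xai_well_localized_rate"] = float(xai_table["well_localized"].mean())

    # -- report + manifest --------------------------------------------------
    with open(out / "metrics.json", "w") as fh:
        json.dump(_jsonable(metrics), fh, indent=2)
    manifest = {
        "version": __version__,
        "config": _jsonable(asdict(config)),
        "resolved_preset": _jsonable(cfg),
        "seeds": seeds,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log("done")
    return {"metrics": metrics, "predictions": preds, "rater_table": rater_table,
            "kappa_table": kappa_table, "xai": xai_table, "manifest": manifest}


def run_from_manifest(manifest_path, out_dir) -> dict:
    """Reproduce a run from its manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    c = manifest["config"]
    c["ratios"] = tuple(c["ratios"])
    config = RunConfig(**c)
    return run_pipeline(config, out_dir, quiet=True)
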