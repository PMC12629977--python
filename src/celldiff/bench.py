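"""End-to-end evaluation harness.

Implements the four evaluation protocols — in-domain classification,
anomaly detection with a held-out class, domain shift, and low-data
training — on the synthetic cytology benchmark, plus a small discriminative
softmax baseline for comparison.  Protocol hygiene (split disjointness,
held-out exclusion from training and calibration, confidence calibration
frozen before test) is enforced by assertions, not conventions: a
violation raises :class:`ProtocolViolation`.

Every run reports the seeds and a hash of its configuration so results
are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .anomaly import ProfileScorer, anomaly_metrics, error_table, kde_report, normalize_scores
from .classifier import ConfidenceCalibrator, DiffusionClassifier
from .denoiser import TrainConfig, train_denoiser
from .diffusion import ClassConditioning, IdentityCodec, build_schedule
from .metrics import SplitPlan, compute_metrics, split_manifest
from .psychometrics import logit_gap_confidence
from .rng import child_seed
from .synthetic import (
    DOMAIN_PRESETS,
    ClassSpec,
    DomainSpec,
    anomalous_class_spec,
    default_class_specs,
    generate_arrays,
)

__all__ = [
    "ProtocolViolation",
    "BenchmarkConfig",
    "TrainedSystem",
    "build_benchmark_data",
    "train_system",
    "run_in_domain",
    "run_anomaly",
    "run_domain_shift",
    "run_low_data",
    "train_discriminative_baseline",
    "BaselineClassifier",
]

logger = logging.getLogger(__name__)


class ProtocolViolation(RuntimeError):
    """An evaluation-protocol audit failed (leakage, overlap, ordering)."""


@dataclass(frozen=True)
class BenchmarkConfig:
    """Synthetic benchmark settings (desk-scale defaults).

    ``n_pool`` images per class are generated and split 70-10-20; the
    anomalous held-out class never enters the pool.  All component seeds
    derive from ``seed``.
    """

    seed: int = 0
    n_pool: int = 300  # per class -> 210 train / 30 val / 60 test
    img_size: int = 32
    T: int = 400
    schedule_kind: str = "linear"
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        steps=4000, arch="conv", low_t_frac=0.5))
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    # classifier settings
    p_threshold: float = 2e-3
    min_evals: int = 20
    max_iters: int = 2000
    t_range: tuple[int, int] | None = None
    wt_scheme: str = "inverse_mean"  # or "uniform"
    # anomaly settings
    holdout_class: str = "erythroblastoid"
    anomaly_iters: int = 200
    anomaly_strategy: str = "profile"  # or "min_error"
    n_anomaly_eval: int = 50  # images per group scored in run_anomaly
    anomaly_cal_per_class: int = 20  # validation images per class for the scorer
    conf_cal_per_class: int = 10  # validation images per class for the calibrator
    # domain shift / low data
    shift_domains: tuple[str, ...] = ("shifted",)
    n_reps: int = 5
    low_data_sizes: tuple[int, ...] = (10, 20, 50)
    low_data_reps: int = 5

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["train"] = self.train.to_dict()
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _specs_by_name() -> dict[str, ClassSpec]:
    specs = default_class_specs() + [anomalous_class_spec()]
    return {s.name: s for s in specs}


def build_benchmark_data(cfg: BenchmarkConfig, domain: DomainSpec | None = None,
                         pool_tag: str = "pool") -> dict:
    """Generate the class-stratified pool and its 70-10-20 split.

    Returns images, manifest (with split column re-joined) and the three
    split index arrays; asserts the split partitions the pool.
    """
    specs = default_class_specs()
    X, labels, sids = generate_arrays(
        specs, cfg.n_pool, domain=domain, seed=child_seed(cfg.seed, pool_tag),
        img_size=cfg.img_size)
    manifest = pd.DataFrame({"label": labels, "source_id": sids})
    plan = SplitPlan(*cfg.split, stratify_by_label=True,
                     seed=child_seed(cfg.seed, pool_tag, "split"))
    manifest = manifest.reset_index().rename(columns={"index": "row"})
    tr, va, te = split_manifest(manifest, plan)
    parts = {"train": tr, "val": va, "test": te}
    all_ids = [sid for p in parts.values() for sid in p["source_id"]]
    if len(all_ids) != len(manifest) or len(set(all_ids)) != len(manifest):
        raise ProtocolViolation("splits do not partition the pool")
    return {
        "specs": specs,
        "images": X,
        "manifest": manifest,
        "splits": {k: v for k, v in parts.items()},
        "index": {k: v["row"].to_numpy() for k, v in parts.items()},
    }


@dataclass
class TrainedSystem:
    """A trained denoiser bundled into a ready-to-use classifier."""

    classifier: DiffusionClassifier
    history: dict
    train_source_ids: set[str]
    calibration_source_ids: set[str] = field(default_factory=set)
    anomaly_scorer: ProfileScorer | None = None

    @property
    def class_names(self) -> list[str]:
        return self.classifier.conditioning.class_names


def train_system(
    cfg: BenchmarkConfig,
    images: np.ndarray,
    labels,
    source_ids=None,
    val_images: np.ndarray | None = None,
    val_labels=None,
    class_names: list[str] | None = None,
    train_config: TrainConfig | None = None,
) -> TrainedSystem:
    """Train the denoiser and assemble the classifier.

    If a validation set is given, the per-timestep weights w_t and the
    confidence calibrator are fitted on it and frozen (calibration before
    test); with ``anomaly_strategy='profile'`` the normality scorer is
    fitted there too.
    """
    class_names = sorted(set(labels)) if class_names is None else list(class_names)
    schedule = build_schedule(cfg.T, cfg.schedule_kind)
    conditioning = ClassConditioning(class_names)
    codec = IdentityCodec((cfg.img_size, cfg.img_size, 3))
    tconf = train_config if train_config is not None else dataclasses.replace(
        cfg.train, seed=child_seed(cfg.seed, "train"))
    model, history = train_denoiser(images, list(labels), codec, schedule,
                                    conditioning, tconf)
    clf = DiffusionClassifier(model, schedule, conditioning, codec,
                              t_range=cfg.t_range)
    system = TrainedSystem(
        classifier=clf, history=history,
        train_source_ids=set(source_ids) if source_ids is not None else set(),
    )
    if val_images is not None and len(val_images):
        if cfg.wt_scheme == "inverse_mean":
            clf.fit_timestep_weights(val_images, seed=child_seed(cfg.seed, "wt"))
        if val_labels is not None:
            vl_all = np.asarray(list(val_labels))
            cal_keep = np.concatenate([
                np.flatnonzero(vl_all == c)[:cfg.conf_cal_per_class]
                for c in class_names if np.any(vl_all == c)])
            cal_images = np.asarray(val_images)[cal_keep]
        else:
            cal_images = val_images
        val_results = clf.classify_batch(cal_images, mode="eliminate",
                                         seed=child_seed(cfg.seed, "cal"),
                                         p_threshold=cfg.p_threshold,
                                         min_evals=cfg.min_evals,
                                         max_iters=cfg.max_iters)
        clf.calibrator = ConfidenceCalibrator.fit(
            [r.confidence_raw for r in val_results])
        if cfg.anomaly_strategy == "profile" and val_labels is not None:
            # stratified cap keeps the calibration pass cheap
            vl = np.asarray(list(val_labels))
            keep = np.concatenate([
                np.flatnonzero(vl == c)[:cfg.anomaly_cal_per_class]
                for c in class_names])
            errs = error_table(clf, np.asarray(val_images)[keep],
                               n_iters=cfg.anomaly_iters,
                               seed=child_seed(cfg.seed, "anomaly_cal"))
            system.anomaly_scorer = ProfileScorer().fit(errs, vl[keep],
                                                        class_names)
    return system


def _classify_split(system: TrainedSystem, cfg: BenchmarkConfig,
                    images: np.ndarray, seed_tag: str):
    return system.classifier.classify_batch(
        images, mode="eliminate", seed=child_seed(cfg.seed, seed_tag),
        p_threshold=cfg.p_threshold, min_evals=cfg.min_evals,
        max_iters=cfg.max_iters)


def _write_json(payload: dict, out_dir, name: str) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / name).write_text(json.dumps(payload, indent=2, default=float))


def run_in_domain(cfg: BenchmarkConfig, out_dir=None,
                  system: TrainedSystem | None = None,
                  data: dict | None = None) -> dict:
    """Train on the 70% split, calibrate on 10%, classify the 20% test split."""
    data = build_benchmark_data(cfg) if data is None else data
    idx = data["index"]
    X, man = data["images"], data["manifest"]
    if system is None:
        system = train_system(
            cfg, X[idx["train"]], man["label"].iloc[idx["train"]],
            source_ids=man["source_id"].iloc[idx["train"]],
            val_images=X[idx["val"]], val_labels=man["label"].iloc[idx["val"]],
            class_names=sorted(man["label"].unique()),
        )
        system.calibration_source_ids = set(man["source_id"].iloc[idx["val"]])
    test_ids = set(man["source_id"].iloc[idx["test"]])
    if system.train_source_ids & test_ids or system.calibration_source_ids & test_ids:
        raise ProtocolViolation("test images overlap train or calibration sets")
    results = _classify_split(system, cfg, X[idx["test"]], "test")
    truth = list(man["label"].iloc[idx["test"]])
    report = compute_metrics(truth, [r.predicted for r in results],
                             classes=system.class_names)
    payload = {
        "protocol": "in_domain",
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "metrics": report.to_dict(),
        "mean_iterations": float(np.mean([r.total_iterations for r in results])),
        "per_image": [
            {"source_id": sid, "truth": t, **r.to_dict()}
            for sid, t, r in zip(man["source_id"].iloc[idx["test"]], truth, results)
        ],
    }
    _write_json(payload, out_dir, "in_domain.json")
    return {"report": report, "results": results, "truth": truth,
            "system": system, "data": data, "payload": payload}


def run_anomaly(cfg: BenchmarkConfig, out_dir=None,
                system: TrainedSystem | None = None,
                data: dict | None = None, plot_path=None) -> dict:
    """Score in-distribution test images against the held-out class.

    The held-out class must be absent from training and calibration; this
    is checked before any scoring happens.
    """
    data = build_benchmark_data(cfg) if data is None else data
    idx = data["index"]
    X, man = data["images"], data["manifest"]
    train_labels = set(man["label"].iloc[idx["train"]])
    if cfg.holdout_class in train_labels:
        raise ProtocolViolation(
            f"held-out class {cfg.holdout_class!r} present in training manifest")
    if system is None:
        system = train_system(
            cfg, X[idx["train"]], man["label"].iloc[idx["train"]],
            source_ids=man["source_id"].iloc[idx["train"]],
            val_images=X[idx["val"]], val_labels=man["label"].iloc[idx["val"]],
            class_names=sorted(man["label"].unique()),
        )
    if cfg.holdout_class in system.class_names:
        raise ProtocolViolation("held-out class leaked into the conditioning set")

    spec = _specs_by_name()[cfg.holdout_class]
    n_eval = cfg.n_anomaly_eval
    X_ab, _, ab_sids = generate_arrays([spec], n_eval,
                                       seed=child_seed(cfg.seed, "holdout"),
                                       img_size=cfg.img_size)
    if set(ab_sids) & system.train_source_ids:
        raise ProtocolViolation("held-out images overlap the training set")
    # stratified subset of the test split for the normal group
    test_man = man.iloc[idx["test"]]
    per_class = max(1, n_eval // len(system.class_names))
    normal_rows = test_man.groupby("label", group_keys=False).head(per_class)
    X_norm = X[normal_rows["row"].to_numpy()]

    scorer = system.anomaly_scorer if cfg.anomaly_strategy == "profile" else None
    errs_n = error_table(system.classifier, X_norm, n_iters=cfg.anomaly_iters,
                         seed=child_seed(cfg.seed, "an_norm"))
    errs_a = error_table(system.classifier, X_ab, n_iters=cfg.anomaly_iters,
                         seed=child_seed(cfg.seed, "an_abn"))
    if scorer is not None:
        sn = np.array([scorer.raw_score(e) for e in errs_n])
        sa = np.array([scorer.raw_score(e) for e in errs_a])
    else:
        sn, sa = -errs_n.min(axis=1), -errs_a.min(axis=1)
    combined = normalize_scores(np.concatenate([sn, sa]))
    norm_n, norm_a = combined[: len(sn)], combined[len(sn):]
    metrics = anomaly_metrics(norm_n, norm_a)
    kde = kde_report(norm_n, norm_a, plot_path=plot_path)
    payload = {
        "protocol": "anomaly",
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "holdout_class": cfg.holdout_class,
        "strategy": cfg.anomaly_strategy,
        "n_normal": int(len(sn)),
        "n_abnormal": int(len(sa)),
        "metrics": metrics,
        "scores_normal": norm_n.tolist(),
        "scores_abnormal": norm_a.tolist(),
    }
    _write_json(payload, out_dir, "anomaly.json")
    return {"metrics": metrics, "scores_normal": norm_n, "scores_abnormal": norm_a,
            "raw_normal": sn, "raw_abnormal": sa, "kde": kde,
            "system": system, "payload": payload}


def run_domain_shift(cfg: BenchmarkConfig, out_dir=None,
                     zoom_augment: bool = False, n_reps: int | None = None) -> dict:
    """Train on the source domain, evaluate on shifted test domains.

    Shifted-domain images are generated fresh (disjoint source ids,
    audited) and never seen in training.  Repeated ``n_reps`` times with
    distinct seeds; mean and SD per domain are reported.
    """
    n_reps = cfg.n_reps if n_reps is None else n_reps
    per_domain: dict[str, list[float]] = {d: [] for d in ("identity",) + cfg.shift_domains}
    for rep in range(n_reps):
        rep_cfg = dataclasses.replace(cfg, seed=child_seed(cfg.seed, "shift_rep", rep))
        data = build_benchmark_data(rep_cfg)
        idx, X, man = data["index"], data["images"], data["manifest"]
        tconf = dataclasses.replace(
            rep_cfg.train, seed=child_seed(rep_cfg.seed, "train"),
            zoom_augment=(1.0, 2.2) if zoom_augment else None)
        system = train_system(
            rep_cfg, X[idx["train"]], man["label"].iloc[idx["train"]],
            source_ids=man["source_id"].iloc[idx["train"]],
            val_images=X[idx["val"]], val_labels=man["label"].iloc[idx["val"]],
            class_names=sorted(man["label"].unique()), train_config=tconf)
        for dom in per_domain:
            dspec = DOMAIN_PRESETS[dom]
            Xs, ys, sids = generate_arrays(
                data["specs"], max(2, rep_cfg.n_pool // 10), domain=dspec,
                seed=child_seed(rep_cfg.seed, "shift_eval", dom),
                img_size=rep_cfg.img_size, domain_name=dom)
            if set(sids) & system.train_source_ids:
                raise ProtocolViolation("shifted test images overlap training set")
            res = _classify_split(system, rep_cfg, Xs, f"shift_{dom}")
            rep_report = compute_metrics(ys, [r.predicted for r in res],
                                         classes=system.class_names)
            per_domain[dom].append(rep_report.balanced_accuracy)
    summary = {d: {"mean_balanced_accuracy": float(np.mean(v)),
                   "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                   "reps": v}
               for d, v in per_domain.items()}
    payload = {"protocol": "domain_shift", "seed": cfg.seed,
               "config_hash": cfg.config_hash(), "zoom_augment": zoom_augment,
               "domains": summary}
    _write_json(payload, out_dir, "domain_shift.json")
    return {"summary": summary, "payload": payload}


def run_low_data(cfg: BenchmarkConfig, out_dir=None,
                 sizes: tuple[int, ...] | None = None,
                 n_reps: int | None = None,
                 eval_per_class: int = 20) -> dict:
    """Low-data protocol: subset sizes x repetitions, checkpoint selection.

    Each repetition resamples a fresh training subset per class, trains
    with periodic parameter snapshots, selects the snapshot with the best
    validation accuracy, and evaluates on the common test split.
    """
    sizes = cfg.low_data_sizes if sizes is None else tuple(sizes)
    n_reps = cfg.low_data_reps if n_reps is None else n_reps
    data = build_benchmark_data(cfg)
    idx, X, man = data["index"], data["images"], data["manifest"]
    class_names = sorted(man["label"].unique())
    train_man = man.iloc[idx["train"]]
    max_avail = train_man.groupby("label").size().min()
    if max(sizes) > max_avail:
        raise ValueError(f"subset size {max(sizes)} exceeds available {max_avail} per class")
    test_rows = (man.iloc[idx["test"]].groupby("label", group_keys=False)
                 .head(eval_per_class))
    X_test, y_test = X[test_rows["row"].to_numpy()], list(test_rows["label"])
    val_rows = man.iloc[idx["val"]].groupby("label", group_keys=False).head(eval_per_class)
    X_val, y_val = X[val_rows["row"].to_numpy()], list(val_rows["label"])

    table = np.zeros((len(sizes), n_reps))
    subset_ids: dict[tuple[int, int], set] = {}
    for rep in range(n_reps):
        for si, size in enumerate(sizes):
            rng_seed = child_seed(cfg.seed, "lowdata", rep, size)
            rows = (train_man.sample(frac=1.0, random_state=rng_seed % (2**32))
                    .groupby("label", group_keys=False).head(size))
            subset_ids[(si, rep)] = set(rows["source_id"])
            tconf = dataclasses.replace(
                cfg.train, seed=rng_seed,
                checkpoint_every=max(1, cfg.train.steps // 4))
            rep_cfg = dataclasses.replace(cfg, seed=rng_seed)
            system = train_system(
                rep_cfg, X[rows["row"].to_numpy()], list(rows["label"]),
                source_ids=rows["source_id"], class_names=class_names,
                train_config=tconf)
            # checkpoint selection by validation accuracy
            clf = system.classifier
            best_acc, best_params = -1.0, None
            for step, params in system.history["checkpoints"]:
                clf.model.params = params
                res = clf.classify_batch(X_val, mode="eliminate",
                                         seed=child_seed(rng_seed, "ld_val"),
                                         p_threshold=cfg.p_threshold,
                                         min_evals=cfg.min_evals,
                                         max_iters=cfg.max_iters)
                acc = float(np.mean([r.predicted == t for r, t in zip(res, y_val)]))
                if acc > best_acc:
                    best_acc, best_params = acc, params
            clf.model.params = best_params
            if cfg.wt_scheme == "inverse_mean":
                clf.fit_timestep_weights(X_val, seed=child_seed(rng_seed, "wt"))
            res = clf.classify_batch(X_test, mode="eliminate",
                                     seed=child_seed(rng_seed, "ld_test"),
                                     p_threshold=cfg.p_threshold,
                                     min_evals=cfg.min_evals,
                                     max_iters=cfg.max_iters)
            report = compute_metrics(y_test, [r.predicted for r in res],
                                     classes=class_names)
            table[si, rep] = report.balanced_accuracy
    # resampled subsets must differ across repetitions (protocol audit)
    for si in range(len(sizes)):
        if n_reps > 1 and len({frozenset(subset_ids[(si, r)]) for r in range(n_reps)}) == 1:
            raise ProtocolViolation("low-data subsets identical across repetitions")
    summary = {int(s): {"mean": float(table[i].mean()),
                        "sd": float(table[i].std(ddof=1)) if n_reps > 1 else 0.0,
                        "reps": table[i].tolist()}
               for i, s in enumerate(sizes)}
    payload = {"protocol": "low_data", "seed": cfg.seed,
               "config_hash": cfg.config_hash(), "table": summary}
    _write_json(payload, out_dir, "low_data.json")
    return {"table": table, "sizes": sizes, "summary": summary, "payload": payload}


# ---------------------------------------------------------------------------
# discriminative baseline

class BaselineClassifier:
    """Small softmax (multinomial logistic) classifier on raw pixels.

    Stands in for large pretrained discriminative baselines: exposes
    logits so the confidence, psychometric and anomaly-by-max-logit
    analyses run identically on a discriminative model.
    """

    def __init__(self, model: LogisticRegression, classes: list[str]):
        self._model = model
        self.classes = classes
        self.calibrator: ConfidenceCalibrator | None = None

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        X = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
        z = self._model.decision_function(X)
        if z.ndim == 1:  # binary case: sklearn returns one column
            z = np.stack([-z, z], axis=1) / 2.0
        return z

    def predict(self, images: np.ndarray) -> list[str]:
        return [self.classes[i] for i in np.argmax(self.predict_logits(images), axis=1)]

    def confidence_raw(self, images: np.ndarray) -> np.ndarray:
        return np.array([logit_gap_confidence(z) for z in self.predict_logits(images)])


def train_discriminative_baseline(images: np.ndarray, labels, seed: int = 0,
                                  val_images: np.ndarray | None = None) -> BaselineClassifier:
    """Fit the softmax baseline; calibrates its logit-gap confidence on val."""
    labels = list(labels)
    if len(images) == 0:
        raise ValueError("empty training set")
    classes = sorted(set(labels))
    X = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
    model = LogisticRegression(max_iter=500, random_state=seed % (2**32))
    model.fit(X, labels)
    # sklearn orders classes_ lexicographically for string labels
    baseline = BaselineClassifier(model, list(model.classes_))
    if val_images is not None and len(val_images) >= 2:
        baseline.calibrator = ConfidenceCalibrator.fit(
            baseline.confidence_raw(val_images))
    return baseline
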