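import dataclasses

import numpy as np
import pandas as pd
import pytest

from celldiff.bench import (
    BenchmarkConfig,
    ProtocolViolation,
    TrainedSystem,
    run_anomaly,
    run_domain_shift,
    run_in_domain,
    run_low_data,
    train_discriminative_baseline,
)
from celldiff.classifier import DiffusionClassifier
from celldiff.denoiser import TrainConfig
from celldiff.diffusion import ClassConditioning, IdentityCodec, build_schedule
from celldiff.metrics import SplitPlan, compute_metrics, split_manifest
from celldiff.rng import stream
from helpers import GaussianOptimalStub

# bookkeeping-focused config: model quality is irrelevant, so elimination
# is capped early to keep the protocol runs fast
TINY_CFG = BenchmarkConfig(
    seed=3, n_pool=20, n_anomaly_eval=10, anomaly_iters=20, max_iters=40,
    train=TrainConfig(steps=40, arch="mlp", hidden=16, low_t_frac=0.5))


def _manifest(n=100, labels=("a", "b")):
    rng = stream(1, "man")
    lab = [labels[i % len(labels)] for i in range(n)]
    return pd.DataFrame({"label": lab,
                         "source_id": [f"s{i}" for i in range(n)],
                         "row": np.arange(n)})


class TestSplit:
    def test_counts_70_10_20(self):
        tr, va, te = split_manifest(_manifest(100), SplitPlan(seed=4))
        assert (len(tr), len(va), len(te)) == (70, 10, 20)

    def test_partition_no_duplicates(self):
        man = _manifest(83)
        tr, va, te = split_manifest(man, SplitPlan(seed=2))
        ids = pd.concat([tr, va, te])["source_id"]
        assert sorted(ids) == sorted(man["source_id"])

    def test_stratification_per_class(self):
        tr, va, te = split_manifest(_manifest(100), SplitPlan(seed=0))
        for part, n in ((tr, 35), (va, 5), (te, 10)):
            assert part["label"].value_counts().eq(n).all()

    def test_deterministic_in_seed(self):
        man = _manifest(60)
        a = list(split_manifest(man, SplitPlan(seed=9)))
        b = list(split_manifest(man, SplitPlan(seed=9)))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_too_small_class_raises(self):
        man = _manifest(4, labels=("a", "b"))
        with pytest.raises(ValueError, match="too few"):
            split_manifest(man, SplitPlan(seed=1))

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            SplitPlan(0.5, 0.5, 0.5)


class TestMetrics:
    def test_perfect_two_class(self):
        r = compute_metrics(["a", "b", "a"], ["a", "b", "a"])
        assert r.accuracy == r.balanced_accuracy == r.macro_f1 == 1.0
        assert np.all(r.confusion == np.array([[2, 0], [0, 1]]))

    def test_degenerate_single_prediction(self):
        r = compute_metrics(["a", "b"] * 5, ["a"] * 10, classes=["a", "b"])
        assert r.balanced_accuracy == 0.5

    def test_three_class_hand_example(self):
        truth = ["a"] * 4 + ["b"] * 3 + ["c"] * 3
        pred = ["a", "a", "b", "c", "b", "b", "a", "c", "c", "b"]
        r = compute_metrics(truth, pred, classes=["a", "b", "c"])
        # hand confusion: a:[2,1,1] b:[1,2,0] c:[0,1,2]
        sens = np.array([2 / 4, 2 / 3, 2 / 3])
        prec = np.array([2 / 3, 2 / 4, 2 / 3])
        f1 = 2 * sens * prec / (sens + prec)
        assert abs(r.macro_f1 - f1.mean()) <= 1e-12
        assert abs(r.balanced_accuracy - sens.mean()) <= 1e-12
        assert abs(r.macro_precision - prec.mean()) <= 1e-12
        assert r.accuracy == pytest.approx(0.6)

    def test_row_sums_match_truth_counts(self):
        truth = ["a", "a", "b", "c"]
        r = compute_metrics(truth, ["a", "b", "b", "a"], classes=["a", "b", "c"])
        np.testing.assert_array_equal(r.confusion.sum(axis=1), [2, 1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


def _oracle_system(cfg, data):
    """System whose denoiser is Bayes-optimal for constant-per-class images."""
    class_names = sorted(data["manifest"]["label"].unique())
    sched = build_schedule(cfg.T)
    cond = ClassConditioning(class_names)
    codec = IdentityCodec((cfg.img_size, cfg.img_size, 3))
    means = []
    for c in class_names:
        rows = data["manifest"][data["manifest"]["label"] == c]["row"].to_numpy()
        means.append(codec.encode(data["images"][rows]).mean(axis=0))
    model = GaussianOptimalStub(sched, np.stack(means))
    clf = DiffusionClassifier(model, sched, cond, codec)
    idx = data["index"]
    sys = TrainedSystem(classifier=clf, history={},
                        train_source_ids=set(
                            data["manifest"]["source_id"].iloc[idx["train"]]))
    return sys


@pytest.fixture(scope="module")
def constant_data():
    """Pool whose images are constant per class: separable exactly."""
    from celldiff.bench import build_benchmark_data

    cfg = dataclasses.replace(TINY_CFG, n_pool=20)
    data = build_benchmark_data(cfg)
    labels = data["manifest"]["label"].to_numpy()
    classes = sorted(set(labels))
    X = np.zeros_like(data["images"])
    for i, lab in enumerate(labels):
        X[i] = (classes.index(lab) + 1) / (len(classes) + 1)
    data["images"] = X
    return cfg, data


class TestProtocols:
    def test_oracle_denoiser_scores_perfectly(self, constant_data):
        cfg, data = constant_data
        out = run_in_domain(cfg, system=_oracle_system(cfg, data), data=data)
        assert out["report"].accuracy == 1.0
        assert out["report"].balanced_accuracy == 1.0

    def test_in_domain_payload_reproducible(self, constant_data):
        cfg, data = constant_data
        p1 = run_in_domain(cfg, system=_oracle_system(cfg, data), data=data)["payload"]
        p2 = run_in_domain(cfg, system=_oracle_system(cfg, data), data=data)["payload"]
        assert p1 == p2

    def test_holdout_in_training_pool_rejected_before_training(self):
        cfg = dataclasses.replace(TINY_CFG, holdout_class="neutrophil")
        with pytest.raises(ProtocolViolation, match="held-out"):
            run_anomaly(cfg)

    def test_anomaly_runs_and_reports(self, constant_data):
        cfg, data = constant_data
        sys = _oracle_system(cfg, data)
        # min_error strategy needs no calibration
        cfg2 = dataclasses.replace(cfg, anomaly_strategy="min_error")
        out = run_anomaly(cfg2, system=sys, data=data)
        for key in ("sensitivity", "specificity", "auc", "threshold"):
            assert key in out["metrics"]
        assert out["metrics"]["auc"] >= 0.9  # constant images vs real anomalies

    def test_low_data_bookkeeping(self):
        out = run_low_data(TINY_CFG, sizes=(3, 5), n_reps=2, eval_per_class=3)
        assert out["table"].shape == (2, 2)
        assert set(out["summary"]) == {3, 5}

    def test_domain_shift_summary_structure(self):
        out = run_domain_shift(TINY_CFG, n_reps=1)
        assert set(out["summary"]) == {"identity", "shifted"}
        for v in out["summary"].values():
            assert 0.0 <= v["mean_balanced_accuracy"] <= 1.0


@pytest.fixture(scope="module")
def trained():
    from celldiff.synthetic import default_class_specs, generate_arrays

    specs = default_class_specs()
    Xtr, ytr, _ = generate_arrays(specs, 30, seed=5)
    Xv, _, _ = generate_arrays(specs, 10, seed=6)
    Xte, yte, _ = generate_arrays(specs, 20, seed=7)
    bl = train_discriminative_baseline(Xtr, ytr, seed=1, val_images=Xv)
    return bl, Xte, yte


class TestBaseline:
    def test_competitive_in_domain(self, trained):
        bl, Xte, yte = trained
        report = compute_metrics(yte, bl.predict(Xte), classes=bl.classes)
        assert report.balanced_accuracy >= 0.85

    def test_calibrated_logit_gap_in_unit_interval(self, trained):
        bl, Xte, _ = trained
        conf = bl.calibrator.transform(bl.confidence_raw(Xte))
        assert np.all((conf >= 0) & (conf <= 1))

    def test_deterministic_rerun(self, trained):
        from celldiff.synthetic import default_class_specs, generate_arrays

        bl, Xte, yte = trained
        specs = default_class_specs()
        Xtr, ytr, _ = generate_arrays(specs, 30, seed=5)
        bl2 = train_discriminative_baseline(Xtr, ytr, seed=1)
        assert bl.predict(Xte) == bl2.predict(Xte)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            train_discriminative_baseline(np.empty((0, 2, 2, 3)), [])
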