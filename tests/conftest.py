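import numpy as np
import pytest

from celldiff.bench import BenchmarkConfig, run_in_domain
from celldiff.classifier import DiffusionClassifier
from celldiff.denoiser import TrainConfig, train_denoiser
from celldiff.diffusion import ClassConditioning, IdentityCodec, build_schedule
from celldiff.rng import child_seed
from celldiff.synthetic import default_class_specs, generate_arrays


@pytest.fixture(scope="session")
def bench_cfg() -> BenchmarkConfig:
    """The default synthetic benchmark configuration, seed pinned."""
    return BenchmarkConfig(seed=1)


@pytest.fixture(scope="session")
def benchmark_run(bench_cfg):
    """Full in-domain benchmark run: trains the conv denoiser once per session."""
    return run_in_domain(bench_cfg)


@pytest.fixture(scope="session")
def fast_system():
    """A cheaper trained system (MLP backbone) for algorithmic checks.

    Model quality only needs to make the synthetic task 'easy', not
    state-of-the-art; the MLP trains in well under a minute.
    """
    specs = default_class_specs()
    seed = 11
    Xtr, ytr, _ = generate_arrays(specs, 150, seed=child_seed(seed, "train"))
    Xval, yval, _ = generate_arrays(specs, 30, seed=child_seed(seed, "val"))
    Xte, yte, _ = generate_arrays(specs, 40, seed=child_seed(seed, "test"))
    sched = build_schedule(400)
    cond = ClassConditioning([s.name for s in specs])
    codec = IdentityCodec((32, 32, 3))
    model, _ = train_denoiser(Xtr, ytr, codec, sched, cond,
                              TrainConfig(steps=3000, arch="mlp", low_t_frac=0.5,
                                          seed=seed))
    clf = DiffusionClassifier(model, sched, cond, codec)
    clf.fit_timestep_weights(Xval, seed=child_seed(seed, "wt"))
    return {"classifier": clf, "X_test": Xte, "y_test": yte,
            "X_val": Xval, "y_val": yval, "specs": specs}
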