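import numpy as np
import pandas as pd
import pytest

from celldiff.synthetic import (
    DOMAIN_PRESETS,
    ClassSpec,
    DomainSpec,
    default_class_specs,
    generate_arrays,
    generate_dataset,
    generate_image,
    generate_morph_continuum,
    load_manifest_images,
    make_expert_panel,
)


@pytest.fixture
def spec_a():
    return ClassSpec("alpha", nucleus_lobes=2, nucleus_area_frac=0.4,
                     granule_density=2.0, cytoplasm_hue=200.0, cell_radius_px=10.0)


class TestGenerateImage:
    def test_deterministic_in_all_arguments(self, spec_a):
        s1 = generate_image(spec_a, seed=7)
        s2 = generate_image(spec_a, seed=7)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        assert not np.array_equal(s1.pixels, generate_image(spec_a, seed=8).pixels)

    def test_identical_fields_give_identical_law(self, spec_a):
        clone = ClassSpec("other_name", nucleus_lobes=2, nucleus_area_frac=0.4,
                          granule_density=2.0, cytoplasm_hue=200.0,
                          cell_radius_px=10.0)
        np.testing.assert_array_equal(generate_image(spec_a, seed=3).pixels,
                                      generate_image(clone, seed=3).pixels)

    def test_explicit_identity_domain_matches_default(self, spec_a):
        ident = DomainSpec(hue_shift=0.0, contrast_gain=1.0, blur_sigma=0.0, zoom=1.0)
        np.testing.assert_array_equal(
            generate_image(spec_a, seed=5).pixels,
            generate_image(spec_a, domain=ident, seed=5).pixels)

    def test_zero_granule_density_yields_zero_granules(self):
        spec = ClassSpec("bare", granule_density=0.0)
        for seed in range(5):
            assert generate_image(spec, seed=seed).meta["n_granules"] == 0

    def test_pixels_in_unit_interval(self, spec_a):
        for dom in DOMAIN_PRESETS.values():
            px = generate_image(spec_a, domain=dom, seed=2).pixels
            assert px.shape == (32, 32, 3)
            assert px.min() >= 0.0 and px.max() <= 1.0

    @pytest.mark.parametrize("field,value", [
        ("nucleus_lobes", 0),
        ("nucleus_area_frac", 1.5),
        ("granule_density", -1.0),
        ("cytoplasm_hue", 400.0),
        ("cell_radius_px", -2.0),
        ("jitter", -0.1),
    ])
    def test_invalid_spec_names_offending_field(self, field, value):
        kwargs = {field: value}
        with pytest.raises(ValueError, match=field):
            ClassSpec("bad", **kwargs)

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError, match="zoom"):
            DomainSpec(zoom=0.0)
        with pytest.raises(ValueError, match="contrast_gain"):
            DomainSpec(contrast_gain=-1.0)


class TestDataset:
    def test_empty_dataset_has_header_only(self, tmp_path):
        manifest = generate_dataset(default_class_specs(), 0, out_dir=tmp_path)
        assert len(manifest) == 0
        assert list(manifest.columns) == ["path", "label", "domain", "source_id"]
        assert (tmp_path / "manifest.csv").exists()

    def test_stratification(self, tmp_path):
        manifest = generate_dataset(default_class_specs(), 10, out_dir=tmp_path, seed=4)
        assert len(manifest) == 50
        assert manifest["label"].value_counts().eq(10).all()

    def test_regeneration_is_byte_identical(self, tmp_path):
        specs = default_class_specs()[:2]
        m1 = generate_dataset(specs, 3, out_dir=tmp_path / "a", seed=9)
        m2 = generate_dataset(specs, 3, out_dir=tmp_path / "b", seed=9)
        pd.testing.assert_frame_equal(m1, m2)
        for p in m1["path"]:
            assert (tmp_path / "a" / p).read_bytes() == (tmp_path / "b" / p).read_bytes()

    def test_duplicate_class_names_rejected(self, tmp_path):
        spec = default_class_specs()[0]
        with pytest.raises(ValueError, match="duplicate"):
            generate_dataset([spec, spec], 2, out_dir=tmp_path)

    def test_domain_never_changes_labels(self, tmp_path):
        specs = default_class_specs()[:3]
        base = generate_dataset(specs, 4, out_dir=tmp_path / "i", seed=2)
        shifted = generate_dataset(specs, 4, DOMAIN_PRESETS["shifted"],
                                   out_dir=tmp_path / "s", seed=2,
                                   domain_name="shifted")
        assert list(base["label"]) == list(shifted["label"])

    def test_manifest_roundtrip(self, tmp_path):
        generate_dataset(default_class_specs()[:2], 2, out_dir=tmp_path, seed=1)
        imgs, man = load_manifest_images(tmp_path / "manifest.csv")
        assert imgs.shape == (4, 32, 32, 3)
        # PNG round trip is 8-bit quantised
        direct = generate_image(default_class_specs()[0], seed=man.index[0]).pixels
        assert np.abs(imgs).max() <= 1.0


class TestMorphContinuum:
    def test_signal_one_reproduces_spec_a(self, spec_a):
        spec_b = ClassSpec("beta", nucleus_lobes=1, nucleus_area_frac=0.7,
                           granule_density=0.0, cytoplasm_hue=100.0,
                           cell_radius_px=8.0)
        np.testing.assert_array_equal(
            generate_morph_continuum(spec_a, spec_b, 1.0, seed=6).pixels,
            generate_image(spec_a, seed=6).pixels)

    def test_degenerate_identical_specs(self, spec_a):
        np.testing.assert_array_equal(
            generate_morph_continuum(spec_a, spec_a, 0.0, seed=3).pixels,
            generate_image(spec_a, seed=3).pixels)

    def test_interpolation_arithmetic(self):
        # signal 0.5 -> weight (1+0.5)/2 = 0.75 toward a: 0.75*10 + 0.25*20 = 12.5
        a = ClassSpec("a", cell_radius_px=10.0, jitter=0.0)
        b = ClassSpec("b", cell_radius_px=20.0, jitter=0.0)
        mid = ClassSpec("a", cell_radius_px=12.5, jitter=0.0)
        np.testing.assert_array_equal(
            generate_morph_continuum(a, b, 0.5, seed=1).pixels,
            generate_image(mid, seed=1).pixels)

    def test_signal_bounds(self, spec_a):
        with pytest.raises(ValueError, match="signal"):
            generate_morph_continuum(spec_a, spec_a, 1.2, seed=0)


class TestExpertPanel:
    def _manifest(self, n=30):
        specs = default_class_specs()
        _, labels, sids = generate_arrays(specs, n // 5, seed=3)
        return pd.DataFrame({"path": sids, "label": labels, "source_id": sids})

    def test_infinite_slope_high_signal_is_perfect(self):
        man = self._manifest(30)
        out = make_expert_panel(man, np.ones(len(man)), 1, [np.inf], seed=5)
        assert (out["label_expert_1"] == out["label"]).all()
        assert (out["conf_expert_1"] == "high").all()

    def test_zero_slope_is_chance_level(self):
        specs = default_class_specs()
        _, labels, sids = generate_arrays(specs, 400, seed=8)
        man = pd.DataFrame({"path": sids, "label": labels})
        out = make_expert_panel(man, np.full(len(man), 0.8), 1, [0.0], seed=5)
        acc = (out["label_expert_1"] == out["label"]).mean()
        # binomial tolerance around 1/K = 0.2 at n = 2000
        assert abs(acc - 0.2) < 4 * np.sqrt(0.2 * 0.8 / len(man))

    def test_seeded_panel_is_reproducible(self):
        man = self._manifest(20)
        sig = np.linspace(0, 1, len(man))
        p1 = make_expert_panel(man, sig, 2, [1.0, 3.0], seed=9)
        p2 = make_expert_panel(man, sig, 2, [1.0, 3.0], seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_input_validation(self):
        man = self._manifest(10)
        with pytest.raises(ValueError, match="n_experts"):
            make_expert_panel(man, np.zeros(len(man)), 0, [], seed=0)
        with pytest.raises(ValueError, match="signals"):
            make_expert_panel(man, np.full(len(man), 2.0), 1, [1.0], seed=0)


def test_separability_monotone_in_granule_density_gap():
    """A pixel-histogram nearest-centroid classifier improves as the only
    differing parameter (granule density) moves the classes apart."""
    base = dict(nucleus_lobes=2, nucleus_area_frac=0.4, cytoplasm_hue=200.0,
                cell_radius_px=10.0, jitter=0.05)
    accs = []
    for gap in (0.5, 3.0, 8.0):
        a = ClassSpec("a", granule_density=1.0, **base)
        b = ClassSpec("b", granule_density=1.0 + gap, **base)
        X, y, _ = generate_arrays([a, b], 100, seed=21)

        def hist(img):
            return np.concatenate([np.histogram(img[..., c], bins=16,
                                                range=(0, 1))[0] for c in range(3)])

        H = np.array([hist(im) for im in X], dtype=float)
        y = np.array(y)
        half = 50
        train_idx = np.concatenate([np.arange(half), 100 + np.arange(half)])
        test_idx = np.setdiff1d(np.arange(200), train_idx)
        cents = {c: H[train_idx][y[train_idx] == c].mean(0) for c in ("a", "b")}
        pred = [min(cents, key=lambda c: np.linalg.norm(h - cents[c]))
                for h in H[test_idx]]
        accs.append(np.mean(np.array(pred) == y[test_idx]))
    assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05
    assert accs[2] > 0.9
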