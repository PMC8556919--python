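import numpy as np
import pytest

from specsim.binning import BinnedSpectrum, BinningScheme
from specsim.labels import SimilarityLabelMatrix
from specsim.model import (
    EarlyStopper,
    ModelConfig,
    SiameseModel,
    build_model,
    load_model,
    save_model,
    score_pair,
    split_by_compound,
    train,
)
from specsim.pairs import GeneratorConfig


def mini_scheme(n=20):
    return BinningScheme(n, 10.0, 10.0 + n, known_bins=np.arange(n))


def mini_config(n=20, **kw):
    defaults = dict(input_dim=n, hidden_dims=[8, 8], embedding_dim=4, seed=1, max_epochs=3)
    defaults.update(kw)
    return ModelConfig(**defaults)


def binned(values, source_id="x", key="K"):
    return BinnedSpectrum(values=np.asarray(values, dtype=float), source_id=source_id,
                          compound_key=key)


class TestBuildModel:
    def test_embedding_dimension(self):
        model = build_model(mini_config(), mini_scheme())
        e = model.embed(binned(np.zeros(20)))
        assert e.values.shape == (4,)

    def test_seeded_init_identical(self):
        m1 = build_model(mini_config(), mini_scheme())
        m2 = build_model(mini_config(), mini_scheme())
        for w1, w2 in zip(m1.base.get_weights(), m2.base.get_weights()):
            np.testing.assert_array_equal(w1, w2)

    def test_miniature_model_runs_forward(self):
        cfg = ModelConfig(input_dim=20, hidden_dims=[8], embedding_dim=4, seed=0)
        model = SiameseModel(cfg, mini_scheme())
        out = model.embed(binned(np.random.default_rng(0).random(20)))
        assert out.values.shape == (4,)

    def test_input_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="known bins"):
            SiameseModel(mini_config(n=21), mini_scheme(20))

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_dim=0)
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)


class TestEmbed:
    def test_deterministic_without_dropout(self):
        model = build_model(mini_config(), mini_scheme())
        x = binned(np.random.default_rng(2).random(20))
        e1, e2 = model.embed(x), model.embed(x)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_all_zero_input_finite(self):
        model = build_model(mini_config(), mini_scheme())
        e = model.embed(binned(np.zeros(20)))
        assert np.all(np.isfinite(e.values))

    def test_dropout_rate_zero_equals_off(self):
        model = build_model(mini_config(dropout_rate=0.0), mini_scheme())
        x = binned(np.random.default_rng(3).random(20))
        on = model.embed(x, dropout_active=True, rng=np.random.default_rng(0))
        off = model.embed(x)
        np.testing.assert_array_equal(on.values, off.values)

    def test_dropout_active_is_stochastic(self):
        model = build_model(mini_config(), mini_scheme())
        x = binned(np.random.default_rng(4).random(20))
        rng = np.random.default_rng(5)
        e1 = model.embed(x, dropout_active=True, rng=rng)
        e2 = model.embed(x, dropout_active=True, rng=rng)
        assert not np.array_equal(e1.values, e2.values)

    def test_dimension_mismatch_errors(self):
        model = build_model(mini_config(), mini_scheme())
        with pytest.raises(ValueError):
            model.embed(binned(np.zeros(7)))

    def test_forward_pass_counter(self):
        model = build_model(mini_config(), mini_scheme())
        before = model.n_forward_passes
        model.embed(binned(np.zeros(20)))
        assert model.n_forward_passes == before + 1


class TestScorePair:
    def test_self_score_one(self):
        e = np.array([1.0, -2.0, 0.5])
        assert score_pair(e, e) == pytest.approx(1.0)

    def test_antiparallel_minus_one(self):
        e = np.array([1.0, 2.0])
        assert score_pair(e, -e) == pytest.approx(-1.0)

    def test_orthogonal_zero(self):
        assert score_pair(np.array([1.0, 0.0]), np.array([0.0, 3.0])) == pytest.approx(0.0)

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert score_pair(a, b) == pytest.approx(score_pair(b, a))
        assert score_pair(3.7 * a, b) == pytest.approx(score_pair(a, b))

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError):
            score_pair(np.zeros(3), np.ones(3))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            score_pair(np.ones(3), np.ones(4))


class TestEarlyStopper:
    def test_stops_after_exactly_five_bad_epochs(self):
        # crafted loss sequence: improvement at epochs 0,1 then plateau
        stopper = EarlyStopper(patience=5)
        losses = [1.0, 0.5, 0.6, 0.6, 0.6, 0.6, 0.6]
        stops = [stopper.update(loss, i) for i, loss in enumerate(losses)]
        assert stops == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 1

    def test_counter_resets_on_improvement(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(1.0, 0)
        assert not stopper.update(1.1, 1)
        assert not stopper.update(0.9, 2)  # reset
        assert not stopper.update(1.0, 3)
        assert stopper.update(1.0, 4)


class TestSplitByCompound:
    def test_counts(self):
        keys = [f"K{i}" for i in range(1000)]
        tr, va, te = split_by_compound(keys, 100, 100, seed=0)
        assert len(tr) == 800 and len(va) == 100 and len(te) == 100

    def test_same_seed_same_split(self):
        keys = [f"K{i}" for i in range(50)]
        assert split_by_compound(keys, 5, 5, seed=3) == split_by_compound(keys, 5, 5, seed=3)

    def test_partition(self):
        keys = [f"K{i}" for i in range(30)]
        tr, va, te = split_by_compound(keys, 4, 6, seed=1)
        assert sorted(tr + va + te) == sorted(keys)
        assert not (set(tr) & set(va)) and not (set(va) & set(te)) and not (set(tr) & set(te))

    def test_too_few_keys_errors(self):
        with pytest.raises(ValueError):
            split_by_compound(["a", "b"], 1, 1)


def make_training_setup(n_compounds=10, spectra_per=2, n_bins=20, seed=0):
    rng = np.random.default_rng(seed)
    keys = [f"{chr(65 + i) * 14}" for i in range(n_compounds)]
    # block-structured labels: two families
    scores = np.ones((n_compounds, n_compounds))
    for i in range(n_compounds):
        for j in range(n_compounds):
            if i != j:
                scores[i, j] = 0.8 if (i < n_compounds // 2) == (j < n_compounds // 2) else 0.1
    labels = SimilarityLabelMatrix(keys, scores, metric="tanimoto", fp_type="synthetic")
    pool = []
    for i, key in enumerate(keys):
        base = np.zeros(n_bins)
        family = slice(0, n_bins // 2) if i < n_compounds // 2 else slice(n_bins // 2, n_bins)
        base[family] = rng.uniform(0.3, 1.0, n_bins // 2)
        base[i % n_bins] = 1.0
        for r in range(spectra_per):
            noise = 1.0 + 0.02 * rng.standard_normal(n_bins)
            pool.append(BinnedSpectrum(values=np.clip(base * noise, 0, None),
                                       source_id=f"{key}_{r}", compound_key=key))
    return pool, labels


class TestTrain:
    def test_overfit_tiny_set(self):
        # 20 spectra, no augmentation: training MSE driven below 0.01
        pool, labels = make_training_setup()
        tr = [b for b in pool if b.compound_key < "F" * 14]
        va = [b for b in pool if b.compound_key >= "F" * 14]
        cfg = ModelConfig(input_dim=20, hidden_dims=[32, 32], embedding_dim=8,
                          dropout_rate=0.0, max_epochs=200, early_stop_patience=200, seed=0)
        model = SiameseModel(cfg, mini_scheme())
        gen_cfg = GeneratorConfig(batch_size=8, augmentation_enabled=False, cycles_per_epoch=4)
        train(model, tr, va, labels, gen_cfg)
        assert min(h["train_loss"] for h in model.training_history) < 0.01

    def test_leakage_guard(self):
        pool, labels = make_training_setup()
        with pytest.raises(ValueError, match="shared between"):
            train(SiameseModel(mini_config(), mini_scheme()), pool, pool[:2], labels)

    def test_identical_seeds_identical_history(self):
        pool, labels = make_training_setup()
        tr = [b for b in pool if b.compound_key < "F" * 14]
        va = [b for b in pool if b.compound_key >= "F" * 14]

        def run():
            cfg = ModelConfig(input_dim=20, hidden_dims=[8, 8], embedding_dim=4,
                              max_epochs=4, seed=11)
            model = SiameseModel(cfg, mini_scheme())
            train(model, tr, va, labels, GeneratorConfig(batch_size=8))
            return model

        h1 = run().training_history
        h2 = run().training_history
        assert h1 == h2

    def test_early_stopping_halts_training(self):
        pool, labels = make_training_setup()
        tr = [b for b in pool if b.compound_key < "F" * 14]
        va = [b for b in pool if b.compound_key >= "F" * 14]
        cfg = ModelConfig(input_dim=20, hidden_dims=[8, 8], embedding_dim=4,
                          max_epochs=500, early_stop_patience=3, seed=0)
        model = SiameseModel(cfg, mini_scheme())
        train(model, tr, va, labels, GeneratorConfig(batch_size=8))
        history = model.training_history
        assert len(history) < 500  # stopped early
        # the final `patience` epochs did not improve on the best epoch before them
        best = min(h["val_loss"] for h in history[:-3])
        assert all(h["val_loss"] >= best for h in history[-3:])


class TestPersistence:
    def test_roundtrip_embeddings_identical(self, tmp_path):
        pool, labels = make_training_setup()
        model = build_model(mini_config(), mini_scheme())
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        x = binned(np.random.default_rng(1).random(20))
        np.testing.assert_array_equal(model.embed(x).values, back.embed(x).values)

    def test_missing_binning_refused(self, tmp_path):
        model = build_model(mini_config(), mini_scheme())
        save_model(model, tmp_path / "m")
        (tmp_path / "m" / "binning.json").unlink()
        with pytest.raises(FileNotFoundError, match="binning"):
            load_model(tmp_path / "m")

    def test_version_mismatch_refused(self, tmp_path):
        import json

        model = build_model(mini_config(), mini_scheme())
        save_model(model, tmp_path / "m")
        meta = json.loads((tmp_path / "m" / "metadata.json").read_text())
        meta["format_version"] = "other-version-0"
        (tmp_path / "m" / "metadata.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="other-version-0"):
            load_model(tmp_path / "m")

    def test_inconsistent_input_dim_refused(self, tmp_path):
        import json

        model = build_model(mini_config(), mini_scheme())
        save_model(model, tmp_path / "m")
        cfg = json.loads((tmp_path / "m" / "config.json").read_text())
        cfg["input_dim"] = 21
        (tmp_path / "m" / "config.json").write_text(json.dumps(cfg))
        with pytest.raises(ValueError):
            load_model(tmp_path / "m")

    def test_history_restored(self, tmp_path):
        pool, labels = make_training_setup()
        tr = [b for b in pool if b.compound_key < "F" * 14]
        va = [b for b in pool if b.compound_key >= "F" * 14]
        model = SiameseModel(mini_config(max_epochs=2), mini_scheme())
        train(model, tr, va, labels, GeneratorConfig(batch_size=8))
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert back.training_history == model.training_history
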