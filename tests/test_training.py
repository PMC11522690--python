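import numpy as np
import pytest

from qtaimnet import RepresentationConfig, ReadoutConfig
from qtaimnet.chemsys import LocalPropertyRecord
from qtaimnet.training import (
    EvalReport,
    TrainConfig,
    composite_loss,
    evaluate,
    split_dataset,
    train,
)


@pytest.fixture(scope="module")
def fast_rep():
    return RepresentationConfig(n=16, n_interactions=2, n_rbf=8, seed=5)


@pytest.fixture(scope="module")
def fast_train_cfg():
    return TrainConfig(
        property_name="q", mode="ElementalAIMwise", epochs=8, patience=8,
        learning_rate=4e-3, seed=5, w_global=0.0, global_kind="none",
    )


class TestSplit:
    def test_sizes_and_determinism(self, small_dataset):
        recs = small_dataset[:10]
        a = split_dataset(recs, (0.8, 0.1, 0.1), seed=7)
        b = split_dataset(recs, (0.8, 0.1, 0.1), seed=7)
        assert tuple(len(p) for p in a) == (8, 1, 1)
        for pa, pb in zip(a, b):
            assert [r.molecule.id for r in pa] == [r.molecule.id for r in pb]

    def test_partition_law(self, small_dataset):
        recs = small_dataset[:37]
        parts = split_dataset(recs, (0.6, 0.2, 0.2), seed=3)
        ids = [r.molecule.id for p in parts for r in p]
        assert sorted(ids) == sorted(r.molecule.id for r in recs)
        sets = [set(r.molecule.id for r in p) for p in parts]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])

    def test_seed_sensitivity(self, small_dataset):
        recs = small_dataset[:50]
        a = split_dataset(recs, (0.8, 0.1, 0.1), seed=1)
        b = split_dataset(recs, (0.8, 0.1, 0.1), seed=2)
        assert [r.molecule.id for r in a[0]] != [r.molecule.id for r in b[0]]

    def test_bad_fractions(self, small_dataset):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(small_dataset[:10], (0.5, 0.2, 0.2), seed=0)

    def test_too_few_records(self, small_dataset):
        with pytest.raises(ValueError):
            split_dataset(small_dataset[:2], (0.8, 0.1, 0.1), seed=0)


class TestCompositeLoss:
    def test_perfect_predictions(self):
        labels = [np.array([0.1, -0.1]), np.array([0.2, -0.2, 0.0])]
        Z = [[1, 8], [1, 1, 8]]
        loss = composite_loss(labels, labels, Z, 1.0, 0.5, "charge")
        assert loss == 0.0

    def test_wglobal_zero_reduces_to_mse(self):
        rng = np.random.default_rng(0)
        pred = [rng.normal(size=4), rng.normal(size=3)]
        labels = [rng.normal(size=4), rng.normal(size=3)]
        Z = [[1] * 4, [1] * 3]
        loss = composite_loss(pred, labels, Z, 1.0, 0.0, "charge")
        mse = np.mean(np.concatenate([(p - t) ** 2 for p, t in zip(pred, labels)]))
        assert loss == pytest.approx(mse, rel=1e-12)

    def test_uniform_offset_global_algebra(self):
        # uniform +c on each of M charges adds w_global (M c)^2 per molecule
        M, c = 5, 0.07
        labels = [np.zeros(M)]
        pred = [np.full(M, c)]
        loss = composite_loss(pred, labels, [[1] * M], 0.0, 0.3, "charge")
        assert loss == pytest.approx(0.3 * (M * c) ** 2, rel=1e-12)

    def test_electron_count_kind(self):
        lam = [np.array([0.5, 0.5])]
        delta = [np.array([1.0])]
        loss = composite_loss(lam, lam, [[1, 1]], 0.0, 1.0, "electron_count",
                              predictions_2p=delta)
        assert loss == pytest.approx(0.0, abs=1e-24)

    def test_energy_kind_needs_refs(self):
        with pytest.raises(ValueError, match="total_refs"):
            composite_loss([np.zeros(2)], [np.zeros(2)], [[1, 1]], 0.0, 1.0,
                           "energy", predictions_2p=[np.zeros(1)])

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="global loss kind"):
            composite_loss([np.zeros(2)], [np.zeros(2)], [[1, 1]], 1.0, 0.5, "entropy")


class TestTrain:
    def test_loss_decreases(self, small_dataset, fast_rep, fast_train_cfg):
        model, log = train(small_dataset, fast_train_cfg, fast_rep)
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_same_seed_identical_parameters(self, small_dataset, fast_rep, fast_train_cfg):
        subset = small_dataset[:40]
        cfg = TrainConfig(
            property_name="q", mode="ElementalAIMwise", epochs=3, patience=3,
            seed=9, w_global=0.0, global_kind="none",
        )
        m1, _ = train(subset, cfg, fast_rep)
        m2, _ = train(subset, cfg, fast_rep)
        for key in m1.params:
            assert np.array_equal(m1.params[key], m2.params[key]), key

    def test_constant_labels_absorbed(self, small_dataset, fast_rep):
        const_records = [
            LocalPropertyRecord(
                molecule=rec.molecule,
                props_1p={"q": np.full(rec.molecule.n_atoms, 0.37)},
                units={"q": "e"},
            )
            for rec in small_dataset[:60]
        ]
        cfg = TrainConfig(
            property_name="q", mode="AIMwise-1P", epochs=40, patience=40,
            learning_rate=5e-3, seed=1, w_global=0.0, global_kind="none",
        )
        model, log = train(const_records, cfg, fast_rep)
        assert log[-1]["val_mae"] <= 0.02

    def test_unseen_element_in_split_rejected(self, small_dataset, fast_rep, chon):
        from qtaimnet.surrogate_data import generate_geometry, label_molecule
        from dataclasses import replace

        # craft a split where a sulfur-free training set meets an S record:
        # easier to assert via explicit element check by adding a Cl molecule
        import numpy as np
        from qtaimnet.chemsys import Molecule

        weird = LocalPropertyRecord(
            molecule=Molecule((17, 17), np.array([[0.0, 0, 0], [0, 0, 2.0]]), id="cl2"),
            props_1p={"q": np.zeros(2)},
            units={"q": "e"},
        )
        records = list(small_dataset[:30])
        # seed chosen so the odd record lands outside the training partition
        for seed in range(20):
            parts = split_dataset(records + [weird], (0.8, 0.1, 0.1), seed)
            if all(r.molecule.id != "cl2" for r in parts[0]):
                cfg = TrainConfig(
                    property_name="q", mode="ElementalAIMwise", epochs=1,
                    seed=seed, w_global=0.0, global_kind="none",
                )
                with pytest.raises(ValueError, match="unseen"):
                    train(records + [weird], cfg, fast_rep)
                return
        pytest.fail("no seed placed the probe record outside training")


class TestEvaluate:
    def test_perfect_model_zero_error(self, small_dataset, fast_rep, fast_train_cfg):
        model, _ = train(small_dataset[:40],
                         TrainConfig(property_name="q", mode="ElementalAIMwise",
                                     epochs=1, seed=0, w_global=0.0, global_kind="none"),
                         fast_rep)
        # evaluate against the model's own predictions as labels
        from qtaimnet.training import predictions_for_records

        recs = small_dataset[:10]
        preds = predictions_for_records(model, recs)
        relabeled = [
            LocalPropertyRecord(molecule=r.molecule, props_1p={"q": p}, units={"q": "e"})
            for r, p in zip(recs, preds)
        ]
        report = evaluate(model, relabeled)
        assert report.mae == 0.0 and report.rmse == 0.0

    def test_mae_rmse_definitions(self):
        # errors {0, 0.2} -> MAE 0.1, RMSE 0.1414...
        errs = np.array([0.0, 0.2])
        assert np.mean(np.abs(errs)) == pytest.approx(0.1)
        assert np.sqrt(np.mean(errs**2)) == pytest.approx(0.14142135, rel=1e-6)

    def test_rmse_ge_mae(self, small_dataset, fast_rep, fast_train_cfg):
        model, _ = train(small_dataset, fast_train_cfg, fast_rep)
        report = evaluate(model, small_dataset[:30])
        assert report.rmse >= report.mae >= 0.0
        assert set(report.per_type) <= {"H", "C", "N", "O"}

    def test_empty_records_rejected(self, small_dataset, fast_rep, fast_train_cfg):
        model, _ = train(small_dataset[:40],
                         TrainConfig(property_name="q", mode="ElementalAIMwise",
                                     epochs=1, seed=0, w_global=0.0, global_kind="none"),
                         fast_rep)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])

    def test_kcalmol_conversion(self):
        report = EvalReport(property_name="E_inter", unit="au", mae=0.001,
                            rmse=0.002, n_values=10)
        conv = report.in_kcalmol()
        assert conv.mae == pytest.approx(0.6275)
        assert conv.unit == "kcal/mol"


class TestEnergyProperty:
    def test_pair_energy_training_and_units(self, small_dataset, fast_rep):
        cfg = TrainConfig(
            property_name="E_inter", mode="AIMwise-2P", epochs=2, seed=2,
            w_global=0.0, global_kind="none",
        )
        model, _ = train(small_dataset[:40], cfg, fast_rep)
        assert model.unit == "au"
        report = evaluate(model, small_dataset[40:60])
        conv = report.in_kcalmol()
        assert conv.mae == pytest.approx(report.mae * 627.5)


class TestTrainConfig:
    def test_weight_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(w_local=0.0, w_global=0.0, global_kind="none")

    def test_split_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrainConfig(splits=(0.5, 0.2, 0.2))

    def test_global_kind_required(self):
        with pytest.raises(ValueError):
            TrainConfig(w_global=0.5, global_kind="none")
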