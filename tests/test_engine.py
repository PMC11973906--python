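"""Training loop, evaluation, prediction and ablation orchestration."""

import json

import numpy as np
import pytest
from PIL import Image

from lite_thyseg.engine import (
    RunRecord,
    TrainConfig,
    ablate,
    dataset_loss,
    evaluate,
    predict,
    train,
)
from lite_thyseg.losses import tversky_loss
from lite_thyseg.network import ModelConfig, build_model, param_report
from lite_thyseg.phantom import PhantomSpec, generate_dataset

TINY_MODEL = dict(input_size=64, width_multiplier=0.35, aspp_branch_channels=16,
                  aspp_out_channels=16, ppm_branch_channels=8,
                  ppm_pool_sizes=(1, 2), attention_reduction=8,
                  decoder_channels={"fuse_s8": 16, "fuse_s4": 16, "shallow": 8,
                                    "horizontal": 16, "simple": 16})
TINY_SPEC = PhantomSpec(size=64, radius_range=(30, 80), prevalence=1.0,
                        shadow_prob=0.0)


@pytest.fixture(scope="module")
def tiny_records():
    return generate_dataset(4, TINY_SPEC, seed=0).records


class OracleModel:
    """Stub that returns the true mask as its probability map."""

    def __init__(self, records):
        self.lookup = {r.image.tobytes(): r.mask for r in records}
        self.config = ModelConfig(**TINY_MODEL)

    def predict_probs(self, x):
        key = (x[0, 0] * 255.0).astype(np.uint8).tobytes()
        return self.lookup[key][None, None].astype(np.float32)


class ConstantModel:
    def __init__(self, value, size=64):
        self.value = value
        self.config = ModelConfig(**TINY_MODEL)

    def predict_probs(self, x):
        return np.full_like(x, self.value)


class TestEvaluate:
    def test_oracle_model_scores_perfect(self, tiny_records):
        report = evaluate(OracleModel(tiny_records), tiny_records)
        assert report.dsc == report.iou == report.acc == 1.0

    def test_constant_zero_on_empty_masks(self):
        empty = generate_dataset(
            3, PhantomSpec(size=64, nodule_count_range=(0, 0), prevalence=0.0),
            seed=1).records
        report = evaluate(ConstantModel(0.0), empty)
        assert report.acc == 1.0
        assert report.se == 1.0  # degenerate: no positives anywhere

    def test_matches_hand_recount(self, tiny_records):
        model = ConstantModel(0.9)
        report = evaluate(model, tiny_records[:3])
        tp = sum(int(r.mask.sum()) for r in tiny_records[:3])
        fp = sum(int((1 - r.mask).sum()) for r in tiny_records[:3])
        assert report.se == 1.0
        assert report.iou == pytest.approx(tp / (tp + fp))

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            evaluate(ConstantModel(0.5), [])


class TestTrain:
    def test_untrained_loss_near_constant_half_predictor(self, tiny_records):
        """A fresh network outputs ~0.5 everywhere, so its Tversky loss
        should sit within 20% of the analytic constant-0.5 loss."""
        model = build_model(ModelConfig(**TINY_MODEL), seed=0)
        actual = dataset_loss(model, tiny_records, tversky_loss)
        reference = np.mean([
            tversky_loss(np.full(r.mask.shape, 0.5), r.mask.astype(float))
            for r in tiny_records])
        assert actual == pytest.approx(reference, rel=0.2)

    def test_same_seed_identical_trajectories(self, tiny_records):
        histories = []
        for _ in range(2):
            model = build_model(ModelConfig(**TINY_MODEL), seed=7)
            cfg = TrainConfig(epochs=2, batch_size=2, seed=7)
            rec = train(model, (tiny_records, [], []), cfg)
            histories.append([e["train_loss"] for e in rec.history])
        assert histories[0] == histories[1]

    def test_records_epochs_and_best_checkpoint(self, tiny_records):
        model = build_model(ModelConfig(**TINY_MODEL), seed=3)
        cfg = TrainConfig(epochs=3, batch_size=2, seed=3)
        rec = train(model, (tiny_records[:3], tiny_records[3:], []), cfg)
        assert len(rec.history) == 3
        assert rec.best_epoch >= 0
        assert "val" in rec.final_metrics and "train" in rec.final_metrics
        assert rec.params["encoder"] > 0

    def test_empty_train_split_rejected(self, tiny_records):
        model = build_model(ModelConfig(**TINY_MODEL), seed=0)
        with pytest.raises(ValueError):
            train(model, ([], tiny_records, []), TrainConfig(epochs=1))

    def test_run_record_serializes(self, tiny_records, tmp_path):
        model = build_model(ModelConfig(**TINY_MODEL), seed=0)
        rec = train(model, (tiny_records, [], []),
                    TrainConfig(epochs=1, batch_size=4, seed=0))
        rec.to_json(tmp_path / "run.json")
        loaded = json.loads((tmp_path / "run.json").read_text())
        assert loaded["train_config"]["epochs"] == 1


class TestPredict:
    def test_round_trip_with_oracle_stub(self, tiny_records, tmp_path):
        rec = tiny_records[0]
        src = tmp_path / f"{rec.id}.png"
        Image.fromarray(rec.image, mode="L").save(src)
        written, failed = predict(OracleModel(tiny_records), [src], tmp_path / "out")
        assert not failed and len(written) == 1
        mask = np.asarray(Image.open(written[0]))
        assert set(np.unique(mask)) <= {0, 255}
        assert mask.shape == rec.image.shape
        assert np.array_equal((mask > 0).astype(np.uint8), rec.mask)

    def test_unreadable_file_listed(self, tiny_records, tmp_path):
        bogus = tmp_path / "nope.png"
        bogus.write_text("not a png")
        written, failed = predict(OracleModel(tiny_records), [bogus], tmp_path / "out")
        assert failed == [bogus] and written == []


class TestAblate:
    def test_param_rows_match_conv_math_and_shared_splits(self, tiny_records):
        from lite_thyseg.network import expected_param_count, build_model as bm

        grid = [{"use_ppm": False}, {"use_ppm": True}]
        rows = ablate(grid, (tiny_records, [], []),
                      ModelConfig(**TINY_MODEL), TrainConfig(epochs=0))
        assert len(rows) == 2
        for toggles, row in zip(grid, rows):
            cfg = ModelConfig(**{**TINY_MODEL, **toggles})
            assert row["params"] == expected_param_count(bm(cfg))
        assert rows[0]["params"] != rows[1]["params"]

    def test_training_rows_report_metrics(self, tiny_records):
        rows = ablate([{"use_attention": False}], (tiny_records, [], []),
                      ModelConfig(**TINY_MODEL),
                      TrainConfig(epochs=1, batch_size=4, seed=0))
        assert "iou" in rows[0] and "params_mb" in rows[0]


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1)
    with pytest.raises(ValueError):
        TrainConfig(loss="focal")
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
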