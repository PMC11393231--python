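"""Subject I/O, normalisation, sliding-window inference, splitting,
training-loop behaviour, and the end-to-end CLI pipeline."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from dsaseg import (MultiChannelVolume, PhantomSpec, RunConfig, ShapeError,
                    generate_cohort, generate_phantom, load_subject,
                    normalize_intensity, sliding_window_predict, split_dataset,
                    train)
from dsaseg.cli import main as cli_main
from dsaseg.volumes import save_nifti


@pytest.fixture(scope="module")
def train_cohort(tmp_path_factory):
    """Four 32^3 phantoms, all in the training split (no validation)."""
    out = tmp_path_factory.mktemp("traincohort")
    spec = PhantomSpec(shape=(32, 32, 32))
    generate_cohort(4, out, spec=spec, seed=3, proportions=(1.0, 0.0, 0.0),
                    nonlesional_fraction=0.0)
    return out


def quick_config(seed=0, **overrides):
    cfg = RunConfig.desk_scale(seed=seed)
    d = cfg.to_dict()
    d.update(batch_size=1, epochs=2, steps_per_epoch=2)
    d.update(overrides)
    return RunConfig.from_dict(d)


class TestLoadSubject:
    def test_two_channel_stack_in_declared_order(self, tmp_path, rng):
        eye = np.eye(4)
        t1 = rng.normal(size=(8, 8, 8)).astype(np.float32)
        flair = rng.normal(size=(8, 8, 8)).astype(np.float32)
        save_nifti(t1, eye, tmp_path / "t1.nii.gz")
        save_nifti(flair, eye, tmp_path / "flair.nii.gz")
        vol, mask = load_subject([tmp_path / "t1.nii.gz", tmp_path / "flair.nii.gz"])
        assert vol.n_channels == 2
        assert mask is None
        np.testing.assert_allclose(vol.values[0], t1, atol=1e-5)

    def test_single_channel_volume(self, tmp_path, rng):
        save_nifti(rng.normal(size=(8, 8, 8)), np.eye(4), tmp_path / "flair.nii.gz")
        vol, _ = load_subject([tmp_path / "flair.nii.gz"])
        assert vol.n_channels == 1

    def test_multilabel_mask_binarised_with_warning(self, tmp_path, rng):
        eye = np.eye(4)
        save_nifti(rng.normal(size=(6, 6, 6)), eye, tmp_path / "im.nii.gz")
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[2:4, 2:4, 2:4] = 2
        save_nifti(labels, eye, tmp_path / "mask.nii.gz")
        with pytest.warns(UserWarning, match="binarised"):
            _, mask = load_subject([tmp_path / "im.nii.gz"], tmp_path / "mask.nii.gz")
        assert set(np.unique(mask.values)) == {0, 1}

    def test_shape_mismatch_names_both_files(self, tmp_path, rng):
        eye = np.eye(4)
        save_nifti(rng.normal(size=(8, 8, 8)), eye, tmp_path / "a.nii.gz")
        save_nifti(rng.normal(size=(8, 8, 9)), eye, tmp_path / "b.nii.gz")
        with pytest.raises(ShapeError, match="a.nii.gz.*b.nii.gz"):
            load_subject([tmp_path / "a.nii.gz", tmp_path / "b.nii.gz"])

    def test_affine_mismatch_is_rejected(self, tmp_path, rng):
        a2 = np.eye(4)
        a2[0, 3] = 5.0
        save_nifti(rng.normal(size=(8, 8, 8)), np.eye(4), tmp_path / "a.nii.gz")
        save_nifti(rng.normal(size=(8, 8, 8)), a2, tmp_path / "b.nii.gz")
        with pytest.raises(ValueError, match="affine"):
            load_subject([tmp_path / "a.nii.gz", tmp_path / "b.nii.gz"],
                         canonical=False)


class TestNormalizeIntensity:
    def test_nonzero_voxels_become_zero_mean_unit_sd(self, rng):
        values = rng.normal(3.0, 2.5, size=(2, 8, 8, 8)).astype(np.float32)
        values[:, :2] = 0.0
        out = normalize_intensity(MultiChannelVolume(values))
        for ch in range(2):
            nz = out.values[ch][out.values[ch] != 0]
            assert abs(nz.mean()) < 1e-5
            assert abs(nz.std() - 1.0) < 1e-5
        assert (out.values[:, :2] == 0).all()

    def test_phantom_round_trip_is_near_identity(self):
        vol, _ = generate_phantom(PhantomSpec(shape=(32, 32, 32), seed=2))
        out = normalize_intensity(vol)
        assert np.abs(out.values - vol.values).max() < 1e-3

    def test_constant_channel_is_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_intensity(MultiChannelVolume(np.zeros((1, 4, 4, 4))))


class _ConstantModel:
    """Stub predictor returning a fixed probability everywhere."""

    patch_size = (32, 32, 32)

    def __init__(self, p=0.7):
        self.p = p
        self.calls = 0

    def __call__(self, x):
        from dsaseg.autodiff import Tensor
        n, _, d, h, w = x.shape
        probs = np.empty((n, 2, d, h, w), dtype=np.float32)
        probs[:, 0] = 1 - self.p
        probs[:, 1] = self.p
        self.calls += 1
        return Tensor(probs)

    def eval(self):
        return self

    def train(self, mode=True):
        return self


class TestSlidingWindow:
    def test_volume_equal_to_patch_uses_exactly_one_window(self, rng):
        model = _ConstantModel()
        vol = MultiChannelVolume(rng.normal(size=(2, 32, 32, 32)).astype(np.float32))
        sliding_window_predict(vol, model, (32, 32, 32), overlap=0.5)
        assert model.calls == 1

    def test_constant_model_blends_without_seams(self, rng):
        model = _ConstantModel(p=0.7)
        vol = MultiChannelVolume(rng.normal(size=(2, 64, 48, 32)).astype(np.float32))
        pm = sliding_window_predict(vol, model, (32, 32, 32), overlap=0.5)
        assert pm.probs.shape == (2, 64, 48, 32)
        np.testing.assert_allclose(pm.probs[1], 0.7, atol=1e-6)
        np.testing.assert_allclose(pm.probs.sum(axis=0), 1.0, atol=1e-6)
        assert model.calls == 3 * 2 * 1

    def test_small_volume_is_padded_and_cropped(self, rng):
        model = _ConstantModel()
        vol = MultiChannelVolume(rng.normal(size=(2, 20, 32, 40)).astype(np.float32))
        pm = sliding_window_predict(vol, model, (32, 32, 32), overlap=0.5)
        assert pm.probs.shape == (2, 20, 32, 40)


class TestSplitDataset:
    def test_85_subjects_at_reference_proportions(self):
        ids = [f"s{i}" for i in range(85)]
        manifest = split_dataset(ids, (62 / 85, 6 / 85, 17 / 85), seed=4)
        counts = manifest.split.value_counts()
        assert (counts["train"], counts["val"], counts["test"]) == (62, 6, 17)

    def test_fixed_seed_reproduces_manifest(self):
        ids = [f"s{i}" for i in range(20)]
        a = split_dataset(ids, (0.6, 0.2, 0.2), seed=9)
        b = split_dataset(ids, (0.6, 0.2, 0.2), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_partition_is_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(13)]
        manifest = split_dataset(ids, (7, 3, 3), seed=0)
        assert sorted(manifest.subject_id) == sorted(ids)
        assert manifest.subject_id.is_unique

    def test_more_splits_than_subjects_is_rejected(self):
        with pytest.raises(ValueError, match="cannot fill"):
            split_dataset(["a", "b"], (0.4, 0.3, 0.3), seed=0)


class TestTrainLoop:
    def test_loss_decreases_between_epochs(self, train_cohort, tmp_path):
        cfg = quick_config(seed=5, steps_per_epoch=4)
        result = train(cfg, train_cohort, tmp_path / "run")
        by_epoch = result.history.groupby("epoch").L.mean()
        assert by_epoch[2] < by_epoch[1]

    def test_omega_zero_makes_total_loss_equal_dice_part(self, train_cohort,
                                                         tmp_path):
        cfg = quick_config(seed=6)
        d = cfg.to_dict()
        d["loss"]["omega"] = 0.0
        cfg = RunConfig.from_dict(d)
        result = train(cfg, train_cohort, tmp_path / "run")
        np.testing.assert_allclose(result.history.L, result.history.L_dc,
                                   rtol=1e-6)

    def test_resume_reproduces_uninterrupted_run(self, train_cohort, tmp_path):
        # constant learning rate so both runs share the same schedule horizon
        cfg = quick_config(seed=7, lr_schedule="constant")
        full = train(cfg, train_cohort, tmp_path / "full")

        cfg1 = quick_config(seed=7, lr_schedule="constant", epochs=1)
        part = train(cfg1, train_cohort, tmp_path / "part1")
        # continue for the second epoch from the 1-epoch checkpoint
        resumed = train(cfg, train_cohort, tmp_path / "part2",
                        resume_from=part.last_checkpoint)
        second_epoch_full = full.history[full.history.epoch == 2].L.to_numpy()
        second_epoch_resumed = resumed.history.L.to_numpy()
        np.testing.assert_allclose(second_epoch_resumed, second_epoch_full,
                                   atol=1e-6)

    def test_empty_training_split_is_rejected(self, tmp_path):
        out = tmp_path / "empty"
        generate_cohort(2, out, spec=PhantomSpec(shape=(32, 32, 32)), seed=1,
                        proportions=(0.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="training"):
            train(quick_config(), out, tmp_path / "run")


class TestCliPipeline:
    def test_generate_train_predict_evaluate_round_trip(self, tmp_path):
        """The full shell workflow on a small phantom cohort produces a
        well-formed metrics CSV."""
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(cli_main, ["generate", "--out-dir", str(data),
                                     "--n-subjects", "6", "--shape", "32",
                                     "--seed", "1"])
        assert r.exit_code == 0, r.output

        cfg = quick_config(seed=1)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        r = runner.invoke(cli_main, ["train", "--dataset-dir", str(data),
                                     "--out-dir", str(tmp_path / "run"),
                                     "--config", str(tmp_path / "cfg.yaml")])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, [
            "predict", "--checkpoint", str(tmp_path / "run" / "checkpoint_best.npz"),
            "--dataset-dir", str(data), "--out-dir", str(tmp_path / "pred")])
        assert r.exit_code == 0, r.output

        manifest = pd.read_csv(data / "manifest.tsv", sep="\t")
        test_ids = manifest[manifest.split == "test"].subject_id.tolist()
        gt_dir = tmp_path / "gt"
        gt_dir.mkdir()
        for sid in test_ids:
            (gt_dir / f"{sid}.nii.gz").write_bytes(
                (data / f"{sid}_mask.nii.gz").read_bytes())
        r = runner.invoke(cli_main, ["evaluate", "--pred-dir", str(tmp_path / "pred"),
                                     "--gt-dir", str(gt_dir),
                                     "--out-dir", str(tmp_path / "metrics")])
        assert r.exit_code == 0, r.output
        per = pd.read_csv(tmp_path / "metrics" / "per_subject.csv")
        assert len(per) == len(test_ids) > 0
        assert list(per.columns) == ["subject", "detected", "fpc", "tp", "fp",
                                     "fn", "sens", "prec", "dc"]
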