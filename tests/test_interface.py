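import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from spdfatigue import fusion, io as fio
from spdfatigue.cli import main as cli_main
from spdfatigue.config import config_hash, load_run_config, write_provenance
from spdfatigue.synthetic import GenConfig, generate_dataset


def write_minimal_edf(path, data, fs, labels):
    """Write a single-record EDF byte stream (synthetic fixture, int16 samples)."""
    n_sig, n_samp = data.shape
    header = b""
    header += b"0".ljust(8)
    header += b"synthetic patient".ljust(80)
    header += b"synthetic recording".ljust(80)
    header += b"01.01.20".ljust(8)
    header += b"00.00.00".ljust(8)
    header += str(256 * (n_sig + 1)).encode().ljust(8)
    header += b"".ljust(44)
    header += b"1".ljust(8)  # one data record
    header += str(n_samp / fs).encode()[:8].ljust(8)  # record duration (s)
    header += str(n_sig).encode().ljust(4)

    def field(values, width):
        return b"".join(str(v).encode()[:width].ljust(width) for v in values)

    header += field(labels, 16)
    header += field([""] * n_sig, 80)  # transducer
    header += field(["uV"] * n_sig, 8)
    header += field([-1000] * n_sig, 8)  # physical min
    header += field([1000] * n_sig, 8)
    header += field([-32768] * n_sig, 8)  # digital min
    header += field([32767] * n_sig, 8)
    header += field([""] * n_sig, 80)  # prefiltering
    header += field([n_samp] * n_sig, 8)
    header += field([""] * n_sig, 32)
    digital = np.clip(data / 1000.0 * 32767, -32768, 32767).astype("<i2")
    Path(path).write_bytes(header + digital.tobytes())


class TestContainer:
    def test_roundtrip_bit_exact(self, tmp_path, rng):
        sig = rng.standard_normal((5, 100))
        fio.save_trial(tmp_path / "t0", sig, fs=250.0, channel_names=list("abcde"))
        loaded, meta = fio.load_trial(tmp_path / "t0")
        assert np.array_equal(loaded, sig)
        assert meta["fs"] == 250.0
        assert meta["channel_names"] == list("abcde")

    def test_header_shape_mismatch_detected(self, tmp_path, rng):
        fio.save_trial(tmp_path / "t0", rng.standard_normal((3, 10)), fs=250.0)
        np.save(tmp_path / "t0.npy", rng.standard_normal((4, 10)))
        with pytest.raises(ValueError, match="shape"):
            fio.load_trial(tmp_path / "t0")

    def test_dataset_roundtrip(self, tmp_path):
        ds = generate_dataset(GenConfig(n_subjects=2, trials_per_subject=(2, 3), seed=3))
        fio.save_dataset(tmp_path / "ds", ds)
        signals, table = fio.load_dataset(tmp_path / "ds")
        assert len(signals) == len(ds)
        assert np.array_equal(signals[0], ds.trials[0].signal)
        assert set(table.columns) >= {"trial_id", "subject_id", "local_RT",
                                      "global_RT", "class", "label"}


class TestEDF:
    def test_reference_channels_dropped(self, tmp_path, rng):
        data = rng.standard_normal((32, 500)) * 50
        labels = [f"EEG ch{i:02d}" for i in range(30)] + ["REF1", "REF2"]
        write_minimal_edf(tmp_path / "rec.edf", data, fs=500.0, labels=labels)
        out, fs, names = fio.read_edf(tmp_path / "rec.edf",
                                      drop_channels=["REF1", "REF2"])
        assert out.shape[0] == 30
        assert fs == 500.0
        assert "REF1" not in names

    def test_sample_values_roundtrip(self, tmp_path):
        t = np.arange(500) / 500.0
        data = np.tile(100.0 * np.sin(2 * np.pi * 10 * t), (2, 1))
        write_minimal_edf(tmp_path / "rec.edf", data, fs=500.0,
                          labels=["EEG a", "EEG b"])
        out, _, _ = fio.read_edf(tmp_path / "rec.edf")
        # mne returns volts; EDF quantization limits agreement
        assert np.allclose(out * 1e6, data, atol=0.1)


class TestCheckpoint:
    def test_reload_reproduces_predictions(self, tmp_path, small_features,
                                           small_train_config):
        covs, seqs, y, _ = small_features
        model = fusion.train_alternating(covs, seqs, y, small_train_config)
        before = fusion.model_probabilities(model, covs, seqs)
        fio.save_checkpoint(tmp_path / "ckpt", model)
        reloaded = fio.load_checkpoint(tmp_path / "ckpt")
        after = fusion.model_probabilities(reloaded, covs, seqs)
        assert np.array_equal(before, after)
        manifest = json.loads((tmp_path / "ckpt.json").read_text())
        assert manifest["layer_order"] == ["BiMap", "ReEig", "BiMap", "LogEig"]
        assert "row-major" in manifest["vech_ordering"]


class TestRunConfig:
    def test_defaults_carry_printed_constants(self):
        run = load_run_config()
        assert run.preprocess.band == (1.0, 50.0)
        assert run.preprocess.fs_out == 250.0
        assert run.train.maxite == 50
        assert run.train.center_thre == 1e-9
        assert run.train.center_max_iter == 50
        assert run.train.eps_cov == 1e-8
        assert run.analysis.zeta_omega == 0.9

    def test_yaml_overrides(self, tmp_path):
        cfg_file = tmp_path / "run.yaml"
        cfg_file.write_text(yaml.safe_dump(
            {"generate": {"n_subjects": 3, "separation": 1.5},
             "train": {"hidden_size": 8}}
        ))
        run = load_run_config(cfg_file)
        assert run.generate.n_subjects == 3
        assert run.train.hidden_size == 8

    def test_unknown_keys_rejected(self, tmp_path):
        cfg_file = tmp_path / "run.yaml"
        cfg_file.write_text(yaml.safe_dump({"train": {"learning_rate": 1.0}}))
        with pytest.raises(ValueError, match="learning_rate"):
            load_run_config(cfg_file)
        cfg_file.write_text(yaml.safe_dump({"nonsense": {}}))
        with pytest.raises(ValueError, match="nonsense"):
            load_run_config(cfg_file)

    def test_hash_stable_and_sensitive(self):
        a = load_run_config()
        b = load_run_config(overrides={"train": {"hidden_size": 8}})
        assert config_hash(a) == config_hash(load_run_config())
        assert config_hash(a) != config_hash(b)

    def test_provenance_written(self, tmp_path):
        write_provenance(tmp_path / "out", load_run_config())
        payload = json.loads((tmp_path / "out" / "run_config.json").read_text())
        assert "config_hash" in payload


@pytest.fixture(scope="module")
def tiny_yaml(tmp_path_factory):
    path = tmp_path_factory.mktemp("cfg") / "tiny.yaml"
    path.write_text(yaml.safe_dump({
        "generate": {"n_subjects": 3, "trials_per_subject": [4, 6],
                     "separation": 2.0, "seed": 5},
        "train": {"hidden_size": 8, "d1": 8, "d2": 4, "maxite": 6, "seed": 5},
        "analysis": {"zeta_k": 2, "zeta_n_samples": 10, "n_sources": 12,
                     "kl_grid": 128},
    }))
    return str(path)


class TestCLI:
    def test_simulate_deterministic(self, tmp_path, tiny_yaml):
        runner = CliRunner()
        for d in ("a", "b"):
            res = runner.invoke(cli_main, ["--config", tiny_yaml, "simulate",
                                           "--out", str(tmp_path / d)])
            assert res.exit_code == 0, res.output
        csv_a = (tmp_path / "a" / "trials.csv").read_bytes()
        csv_b = (tmp_path / "b" / "trials.csv").read_bytes()
        assert csv_a == csv_b
        npy_a = (tmp_path / "a" / "trials" / "trial_00000.npy").read_bytes()
        npy_b = (tmp_path / "b" / "trials" / "trial_00000.npy").read_bytes()
        assert npy_a == npy_b

    def test_train_missing_data_dir_fails_with_path(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["train", "--data", str(tmp_path / "nope"),
                                       "--out", str(tmp_path / "out")])
        assert res.exit_code != 0
        assert "nope" in res.output

    def test_full_pipeline_smoke(self, tmp_path, tiny_yaml):
        """simulate -> features -> train -> evaluate writes a metrics JSON."""
        runner = CliRunner()
        data = str(tmp_path / "data")
        steps = [
            ["--config", tiny_yaml, "simulate", "--out", data],
            ["--config", tiny_yaml, "features", "--data", data,
             "--out", str(tmp_path / "feat")],
            ["--config", tiny_yaml, "train", "--data", data,
             "--out", str(tmp_path / "model")],
            ["--config", tiny_yaml, "evaluate", "--data", data,
             "--out", str(tmp_path / "eval")],
        ]
        for argv in steps:
            res = runner.invoke(cli_main, argv)
            assert res.exit_code == 0, f"{argv}: {res.output}"
        metrics = json.loads((tmp_path / "eval" / "metrics.json").read_text())
        assert set(metrics["mean"]) == {"accuracy", "sensitivity", "specificity", "f1"}
        assert (tmp_path / "model" / "checkpoint.npz").exists()
        assert (tmp_path / "eval" / "run_config.json").exists()

    def test_analysis_commands(self, tmp_path, tiny_yaml):
        runner = CliRunner()
        data = str(tmp_path / "data")
        assert runner.invoke(cli_main, ["--config", tiny_yaml, "simulate",
                                        "--out", data]).exit_code == 0
        res = runner.invoke(cli_main, ["--config", tiny_yaml, "analyze-zeta",
                                       "--data", data, "--out", str(tmp_path / "z")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "z" / "zeta_ranking.csv").exists()
        res = runner.invoke(cli_main, ["--config", tiny_yaml, "analyze-source",
                                       "--data", data, "--n-sources", "12",
                                       "--out", str(tmp_path / "s")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "s" / "source_kl.csv").exists()
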