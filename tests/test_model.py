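"""Model assembly: forward semantics, loss, variants, checkpoints."""

import dataclasses

import numpy as np
import pytest

from synergynet.config import TrainConfig
from synergynet.data_io import load_checkpoint, save_checkpoint
from synergynet.model import (VARIANTS, FeatureStore, SynergyModel,
                              assemble_batch, build_variant, mse_loss)
from synergynet.nn import Tensor
from synergynet.train_eval import train


def _batch(bundle, store, examples=None):
    cm, cr = bundle.cell_matrix()
    return assemble_batch(examples or bundle.examples[:16], store, cm, cr), cm, cr


class TestMSELoss:
    def test_perfect_prediction_is_zero(self):
        assert mse_loss(Tensor(np.array([1.0, 2.0])),
                        np.array([1.0, 2.0])).item() == 0.0

    def test_small_example(self):
        assert mse_loss(Tensor(np.array([0.0, 2.0])),
                        np.array([2.0, 2.0])).item() == 2.0

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            pred, truth = rng.normal(size=n), rng.normal(size=n)
            expected = float(np.mean((pred - truth) ** 2))
            assert abs(mse_loss(Tensor(pred), truth).item() - expected) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(Tensor(np.zeros(3)), np.zeros(4))


class TestForward:
    def test_one_score_per_example_and_eval_determinism(
            self, tiny_bundle, tiny_model, tiny_store):
        tiny_model.eval()
        batch, _, _ = _batch(tiny_bundle, tiny_store)
        a = tiny_model.forward(batch, tiny_store).data
        b = tiny_model.forward(batch, tiny_store).data
        assert a.shape == (16,)
        np.testing.assert_array_equal(a, b)

    def test_batched_equals_looped_singles_in_eval(
            self, tiny_bundle, tiny_model, tiny_store):
        tiny_model.eval()
        cm, cr = tiny_bundle.cell_matrix()
        examples = tiny_bundle.examples[:5]
        batched = tiny_model.forward(
            assemble_batch(examples, tiny_store, cm, cr), tiny_store).data
        singles = [
            tiny_model.forward(
                assemble_batch([e], tiny_store, cm, cr), tiny_store).data[0]
            for e in examples
        ]
        np.testing.assert_allclose(batched, singles, atol=1e-9)

    def test_every_modality_input_perturbs_output(
            self, tiny_bundle, small_config):
        model = SynergyModel(small_config, tiny_bundle.expr_width,
                             tiny_bundle.mut_width, len(tiny_bundle.cells))
        model.eval()
        store = FeatureStore(tiny_bundle.drugs, small_config)
        batch, cm, cr = _batch(tiny_bundle, store, tiny_bundle.examples[:4])
        base = model.forward(batch, store).data.copy()
        perturbations = {
            "morgan": lambda: np.put(store.fps, [0, 1, 2], 1 - store.fps.flat[:3]),
            "sequence/graph": lambda: store.seq.__setitem__(
                (slice(None), 0, 16), store.seq[:, 0, 16] + 1.0),
            "cloud": lambda: store.clouds.__setitem__(
                (slice(None), 0, 0), store.clouds[:, 0, 0] + 0.5),
            "cell": lambda: batch.cell_matrix.__setitem__(
                (slice(None), 0), batch.cell_matrix[:, 0] + 1.0),
        }
        for name, perturb in perturbations.items():
            saved = (store.fps.copy(), store.seq.copy(), store.clouds.copy(),
                     batch.cell_matrix.copy())
            perturb()
            out = model.forward(batch, store).data
            assert np.any(out != base), f"{name} branch is disconnected"
            store.fps, store.seq, store.clouds = (saved[0].copy(),
                                                  saved[1].copy(),
                                                  saved[2].copy())
            batch.cell_matrix[...] = saved[3]


class TestVariants:
    def test_unknown_name_lists_valid_names(self, tiny_bundle, small_config):
        with pytest.raises(ValueError, match="MMFSyn_base"):
            build_variant("bogus", small_config, tiny_bundle.expr_width,
                          tiny_bundle.mut_width, len(tiny_bundle.cells))

    def test_base_variant_has_no_sequence_or_graph_encoders(
            self, tiny_bundle, small_config):
        m = build_variant("MMFSyn_base", small_config, tiny_bundle.expr_width,
                          tiny_bundle.mut_width, len(tiny_bundle.cells))
        assert not hasattr(m, "seq_encoder") and not hasattr(m, "graph_encoder")

    def test_cell_base_input_width_is_cell_count(self, tiny_bundle,
                                                 small_config):
        m = build_variant("Cell_base", small_config, tiny_bundle.expr_width,
                          tiny_bundle.mut_width, len(tiny_bundle.cells))
        assert m.cell_encoder.expr_width == len(tiny_bundle.cells)
        assert m.cell_encoder.mut_width == 0

    def test_cell_gen_ignores_mutation_data(self, tiny_bundle, small_config,
                                            tiny_store, rng):
        m = build_variant("Cell_gen", small_config, tiny_bundle.expr_width,
                          tiny_bundle.mut_width, len(tiny_bundle.cells))
        m.eval()
        batch, cm, cr = _batch(tiny_bundle, tiny_store)
        a = m.forward(batch, tiny_store).data
        batch.cell_matrix[:, tiny_bundle.expr_width:] = rng.integers(
            0, 2, size=batch.cell_matrix[:, tiny_bundle.expr_width:].shape)
        b = m.forward(batch, tiny_store).data
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("name", sorted(VARIANTS))
    def test_every_variant_trains_one_step(self, name, tiny_bundle,
                                           small_config, tiny_store):
        model = build_variant(name, small_config, tiny_bundle.expr_width,
                              tiny_bundle.mut_width, len(tiny_bundle.cells))
        result = train(model, tiny_bundle,
                       TrainConfig(epochs=1, batch_size=16, seed=2,
                                   val_fraction=0.0),
                       store=tiny_store, examples=tiny_bundle.examples[:16])
        assert len(result.history) == 1
        assert np.isfinite(result.history[0]["train_mse"])

    def test_parameter_count_stable_across_rebuilds(self, tiny_bundle,
                                                    small_config):
        counts = [
            SynergyModel(small_config, tiny_bundle.expr_width,
                         tiny_bundle.mut_width,
                         len(tiny_bundle.cells)).summary()["total"]
            for _ in range(2)
        ]
        assert counts[0] == counts[1]


class TestCheckpoint:
    def test_round_trip_is_bitwise_identical(self, tiny_bundle, tiny_model,
                                             tiny_store, tmp_path):
        cm, cr = tiny_bundle.cell_matrix()
        examples = tiny_bundle.examples[:8]
        before = tiny_model.predict(examples, tiny_store, cm, cr)
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        loaded = load_checkpoint(path)
        after = loaded.predict(examples, tiny_store, cm, cr)
        np.testing.assert_array_equal(before, after)
        assert loaded.config.to_dict() == tiny_model.config.to_dict()

    def test_truncated_file_raises_clean_error(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        data = path.read_bytes()
        path.write_bytes(data[:len(data) // 3])
        with pytest.raises(IOError):
            load_checkpoint(path)

    def test_version_mismatch_rejected(self, tiny_model, tmp_path,
                                       monkeypatch):
        import synergynet.model as model_mod
        path = tmp_path / "model.npz"
        monkeypatch.setattr(model_mod, "CHECKPOINT_VERSION", 99)
        save_checkpoint(tiny_model, path)
        monkeypatch.undo()
        with pytest.raises(IOError, match="version"):
            load_checkpoint(path)


def test_order_augmented_prediction_is_order_invariant(tiny_bundle,
                                                       tiny_model, tiny_store):
    cm, cr = tiny_bundle.cell_matrix()
    examples = tiny_bundle.examples[:6]
    swapped = [dataclasses.replace(e, drug_a=e.drug_b, drug_b=e.drug_a)
               for e in examples]
    a = tiny_model.predict(examples, tiny_store, cm, cr,
                           average_orderings=True)
    b = tiny_model.predict(swapped, tiny_store, cm, cr,
                           average_orderings=True)
    np.testing.assert_allclose(a, b, atol=1e-9)
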