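"""Interaction head: token assembly, pocket-rank positions, attention
invariants, the sigmoid head and the cross-entropy loss."""
import numpy as np
import pytest

from pocketdti import interaction as ia
from pocketdti.nn import autograd as ag
from pocketdti.nn.autograd import Tensor


def _rng():
    return np.random.default_rng(5)


def _config(d=16, layers=1, dropout=0.0):
    return ia.TransformerConfig(d=d, heads=4, ff_dim=32, dropout=dropout,
                                layers=layers, max_rank=8)


class TestAssembleInput:
    def test_shape_m3(self):
        r = _rng()
        inp = ia.assemble_input(Tensor(r.normal(size=4)), Tensor(r.normal(size=4)),
                                Tensor(r.normal(size=(3, 4))), np.array([1, 1, 2]))
        assert inp.X.shape == (1, 5, 4)

    def test_positions_follow_pocket_ranks(self):
        """Drug and protein rows sit at position 0; each subpocket carries its
        parent pocket's rank."""
        r = _rng()
        inp = ia.assemble_input(Tensor(r.normal(size=4)), Tensor(r.normal(size=4)),
                                Tensor(r.normal(size=(3, 4))), np.array([1, 1, 2]))
        assert inp.positions.tolist() == [[0, 0, 1, 1, 2]]

    def test_all_placeholders_position_zero(self):
        r = _rng()
        inp = ia.assemble_input(Tensor(r.normal(size=4)), Tensor(r.normal(size=4)),
                                Tensor(np.zeros((6, 4))), np.zeros(6, dtype=int))
        assert inp.positions.tolist() == [[0] * 8]

    def test_width_mismatch_rejected(self):
        r = _rng()
        with pytest.raises(ValueError, match="width"):
            ia.assemble_input(Tensor(r.normal(size=3)), Tensor(r.normal(size=4)),
                              Tensor(r.normal(size=(2, 4))), np.array([1, 1]))


class TestPositionalEncoding:
    def test_zero_initialized_table_leaves_x_unchanged(self):
        enc = ia.PositionalEncoding(_config())
        x = Tensor(_rng().normal(size=(1, 5, 16)).astype(np.float32))
        inp = ia.InteractionInput(x, np.array([[0, 0, 1, 1, 2]]))
        assert np.array_equal(enc(inp).data, x.data)

    def test_same_rank_rows_receive_same_vector(self):
        enc = ia.PositionalEncoding(_config())
        enc.table.table.data[:] = _rng().normal(size=enc.table.table.shape)
        x = Tensor(np.zeros((1, 5, 16), np.float32))
        out = enc(ia.InteractionInput(x, np.array([[0, 0, 1, 1, 2]])))
        assert np.allclose(out.data[0, 2], out.data[0, 3])
        assert not np.allclose(out.data[0, 2], out.data[0, 4])

    def test_position_beyond_table_rejected(self):
        enc = ia.PositionalEncoding(_config())
        x = Tensor(np.zeros((1, 3, 16), np.float32))
        with pytest.raises(ValueError, match="table"):
            enc(ia.InteractionInput(x, np.array([[0, 0, 99]])))

    def test_joint_row_and_position_swap_equivariant(self):
        enc = ia.PositionalEncoding(_config())
        enc.table.table.data[:] = _rng().normal(size=enc.table.table.shape)
        x = _rng().normal(size=(1, 5, 16)).astype(np.float32)
        pos = np.array([[0, 0, 1, 2, 3]])
        out = enc(ia.InteractionInput(Tensor(x), pos)).data
        swap = [0, 1, 3, 2, 4]
        out_sw = enc(ia.InteractionInput(Tensor(x[:, swap]), pos[:, swap])).data
        assert np.allclose(out[:, swap], out_sw, atol=1e-6)


class TestTransformer:
    def test_output_shape_preserved(self):
        tx = ia.TransformerEncoder(_config(), _rng())
        x = Tensor(_rng().normal(size=(2, 7, 16)).astype(np.float32))
        out = tx(ia.InteractionInput(x, np.zeros((2, 7), dtype=int)))
        assert out.shape == (2, 7, 16)

    def test_attention_rows_sum_to_one(self):
        tx = ia.TransformerEncoder(_config(layers=2), _rng())
        x = Tensor(_rng().normal(size=(3, 6, 16)).astype(np.float32))
        tx(ia.InteractionInput(x, np.zeros((3, 6), dtype=int)))
        for att in tx.attention_tensors:
            assert np.allclose(att.sum(axis=-1), 1.0, atol=1e-5)

    def test_subpocket_permutation_leaves_global_rows_unchanged(self):
        """Permuting subpocket tokens together with their positions must not
        change the drug/protein rows of the update (self-attention is
        permutation-equivariant when positions travel with tokens)."""
        tx = ia.TransformerEncoder(_config(), _rng())
        tx.positional.table.table.data[:] = _rng().normal(
            size=tx.positional.table.table.shape).astype(np.float32) * 0.1
        x = _rng().normal(size=(1, 6, 16)).astype(np.float32)
        pos = np.array([[0, 0, 1, 2, 2, 3]])
        out = tx(ia.InteractionInput(Tensor(x), pos)).data
        perm = [0, 1, 4, 5, 2, 3]
        out_p = tx(ia.InteractionInput(Tensor(x[:, perm]), pos[:, perm])).data
        assert np.allclose(out[:, :2], out_p[:, :2], atol=1e-5)

    def test_indivisible_head_count_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ia.TransformerConfig(d=30, heads=4)


class TestPredictionHead:
    def test_zero_logit_gives_half(self):
        head = ia.PredictionHead(8, _rng())
        head.out.weight.data[:] = 0.0
        head.out.bias.data[:] = 0.0
        x = Tensor(_rng().normal(size=(4, 5, 8)).astype(np.float32))
        assert np.allclose(head(x).data, 0.5)

    def test_probability_monotone_in_logit(self):
        head = ia.PredictionHead(4, _rng())
        x = Tensor(_rng().normal(size=(3, 4, 4)).astype(np.float32))
        logits = head.logit(x).data
        probs = head(x).data
        order = np.argsort(logits)
        assert np.all(np.diff(probs[order]) >= 0)

    def test_identity_mlp_reduces_to_first_coordinate_sigmoid(self):
        """With an identity MLP and W_o = e_1, P = sigmoid(X'[0, 0])."""
        d = 4
        head = ia.PredictionHead(d, _rng(), mlp_widths=(2 * d, 2 * d))
        head.mlp.layers[0].weight.data = np.eye(2 * d, dtype=np.float32)
        head.mlp.layers[0].bias.data[:] = 0.0
        head.out.weight.data[:] = 0.0
        head.out.weight.data[0, 0] = 1.0
        head.out.bias.data[:] = 0.0
        x = _rng().normal(size=(2, 5, d)).astype(np.float32)
        expected = 1.0 / (1.0 + np.exp(-x[:, 0, 0]))
        assert np.allclose(head(Tensor(x)).data, expected, atol=1e-6)


class TestBceLoss:
    def test_confident_correct_loss_vanishes(self):
        loss = ia.bce_loss(np.array([1.0]), Tensor(np.array([1.0 - 1e-9])))
        assert float(loss.data) < 1e-5

    def test_half_probability_gives_ln2(self):
        loss = ia.bce_loss(np.array([1.0]), Tensor(np.array([0.5])))
        assert float(loss.data) == pytest.approx(np.log(2.0), abs=1e-6)

    def test_wrong_confident_gives_ln10(self):
        loss = ia.bce_loss(np.array([0.0]), Tensor(np.array([0.9])))
        assert float(loss.data) == pytest.approx(-np.log(0.1), abs=1e-6)

    def test_batch_loss_is_mean(self):
        loss = ia.bce_loss(np.array([1.0, 0.0]),
                           Tensor(np.array([0.5, 0.9])))
        expected = (np.log(2.0) - np.log(0.1)) / 2
        assert float(loss.data) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("y", [0.0, 1.0])
    def test_minimum_at_true_label_on_grid(self, y):
        grid = np.linspace(0.01, 0.99, 99)
        losses = [float(ia.bce_loss(np.array([y]), Tensor(np.array([p]))).data)
                  for p in grid]
        assert np.argmin(losses) == (len(grid) - 1 if y == 1.0 else 0)


def test_gradient_reaches_every_parameter(small_model, tiny_featurized, tiny_dataset):
    """One random training batch sends a nonzero gradient to every trainable
    parameter: encoders, positional table, attention, head."""
    model = small_model
    model.zero_grad()
    batch = tiny_dataset.pairs[:16]
    labels = np.array([p.label for p in batch])
    probs = model.forward(batch, tiny_featurized, training=True,
                          rng=np.random.default_rng(0))
    loss = ia.bce_loss(labels, probs)
    loss.backward()
    missing = [p.name for p in model.parameters()
               if p.grad is None or not np.any(p.grad)]
    assert missing == []
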