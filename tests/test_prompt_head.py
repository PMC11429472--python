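"""Prompt template, text encoding, controller and dynamic head."""

import numpy as np
import pytest

from conftest import micro_model_config
from fundusseg.autograd import Tensor, no_grad
from fundusseg.model import FundusTumorNet
from fundusseg.prompt_head import (DEFAULT_CHAIN, Classifier, Controller,
                                   DynamicHeadParams, HashTextEncoder,
                                   PromptTemplate, apply_dynamic_head,
                                   chain_param_count, fill_prompt)


class TestPromptTemplate:
    def test_exact_sentences(self):
        t = PromptTemplate()
        assert fill_prompt(t, 0) == "it is a image of benign tumor"
        assert fill_prompt(t, 1) == "it is a image of malignant tumor"

    def test_no_placeholder_remains(self):
        assert "{" not in fill_prompt(PromptTemplate(), 0)

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            fill_prompt(PromptTemplate(), 2)


class TestHashTextEncoder:
    def test_deterministic_unit_norm(self):
        enc = HashTextEncoder()
        v1 = enc.encode("it is a image of benign tumor")
        v2 = enc.encode("it is a image of benign tumor")
        assert np.array_equal(v1, v2)
        assert v1.shape == (512,)
        assert np.isclose(np.linalg.norm(v1), 1.0, atol=1e-6)

    def test_distinct_sentences_distinct_vectors(self):
        enc = HashTextEncoder()
        a = enc.encode("it is a image of benign tumor")
        b = enc.encode("it is a image of malignant tumor")
        assert abs(float(a @ b)) < 0.99

    def test_token_normalisation(self):
        enc = HashTextEncoder()
        assert np.array_equal(enc.encode("Benign  Tumor"), enc.encode("benign tumor"))

    def test_empty_sentence_rejected(self):
        with pytest.raises(ValueError):
            HashTextEncoder().encode("")


class TestController:
    def test_flat_vector_length_113(self):
        assert chain_param_count(DEFAULT_CHAIN) == 113
        ctrl = Controller(16, np.random.default_rng(0))
        params = ctrl(Tensor(np.random.default_rng(1).random((2, 16))))
        total = sum(int(np.prod(w.shape[1:])) for w in params.weights) + \
            sum(int(np.prod(b.shape[1:])) for b in params.biases)
        assert total == 113

    def test_zero_controller_gives_zero_params(self):
        ctrl = Controller(8, np.random.default_rng(0))
        for p in ctrl.parameters():
            p.data[:] = 0.0
        params = ctrl(Tensor(np.ones((1, 8))))
        for w, b in zip(params.weights, params.biases):
            assert np.allclose(w.data, 0.0) and np.allclose(b.data, 0.0)

    def test_distinct_inputs_distinct_params(self):
        ctrl = Controller(8, np.random.default_rng(3))
        a = ctrl(Tensor(np.zeros((1, 8))))
        b = ctrl(Tensor(np.ones((1, 8))))
        assert np.abs(a.weights[0].data - b.weights[0].data).max() > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DynamicHeadParams.from_flat(Tensor(np.zeros((1, 100))))


class TestDynamicHead:
    def test_zero_params_give_uniform_half(self):
        flat = Tensor(np.zeros((1, 113)))
        params = DynamicHeadParams.from_flat(flat)
        out = apply_dynamic_head(np.random.default_rng(0).random((1, 3, 4, 4)), params)
        assert np.allclose(out.data, 0.5)

    def test_output_bounded(self):
        rng = np.random.default_rng(1)
        params = DynamicHeadParams.from_flat(Tensor(rng.standard_normal((2, 113))))
        out = apply_dynamic_head(rng.standard_normal((2, 3, 5, 5)), params)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            flat = rng.standard_normal(113)
            params = DynamicHeadParams.from_flat(Tensor(flat[None]))
            x = rng.standard_normal((3, 1, 3))   # 3 pixels
            got = apply_dynamic_head(x[None], params).data[0]
            # brute-force per-pixel evaluation
            ws, bs, off = [], [], 0
            for cin, cout in zip(DEFAULT_CHAIN, DEFAULT_CHAIN[1:]):
                ws.append(flat[off:off + cin * cout].reshape(cout, cin)); off += cin * cout
                bs.append(flat[off:off + cout]); off += cout
            for i in range(1):
                for j in range(3):
                    v = x[:, i, j]
                    for li, (w, b) in enumerate(zip(ws, bs)):
                        v = w @ v + b
                        if li < 2:
                            v = np.maximum(v, 0)
                    expect = 1 / (1 + np.exp(-v[0]))
                    assert abs(got[i, j] - expect) < 1e-4

    def test_channel_mismatch_rejected(self):
        params = DynamicHeadParams.from_flat(Tensor(np.zeros((1, 113))))
        with pytest.raises(ValueError):
            apply_dynamic_head(np.zeros((1, 4, 2, 2)), params)


class TestClassifier:
    def test_probabilities_sum_to_one(self):
        clf = Classifier(16, np.random.default_rng(0))
        probs = clf(Tensor(np.random.default_rng(1).random((3, 16, 2, 2))))
        assert np.allclose(probs.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform(self):
        clf = Classifier(8, np.random.default_rng(0))
        for p in clf.parameters():
            p.data[:] = 0.0
        probs = clf(Tensor(np.random.default_rng(2).random((2, 8, 2, 2))))
        assert np.allclose(probs.data, 0.5, atol=1e-7)


class TestPromptPathLiveness:
    def test_swapping_prompt_changes_mask(self, micro_model, tiny_dataset):
        X, _, _ = tiny_dataset
        benign = micro_model.predict(X[:1], class_override=[0])["mask_prob"]
        malignant = micro_model.predict(X[:1], class_override=[1])["mask_prob"]
        assert np.abs(benign - malignant).max() > 0

    def test_text_encoder_has_no_trainable_parameters(self, micro_model):
        names = [n for n, _ in micro_model.named_parameters()]
        assert not any("text_encoder" in n for n in names)

    def test_teacher_forcing_and_eval_share_code_path(self, tiny_dataset):
        """With the override equal to the predicted class, outputs coincide."""
        X, _, _ = tiny_dataset
        model = FundusTumorNet(micro_model_config(seed=2))
        free = model.predict(X[:1])
        forced = model.predict(X[:1], class_override=[int(free["class_index"][0])])
        assert np.array_equal(free["mask_prob"], forced["mask_prob"])
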