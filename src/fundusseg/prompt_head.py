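"""Classification-driven prompt dynamic segmentation head.

The fused encoder map F is pooled and classified (benign vs malignant) by a
small MLP; the predicted class fills a fixed natural-language template —
``"it is a image of {lesion class}"`` with class names "benign tumor" /
"malignant tumor" — and a frozen text encoder embeds the sentence.  The
pooled features concatenated with the prompt embedding (proF) drive a
three-layer controller that emits, per image, the kernels and biases of a
three-layer 1x1 convolutional head over the decoded full-resolution map F'
(channel chain 3 -> 8 -> 8 -> 1, sigmoid output; 113 parameters).

During training the template is filled with the ground-truth class (teacher
forcing); at inference the classifier's argmax is used — both run through
the identical code path via ``class_override``.  The default text encoder
is a deterministic hash embedding (unit-norm, 512-dimensional) so nothing
needs downloading; any callable mapping a sentence to a fixed-size vector
(e.g. a real CLIP text tower) can be injected instead, and is never
trained.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, concatenate, maximum
from .fusion import gap
from .nn import Linear, Module, softmax

__all__ = ["PromptTemplate", "HashTextEncoder", "DynamicHeadParams", "fill_prompt",
           "Classifier", "Controller", "apply_dynamic_head", "PromptDynamicHead",
           "DEFAULT_CHAIN"]

DEFAULT_CHAIN = (3, 8, 8, 1)


@dataclass(frozen=True)
class PromptTemplate:
    template: str = "it is a image of {lesion class}"
    class_names: tuple = ("benign tumor", "malignant tumor")

    def fill(self, class_index: int) -> str:
        if not 0 <= class_index < len(self.class_names):
            raise IndexError(f"class index {class_index} out of range")
        sentence = self.template.replace("{lesion class}", self.class_names[class_index])
        if "{" in sentence or "}" in sentence:
            raise ValueError(f"unexpanded placeholder in prompt: {sentence!r}")
        return sentence


def fill_prompt(template: PromptTemplate, class_index: int) -> str:
    return template.fill(class_index)


class HashTextEncoder:
    """Deterministic stand-in text encoder: a unit-norm vector seeded by a
    stable hash of the lowercased token sequence.  Has no trainable state."""

    name = "hash"
    frozen = True

    def __init__(self, dim: int = 512):
        self.dim = dim

    def encode(self, sentence: str) -> np.ndarray:
        if not sentence:
            raise ValueError("cannot encode an empty sentence")
        tokens = " ".join(sentence.lower().split())
        digest = hashlib.sha256(tokens.encode("utf-8")).digest()
        seed = int.from_bytes(digest[:8], "little")
        vec = np.random.default_rng(seed).standard_normal(self.dim)
        return (vec / np.linalg.norm(vec)).astype(np.float32)

    def __call__(self, sentence: str) -> np.ndarray:
        return self.encode(sentence)


def chain_param_count(chain=DEFAULT_CHAIN) -> int:
    return sum(cin * cout + cout for cin, cout in zip(chain, chain[1:]))


@dataclass
class DynamicHeadParams:
    """Per-image kernels and biases for the 1x1 head, split from a flat vector."""

    weights: list  # per layer: [N, C_out, C_in]
    biases: list   # per layer: [N, C_out]
    chain: tuple = DEFAULT_CHAIN

    @classmethod
    def from_flat(cls, flat: Tensor, chain=DEFAULT_CHAIN) -> "DynamicHeadParams":
        expected = chain_param_count(chain)
        if flat.shape[-1] != expected:
            raise ValueError(f"flat parameter vector has length {flat.shape[-1]}, "
                             f"expected {expected} for chain {chain}")
        n = flat.shape[0]
        weights, biases, offset = [], [], 0
        for cin, cout in zip(chain, chain[1:]):
            w = flat[:, offset:offset + cin * cout].reshape(n, cout, cin)
            offset += cin * cout
            b = flat[:, offset:offset + cout]
            offset += cout
            weights.append(w)
            biases.append(b)
        return cls(weights=weights, biases=biases, chain=tuple(chain))


class Classifier(Module):
    """GAP -> two-layer MLP -> softmax over {benign, malignant}."""

    def __init__(self, in_channels: int, rng: np.random.Generator, hidden: int = 256):
        self.fc1 = Linear(in_channels, hidden, rng)
        self.fc2 = Linear(hidden, 2, rng)

    def forward(self, fused: Tensor) -> Tensor:
        pooled = gap(as_tensor(fused))
        n, c = pooled.shape[0], pooled.shape[1]
        return softmax(self.fc2(self.fc1(pooled.reshape(n, c)).relu()), axis=-1)


class Controller(Module):
    """Three linear layers mapping proF to the flat dynamic parameter vector."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 hidden: int = 256, chain=DEFAULT_CHAIN):
        self.chain = tuple(chain)
        out = chain_param_count(chain)
        self.fc1 = Linear(in_features, hidden, rng)
        self.fc2 = Linear(hidden, hidden, rng)
        self.fc3 = Linear(hidden, out, rng)

    def forward(self, pro_f: Tensor) -> DynamicHeadParams:
        flat = self.fc3(self.fc2(self.fc1(as_tensor(pro_f)).relu()).relu())
        return DynamicHeadParams.from_flat(flat, self.chain)


def apply_dynamic_head(f_prime, params: DynamicHeadParams) -> Tensor:
    """Run the per-image 1x1 convolution chain; returns [N, H, W] in (0, 1)."""
    x = as_tensor(f_prime)
    if x.ndim == 3:
        x = x.reshape(1, *x.shape)
    n, c, h, w = x.shape
    if c != params.chain[0]:
        raise ValueError(f"F' has {c} channels, head chain expects {params.chain[0]}")
    y = x.reshape(n, c, h * w)
    last = len(params.weights) - 1
    for i, (wgt, bias) in enumerate(zip(params.weights, params.biases)):
        y = wgt @ y + bias.reshape(n, -1, 1)
        if i < last:
            y = y.relu()
    return y.sigmoid().reshape(n, h, w)


class PromptDynamicHead(Module):
    """Classifier + prompt template + frozen text encoder + controller + head."""

    def __init__(self, fused_channels: int, rng: np.random.Generator,
                 text_encoder=None, template: PromptTemplate | None = None,
                 controller_hidden: int = 256, chain=DEFAULT_CHAIN):
        self.template = template or PromptTemplate()
        self.text_encoder = text_encoder or HashTextEncoder()
        self.chain = tuple(chain)
        self.classifier = Classifier(fused_channels, rng)
        self.controller = Controller(fused_channels + self.text_encoder.dim, rng,
                                     hidden=controller_hidden, chain=chain)
        # prompt embeddings are deterministic; cache per class index
        self._prompt_cache: dict = {}

    def prompt_embedding(self, class_index: int) -> np.ndarray:
        if class_index not in self._prompt_cache:
            sentence = self.template.fill(class_index)
            self._prompt_cache[class_index] = self.text_encoder.encode(sentence)
        return self._prompt_cache[class_index]

    def forward(self, fused: Tensor, f_prime: Tensor, class_override=None):
        """Returns (probability map [N,H,W], class probabilities [N,2]).

        ``class_override``: integer labels used to fill the template instead
        of the classifier argmax (teacher forcing / ablation probing).
        """
        fused = as_tensor(fused)
        class_probs = self.classifier(fused)
        if class_override is None:
            class_idx = np.argmax(class_probs.data, axis=-1)
        else:
            class_idx = np.asarray(class_override, dtype=np.int64).reshape(-1)
        n, c = fused.shape[0], fused.shape[1]
        pooled = gap(fused).reshape(n, c)
        prompts = np.stack([self.prompt_embedding(int(i)) for i in class_idx])
        pro_f = concatenate([pooled, Tensor(prompts)], axis=1)
        params = self.controller(pro_f)
        prob_map = apply_dynamic_head(f_prime, params)
        return prob_map, class_probs
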