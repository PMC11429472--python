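"""The full segmentation network: pyramid -> encoder -> fusion -> classifier/
prompt -> decoder -> dynamic head."""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor, no_grad
from .decoder import Decoder, DecoderConfig
from .encoder import EncoderConfig, MultiBranchEncoder
from .fusion import FeatureFusion
from .nn import Module
from .prompt_head import DEFAULT_CHAIN, PromptDynamicHead, PromptTemplate
from .pyramid import build_pyramid

__all__ = ["ModelConfig", "FundusTumorNet"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    head_chain: tuple = DEFAULT_CHAIN
    controller_hidden: int = 256
    text_encoder: str = "hash"            # injection point; "hash" is built in
    prompt_template: str = "it is a image of {lesion class}"
    class_names: tuple = ("benign tumor", "malignant tumor")
    seed: int = 0

    @property
    def decoder_channels(self) -> tuple:
        d = self.encoder.micro_scale
        seq = self.decoder.channel_sequence
        return tuple(c // d for c in seq[:-1]) + (seq[-1],)


class FundusTumorNet(Module):
    """End-to-end model; construction is a pure function of the config."""

    def __init__(self, cfg: ModelConfig | None = None, text_encoder=None):
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = MultiBranchEncoder(cfg.encoder, rng)
        c_last = cfg.encoder.out_channels
        self.fusion = (FeatureFusion(c_last, rng)
                       if cfg.encoder.variant == "multiscale" else None)
        self.decoder = Decoder(c_last, self._skip_plan(), rng,
                               DecoderConfig(self.decoder_channels))
        template = PromptTemplate(cfg.prompt_template, tuple(cfg.class_names))
        self.head = PromptDynamicHead(c_last, rng, text_encoder=text_encoder,
                                      template=template,
                                      controller_hidden=cfg.controller_hidden,
                                      chain=cfg.head_chain)

    @property
    def decoder_channels(self):
        return self.cfg.decoder_channels

    def _skip_plan(self) -> dict:
        """Concatenated skip widths per resolution divisor, from the config."""
        enc = self.cfg.encoder
        ch = enc.channels
        if enc.variant == "multiscale":
            return {4: 2 * ch[0], 8: 3 * ch[1], 16: 3 * ch[2], 32: 3 * ch[3]}
        return {4: ch[0], 8: ch[1], 16: ch[2], 32: ch[3]}

    def forward(self, images, class_override=None) -> dict:
        """images: [N, 3, H, W] with H, W divisible by 32.

        Returns mask probabilities [N, H, W], class probabilities [N, 2],
        the fused map F and decoded map F'.
        """
        x = as_tensor(images)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        pyr = build_pyramid(x)
        feats = self.encoder(pyr)
        if self.fusion is not None:
            fused = self.fusion(feats.f1, feats.f2, feats.f3)
        else:
            fused = feats.f1
        f_prime = self.decoder(fused, feats.stage_maps)
        prob_map, class_probs = self.head(fused, f_prime, class_override=class_override)
        return {"mask_prob": prob_map, "class_probs": class_probs,
                "fused": fused, "f_prime": f_prime, "pyramid": feats}

    def predict(self, images, threshold: float = 0.5, class_override=None) -> dict:
        """Inference without graph recording; adds binary masks and labels."""
        with no_grad():
            out = self.forward(images, class_override=class_override)
        prob = out["mask_prob"].data
        cls = out["class_probs"].data
        return {
            "mask_prob": prob,
            "mask": (prob >= threshold).astype(np.uint8),
            "class_probs": cls,
            "class_index": np.argmax(cls, axis=-1),
        }

    # -- checkpoints ----------------------------------------------------------

    def save(self, path) -> None:
        """Single-file zip archive: version + config JSON + parameter arrays."""
        meta = {"version": CHECKPOINT_VERSION, "config": _config_dict(self.cfg)}
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("meta.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **self.state_dict())
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path, text_encoder=None) -> "FundusTumorNet":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
            cfg = config_from_dict(meta["config"])
            with zf.open("params.npz") as fh:
                arrays = dict(np.load(io.BytesIO(fh.read())))
        model = cls(cfg, text_encoder=text_encoder)
        model.load_state_dict(arrays)
        return model


def _config_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    return d


def config_from_dict(d: dict) -> ModelConfig:
    enc = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d["encoder"].items()})
    dec = DecoderConfig(channel_sequence=tuple(d["decoder"]["channel_sequence"]))
    return ModelConfig(
        encoder=enc, decoder=dec,
        head_chain=tuple(d["head_chain"]),
        controller_hidden=d["controller_hidden"],
        text_encoder=d["text_encoder"],
        prompt_template=d["prompt_template"],
        class_names=tuple(d["class_names"]),
        seed=d["seed"],
    )
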