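"""The assembled multi-task network: shared backbone + task heads.

A single forward pass yields the per-class prediction vector Vp and (unless
the reconstruction head is ablated) the reconstructed image.  The two heads
share the backbone, so the reconstruction objective shapes the same features
the classifier reads — this is what lets unlabeled images contribute to
training.
"""

from __future__ import annotations

import json

import numpy as np

from . import nn
from .backbone import Backbone, BackboneConfig
from .heads import ClassificationHead, Decoder, DecoderConfig, Encoder
from .nn import Tensor

__all__ = ["MultiTaskNet", "save_checkpoint", "load_checkpoint"]


class MultiTaskNet(nn.Module):
    """Backbone -> Vf -> {classification head, encoder + decoder}.

    ``use_rsn=False`` ablates the reconstruction sub-network (its parameters
    are never allocated); ``cfg.use_attention=False`` on the backbone config
    ablates the attention modules.
    """

    def __init__(
        self,
        backbone_cfg: BackboneConfig,
        n_classes: int,
        decoder_cfg: DecoderConfig | None = None,
        seed: int = 0,
        use_softmax: bool = False,
        encoder_hidden: int | None = None,
    ):
        super().__init__()
        if n_classes < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(seed)
        self.backbone_cfg = backbone_cfg
        self.decoder_cfg = decoder_cfg
        self.n_classes = n_classes
        self.backbone = Backbone(backbone_cfg, rng)
        self.csn = ClassificationHead(
            backbone_cfg.feature_dim, n_classes, rng, use_softmax
        )
        self.encoder = None
        self.decoder = None
        if decoder_cfg is not None:
            decoder_cfg.validate_against(backbone_cfg.input_size)
            if decoder_cfg.dimensionality != backbone_cfg.dimensionality:
                raise ValueError("decoder/backbone dimensionality mismatch")
            self.encoder = Encoder(
                backbone_cfg.feature_dim, decoder_cfg.encoded_dim, rng, encoder_hidden
            )
            self.decoder = Decoder(decoder_cfg, rng)

    @property
    def has_rsn(self) -> bool:
        return self.decoder is not None

    def forward(self, x: Tensor, with_reconstruction: bool = True):
        """Return (Vp, reconstruction-or-None) for an image batch."""
        vf = self.backbone(x)
        vp = self.csn(vf)
        imr = None
        if with_reconstruction and self.has_rsn:
            imr = self.decoder(self.encoder(vf))
        return vp, imr

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Eval-mode class probabilities for an array of images (no channel axis)."""
        self.eval()
        out = []
        x = np.asarray(images, dtype=float)
        for start in range(0, len(x), batch_size):
            batch = x[start : start + batch_size, None]  # add channel axis
            vp, _ = self.forward(Tensor(batch), with_reconstruction=False)
            out.append(vp.data)
        return np.concatenate(out, axis=0)

    def csn_parameters(self) -> list[nn.Parameter]:
        return self.csn.parameters()

    def rsn_parameters(self) -> list[nn.Parameter]:
        if not self.has_rsn:
            return []
        return self.encoder.parameters() + self.decoder.parameters()


def _cfg_to_json(model: MultiTaskNet) -> str:
    payload = {
        "backbone": {**vars(model.backbone_cfg)},
        "decoder": None if model.decoder_cfg is None else {**vars(model.decoder_cfg)},
        "n_classes": model.n_classes,
        "use_softmax": model.csn.use_softmax,
    }
    return json.dumps(payload, default=list)


def save_checkpoint(model: MultiTaskNet, path, extra: dict | None = None) -> None:
    """Write parameters + architecture config into one .npz checkpoint."""
    state = model.state_dict()
    meta = {"config": _cfg_to_json(model), "extra": json.dumps(extra or {})}
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[MultiTaskNet, dict]:
    """Rebuild the network from a checkpoint; returns (model, extra-metadata)."""
    with np.load(path, allow_pickle=False) as zf:
        meta = json.loads(str(zf["__meta__"]))
        state = {k: zf[k] for k in zf.files if k != "__meta__"}
    cfg = json.loads(meta["config"])
    backbone_cfg = BackboneConfig(**{
        **cfg["backbone"],
        "stage_channels": tuple(cfg["backbone"]["stage_channels"]),
        "blocks_per_stage": tuple(cfg["backbone"]["blocks_per_stage"]),
        "input_size": tuple(cfg["backbone"]["input_size"]),
    })
    decoder_cfg = None
    if cfg["decoder"] is not None:
        decoder_cfg = DecoderConfig(**cfg["decoder"])
    model = MultiTaskNet(
        backbone_cfg, cfg["n_classes"], decoder_cfg, use_softmax=cfg["use_softmax"]
    )
    model.load_state_dict(state)
    return model, json.loads(meta["extra"])
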