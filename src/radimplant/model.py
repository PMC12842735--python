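"""Masked autoencoder with pixel- and embedding-prediction heads.

The encoder is a ViT over patch tokens; during pre-training it sees only
the visible tokens (their embeddings plus fixed 2-D sine-cosine position
codes). A lightweight decoder receives the full-length token sequence —
projected visible latents plus a single shared learnable mask token at
every masked slot, each with its decoder-side position code — and a
linear head predicts, per masked patch, either the raw pixels (the
classic masked-autoencoder baseline) or the deep patch embedding (the
masked-deep-embedding objective, trained with an L1 loss elsewhere).

A ``simmim_routing`` switch instead feeds the corrupted full sequence to
the encoder, for comparison with the alternative reading of the
architecture; the default is the encoder-sees-visible-only routing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from ._autograd import Tensor, concatenate, gather
from .config import RunConfig, rng_for
from .patches import MaskSpec, PatchGrid, patchify, positional_encoding, unpatchify

__all__ = ["MaskedAutoencoder", "load_checkpoint"]

_HEADS = ("pixel", "embedding")


class MaskedAutoencoder(nn.Module):
    def __init__(self, cfg: RunConfig, head: str = "embedding", channels: int = 1,
                 tokenizer_depth: int = 1, simmim_routing: bool = False,
                 init_seed: int | None = None):
        if head not in _HEADS:
            raise ValueError(f"head must be one of {_HEADS}, got {head!r}")
        rng = rng_for(cfg.seed if init_seed is None else init_seed, "model-init")
        self.cfg = cfg
        self.head_type = head
        self.channels = channels
        self.simmim_routing = simmim_routing
        p = cfg.patch_size
        self.patch_dim = p * p * channels
        if tokenizer_depth == 1:
            self.tokenizer = nn.Linear(self.patch_dim, cfg.enc_dim, rng)
        elif tokenizer_depth == 2:
            self.tokenizer = _MLPTokenizer(self.patch_dim, cfg.enc_dim, rng)
        else:
            raise ValueError("tokenizer_depth must be 1 or 2")
        self.tokenizer_depth = tokenizer_depth
        self.encoder = nn.TransformerEncoder(cfg.enc_dim, cfg.enc_depth, cfg.enc_heads, rng)
        self.enc_norm = nn.LayerNorm(cfg.enc_dim)
        self.dec_embed = nn.Linear(cfg.enc_dim, cfg.dec_dim, rng)
        self.mask_token = Tensor(rng.normal(0.0, 0.02, size=(1, cfg.dec_dim)), requires_grad=True)
        if simmim_routing:
            self.enc_mask_token = Tensor(rng.normal(0.0, 0.02, size=(1, cfg.enc_dim)),
                                         requires_grad=True)
        self.decoder = nn.TransformerEncoder(cfg.dec_dim, cfg.dec_depth, cfg.dec_heads, rng)
        self.dec_norm = nn.LayerNorm(cfg.dec_dim)
        out_dim = self.patch_dim if head == "pixel" else cfg.enc_dim
        self.head = nn.Linear(cfg.dec_dim, out_dim, rng)
        rows, cols = cfg.grid
        self.pos_enc = positional_encoding((rows, cols), cfg.enc_dim)  # fixed, (N, D_enc)
        self.pos_dec = positional_encoding((rows, cols), cfg.dec_dim)
        self.n_patches = rows * cols

    # -- pieces ---------------------------------------------------------
    def embed_patches(self, patches) -> Tensor:
        """Map flattened patches (..., N, P*P*C) to embeddings (..., N, D_enc)."""
        x = patches if isinstance(patches, Tensor) else Tensor(np.asarray(patches, dtype=np.float64))
        if x.shape[-1] != self.patch_dim:
            raise ValueError(f"patch vectors of length {x.shape[-1]}, expected {self.patch_dim}")
        return self.tokenizer(x)

    def encode_visible(self, tokens: Tensor) -> Tensor:
        """Run the encoder over an already-selected visible token sequence."""
        return self.enc_norm(self.encoder(tokens))

    def assemble_decoder_input(self, latent: Tensor, masks: np.ndarray,
                               visibles: np.ndarray) -> Tensor:
        """Restore original patch order: projected latents at visible slots,
        the shared mask token at masked slots, each plus its decoder position code.

        ``masks``/``visibles`` are index arrays, (M,)/(V,) or batched (B, M)/(B, V).
        """
        batched = latent.ndim == 3
        masks = np.atleast_2d(np.asarray(masks)) if batched else np.asarray(masks)
        visibles = np.atleast_2d(np.asarray(visibles)) if batched else np.asarray(visibles)
        proj = self.dec_embed(latent)
        if batched:
            vis_part = proj + Tensor(self.pos_dec[visibles])          # (B, V, Dd)
            mask_part = self.mask_token + Tensor(self.pos_dec[masks])  # (B, M, Dd)
            combined = concatenate([vis_part, mask_part], axis=1)
            order = np.concatenate([visibles, masks], axis=1)          # (B, N)
            inv = np.argsort(order, axis=1)
        else:
            vis_part = proj + Tensor(self.pos_dec[visibles])
            mask_part = self.mask_token + Tensor(self.pos_dec[masks])
            combined = concatenate([vis_part, mask_part], axis=0)
            order = np.concatenate([visibles, masks])
            inv = np.argsort(order)
            if len(order) != len(set(order.tolist())):
                raise ValueError("visible and masked index sets overlap")
        return gather(combined, inv)

    def decode(self, ec: Tensor) -> Tensor:
        if ec.shape[-2] != self.n_patches:
            raise ValueError(f"decoder input length {ec.shape[-2]}, expected {self.n_patches}")
        return self.dec_norm(self.decoder(ec))

    def predict_targets(self, decoder_out: Tensor, masks: np.ndarray) -> Tensor:
        """Head outputs at masked positions only: (..., M, P²C) or (..., M, D_enc)."""
        return gather(self.head(decoder_out), np.asarray(masks))

    # -- end-to-end pre-training forward --------------------------------
    def forward_pretrain(self, images: np.ndarray, mask_specs: list[MaskSpec]) -> dict:
        """One pre-training forward pass over a batch of images.

        Returns predictions at masked positions plus the matching targets:
        pixel-space patches for the pixel head, stop-gradient patch
        embeddings of the original (uncorrupted) patches for the
        embedding head.
        """
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        batch = images.shape[0]
        if len(mask_specs) != batch:
            raise ValueError("one MaskSpec per image required")
        p = self.cfg.patch_size
        patch_stack = np.stack([patchify(im, p).patches for im in images])  # (B, N, L)
        masked = np.stack([m.masked_idx for m in mask_specs])
        visible = np.stack([m.visible_idx for m in mask_specs])
        emb = self.embed_patches(patch_stack)  # (B, N, D)
        if self.simmim_routing:
            full = emb + Tensor(self.pos_enc)
            # overwrite masked slots with the encoder-side mask token
            keep = np.ones((batch, self.n_patches, 1))
            np.put_along_axis(keep, masked[:, :, None], 0.0, axis=1)
            corrupted = full * Tensor(keep) + (self.enc_mask_token + Tensor(self.pos_enc)) * Tensor(1.0 - keep)
            latent = self.encode_visible(corrupted)
            dec_in = self.dec_embed(latent) + Tensor(self.pos_dec)
            dec_out = self.dec_norm(self.decoder(dec_in))
        else:
            vis_tokens = gather(emb + Tensor(self.pos_enc), visible)
            latent = self.encode_visible(vis_tokens)
            ec = self.assemble_decoder_input(latent, masked, visible)
            dec_out = self.decode(ec)
        pred = gather(self.head(dec_out), masked)
        if self.head_type == "pixel":
            target = np.take_along_axis(patch_stack, masked[:, :, None], axis=1)
        else:
            target = np.take_along_axis(emb.data, masked[:, :, None], axis=1)  # stop-gradient
        return {"pred": pred, "target": target, "masked": masked, "visible": visible}

    # -- detection backbone ---------------------------------------------
    def encoder_features(self, image: np.ndarray) -> Tensor:
        """Full-sequence encoder tokens for a (H, W) image or (B, H, W) batch."""
        images = np.asarray(image, dtype=np.float64)
        single = images.ndim == 2
        if single:
            images = images[None]
        patch_stack = np.stack([patchify(im, self.cfg.patch_size).patches for im in images])
        tokens = self.encode_visible(self.embed_patches(patch_stack) + Tensor(self.pos_enc))
        return tokens[0] if single else tokens

    # -- qualitative reconstruction -------------------------------------
    def visualize_reconstruction(self, image: np.ndarray, mask: MaskSpec) -> np.ndarray:
        """Composite of visible patches and predicted masked content.

        Qualitative only — never used for supervision. For the embedding
        head, predicted embeddings are mapped back to pixels through the
        least-squares pseudo-inverse of the affine tokenizer.
        """
        out = self.forward_pretrain(image, [mask])
        pred = out["pred"].data[0]  # (M, out_dim)
        grid = patchify(np.asarray(image, dtype=np.float64), self.cfg.patch_size)
        patches = grid.patches.copy()
        if self.head_type == "pixel":
            patches[mask.masked_idx] = pred
        else:
            if self.tokenizer_depth != 1:
                raise ValueError("embedding-head visualization needs the affine tokenizer")
            w, b = self.tokenizer.weight.data, self.tokenizer.bias.data
            patches[mask.masked_idx] = (pred - b) @ np.linalg.pinv(w)
        return unpatchify(PatchGrid(grid.patch_size, grid.rows, grid.cols,
                                    grid.channels, patches))

    # -- checkpoints -----------------------------------------------------
    def _meta(self) -> dict:
        from dataclasses import asdict
        return {"run_config": asdict(self.cfg), "head": self.head_type,
                "channels": self.channels, "tokenizer_depth": self.tokenizer_depth,
                "simmim_routing": self.simmim_routing, "schema": 1}

    def encoder_state(self) -> dict[str, np.ndarray]:
        """Backbone-only weights: tokenizer + encoder + final norm.

        Decoder, mask token and prediction head are pre-training
        auxiliaries and are deliberately absent.
        """
        keep = ("tokenizer.", "encoder.", "enc_norm.")
        return {k: v for k, v in self.state_dict().items() if k.startswith(keep)}

    def save_checkpoint(self, path: str | Path, encoder_only: bool = False):
        state = self.encoder_state() if encoder_only else self.state_dict()
        meta = self._meta()
        meta["encoder_only"] = encoder_only
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                     **state)

    def load_encoder_state(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        for k, arr in state.items():
            if k not in own:
                raise KeyError(f"unexpected checkpoint key {k}")
            own[k].data = np.asarray(arr, dtype=np.float64).copy()


class _MLPTokenizer(nn.Module):
    """Optional 2-layer patch tokenizer."""

    def __init__(self, in_dim: int, out_dim: int, rng):
        self.fc1 = nn.Linear(in_dim, out_dim, rng)
        self.fc2 = nn.Linear(out_dim, out_dim, rng)

    def __call__(self, x):
        return self.fc2(self.fc1(x).gelu())


def load_checkpoint(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    """Read a saved checkpoint; returns (metadata, state arrays)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    return meta, state
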