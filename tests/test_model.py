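"""Autoencoder structure: tokenizer, visible-only encoding, decoder
assembly bookkeeping, heads, checkpoints, reconstruction."""

import itertools

import numpy as np
import pytest

from radimplant import RunConfig
from radimplant._autograd import Tensor
from radimplant.model import MaskedAutoencoder, load_checkpoint
from radimplant.patches import MaskSpec, patchify, sample_mask


@pytest.fixture()
def model(tiny_cfg):
    return MaskedAutoencoder(tiny_cfg, head="embedding")


def _mask_from_sets(n, masked):
    masked = np.asarray(sorted(masked))
    visible = np.setdiff1d(np.arange(n), masked)
    return MaskSpec(n_patches=n, masked_idx=masked, visible_idx=visible,
                    ratio=len(masked) / n)


def test_embed_patches_matches_affine_oracle(model, rng):
    patches = rng.random((5, model.patch_dim))
    out = model.embed_patches(patches).data
    oracle = patches @ model.tokenizer.weight.data + model.tokenizer.bias.data
    np.testing.assert_allclose(out, oracle, atol=1e-12)
    assert out.shape == (5, model.cfg.enc_dim)


def test_zero_patches_zero_bias_give_zero_embeddings(model):
    model.tokenizer.bias.data[:] = 0.0
    out = model.embed_patches(np.zeros((3, model.patch_dim)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_encoder_output_length_and_permutation_consistency(model, rng):
    tokens = rng.normal(size=(10, model.cfg.enc_dim))
    out = model.encode_visible(Tensor(tokens)).data
    assert out.shape == (10, model.cfg.enc_dim)
    perm = rng.permutation(10)
    out_perm = model.encode_visible(Tensor(tokens[perm])).data
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-5)


def test_depth_zero_encoder_is_layernorm_only(tiny_cfg, rng):
    cfg = RunConfig.tiny(seed=5, enc_depth=0)
    m = MaskedAutoencoder(cfg, head="embedding")
    x = rng.normal(size=(4, cfg.enc_dim))
    out = m.encode_visible(Tensor(x)).data
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    np.testing.assert_allclose(out, (x - mu) / np.sqrt(var + 1e-6), atol=1e-9)


def test_visibility_invariant_masked_patch_cannot_reach_encoder(model, rng):
    """Perturbing any masked patch leaves encoder outputs bit-unchanged;
    perturbing any visible patch changes them."""
    img = rng.random((64, 64))
    n = model.n_patches
    spec = sample_mask(n, 0.25, np.random.default_rng(0))

    def encoder_out(image):
        patches = patchify(image, model.cfg.patch_size).patches
        emb = model.embed_patches(patches)
        from radimplant._autograd import gather
        vis = gather(emb + Tensor(model.pos_enc), spec.visible_idx)
        return model.encode_visible(vis).data

    base = encoder_out(img)
    p = model.cfg.patch_size
    cols = model.cfg.grid[1]
    for idx in spec.masked_idx[:16]:
        r, c = divmod(int(idx), cols)
        perturbed = img.copy()
        perturbed[r * p:(r + 1) * p, c * p:(c + 1) * p] += 10.0
        assert np.array_equal(encoder_out(perturbed), base)
    r, c = divmod(int(spec.visible_idx[0]), cols)
    perturbed = img.copy()
    perturbed[r * p:(r + 1) * p, c * p:(c + 1) * p] += 10.0
    assert not np.array_equal(encoder_out(perturbed), base)


def test_decoder_input_slots_and_mask_token(model, rng):
    n = 4
    latent = Tensor(rng.normal(size=(3, model.cfg.enc_dim)))
    spec = _mask_from_sets(n, [2])
    ec = model.assemble_decoder_input(latent, spec.masked_idx, spec.visible_idx)
    assert ec.shape == (n, model.cfg.dec_dim)
    expected_masked = model.mask_token.data[0] + model.pos_dec[2]
    np.testing.assert_allclose(ec.data[2], expected_masked, atol=1e-12)
    proj = latent.data @ model.dec_embed.weight.data + model.dec_embed.bias.data
    for slot, lat_row in zip([0, 1, 3], proj):
        np.testing.assert_allclose(ec.data[slot], lat_row + model.pos_dec[slot],
                                   atol=1e-12)


def test_order_restoration_exhaustive_small_n(tiny_cfg, rng):
    """For every 1-or-2-element mask of a 16-token sequence the decoder
    input restores the original patch order exactly."""
    cfg = RunConfig.tiny(seed=5, image_size=32, patch_size=8)  # N = 16
    m = MaskedAutoencoder(cfg, head="embedding")
    n = m.n_patches
    marker = rng.normal(size=(n, cfg.enc_dim))
    proj = marker @ m.dec_embed.weight.data + m.dec_embed.bias.data
    subsets = list(itertools.combinations(range(n), 1)) + \
        list(itertools.combinations(range(n), 2))
    for masked in subsets:
        spec = _mask_from_sets(n, masked)
        latent = Tensor(marker[spec.visible_idx])
        ec = m.assemble_decoder_input(latent, spec.masked_idx, spec.visible_idx).data
        for pos in range(n):
            if pos in masked:
                np.testing.assert_allclose(
                    ec[pos], m.mask_token.data[0] + m.pos_dec[pos], atol=1e-12)
            else:
                np.testing.assert_allclose(ec[pos], proj[pos] + m.pos_dec[pos],
                                           atol=1e-12)


def test_decode_shape_and_determinism(model, rng):
    ec = Tensor(rng.normal(size=(model.n_patches, model.cfg.dec_dim)))
    out1 = model.decode(ec).data
    out2 = model.decode(ec).data
    assert out1.shape == (model.n_patches, model.cfg.dec_dim)
    np.testing.assert_array_equal(out1, out2)
    with pytest.raises(ValueError, match="length"):
        model.decode(Tensor(rng.normal(size=(3, model.cfg.dec_dim))))


def test_head_output_dims_and_masked_gather(tiny_cfg, rng):
    emb_model = MaskedAutoencoder(tiny_cfg, head="embedding")
    pix_model = MaskedAutoencoder(tiny_cfg, head="pixel")
    img = rng.random((64, 64))
    spec = sample_mask(emb_model.n_patches, 0.25, np.random.default_rng(1))
    out_e = emb_model.forward_pretrain(img, [spec])
    assert out_e["pred"].shape == (1, len(spec.masked_idx), tiny_cfg.enc_dim)
    out_p = pix_model.forward_pretrain(img, [spec])
    assert out_p["pred"].shape == (1, len(spec.masked_idx), 64)  # 8*8*1
    # gather oracle: head applied to decoder output, rows picked by masked_idx
    dec = Tensor(rng.normal(size=(emb_model.n_patches, tiny_cfg.dec_dim)))
    picked = emb_model.predict_targets(dec, spec.masked_idx).data
    full = dec.data @ emb_model.head.weight.data + emb_model.head.bias.data
    np.testing.assert_allclose(picked, full[spec.masked_idx], atol=1e-12)


def test_encoder_checkpoint_discards_decoder(model, tmp_path):
    path = tmp_path / "enc.npz"
    model.save_checkpoint(path, encoder_only=True)
    meta, state = load_checkpoint(path)
    assert meta["encoder_only"]
    banned = [k for k in state if k.startswith(("decoder.", "head.", "dec_embed.",
                                                "dec_norm.", "mask_token"))]
    assert banned == []
    assert any(k.startswith("encoder.") for k in state)
    fresh = MaskedAutoencoder(RunConfig.tiny(seed=99), head="embedding")
    fresh.load_encoder_state(state)
    np.testing.assert_array_equal(fresh.tokenizer.weight.data,
                                  model.tokenizer.weight.data)


def test_pixel_head_perfect_predictions_reconstruct_image(tiny_cfg, rng):
    m = MaskedAutoencoder(tiny_cfg, head="pixel")
    img = rng.random((64, 64))
    spec = sample_mask(m.n_patches, 0.25, np.random.default_rng(2))
    # force the model's masked predictions to the ground-truth pixels
    grid = patchify(img, tiny_cfg.patch_size)
    composite = img.copy()
    out = m.visualize_reconstruction(img, spec)
    # visible patches are untouched regardless of the model's quality
    cols = tiny_cfg.grid[1]
    p = tiny_cfg.patch_size
    for idx in spec.visible_idx:
        r, c = divmod(int(idx), cols)
        np.testing.assert_array_equal(out[r * p:(r + 1) * p, c * p:(c + 1) * p],
                                      composite[r * p:(r + 1) * p, c * p:(c + 1) * p])
    assert grid.patches.shape[1] == p * p


def test_embedding_visualization_pinv_roundtrip(rng):
    """With a full-column-rank affine tokenizer the pseudo-inverse maps
    unmasked embeddings back to their patches to high accuracy."""
    cfg = RunConfig.tiny(seed=5, image_size=16, patch_size=4, enc_dim=32,
                         enc_heads=4)
    m = MaskedAutoencoder(cfg, head="embedding")
    patches = rng.random((m.n_patches, m.patch_dim))
    emb = m.embed_patches(patches).data
    w, b = m.tokenizer.weight.data, m.tokenizer.bias.data
    recovered = (emb - b) @ np.linalg.pinv(w)
    assert np.abs(recovered - patches).max() < 1e-4
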