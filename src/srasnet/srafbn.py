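"""Self-attention negative-feedback super-resolution network (SRAFBN).

The network learns the residual between a bicubic upsample of a
low-resolution (LR) chromosome crop and its high-resolution (HR)
counterpart, refining features through a recurrent feedback block:

* shallow feature extraction: a 3x3 then a 1x1 convolution produce L0;
* feedback block (FB): ``n_groups`` encode/decode mapping groups with
  dense skip concatenations (every encoder output feeds every later
  decoder, every decoder output feeds every later encoder) followed by a
  1x1 channel reduction; the block is applied recurrently,
  ``FB_n = FBB(FB_{n-1}, L0)`` with ``FB_0 = L0`` and one shared set of
  weights across iterations;
* reconstruction: a transposed convolution to HR scale, then a 3x3 and a
  1x1 convolution produce the residual map ``Res_n``, and
  ``SR_n = Res_n + bicubic(LR)``.

Each iteration emits its own SR image; training weights the per-iteration
losses by a learned attention distribution (softmax over logits), so the
optimiser can emphasise the iterations that reconstruct best.  The final
1x1 reconstruction convolution is zero-initialised, so an untrained
network reproduces plain bicubic interpolation exactly and training can
only move away from that baseline by reducing the loss.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .nn import Adam, Conv2d, Deconv2d, Parameter, ReLU

__all__ = ["SrConfig", "SrModelState", "SrForwardResult", "bicubic_upsample",
           "extract_shallow_features", "feedback_step", "reconstruct_sr",
           "sr_forward", "attention_weighted_loss", "train_sr",
           "super_resolve", "save_state", "load_state", "psnr"]


@dataclass
class SrConfig:
    scale: int = 2
    n_iterations: int = 4
    n_groups: int = 3
    base_channels: int = 32
    learning_rate: float = 5e-4
    loss_norm: str = "L1"  # or "L2"

    def __post_init__(self):
        if self.scale not in (2, 3, 4):
            raise ValueError("scale must be 2, 3 or 4")
        if min(self.n_iterations, self.n_groups, self.base_channels) < 1:
            raise ValueError("iterations, groups and channels must be >= 1")
        if self.loss_norm not in ("L1", "L2"):
            raise ValueError("loss_norm must be 'L1' or 'L2'")


class SrModelState:
    """All learnable parameters plus the architecture configuration.

    Parameter shapes depend only on ``n_groups``/``base_channels``/
    ``scale`` — never on ``n_iterations`` — because the feedback block is
    recurrent with shared weights.
    """

    def __init__(self, config: SrConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        g = config.n_groups
        # Eq-style feature extraction: 3x3 then 1x1
        self.feat3 = Conv2d(1, c, 3, rng)
        self.feat1 = Conv2d(c, c, 1, rng)
        # feedback block
        self.fb_in = Conv2d(2 * c, c, 1, rng)  # fuse [FB_prev, L0]
        self.enc_reduce = [Conv2d(c * (i + 1), c, 1, rng) for i in range(g)]
        self.enc_conv = [Conv2d(c, c, 3, rng) for _ in range(g)]
        self.dec_reduce = [Conv2d(c * (i + 1), c, 1, rng) for i in range(g)]
        self.dec_conv = [Conv2d(c, c, 3, rng) for _ in range(g)]
        self.fb_out = Conv2d(c * g, c, 1, rng)
        # reconstruction
        self.deconv = Deconv2d(c, c, config.scale, rng)
        self.rec3 = Conv2d(c, c, 3, rng)
        self.rec1 = Conv2d(c, 1, 1, rng, zero_init=True)
        # attention over per-iteration losses
        self.attn_logits = Parameter(np.zeros(config.n_iterations,
                                              dtype=np.float32))
        self.relu = ReLU()

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        layers = ([self.feat3, self.feat1, self.fb_in] + self.enc_reduce +
                  self.enc_conv + self.dec_reduce + self.dec_conv +
                  [self.fb_out, self.deconv, self.rec3, self.rec1])
        for layer in layers:
            ps.extend(layer.parameters())
        ps.append(self.attn_logits)
        return ps

    def zero_all_weights(self) -> None:
        """Set every learnable weight to zero (bicubic limit)."""
        for p in self.parameters():
            p.data[...] = 0.0

    def attention_weights(self) -> np.ndarray:
        z = self.attn_logits.data - self.attn_logits.data.max()
        e = np.exp(z)
        return e / e.sum()


@dataclass
class SrForwardResult:
    sr_images: list[np.ndarray]      # one HR-sized image per iteration
    residuals: list[np.ndarray]
    upsampled: np.ndarray            # the bicubic baseline
    caches: list | None = None       # internal, used for backprop

    @property
    def final(self) -> np.ndarray:
        return self.sr_images[-1]


def bicubic_upsample(lr: np.ndarray, scale: int) -> np.ndarray:
    """Bicubic interpolation to scale x the input dims (float64)."""
    lr = np.asarray(lr, dtype=np.float64)
    h, w = lr.shape
    pil = Image.fromarray(lr.astype(np.float32), mode="F")
    up = pil.resize((w * scale, h * scale), Image.BICUBIC)
    return np.asarray(up, dtype=np.float64)


def _as_batch(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.ndim == 2:
        img = img[None, None]
    elif img.ndim == 3:
        img = img[:, None]
    return img


def extract_shallow_features(lr: np.ndarray, state: SrModelState):
    """L0: the two-convolution shallow feature stack at LR dims."""
    x = _as_batch(lr)
    if x.shape[2] < 8 or x.shape[3] < 8:
        raise ValueError("input must be at least 8x8")
    h1, c1 = state.feat3.forward(x)
    a1, ca = state.relu.forward(h1)
    l0, c2 = state.feat1.forward(a1)
    return l0, (c1, ca, c2)


def _extract_backward(state: SrModelState, cache, gout):
    c1, ca, c2 = cache
    g = state.feat1.backward(c2, gout)
    g = state.relu.backward(ca, g)
    return state.feat3.backward(c1, g)


def feedback_step(fb_prev: np.ndarray, l0: np.ndarray, state: SrModelState):
    """One pass through the feedback block with dense skip links."""
    if fb_prev.shape != l0.shape:
        raise ValueError("feedback input and L0 must be spatially aligned")
    caches = {}
    h0, caches["in"] = state.fb_in.forward(
        np.concatenate([fb_prev, l0], axis=1))
    enc_outs, dec_outs = [], []
    enc_caches, dec_caches = [], []
    for i in range(state.config.n_groups):
        e_in = np.concatenate([h0] + dec_outs, axis=1)
        r, cr = state.enc_reduce[i].forward(e_in)
        h, ch = state.enc_conv[i].forward(r)
        e, ce = state.relu.forward(h)
        enc_outs.append(e)
        enc_caches.append((cr, ch, ce, len(dec_outs)))
        d_in = np.concatenate(enc_outs, axis=1)
        r2, cr2 = state.dec_reduce[i].forward(d_in)
        h2, ch2 = state.dec_conv[i].forward(r2)
        d, cd = state.relu.forward(h2)
        dec_outs.append(d)
        dec_caches.append((cr2, ch2, cd, len(enc_outs)))
    out, caches["out"] = state.fb_out.forward(
        np.concatenate(dec_outs, axis=1))
    caches["enc"], caches["dec"] = enc_caches, dec_caches
    caches["shape"] = l0.shape
    return out, caches


def _feedback_backward(state: SrModelState, caches, gout):
    g_total = state.fb_out.backward(caches["out"], gout)
    c = state.config.base_channels
    gdec = [g_total[:, i * c:(i + 1) * c] for i in range(state.config.n_groups)]
    gh0 = np.zeros(caches["shape"], dtype=np.float32)
    genc = [np.zeros(caches["shape"], dtype=np.float32)
            for _ in range(state.config.n_groups)]
    gdec_extra = [np.zeros(caches["shape"], dtype=np.float32)
                  for _ in range(state.config.n_groups)]
    for i in reversed(range(state.config.n_groups)):
        # decoder i
        cr2, ch2, cd, n_enc = caches["dec"][i]
        g = state.relu.backward(cd, gdec[i] + gdec_extra[i])
        g = state.dec_conv[i].backward(ch2, g)
        g = state.dec_reduce[i].backward(cr2, g)
        for j in range(n_enc):
            genc[j] += g[:, j * c:(j + 1) * c]
        # encoder i
        cr, ch, ce, n_dec = caches["enc"][i]
        g = state.relu.backward(ce, genc[i])
        g = state.enc_conv[i].backward(ch, g)
        g = state.enc_reduce[i].backward(cr, g)
        gh0 += g[:, :c]
        for j in range(n_dec):
            gdec_extra[j] += g[:, (j + 1) * c:(j + 2) * c]
    gcat = state.fb_in.backward(caches["in"], gh0)
    gfb_prev, gl0 = gcat[:, :c], gcat[:, c:]
    return gfb_prev, gl0


def reconstruct_sr(fb_n: np.ndarray, lr: np.ndarray, state: SrModelState,
                   config: SrConfig | None = None):
    """(Res_n, SR_n): residual map at HR dims plus the iterative SR image
    SR_n = Res_n + bicubic(LR)."""
    config = config or state.config
    lr = np.asarray(lr, dtype=np.float64)
    if lr.ndim != 2:
        raise ValueError("reconstruct_sr expects a single 2-D LR image")
    up = bicubic_upsample(lr, config.scale)
    (res, sr), _ = _reconstruct_from_features(fb_n, up, state)
    return res, sr


def _reconstruct_backward(state: SrModelState, cache, g_res):
    c1, ca, c2, ca2, c3 = cache
    g = state.rec1.backward(c3, g_res)
    g = state.relu.backward(ca2, g)
    g = state.rec3.backward(c2, g)
    g = state.relu.backward(ca, g)
    return state.deconv.backward(c1, g)


def sr_forward(lr: np.ndarray, state: SrModelState, config: SrConfig | None = None,
               keep_caches: bool = False) -> SrForwardResult:
    """Run the full recurrent forward pass, collecting every SR_n."""
    config = config or state.config
    lr = np.asarray(lr, dtype=np.float64)
    up = bicubic_upsample(lr, config.scale)
    l0, ext_cache = extract_shallow_features(lr, state)
    fb = l0
    sr_images, residuals, caches = [], [], []
    for _ in range(config.n_iterations):
        fb, fb_cache = feedback_step(fb, l0, state)
        (res, sr), rec_cache = _reconstruct_from_features(fb, up, state)
        sr_images.append(sr)
        residuals.append(res)
        caches.append((fb_cache, rec_cache))
    return SrForwardResult(sr_images, residuals, up,
                           caches=(ext_cache, caches) if keep_caches else None)


def _reconstruct_from_features(fb_n, up, state):
    h, c1 = state.deconv.forward(fb_n)
    a, ca = state.relu.forward(h)
    h2, c2 = state.rec3.forward(a)
    a2, ca2 = state.relu.forward(h2)
    res, c3 = state.rec1.forward(a2)
    res2d = res[0, 0].astype(np.float64)
    return (res2d, res2d + up), (c1, ca, c2, ca2, c3)


def attention_weighted_loss(result: SrForwardResult, hr: np.ndarray,
                            state: SrModelState,
                            config: SrConfig | None = None) -> float:
    """Sum_i W_i * loss_i with W = softmax(attention logits)."""
    config = config or state.config
    hr = np.asarray(hr, dtype=np.float64)
    losses = []
    for sr in result.sr_images:
        if sr.shape != hr.shape:
            raise ValueError(f"SR shape {sr.shape} != HR shape {hr.shape}")
        diff = sr - hr
        losses.append(np.abs(diff).mean() if config.loss_norm == "L1"
                      else (diff ** 2).mean())
    w = state.attention_weights()
    return float(np.dot(losses, w))


def _loss_and_backward(lr, hr, state, config):
    """Forward + full backpropagation through time; returns the loss."""
    result = sr_forward(lr, state, config, keep_caches=True)
    ext_cache, caches = result.caches
    hr = np.asarray(hr, dtype=np.float64)
    n = config.n_iterations
    losses = np.empty(n)
    signs = []
    npix = hr.size
    for i, sr in enumerate(result.sr_images):
        diff = sr - hr
        if config.loss_norm == "L1":
            losses[i] = np.abs(diff).mean()
            signs.append(np.sign(diff) / npix)
        else:
            losses[i] = (diff ** 2).mean()
            signs.append(2.0 * diff / npix)
    w = state.attention_weights()
    loss = float(np.dot(losses, w))
    # attention logits gradient: dL/dz_j = w_j (loss_j - L)
    state.attn_logits.grad += (w * (losses - loss)).astype(np.float32)
    # backprop through time, newest iteration first
    gfb_next = None
    gl0_acc = None
    for i in reversed(range(n)):
        fb_cache, rec_cache = caches[i]
        g_res = (w[i] * signs[i]).astype(np.float32)[None, None]
        g_fb = _reconstruct_backward(state, rec_cache, g_res)
        if gfb_next is not None:
            g_fb = g_fb + gfb_next
        gfb_prev, gl0 = _feedback_backward(state, fb_cache, g_fb)
        gl0_acc = gl0 if gl0_acc is None else gl0_acc + gl0
        gfb_next = gfb_prev
    # FB_0 = L0, so the first iteration's feedback-input gradient also
    # flows into L0
    gl0_acc = gl0_acc + gfb_next
    _extract_backward(state, ext_cache, gl0_acc)
    return loss


def train_sr(pairs: list[tuple[np.ndarray, np.ndarray]],
             config: SrConfig, seed: int = 0, epochs: int = 10,
             state: SrModelState | None = None) -> tuple[SrModelState, list]:
    """Train on (LR, HR) pairs; keeps the parameters of the best epoch.

    Returns ``(state, history)`` where history is the per-epoch mean loss.
    """
    if not pairs:
        raise ValueError("need at least one (LR, HR) training pair")
    for lr_img, hr_img in pairs:
        if (hr_img.shape[0] != lr_img.shape[0] * config.scale or
                hr_img.shape[1] != lr_img.shape[1] * config.scale):
            raise ValueError("HR dims must equal scale x LR dims")
    state = state or SrModelState(config, seed=seed)
    opt = Adam(state.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    history: list[float] = []
    best = (np.inf, None)
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        for idx in order:
            lr_img, hr_img = pairs[idx]
            opt.zero_grad()
            epoch_loss += _loss_and_backward(lr_img, hr_img, state, config)
            opt.step()
        epoch_loss /= len(pairs)
        history.append(epoch_loss)
        if epoch_loss < best[0]:
            best = (epoch_loss,
                    [p.data.copy() for p in state.parameters()])
    if best[1] is not None:
        for p, d in zip(state.parameters(), best[1]):
            p.data[...] = d
    return state, history


def super_resolve(lr: np.ndarray, state: SrModelState,
                  config: SrConfig | None = None) -> np.ndarray:
    """Final-iteration SR image, clamped to the 8-bit intensity range."""
    result = sr_forward(lr, state, config)
    return np.clip(result.final, 0.0, 255.0)


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    mse = float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / mse)


def save_state(state: SrModelState, path: str | Path) -> None:
    payload = {
        "config": state.config.__dict__,
        "params": [p.data for p in state.parameters()],
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_state(path: str | Path) -> SrModelState:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    state = SrModelState(SrConfig(**payload["config"]))
    for p, d in zip(state.parameters(), payload["params"]):
        p.data[...] = d
    return state
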