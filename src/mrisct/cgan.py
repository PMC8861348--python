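"""Conditional-GAN MRI -> synthetic-CT translation.

A paired image-to-image cGAN trained on axial slices: the generator is a
U-Net (3x3 stride-1 convolution blocks, 3x3 stride-2 down-sampling, 3x3
stride-2 transpose-convolution up-sampling, skip connections, batch norm
+ ReLU everywhere except the final 1x1 convolution + tanh, dropout 0.5
after the bottleneck and after the widest decoder block); the
discriminator scores (MRI, CT-or-sCT) channel pairs through
CD8-CD16-CD32-CD64-CD128-C128 and a fully connected sigmoid output with
leaky-ReLU (slope 0.2) activations.  The generator loss is adversarial
(binary cross entropy through the discriminator) plus L1 to the target
CT, both weighted 1; optimization is Adam at learning rate 1e-4, batch
size 10.

Two profiles are provided: the full-resolution profile (320 x 320
slices, base 64 filters doubling to 1024 at the bottleneck, 20 epochs)
and a desk profile (64 x 64 slices, filters scaled by 1/4, 5 epochs)
suitable for CPU-only runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .grid import ImageVolume

AIR_HU = -1000.0
N_DOWN = 4  # down/up-sampling depth of the U-Net


@dataclass(frozen=True)
class CganConfig:
    matrix_size: int = 320
    base_filters: int = 64
    learning_rate: float = 1e-4
    batch_size: int = 10
    epochs: int = 20
    adv_weight: float = 1.0
    l1_weight: float = 1.0
    init_sd: float = 1e-4
    dropout_rate: float = 0.5
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size % 2**N_DOWN != 0:
            raise ValueError(
                f"matrix_size must be divisible by {2**N_DOWN} for {N_DOWN} down-samplings"
            )
        for name in ("learning_rate", "batch_size", "epochs", "dropout_rate", "init_sd"):
            if getattr(self, name) <= 0 and name != "dropout_rate":
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk(cls, **overrides) -> "CganConfig":
        """CPU-friendly profile: 64^2 slices, quarter-scale filters, 5 epochs."""
        defaults = dict(matrix_size=64, base_filters=16, epochs=5)
        defaults.update(overrides)
        return cls(**defaults)


def generator_channel_schedule(base: int) -> list[int]:
    """Encoder widths from the first block to the bottleneck (doubling)."""
    return [base * 2**i for i in range(N_DOWN + 1)]


def generator_parameter_count(base: int, in_ch: int = 1, out_ch: int = 1) -> int:
    """Closed-form parameter count of the U-Net generator.

    Counts conv/transpose-conv weights and biases plus the batch-norm
    scale/shift pairs, per the block schedule used by :class:`Generator`.
    """
    ch = generator_channel_schedule(base)
    total = 0

    def conv(cin, cout, k, bn=True):
        return k * k * cin * cout + cout + (2 * cout if bn else 0)

    total += conv(in_ch, ch[0], 3)  # first encoder block
    for i in range(N_DOWN):  # down-sampling blocks
        total += conv(ch[i], ch[i + 1], 3)
    for i in reversed(range(N_DOWN)):  # decoder: up-conv + fuse block
        total += conv(ch[i + 1], ch[i], 3)  # transpose conv (+BN)
        total += conv(2 * ch[i], ch[i], 3)  # conv after skip concat
    total += conv(ch[0], out_ch, 1, bn=False)  # final 1x1, tanh
    return total


def _cbr(cin, cout, stride, cfg, rng, k=3):
    return nn.Sequential(
        nn.Conv2D(cin, cout, k=k, stride=stride, init_sd=cfg.init_sd, rng=rng),
        nn.BatchNorm2D(cout),
        nn.ReLU(),
    )


class Generator:
    """U-Net generator with skip connections; output in (-1, 1) via tanh."""

    def __init__(self, cfg: CganConfig, in_ch: int = 1, out_ch: int = 1):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 102]))
        ch = generator_channel_schedule(cfg.base_filters)
        self.ch = ch
        self.enc0 = _cbr(in_ch, ch[0], 1, cfg, rng)
        self.down = [_cbr(ch[i], ch[i + 1], 2, cfg, rng) for i in range(N_DOWN)]
        self.drop_bottleneck = nn.Dropout(cfg.dropout_rate, rng=drop_rng)
        self.up = []
        self.dec = []
        for i in reversed(range(N_DOWN)):
            self.up.append(
                nn.Sequential(
                    nn.ConvTranspose2D(ch[i + 1], ch[i], init_sd=cfg.init_sd, rng=rng),
                    nn.BatchNorm2D(ch[i]),
                    nn.ReLU(),
                )
            )
            self.dec.append(_cbr(2 * ch[i], ch[i], 1, cfg, rng))
        # dropout after the widest decoder fuse block (CU-<2*bottleneck/2> at full scale)
        self.drop_decoder = nn.Dropout(cfg.dropout_rate, rng=drop_rng)
        self.final = nn.Conv2D(ch[0], out_ch, k=1, init_sd=cfg.init_sd, rng=rng)
        self.tanh = nn.Tanh()
        self._modules = (
            [self.enc0] + self.down + self.up + self.dec + [self.final]
        )

    @property
    def params(self):
        return [p for m in self._modules for p in (m.all_params if isinstance(m, nn.Sequential) else m.params)]

    @property
    def grads(self):
        return [g for m in self._modules for g in (m.all_grads if isinstance(m, nn.Sequential) else m.grads)]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus batch-norm running statistics, in a fixed order."""
        arrays = list(self.params)
        for m in self._modules:
            if isinstance(m, nn.Sequential):
                for l in m.layers:
                    if isinstance(l, nn.BatchNorm2D):
                        arrays += [l.running_mean, l.running_var]
        return arrays

    def load_state(self, arrays) -> None:
        targets = self.state_arrays()
        if len(targets) != len(arrays):
            raise ValueError("checkpoint array count does not match the architecture")
        for t, a in zip(targets, arrays):
            t[...] = a

    def forward(self, x, train=True):
        skips = []
        h = self.enc0.forward(x, train)
        skips.append(h)
        for blk in self.down[:-1]:
            h = blk.forward(h, train)
            skips.append(h)
        h = self.down[-1].forward(h, train)  # bottleneck
        h = self.drop_bottleneck.forward(h, train)
        self._skip_ch = []
        for level, (upblk, decblk) in enumerate(zip(self.up, self.dec)):
            u = upblk.forward(h, train)
            s = skips[-(level + 1)]
            self._skip_ch.append(u.shape[1])
            h = decblk.forward(np.concatenate([u, s], axis=1), train)
            if level == 0:
                h = self.drop_decoder.forward(h, train)
        return self.tanh.forward(self.final.forward(h, train), train)

    def backward(self, g):
        g = self.final.backward(self.tanh.backward(g))
        # decoder level 0 fuses the deepest skip, level N_DOWN-1 the shallowest
        skip_grads: list[np.ndarray] = []
        for level in reversed(range(N_DOWN)):
            if level == 0:
                g = self.drop_decoder.backward(g)
            gc = self.dec[level].backward(g)
            c = self._skip_ch[level]
            gu, gs = gc[:, :c], gc[:, c:]
            skip_grads.append(gs)  # appended shallowest skip (e0) first
            g = self.up[level].backward(gu)
        g = self.drop_bottleneck.backward(g)
        g = self.down[-1].backward(g)
        # encoder walk-back; skip_grads[i] is the gradient into encoder output i
        for i in reversed(range(len(self.down) - 1)):
            g = g + skip_grads[i + 1]
            g = self.down[i].backward(g)
        return self.enc0.backward(g + skip_grads[0])

    def predict(self, x):
        return self.forward(x, train=False)


class Discriminator:
    """CD8-CD16-CD32-CD64-CD128-C128-F conditional discriminator (logit output)."""

    def __init__(self, cfg: CganConfig, in_ch: int = 2):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 201]))
        chans = [8, 16, 32, 64, 128]
        layers = []
        cin = in_ch
        for c in chans:
            layers += [
                nn.Conv2D(cin, c, k=3, stride=2, init_sd=cfg.init_sd, rng=rng),
                nn.LeakyReLU(cfg.leaky_slope),
            ]
            cin = c
        layers += [
            nn.Conv2D(cin, 128, k=1, stride=1, init_sd=cfg.init_sd, rng=rng),
            nn.LeakyReLU(cfg.leaky_slope),
            nn.Flatten(),
        ]
        spatial = cfg.matrix_size // 2 ** len(chans)
        layers.append(nn.Linear(128 * spatial * spatial, 1, init_sd=cfg.init_sd, rng=rng))
        self.net = nn.Sequential(*layers)

    @property
    def params(self):
        return self.net.all_params

    @property
    def grads(self):
        return self.net.all_grads

    def forward(self, x, train=True):
        return self.net.forward(x, train)

    def backward(self, g):
        return self.net.backward(g)


@dataclass
class NormalizationMeta:
    """Everything needed to map raw volumes to network space and back."""

    # symmetric about water so the tanh origin is water-equivalent tissue
    ct_lo: float = -1250.0
    ct_hi: float = 1250.0
    mri_peak_target: float = 0.5
    mri_hi_percentile: float = 99.5
    hist_bins: int = 128
    matrix_size: int = 64

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NormalizationMeta":
        return cls(**json.loads(s))


def mri_mode(data: np.ndarray, body: np.ndarray, meta: NormalizationMeta) -> tuple[float, float]:
    """(histogram mode, high percentile) of in-body MRI intensities."""
    vals = np.asarray(data, dtype=float)[np.asarray(body, dtype=bool)]
    hi = float(np.percentile(vals, meta.mri_hi_percentile))
    hist, edges = np.histogram(vals, bins=meta.hist_bins, range=(0.0, max(hi, 1e-9)))
    centres = 0.5 * (edges[:-1] + edges[1:])
    return float(centres[int(np.argmax(hist))]), hi


def standardize_mri(data: np.ndarray, body: np.ndarray, meta: NormalizationMeta) -> np.ndarray:
    """Piecewise-linear mode alignment: 0 -> 0, peak -> peak_target, hi -> 1."""
    mode, hi = mri_mode(data, body, meta)
    xp = [0.0, mode, max(hi, mode * 1.001)]
    fp = [0.0, meta.mri_peak_target, 1.0]
    out = np.interp(np.asarray(data, dtype=float), xp, fp)
    return np.where(body, out, 0.0)


def scale_ct(hu: np.ndarray, meta: NormalizationMeta) -> np.ndarray:
    clipped = np.clip(hu, meta.ct_lo, meta.ct_hi)
    return (clipped - meta.ct_lo) / (meta.ct_hi - meta.ct_lo) * 2.0 - 1.0


def unscale_ct(y: np.ndarray, meta: NormalizationMeta) -> np.ndarray:
    return (y + 1.0) / 2.0 * (meta.ct_hi - meta.ct_lo) + meta.ct_lo


def _resample_slice(sl: np.ndarray, size: int) -> np.ndarray:
    fy = size / sl.shape[0]
    fx = size / sl.shape[1]
    if fy == 1.0 and fx == 1.0:
        return sl.astype(float)
    return ndimage.zoom(sl.astype(float), (fy, fx), order=1)


def preprocess_pair(
    ct: ImageVolume, mri: ImageVolume, body: np.ndarray, cfg: CganConfig
) -> tuple[np.ndarray, np.ndarray, NormalizationMeta, dict]:
    """Background-masked, peak-standardized, [-1, 1]-scaled axial slice pairs.

    Returns ``(mri_slices, ct_slices, meta, info)`` with slices of shape
    (n, 1, matrix, matrix); ``info`` records the kept slice indices and
    the original grid so the CT scaling can be inverted exactly.
    """
    if not ct.same_grid(mri):
        raise ValueError("CT and MRI are on different grids")
    meta = NormalizationMeta(matrix_size=cfg.matrix_size)
    mri_std = standardize_mri(mri.data, body, meta) * 2.0 - 1.0
    mri_std = np.where(body, mri_std, -1.0)
    ct_scaled = np.where(body, scale_ct(np.asarray(ct.data, dtype=float), meta), -1.0)

    kept, skipped = [], []
    xs, ys = [], []
    for z in range(ct.shape[0]):
        if not body[z].any():
            skipped.append(z)
            continue
        kept.append(z)
        xs.append(_resample_slice(mri_std[z], cfg.matrix_size))
        ys.append(_resample_slice(ct_scaled[z], cfg.matrix_size))
    if not kept:
        raise ValueError("no slice intersects the body mask")
    info = {
        "kept_slices": kept,
        "skipped_slices": skipped,
        "grid_shape": ct.shape,
        "spacing": ct.spacing,
    }
    x = np.clip(np.stack(xs), -1.0, 1.0)[:, None]
    y = np.clip(np.stack(ys), -1.0, 1.0)[:, None]
    return x, y, meta, info


def train_cgan(
    x: np.ndarray, y: np.ndarray, cfg: CganConfig
) -> tuple[Generator, Discriminator, list[dict]]:
    """Alternate generator/discriminator updates over slice pairs.

    ``x``/``y`` are (n, 1, m, m) MRI and CT slice tensors in [-1, 1].
    Returns the trained networks and a per-epoch history of generator
    adversarial loss, generator L1 loss and discriminator loss.
    Deterministic for a fixed config seed.
    """
    n = x.shape[0]
    if n < cfg.batch_size:
        raise ValueError(f"need at least batch_size={cfg.batch_size} slice pairs, got {n}")
    gen = Generator(cfg)
    disc = Discriminator(cfg)
    opt_g = nn.Adam(gen.params, gen.grads, lr=cfg.learning_rate)
    opt_d = nn.Adam(disc.params, disc.grads, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 301]))

    history = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        adv_losses, l1_losses, d_losses = [], [], []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]

            # --- generator update ---
            sct = gen.forward(xb, train=True)
            z_fake = disc.forward(np.concatenate([xb, sct], axis=1), train=True)
            adv, dz = nn.bce_with_logits(z_fake, 1.0)
            l1, dl1 = nn.l1_loss(sct, yb)
            if not (np.isfinite(adv) and np.isfinite(l1)):
                raise RuntimeError(f"non-finite generator loss at epoch {epoch}, batch {start}")
            g_in = disc.backward(cfg.adv_weight * dz)  # grad w.r.t. (mri, sct) pair
            gen.backward(g_in[:, 1:] + cfg.l1_weight * dl1)
            opt_g.step()

            # --- discriminator update (real and fake in one batch) ---
            d_in = np.concatenate(
                [
                    np.concatenate([xb, yb], axis=1),
                    np.concatenate([xb, sct], axis=1),
                ],
                axis=0,
            )
            targets = np.concatenate([np.ones((len(xb), 1)), np.zeros((len(xb), 1))])
            z = disc.forward(d_in, train=True)
            d_loss = float(np.mean(np.logaddexp(0.0, z) - targets * z))
            if not np.isfinite(d_loss):
                raise RuntimeError(f"non-finite discriminator loss at epoch {epoch}, batch {start}")
            disc.backward((nn.sigmoid(z) - targets) / z.size)
            opt_d.step()

            adv_losses.append(adv)
            l1_losses.append(l1)
            d_losses.append(d_loss)
        history.append(
            {
                "epoch": epoch,
                "g_adv": float(np.mean(adv_losses)),
                "g_l1": float(np.mean(l1_losses)),
                "d_loss": float(np.mean(d_losses)),
            }
        )
    return gen, disc, history


def predict_sct(
    gen: Generator,
    mri: ImageVolume,
    body: np.ndarray,
    meta: NormalizationMeta,
) -> ImageVolume:
    """Slice-wise inference back to a HU volume on the MRI grid.

    Outside-body voxels are set to air (-1000 HU).  Inference runs the
    generator in eval mode (no dropout, frozen batch-norm statistics), so
    repeated prediction is bit-identical.
    """
    if meta.matrix_size != gen.cfg.matrix_size:
        raise ValueError("generator matrix size does not match normalization metadata")
    mri_std = standardize_mri(mri.data, body, meta) * 2.0 - 1.0
    mri_std = np.where(body, mri_std, -1.0)
    out = np.full(mri.shape, AIR_HU, dtype=float)
    ny, nx = mri.shape[1], mri.shape[2]
    batch, zs = [], []

    def flush():
        if not batch:
            return
        xb = np.stack(batch)[:, None]
        yb = gen.predict(xb)[:, 0]
        for z, sl in zip(zs, yb):
            full = _resample_slice(sl, ny) if ny == nx else ndimage.zoom(
                sl, (ny / sl.shape[0], nx / sl.shape[1]), order=1
            )
            hu = unscale_ct(full, meta)
            out[z][body[z]] = hu[body[z]]
        batch.clear()
        zs.clear()

    for z in range(mri.shape[0]):
        if not body[z].any():
            continue
        batch.append(_resample_slice(mri_std[z], gen.cfg.matrix_size))
        zs.append(z)
        if len(batch) == 8:
            flush()
    flush()
    return ImageVolume(out, mri.spacing, mri.origin, unit="HU")


def save_generator(gen: Generator, meta: NormalizationMeta, path: str | Path) -> None:
    """Checkpoint: parameter arrays plus a JSON sidecar with config/metadata."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), *gen.state_arrays())
    sidecar = {"config": asdict(gen.cfg), "normalization": asdict(meta)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_generator(path: str | Path) -> tuple[Generator, NormalizationMeta]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = CganConfig(**sidecar["config"])
    gen = Generator(cfg)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    gen.load_state(arrays)
    return gen, NormalizationMeta(**sidecar["normalization"])
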