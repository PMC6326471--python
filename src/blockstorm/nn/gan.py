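"""Conditional-GAN training for frame-to-localization-map translation.

The generator G maps a degraded, upsampled frame x to a localization map
and is trained against three terms: a conditional adversarial cross-entropy
(a PatchGAN discriminator D judges (x, map) pairs), an L1 distance between
the PSF-convolved target and prediction maps (convolving both with a
Gaussian PSF spreads the single-pixel events so the L1 gradient carries
spatial information), and an L1 sparsity penalty on the prediction.  The
total is the lambda-weighted sum; the adversarial weight is held at zero
during a warm-up and then applied only on a fixed cadence of iterations to
keep gradients bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autograd as ag
from .autograd import Adam, Tensor
from .models import (
    DiscriminatorSpec,
    GeneratorSpec,
    PatchDiscriminator,
    UNetGenerator,
)

__all__ = [
    "LossWeights",
    "PsfKernel",
    "TrainConfig",
    "LossBreakdown",
    "TrainedModel",
    "composite_loss",
    "train",
    "infer_stack",
    "maps_to_table",
    "export_model",
    "load_model",
]


@dataclass(frozen=True)
class LossWeights:
    """Loss-term weights and the adversarial-term schedule.

    The adversarial term contributes only from iteration
    ``cgan_warmup_iters`` on, and then only on every
    ``cgan_active_every``-th iteration.
    """

    lambda_cgan: float = 3.0
    lambda_l1: float = 100.0
    lambda_l1s: float = 100.0
    cgan_warmup_iters: int = 1000
    cgan_active_every: int = 3

    def __post_init__(self) -> None:
        if min(self.lambda_cgan, self.lambda_l1, self.lambda_l1s) < 0:
            raise ValueError("loss weights must be >= 0")

    def cgan_active(self, iteration: int) -> bool:
        if self.lambda_cgan == 0:
            return False
        if iteration < self.cgan_warmup_iters:
            return False
        return (iteration - self.cgan_warmup_iters) % self.cgan_active_every == 0


@dataclass(frozen=True)
class PsfKernel:
    """Gaussian kernel used to blur maps inside the L1 loss term.

    sigma is in map-grid pixels; for simulated data the natural choice is
    ``psf_sigma / (pixel_size / upsample)``.  The kernel peak equals
    ``amplitude`` (it is peak-normalized, not sum-normalized): blurring a
    single-pixel event then yields a PSF-shaped spot of comparable peak
    brightness, and the blurred-L1 term carries the kernel mass
    (~2*pi*sigma^2 per event) so it dominates the plain L1 sparsity term
    instead of cancelling against it.
    """

    sigma: float = 2.0
    amplitude: float = 1.0
    support: int | None = None

    def array(self) -> np.ndarray:
        n = self.support or (2 * int(np.ceil(3 * self.sigma)) + 1)
        ax = np.arange(n) - (n - 1) / 2.0
        g = np.exp(-(ax**2) / (2 * self.sigma**2))
        kern = self.amplitude * np.outer(g, g)
        return kern.astype(np.float32)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.25
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LossBreakdown:
    """Evaluated loss terms of one training iteration."""

    l_cgan: float
    l1_psf: float
    l1_sparse: float
    total: float
    iteration: int = 0


def _blur(maps: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.empty_like(maps, dtype=np.float64)
    for i in range(maps.shape[0]):
        out[i] = ndimage.convolve(maps[i].astype(np.float64), kernel, mode="constant")
    return out


def composite_loss(
    x: np.ndarray,
    y: np.ndarray,
    y_hat: np.ndarray,
    d_real: np.ndarray | None,
    d_fake: np.ndarray | None,
    psf: PsfKernel,
    w: LossWeights,
    iteration: int,
) -> LossBreakdown:
    """Evaluate the three loss terms and their scheduled weighted total.

    The adversarial term is the standard conditional-GAN cross-entropy
    (real pairs scored toward 1, generated pairs toward 0); when the
    schedule deactivates it at this iteration (or no discriminator scores
    are supplied) it contributes zero.  ``l1_psf`` is the mean absolute
    difference of the PSF-convolved maps; ``l1_sparse`` the mean absolute
    prediction.  Weights are applied exactly once, in the total.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"map grid mismatch: {y.shape} vs {y_hat.shape}")
    if y.ndim == 2:
        y, y_hat = y[None], y_hat[None]

    kern = psf.array().astype(np.float64)
    l1_psf = float(np.mean(np.abs(_blur(y, kern) - _blur(y_hat, kern))))
    l1_sparse = float(np.mean(np.abs(y_hat)))

    active = w.cgan_active(iteration) and d_real is not None and d_fake is not None
    if active:
        eps = 1e-6
        pr = np.clip(np.asarray(d_real, dtype=np.float64), eps, 1 - eps)
        pf = np.clip(np.asarray(d_fake, dtype=np.float64), eps, 1 - eps)
        l_cgan = float(-np.mean(np.log(pr)) - np.mean(np.log(1.0 - pf)))
        cgan_term = w.lambda_cgan * l_cgan
    else:
        l_cgan = 0.0
        cgan_term = 0.0
    total = cgan_term + w.lambda_l1 * l1_psf + w.lambda_l1s * l1_sparse
    return LossBreakdown(l_cgan=l_cgan, l1_psf=l1_psf, l1_sparse=l1_sparse,
                         total=total, iteration=iteration)


@dataclass
class TrainedModel:
    """A trained generator plus everything needed to reuse it."""

    generator: UNetGenerator
    discriminator: PatchDiscriminator | None
    gspec: GeneratorSpec
    dspec: DiscriminatorSpec
    weights: LossWeights
    config: TrainConfig
    x_scale: float = 1.0
    y_scale: float = 1.0
    history: list[LossBreakdown] = field(default_factory=list)


def train(
    pairs: list,
    gspec: GeneratorSpec,
    dspec: DiscriminatorSpec,
    w: LossWeights,
    tc: TrainConfig,
    psf: PsfKernel | None = None,
) -> TrainedModel:
    """Train the conditional GAN on (frame, map) pairs.

    Alternates discriminator and generator Adam updates (the discriminator
    only trains on iterations where the adversarial term is active).  Inputs
    are normalized by a global high-percentile frame scale and targets by
    their median nonzero value; both scales are stored on the returned
    model so inference undoes them.  Fully reproducible given ``tc.seed``.

    Returns a :class:`TrainedModel` with the per-iteration loss history.
    """
    if tc.epochs > 0 and not pairs:
        raise ValueError("training dataset is empty")
    psf = psf or PsfKernel()
    shapes = {p.x.shape for p in pairs}
    if len(shapes) > 1:
        raise ValueError(f"pairs have mixed grid sizes: {sorted(shapes)}")

    gen = UNetGenerator(gspec, seed=tc.seed)
    disc = PatchDiscriminator(dspec, seed=tc.seed + 1)
    opt_g = Adam(gen.params, lr=tc.learning_rate, beta1=tc.adam_beta1)
    opt_d = Adam(disc.params, lr=tc.learning_rate, beta1=tc.adam_beta1)
    rng = np.random.default_rng(tc.seed + 2)

    if pairs:
        xs = np.stack([p.x for p in pairs]).astype(np.float32)
        ys = np.stack([p.y for p in pairs]).astype(np.float32)
        x_scale = float(np.percentile(xs, 99.5)) or 1.0
        nz = ys[ys > 0]
        y_scale = float(np.median(nz)) if nz.size else 1.0
        xs /= x_scale
        ys /= y_scale
    else:
        x_scale = y_scale = 1.0

    kern_t = Tensor(psf.array())
    kpad = kern_t.shape[0] // 2

    def blur_t(t: Tensor) -> Tensor:
        return ag.conv2d(t, Tensor(kern_t.data[None, None]), None, stride=1, pad=kpad)

    history: list[LossBreakdown] = []
    iteration = 0
    n = len(pairs)
    for _epoch in range(tc.epochs):
        order = rng.permutation(n)
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = Tensor(xs[idx][:, None])
            yb = Tensor(ys[idx][:, None])

            active = w.cgan_active(iteration)
            y_hat = gen.forward(xb, train=True)

            d_real_np = d_fake_np = None
            if active:
                # --- discriminator update ---
                opt_d.zero_grad()
                d_real = disc(xb, yb)
                d_fake_det = disc(xb, y_hat.detach())
                d_loss = ag.scale(
                    ag.add(ag.bce(d_real, 1.0), ag.bce(d_fake_det, 0.0)), 0.5
                )
                d_loss.backward()
                opt_d.step()
                d_real_np = d_real.data.copy()

            # --- generator update ---
            opt_g.zero_grad()
            loss_terms = []
            if active:
                d_fake = disc(xb, y_hat)
                d_fake_np = d_fake.data.copy()
                loss_terms.append(ag.scale(ag.bce(d_fake, 1.0), w.lambda_cgan))
            loss_terms.append(
                ag.scale(ag.mean_abs_diff(blur_t(yb), blur_t(y_hat)), w.lambda_l1)
            )
            loss_terms.append(ag.scale(ag.mean_abs(y_hat), w.lambda_l1s))
            g_loss = loss_terms[0]
            for t in loss_terms[1:]:
                g_loss = ag.add(g_loss, t)
            g_loss.backward()
            opt_g.step()

            history.append(
                composite_loss(
                    xs[idx], ys[idx], y_hat.data[:, 0], d_real_np, d_fake_np,
                    psf, w, iteration,
                )
            )
            iteration += 1

    return TrainedModel(
        generator=gen, discriminator=disc, gspec=gspec, dspec=dspec,
        weights=w, config=tc, x_scale=x_scale, y_scale=y_scale, history=history,
    )


def infer_stack(
    model: TrainedModel, stack: np.ndarray, upsample: int = 1
) -> np.ndarray:
    """Run the generator over a stack of frames.

    Frames are nearest-neighbour upsampled by ``upsample``, normalized with
    the training scale, mapped through the generator and rescaled back to
    map units.  Any frame size divisible by ``2**depth`` after upsampling
    is accepted.  The generator head is linear, so residual negative values
    are clipped to zero here.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if upsample > 1:
        stack = np.repeat(np.repeat(stack, upsample, axis=1), upsample, axis=2)
    d = model.gspec.depth
    if stack.shape[1] % 2**d or stack.shape[2] % 2**d:
        raise ValueError(
            f"frame size {stack.shape[1:]} (after upsampling) must be divisible "
            f"by 2**depth = {2**d}"
        )
    out = np.empty_like(stack)
    for i in range(stack.shape[0]):
        x = Tensor((stack[i] / model.x_scale).astype(np.float32)[None, None])
        out[i] = model.generator.forward(x, train=False).data[0, 0]
    return np.clip(out, 0.0, None) * model.y_scale


def maps_to_table(
    maps: np.ndarray,
    threshold_fraction: float = 0.3,
    pixel_size: float = 100.0,
    upsample: int = 5,
) -> "pd.DataFrame":
    """Convert localization maps to an emitter table.

    Per frame, pixels above ``threshold_fraction * max(frame)`` are grouped
    into 8-connected components; each component contributes one row at its
    intensity-weighted centroid, converted to nm with the upsampled pixel
    pitch (centre-of-pixel convention).
    """
    import pandas as pd

    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim == 2:
        maps = maps[None]
    mp = pixel_size / upsample
    struct = np.ones((3, 3), dtype=bool)
    rows = []
    for f in range(maps.shape[0]):
        frame = maps[f]
        mx = frame.max()
        if mx <= 0:
            continue
        mask = frame > threshold_fraction * mx
        labels, n = ndimage.label(mask, structure=struct)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        total = ndimage.sum_labels(frame, labels, idx)
        cy = ndimage.sum_labels(frame * np.arange(frame.shape[0])[:, None], labels, idx) / total
        cx = ndimage.sum_labels(frame * np.arange(frame.shape[1])[None, :], labels, idx) / total
        for k in range(n):
            rows.append((f, (cx[k] + 0.5) * mp, (cy[k] + 0.5) * mp, total[k]))
    return pd.DataFrame(rows, columns=["frame", "x", "y", "photons"])


def export_model(model: TrainedModel, path: str) -> None:
    """Serialize a trained model to ``path`` (.npz) plus a YAML sidecar.

    The sidecar records the generator/discriminator specs, loss weights,
    training config and seed; reloading reproduces inference bit-compatibly
    on the same platform.
    """
    from dataclasses import asdict
    from pathlib import Path

    import yaml

    path = str(path)
    arrays = {f"g.{k}": v for k, v in model.generator.state_dict().items()}
    if model.discriminator is not None:
        arrays.update(
            {f"d.{k}": v for k, v in model.discriminator.state_dict().items()}
        )
    arrays["x_scale"] = np.array(model.x_scale)
    arrays["y_scale"] = np.array(model.y_scale)
    np.savez(path, **arrays)
    meta = {
        "generator_spec": asdict(model.gspec),
        "discriminator_spec": asdict(model.dspec),
        "loss_weights": asdict(model.weights),
        "train_config": asdict(model.config),
        "seed": model.config.seed,
    }
    Path(path).with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_model(path: str) -> TrainedModel:
    """Reload a model exported with :func:`export_model`."""
    from pathlib import Path

    import yaml

    meta = yaml.safe_load(Path(path).with_suffix(".yaml").read_text())
    gspec = GeneratorSpec(**meta["generator_spec"])
    dspec = DiscriminatorSpec(**meta["discriminator_spec"])
    w = LossWeights(**meta["loss_weights"])
    tc = TrainConfig(**meta["train_config"])
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    gen = UNetGenerator(gspec, seed=tc.seed)
    gen.load_state_dict(
        {k[2:]: data[k] for k in data.files if k.startswith("g.")}
    )
    dkeys = {k[2:]: data[k] for k in data.files if k.startswith("d.")}
    disc = None
    if dkeys:
        disc = PatchDiscriminator(dspec, seed=tc.seed + 1)
        disc.load_state_dict(dkeys)
    return TrainedModel(
        generator=gen, discriminator=disc, gspec=gspec, dspec=dspec,
        weights=w, config=tc,
        x_scale=float(data["x_scale"]), y_scale=float(data["y_scale"]),
    )
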