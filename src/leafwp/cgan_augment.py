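"""Psi-conditioned generative augmentation of spectral training sets.

A conditional GAN learns the joint structure of (reflectance spectrum,
Psi_leaf): the generator G maps a noise vector z and a condition embedding
Psi_c to a synthetic 176-band spectrum, the discriminator D scores
(spectrum, Psi_c) pairs as measured versus synthetic, and the two are
trained on the adversarial value

    min_G max_D  E_x[log D(x | Psi_c)] + E_z[log(1 - D(G(z | Psi_c) | Psi_c))].

After training, Psi conditions are resampled on an evenly spaced grid over
the training range and fed to G, filling the sparsely measured (strongly
water-stressed) part of the label axis; the synthetic rows are concatenated
with the measured training rows. Fidelity is monitored with the Spectral
Angle Mapper between the mean real and mean generated spectrum (angles
below 0.1 rad are conventionally read as high spectral fidelity).

Both networks are small fully connected stacks — appropriate for 176-dim
vectors and a few hundred training rows — with the normalized condition
concatenated to their inputs. The generator step uses the non-saturating
form of its objective (maximize log D(G(z|Psi_c)|Psi_c)), the standard
stabilization of the min-max game.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .spectral_core import (
    PROVENANCE_CGAN,
    SpectraSet,
    WavelengthGrid,
    spectral_angle,
)

__all__ = [
    "CGANConfig",
    "CGANBundle",
    "train_cgan",
    "resample_condition_grid",
    "generate_conditioned_spectra",
    "fidelity_sam",
    "augment_training_set",
]


@dataclass
class CGANConfig:
    """Training configuration for the conditional GAN.

    The adversarial game gives no architecture or schedule, so these are
    engineering defaults sized for a few hundred 176-band spectra on CPU.
    """

    noise_dim: int = 16
    gen_hidden: tuple[int, ...] = (128, 128)
    disc_hidden: tuple[int, ...] = (128, 64)
    epochs: int = 3000
    batch_size: int = 32
    lr: float = 1e-4
    ema_decay: float = 0.999
    seed: int = 0
    n_synthetic: int = 500

    def __post_init__(self) -> None:
        if self.noise_dim <= 0 or self.batch_size <= 0:
            raise ValueError("noise_dim and batch_size must be positive")
        if self.n_synthetic < 0:
            raise ValueError("n_synthetic must be >= 0")


class _Generator(nn.Module):
    def __init__(self, cfg: CGANConfig, n_bands: int, rng):
        super().__init__()
        dims = [cfg.noise_dim + 1, *cfg.gen_hidden, n_bands]
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            layer = nn.Linear(a, b, rng)
            setattr(self, f"fc{i}", layer)
            self.layers.append(layer)

    def forward(self, z: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        h = nn.concat([z, cond], axis=1)
        for layer in self.layers[:-1]:
            h = layer(h).relu()
        return self.layers[-1](h)  # linear output; clipping happens at sampling


class _Discriminator(nn.Module):
    def __init__(self, cfg: CGANConfig, n_bands: int, rng):
        super().__init__()
        dims = [n_bands + 1, *cfg.disc_hidden, 1]
        self.layers = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            layer = nn.Linear(a, b, rng)
            setattr(self, f"fc{i}", layer)
            self.layers.append(layer)

    def forward(self, x: nn.Tensor, cond: nn.Tensor) -> nn.Tensor:
        h = nn.concat([x, cond], axis=1)
        for layer in self.layers[:-1]:
            h = layer(h).relu()
        return self.layers[-1](h).sigmoid()


@dataclass
class CGANBundle:
    """Trained generator/discriminator plus the condition normalization.

    Psi conditions are mapped to [-1, 1] before entering either network
    (psi -> (psi - center) / scale); center and scale are stored so the
    embedding is invertible.
    """

    generator: _Generator
    discriminator: _Discriminator
    cfg: CGANConfig
    grid: WavelengthGrid
    cond_center: float
    cond_scale: float
    gen_loss_trace: list[float] = field(default_factory=list)
    disc_loss_trace: list[float] = field(default_factory=list)
    trained: bool = False

    @property
    def n_bands(self) -> int:
        return self.grid.n_bands

    def embed_condition(self, psi: np.ndarray) -> np.ndarray:
        return (np.asarray(psi, dtype=float) - self.cond_center) / self.cond_scale


def _init_bundle(train_set: SpectraSet, cfg: CGANConfig) -> CGANBundle:
    psi = train_set.psi
    center = float((psi.max() + psi.min()) / 2.0)
    scale = float(max((psi.max() - psi.min()) / 2.0, 1e-6))
    rng = np.random.default_rng(cfg.seed)
    return CGANBundle(
        generator=_Generator(cfg, train_set.grid.n_bands, rng),
        discriminator=_Discriminator(cfg, train_set.grid.n_bands, rng),
        cfg=cfg,
        grid=train_set.grid,
        cond_center=center,
        cond_scale=scale,
    )


def _log(t: nn.Tensor) -> nn.Tensor:
    return (t + 1e-8).log()


def train_cgan(train_set: SpectraSet, cfg: CGANConfig) -> CGANBundle:
    """Adversarial training on labeled *training* rows only.

    Alternates one discriminator ascent step (real up, fake down) and one
    generator step per minibatch; Adam(beta1=0.5) on both players. The
    sampling generator uses an exponential moving average of the generator
    weights (decay ``ema_decay``), which damps the oscillation of the
    adversarial game and markedly improves mean-spectrum fidelity. Returns
    the bundle with per-epoch loss traces for both players.
    """
    if not train_set.is_labeled:
        raise ValueError("CGAN training requires Psi labels")
    n = train_set.n_samples
    if n < cfg.batch_size:
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds n_samples {n}; "
            "use a smaller batch_size"
        )
    bundle = _init_bundle(train_set, cfg)
    G, D = bundle.generator, bundle.discriminator
    opt_g = nn.Adam(G.parameters(), lr=cfg.lr, beta1=0.5)
    opt_d = nn.Adam(D.parameters(), lr=cfg.lr, beta1=0.5)
    rng = np.random.default_rng(cfg.seed + 1)
    X = train_set.spectra
    cond_all = bundle.embed_condition(train_set.psi)
    g_params = G.parameters()
    ema = [p.data.copy() for p in g_params]

    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            real = nn.Tensor(X[idx])
            cond = nn.Tensor(cond_all[idx][:, None])
            z = nn.Tensor(rng.standard_normal((len(idx), cfg.noise_dim)))

            # discriminator step (generator output detached)
            fake = nn.Tensor(G(z, cond).data)
            d_real = D(real, cond)
            d_fake = D(fake, cond)
            loss_d = -(_log(d_real).mean() + _log(1.0 - d_fake).mean())
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()

            # generator step (non-saturating objective)
            z2 = nn.Tensor(rng.standard_normal((len(idx), cfg.noise_dim)))
            fake2 = G(z2, cond)
            loss_g = -_log(D(fake2, cond)).mean()
            opt_g.zero_grad()
            loss_g.backward()
            opt_g.step()
            for e, p in zip(ema, g_params):
                e *= cfg.ema_decay
                e += (1.0 - cfg.ema_decay) * p.data

            d_losses.append(loss_d.item())
            g_losses.append(loss_g.item())
        bundle.disc_loss_trace.append(float(np.mean(d_losses)))
        bundle.gen_loss_trace.append(float(np.mean(g_losses)))
    for e, p in zip(ema, g_params):
        p.data[...] = e
    bundle.trained = True
    return bundle


def resample_condition_grid(n: int, psi_min: float, psi_max: float) -> np.ndarray:
    """n evenly spaced Psi conditions covering [psi_min, psi_max] inclusive.

    The even grid (rather than uniform random draws) guarantees coverage of
    the sparsely measured end of the range.
    """
    if n < 2:
        raise ValueError("need n >= 2 conditions")
    if not psi_min < psi_max <= 0:
        raise ValueError(f"need psi_min < psi_max <= 0, got [{psi_min}, {psi_max}]")
    return np.linspace(psi_min, psi_max, n)


def generate_conditioned_spectra(
    bundle: CGANBundle, psi_values: np.ndarray, seed: int | None = None
) -> SpectraSet:
    """Sample one synthetic spectrum per condition from the trained generator.

    Rows carry the conditioning Psi as their regression label and the
    provenance flag ``"cgan_generated"``; outputs are clipped below at 0
    (reflectance is non-negative).
    """
    if not bundle.trained:
        raise ValueError("bundle is untrained; call train_cgan first")
    psi_values = np.asarray(psi_values, dtype=float)
    rng = np.random.default_rng(bundle.cfg.seed + 2 if seed is None else seed)
    z = nn.Tensor(rng.standard_normal((psi_values.size, bundle.cfg.noise_dim)))
    cond = nn.Tensor(bundle.embed_condition(psi_values)[:, None])
    bundle.generator.eval()
    spectra = np.clip(bundle.generator(z, cond).data, 0.0, None)
    bundle.generator.train()
    return SpectraSet(
        grid=bundle.grid,
        spectra=spectra,
        psi=psi_values,
        sample_ids=[f"gen{i:04d}" for i in range(psi_values.size)],
        provenance=[PROVENANCE_CGAN] * psi_values.size,
    )


def fidelity_sam(real: SpectraSet, generated: SpectraSet) -> float:
    """Spectral angle (rad) between the column-mean real and generated spectra."""
    if real.n_samples == 0 or generated.n_samples == 0:
        raise ValueError("fidelity_sam requires nonempty sets")
    if real.grid != generated.grid:
        raise ValueError("sets are on different wavelength grids")
    return spectral_angle(real.spectra.mean(axis=0), generated.spectra.mean(axis=0))


def augment_training_set(
    train: SpectraSet, bundle: CGANBundle, n_synthetic: int | None = None, seed: int | None = None
) -> SpectraSet:
    """Return train + n_synthetic generated rows (inputs left unmodified).

    Conditions are an even grid over the training Psi range, so the
    augmented set covers the label axis continuously.
    """
    n_syn = bundle.cfg.n_synthetic if n_synthetic is None else n_synthetic
    if n_syn == 0:
        return train
    conditions = resample_condition_grid(n_syn, float(train.psi.min()), float(train.psi.max()))
    generated = generate_conditioned_spectra(bundle, conditions, seed=seed)
    return train.concat(generated)
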