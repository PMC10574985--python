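"""GAN-based epoch augmentation.

The generator maps a 100-dimensional uniform latent vector through fully
connected blocks of widths 128, 256, 512, 1024 and 3750 with leaky-rectifier
activations to a 3750-sample signal (one 15 s epoch at 250 Hz, squashed to
[0, 1] to match the normalized data).  The discriminator is five fully
connected layers with dropout after layers 1 and 3 and a logistic scalar
output.  Both are trained adversarially under the minimax objective

    min_G max_D  E_x[log D(x)] + E_z[log(1 - D(G(z)))]

with k discriminator updates per generator update.  The generator loss
defaults to the non-saturating form ``-E_z[log D(G(z))]`` (the saturating
form ``E_z[log(1 - D(G(z)))]`` is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass
import hashlib

import numpy as np
from sklearn.base import BaseEstimator

from .io import EpochDataset
from .nn import (Dense, Dropout, LeakyReLU, Sequential, Sigmoid,
                 make_optimizer)

EPS = 1e-7  # probability clamp


class DataError(ValueError):
    """Raised when a dataset is too small for the requested operation."""


@dataclass(frozen=True)
class GANSpec:
    """Generator/discriminator dimensions and training hyperparameters."""

    latent_dim: int = 100
    generator_layer_dims: tuple[int, ...] = (128, 256, 512, 1024, 3750)
    discriminator_layer_dims: tuple[int, ...] = (512, 256, 128, 64, 1)
    dropout_rate: float = 0.3
    leaky_slope: float = 0.2
    batch_size: int = 10
    learning_rate: float = 1e-5
    epochs: int = 200
    k_disc_steps: int = 1
    optimizer: str = "sgd"
    saturating_gen_loss: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim != 100:
            raise ValueError("latent_dim is fixed at 100")
        if self.generator_layer_dims[-1] != 3750:
            raise ValueError("the generator must emit 3750-sample signals")
        if len(self.discriminator_layer_dims) != 5:
            raise ValueError("the discriminator has exactly 5 fully connected layers")

    @property
    def signal_len(self) -> int:
        return self.generator_layer_dims[-1]


class Generator:
    """Latent (100,) -> signal (3750,) network with seeded sampling."""

    def __init__(self, spec: GANSpec, seed: int | None = None):
        self.spec = spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        layers: list = []
        n_in = spec.latent_dim
        dims = spec.generator_layer_dims
        for i, n_out in enumerate(dims):
            layers.append(Dense(n_in, n_out, rng=rng))
            layers.append(LeakyReLU(spec.leaky_slope) if i < len(dims) - 1
                          else Sigmoid())
            n_in = n_out
        self.net = Sequential(layers)

    def forward(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"latent vectors must have length {self.spec.latent_dim}, "
                f"got {z.shape[1]}")
        return self.net.forward(z, training)

    __call__ = forward

    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-1.0, 1.0, size=(n, self.spec.latent_dim))

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        return self.forward(self.sample_latent(n, rng))


class Discriminator:
    """Signal (3750,) -> probability of being real, in (0, 1)."""

    #: 1-based indices of the fully connected layers followed by dropout
    DROPOUT_AFTER = (1, 3)

    def __init__(self, spec: GANSpec, seed: int | None = None):
        self.spec = spec
        rng = np.random.default_rng((spec.seed + 1) if seed is None else seed)
        layers: list = []
        n_in = spec.signal_len
        dims = spec.discriminator_layer_dims
        for i, n_out in enumerate(dims):
            layers.append(Dense(n_in, n_out, rng=rng))
            if i < len(dims) - 1:
                layers.append(LeakyReLU(spec.leaky_slope))
                if (i + 1) in self.DROPOUT_AFTER:
                    layers.append(Dropout(spec.dropout_rate))
            else:
                layers.append(Sigmoid())
            n_in = n_out
        self.net = Sequential(layers)

    @property
    def fc_layers(self) -> list[Dense]:
        return [l for l in self.net.layers if isinstance(l, Dense)]

    @property
    def dropout_positions(self) -> set[int]:
        """1-based FC-layer indices that are followed by a dropout layer."""
        pos, fc_idx = set(), 0
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, Dense):
                fc_idx += 1
            if isinstance(layer, Dropout):
                pos.add(fc_idx)
        return pos

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.spec.signal_len:
            raise ValueError(
                f"discriminator input must have length {self.spec.signal_len}, "
                f"got {x.shape[1]}")
        return self.net.forward(x, training)[:, 0]

    __call__ = forward


def build_generator(spec: GANSpec, seed: int | None = None) -> Generator:
    return Generator(spec, seed)


def build_discriminator(spec: GANSpec, seed: int | None = None) -> Discriminator:
    return Discriminator(spec, seed)


def gan_losses(d_real: np.ndarray, d_fake: np.ndarray,
               saturating: bool = False) -> tuple[float, float]:
    """Closed-form adversarial losses from discriminator probabilities.

    Discriminator loss: ``-mean log d_real - mean log(1 - d_fake)``.
    Generator loss: non-saturating ``-mean log d_fake`` (default) or the
    saturating objective ``mean log(1 - d_fake)``.  Probabilities are
    clamped to [EPS, 1-EPS].
    """
    d_real = np.clip(np.asarray(d_real, dtype=float), EPS, 1 - EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=float), EPS, 1 - EPS)
    d_loss = float(-np.mean(np.log(d_real)) - np.mean(np.log(1 - d_fake)))
    if saturating:
        g_loss = float(np.mean(np.log(1 - d_fake)))
    else:
        g_loss = float(-np.mean(np.log(d_fake)))
    return d_loss, g_loss


def train_gan(real_epochs, spec: GANSpec | None = None, seed: int = 0):
    """Adversarial training loop.

    Parameters
    ----------
    real_epochs : (n, 3750) array (or EpochDataset whose channels are
        pooled into single-channel examples).
    spec : GANSpec
    seed : int
        Controls initialization, dropout, latent draws and batching;
        identical seeds reproduce identical loss histories.

    Returns
    -------
    generator, discriminator, history
        ``history`` has per-epoch mean discriminator/generator losses and
        the final discriminator accuracy on a held-out real/fake mix.
    """
    spec = spec or GANSpec()
    if isinstance(real_epochs, EpochDataset):
        X = real_epochs.epochs.reshape(-1, real_epochs.n_samples)
    else:
        X = np.asarray(real_epochs, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.signal_len:
        raise ValueError(f"real epochs must be (n, {spec.signal_len})")
    if len(X) < spec.batch_size:
        raise DataError(
            f"need at least batch_size={spec.batch_size} real epochs, "
            f"got {len(X)}")

    ss = np.random.SeedSequence(entropy=seed)
    s_init_g, s_init_d, s_drop, s_loop = ss.spawn(4)
    gen = Generator(spec, seed=np.random.default_rng(s_init_g).integers(2**31))
    disc = Discriminator(spec, seed=np.random.default_rng(s_init_d).integers(2**31))
    disc.net.seed_dropout(int(np.random.default_rng(s_drop).integers(2**31)))
    rng = np.random.default_rng(s_loop)

    g_opt = make_optimizer(spec.optimizer, gen.net.params(), spec.learning_rate)
    d_opt = make_optimizer(spec.optimizer, disc.net.params(), spec.learning_rate)

    bs = spec.batch_size
    history = {"d_loss": [], "g_loss": []}
    for _epoch in range(spec.epochs):
        order = rng.permutation(len(X))
        d_losses, g_losses = [], []
        n_batches = max(len(X) // bs, 1)
        for b in range(n_batches):
            for _k in range(spec.k_disc_steps):
                start = (b * bs) % max(len(X) - bs + 1, 1)
                real = X[order[start: start + bs]]
                z = gen.sample_latent(bs, rng)
                fake = gen.forward(z, training=False)
                disc.net.zero_grad()
                xb = np.concatenate([real, fake])
                p = np.clip(disc.forward(xb, training=True), EPS, 1 - EPS)
                p_real, p_fake = p[: len(real)], p[len(real):]
                d_loss, _ = gan_losses(p_real, p_fake)
                # d(-log p)/dp = -1/p ; d(-log(1-p))/dp = 1/(1-p)
                gp = np.concatenate([-1.0 / p_real / len(real),
                                     1.0 / (1.0 - p_fake) / bs])
                disc.net.backward(_through_sigmoid(disc, gp))
                d_opt.step()
                d_losses.append(d_loss)
            # generator update: gradients flow through a frozen critic
            z = gen.sample_latent(bs, rng)
            gen.net.zero_grad()
            fake = gen.forward(z, training=True)
            disc.net.zero_grad()
            p_fake = np.clip(disc.forward(fake, training=True), EPS, 1 - EPS)
            if spec.saturating_gen_loss:
                g_loss = float(np.mean(np.log(1 - p_fake)))
                gp = -1.0 / (1.0 - p_fake) / bs
            else:
                g_loss = float(-np.mean(np.log(p_fake)))
                gp = -1.0 / p_fake / bs
            g_at_fake = disc.net.backward(_through_sigmoid(disc, gp))
            disc.net.zero_grad()  # discard critic gradients from this pass
            gen.net.backward(g_at_fake)
            g_opt.step()
            g_losses.append(g_loss)
        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(float(np.mean(g_losses)))

    n_eval = min(len(X), 64)
    fake = gen.sample(n_eval, rng)
    p = np.concatenate([disc.forward(X[:n_eval]), disc.forward(fake)])
    truth = np.concatenate([np.ones(n_eval), np.zeros(n_eval)])
    history["disc_accuracy"] = float(((p > 0.5) == truth).mean())
    return gen, disc, history


def _through_sigmoid(disc: Discriminator, gp: np.ndarray) -> np.ndarray:
    """Shape dL/d(probability) for the discriminator's backward pass; its
    last layer is the sigmoid, which applies p(1-p) itself."""
    return gp[:, None]


def save_generator(gen: Generator, path) -> None:
    """Persist generator weights plus spec to a portable .npz checkpoint."""
    import json
    from dataclasses import asdict

    arrays = {"_spec": np.frombuffer(json.dumps(asdict(gen.spec)).encode(),
                                     dtype=np.uint8)}
    for i, p in enumerate(gen.net.params()):
        arrays[f"p{i:03d}"] = p.value
    np.savez(path, **arrays)


def load_generator(path) -> Generator:
    import json

    with np.load(path) as data:
        spec_d = json.loads(bytes(data["_spec"]).decode())
        spec = GANSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in spec_d.items()})
        gen = Generator(spec)
        for i, p in enumerate(gen.net.params()):
            p.value[...] = data[f"p{i:03d}"]
    return gen


def dataset_checksum(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()


def augment_dataset(dataset: EpochDataset, generators,
                    target_total: int, seed: int = 0) -> EpochDataset:
    """Grow a dataset to ``target_total`` epochs with GAN-generated ones.

    ``generators`` maps class label -> trained Generator (a single
    Generator is accepted and used for every class).  Synthetic epochs are
    flagged in ``synthetic`` and class proportions are preserved (largest-
    remainder apportionment).  Real epochs are never mutated.
    """
    n = len(dataset)
    if target_total < n:
        raise ValueError(f"target_total={target_total} < current size {n}")
    if target_total == n:
        return dataset
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if not isinstance(generators, dict):
        generators = {c: generators for c in classes}
    n_add = target_total - n
    quota = counts / counts.sum() * n_add
    base = np.floor(quota).astype(int)
    rem = quota - base
    for i in np.argsort(-rem)[: n_add - base.sum()]:
        base[i] += 1
    rng = np.random.default_rng(seed)
    new_epochs, new_labels = [], []
    c_chan = dataset.n_channels
    for cls, add in zip(classes, base):
        if add == 0:
            continue
        gen = generators[cls]
        traces = gen.sample(add * c_chan, rng)
        new_epochs.append(traces.reshape(add, c_chan, -1))
        new_labels.extend([cls] * add)
    epochs = np.concatenate([dataset.epochs] + new_epochs)
    labels = np.concatenate([dataset.labels, np.asarray(new_labels)])
    synthetic = np.concatenate([dataset.synthetic,
                                np.ones(n_add, dtype=bool)])
    return EpochDataset(epochs, labels, dataset.channel_names, dataset.fs,
                        dataset.provenance + ("gan_augment",), synthetic,
                        dataset.seed, dataset.config_hash)


class GANAugmenter(BaseEstimator):
    """Per-class GAN augmentation as an estimator.

    ``fit(X, y)`` trains one GAN per class on the pooled single-channel
    traces of that class; ``augment(dataset, target_total)`` grows the
    dataset.  ``X`` may be an EpochDataset or an (n, channels, samples)
    array.
    """

    def __init__(self, spec: GANSpec | None = None, seed: int = 0):
        self.spec = spec
        self.seed = seed

    def fit(self, X, y=None):
        spec = self.spec or GANSpec()
        if isinstance(X, EpochDataset):
            y = X.labels
            X = X.epochs
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.generators_ = {}
        self.histories_ = {}
        for i, cls in enumerate(np.unique(y)):
            traces = X[y == cls].reshape(-1, X.shape[-1])
            gen, _disc, hist = train_gan(traces, spec, seed=self.seed + i)
            self.generators_[cls] = gen
            self.histories_[cls] = hist
        return self

    def augment(self, dataset: EpochDataset, target_total: int) -> EpochDataset:
        return augment_dataset(dataset, self.generators_, target_total,
                               seed=self.seed)
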