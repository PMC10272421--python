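"""Filter-bank GAN: a generator and two discriminators for EEG augmentation.

One unconditional model is trained per (subject, class).  The generator maps
a 1600-d normal noise vector through a fully connected layer and five
transposed convolutions to a 22 x 1000 trial.  Discriminator ``D_raw``
judges raw trials; the second discriminator ``D_fb`` judges the sparsely
spatially-filtered version ``Z = W_csp^T x`` of each trial (columns applied
in their originating filter-bank band), which pressures the generator to
reproduce the class's spatial band-power structure, not just waveform
marginals.

Both discriminator losses are standard binary cross-entropies; the
generator uses the non-saturating objective against both discriminators
with configurable weights (default equal).  Band filtering inside the GAN is
a circular spectral operator (the squared Butterworth magnitude response on
the rFFT), which is exactly linear and self-adjoint, so its backward pass is
the operator itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from . import nn
from .cspselect import SparseSpatialFilter
from .preprocess import DEFAULT_BANDS, EpochSet


# ---------------------------------------------------------------------------
# specs


@dataclass
class ConvTransSpec:
    in_channels: int
    out_channels: int
    kernel: tuple
    stride: tuple
    padding: tuple = (0, 0)
    output_padding: tuple = (0, 0)
    batchnorm: bool = True


@dataclass
class GeneratorSpec:
    noise_dim: int
    fc_out: int
    lattice: tuple                       # (channels, height, width) after FC
    layers: tuple                        # ConvTransSpec roster
    output_shape: tuple = (22, 1000)
    negative_slope: float = 0.2
    final_activation: str = "linear"     # z-scored EEG is signed and unbounded

    @classmethod
    def default(cls) -> "GeneratorSpec":
        """FC(1600 -> 256000) + 5 transposed convolutions landing on (22, 1000).

        Kernels, strides, channel counts and batch-norm placement follow the
        reference roster; the reshape lattice (128, 40, 50) and the padding
        column are this package's completion of the under-determined path
        (the width trace 50 -> 162 -> 496 -> 995 -> 999 -> 1000 is exact).
        """
        return cls(
            noise_dim=1600,
            fc_out=256_000,
            lattice=(128, 40, 50),
            layers=(
                ConvTransSpec(128, 128, (3, 15), (1, 3), (1, 0)),
                ConvTransSpec(128, 128, (3, 15), (1, 3), (1, 1)),
                ConvTransSpec(128, 64, (3, 5), (1, 2), (1, 0)),
                ConvTransSpec(64, 32, (4, 5), (2, 1), (30, 0)),
                ConvTransSpec(32, 1, (1, 2), (1, 1), (0, 0), batchnorm=False),
            ),
            output_shape=(22, 1000),
        )

    @classmethod
    def small(cls, channels: int, samples: int, noise_dim: int = 64,
              base_filters: int = 16) -> "GeneratorSpec":
        """Reduced generator for small problems: same FC + transposed-conv
        shape, three x2 upsampling stages along time (samples must be a
        multiple of 8)."""
        if samples % 8:
            raise ValueError("samples must be a multiple of 8 for the small spec")
        w0 = samples // 8
        lattice = (base_filters, channels, w0)
        return cls(
            noise_dim=noise_dim,
            fc_out=base_filters * channels * w0,
            lattice=lattice,
            layers=(
                ConvTransSpec(base_filters, base_filters, (1, 4), (1, 2), (0, 1)),
                ConvTransSpec(base_filters, base_filters // 2, (1, 4), (1, 2), (0, 1)),
                ConvTransSpec(base_filters // 2, 1, (1, 4), (1, 2), (0, 1), batchnorm=False),
            ),
            output_shape=(channels, samples),
        )

    def shape_trace(self):
        """(H, W) after the reshape and after every transposed conv."""
        c, h, w = self.lattice
        if c * h * w != self.fc_out:
            raise ValueError(
                f"lattice {self.lattice} does not tile fc_out={self.fc_out}")
        trace = [(h, w)]
        for ly in self.layers:
            kh, kw = ly.kernel
            sh, sw = ly.stride
            ph, pw = ly.padding
            oh, ow = ly.output_padding
            h = (h - 1) * sh + kh - 2 * ph + oh
            w = (w - 1) * sw + kw - 2 * pw + ow
            trace.append((h, w))
        return trace


def _var_kernel(n_sel: int) -> int:
    """Adaptive row-kernel of the FB discriminator's third convolution:
    after the stride-4 row reduction, floor(n_sel / 4) rows remain and the
    kernel spans all of them, collapsing the spatial axis to one."""
    if n_sel < 4:
        raise ValueError("the FB discriminator needs n_sel >= 4 selected columns")
    return n_sel // 4


@dataclass
class DiscriminatorSpec:
    kind: str                            # 'raw' | 'fb'
    input_shape: tuple                   # (rows, samples)
    layers: tuple                        # ('conv', cin, cout, k, s) | ('maxpool', k, s)
    negative_slope: float = 0.2

    @classmethod
    def raw_default(cls, channels: int = 22, samples: int = 1000) -> "DiscriminatorSpec":
        return cls(kind="raw", input_shape=(channels, samples), layers=(
            ("conv", 1, 10, (1, 23), (1, 1)),
            ("conv", 10, 30, (channels, 1), (1, 1)),
            ("conv", 30, 30, (1, 17), (1, 1)),
            ("maxpool", (1, 6), (1, 6)),
            ("conv", 30, 30, (1, 7), (1, 1)),
            ("maxpool", (1, 6), (1, 6)),
        ))

    @classmethod
    def fb_default(cls, n_sel: int, samples: int = 1000) -> "DiscriminatorSpec":
        var = _var_kernel(n_sel)
        return cls(kind="fb", input_shape=(n_sel, samples), layers=(
            ("conv", 1, 10, (1, 23), (1, 1)),
            ("conv", 10, 30, (4, 1), (4, 1)),
            ("conv", 30, 30, (var, 1), (1, 1)),
            ("conv", 30, 30, (1, 17), (1, 1)),
            ("maxpool", (1, 6), (1, 6)),
            ("conv", 30, 30, (1, 7), (1, 1)),
            ("maxpool", (1, 6), (1, 6)),
        ))

    @classmethod
    def small(cls, kind: str, rows: int, samples: int) -> "DiscriminatorSpec":
        layers = [("conv", 1, 8, (1, 9), (1, 1))]
        if kind == "raw":
            layers.append(("conv", 8, 16, (rows, 1), (1, 1)))
        else:
            var = _var_kernel(rows)
            layers.append(("conv", 8, 16, (4, 1), (4, 1)))
            layers.append(("conv", 16, 16, (var, 1), (1, 1)))
        layers += [
            ("conv", 16, 16, (1, 5), (1, 1)),
            ("maxpool", (1, 4), (1, 4)),
            ("conv", 16, 16, (1, 5), (1, 1)),
            ("maxpool", (1, 2), (1, 2)),
        ]
        return cls(kind=kind, input_shape=(rows, samples), layers=tuple(layers))

    def feature_count(self) -> int:
        """Flattened width entering the final FC (750 for the default specs)."""
        h, w = self.input_shape
        ch = 1
        for ly in self.layers:
            if ly[0] == "conv":
                _, cin, cout, (kh, kw), (sh, sw) = ly
                if h < kh or w < kw:
                    raise ValueError(
                        f"conv kernel ({kh},{kw}) does not fit ({h},{w}) "
                        f"in the {self.kind} discriminator trace")
                h = (h - kh) // sh + 1
                w = (w - kw) // sw + 1
                ch = cout
            else:
                _, (kh, kw), (sh, sw) = ly
                h = (h - kh) // sh + 1
                w = (w - kw) // sw + 1
        if h <= 0 or w <= 0:
            raise ValueError(
                f"the {self.kind} discriminator collapses input "
                f"{self.input_shape} to ({h},{w}); input is too small")
        return ch * h * w


@dataclass
class GANTrainingConfig:
    lr: float = 1e-4
    batch_size: int = 5
    betas: tuple = (0.5, 0.999)
    n_epochs: int = 50
    seed: int = 0
    disc_weights: tuple = (1.0, 1.0)
    checkpoint_every: int = 0
    negative_slope: float = 0.2

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class GeneratedEpochSet:
    data: np.ndarray            # (n, channels, samples)
    class_label: int
    subject_id: str = ""
    seed: int = 0
    checkpoint_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.isfinite(self.data).all():
            raise ValueError("generated data contains non-finite values")

    @property
    def n(self):
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# builders


class Generator(nn.Module):
    def __init__(self, spec: GeneratorSpec, rng, dtype=np.float32):
        super().__init__()
        self.spec = spec
        layers = [
            nn.Linear(spec.noise_dim, spec.fc_out, rng, dtype=dtype),
            nn.Reshape(spec.lattice),
        ]
        for ly in spec.layers:
            layers.append(nn.ConvTranspose2d(
                ly.in_channels, ly.out_channels, ly.kernel, ly.stride,
                ly.padding, ly.output_padding, rng=rng, dtype=dtype))
            if ly.batchnorm:
                layers.append(nn.BatchNorm2d(ly.out_channels, dtype=dtype))
            layers.append(nn.LeakyReLU(spec.negative_slope))
        if not spec.layers[-1].batchnorm:
            layers.pop()                       # final layer: no activation
        if spec.final_activation == "tanh":
            layers.append(nn.Tanh())
        self.net = nn.Sequential(*layers)

    def forward(self, z):
        return self.net(z)

    def backward(self, grad):
        return self.net.backward(grad)


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0,
                    dtype=np.float32) -> Generator:
    """Construct the generator and verify its shape trace ends on
    ``spec.output_shape``; otherwise raise with the full trace."""
    spec = spec or GeneratorSpec.default()
    trace = spec.shape_trace()
    if tuple(trace[-1]) != tuple(spec.output_shape):
        raise ValueError(
            f"generator layer arithmetic cannot reach {spec.output_shape}; "
            f"shape trace: {trace}")
    return Generator(spec, np.random.default_rng(seed), dtype=dtype)


class Discriminator(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, rng, dtype=np.float32):
        super().__init__()
        self.spec = spec
        layers = []
        for ly in spec.layers:
            if ly[0] == "conv":
                _, cin, cout, k, s = ly
                layers.append(nn.Conv2d(cin, cout, k, s, rng=rng, dtype=dtype))
                layers.append(nn.LeakyReLU(spec.negative_slope))
            else:
                _, k, s = ly
                layers.append(nn.MaxPool2d(k, s))
        layers.append(nn.Flatten())
        layers.append(nn.Linear(spec.feature_count(), 1, rng, dtype=dtype))
        self.net = nn.Sequential(*layers)

    def forward(self, x):
        if x.ndim == 3:
            x = x[:, None]
        return self.net(x)

    def backward(self, grad):
        return self.net.backward(grad)


def build_discriminator(kind: str, n_sel: int | None = None,
                        spec: DiscriminatorSpec | None = None, seed: int = 0,
                        dtype=np.float32) -> Discriminator:
    if spec is None:
        if kind == "raw":
            spec = DiscriminatorSpec.raw_default()
        elif kind == "fb":
            if n_sel is None:
                raise ValueError("fb discriminator needs n_sel")
            spec = DiscriminatorSpec.fb_default(n_sel)
        else:
            raise ValueError("kind must be 'raw' or 'fb'")
    return Discriminator(spec, np.random.default_rng(seed), dtype=dtype)


# ---------------------------------------------------------------------------
# differentiable sparse filter-bank projection


class SparseProjection:
    """Z = W_csp^T x with each row band-filtered in its column's own band.

    The per-band filter multiplies the rFFT by the squared magnitude response
    of the zero-phase Butterworth band (circular convolution with a symmetric
    kernel) — a fixed linear self-adjoint operator, so ``backward`` applies
    the same filtering to the adjoint-projected gradient.
    """

    def __init__(self, W: SparseSpatialFilter, fs: float, n_samples: int,
                 bands=DEFAULT_BANDS, order: int = 5):
        self.W = W
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        self.n_samples = n_samples
        mult = np.empty((W.n_sel, freqs.size))
        for j, b in enumerate(W.band_of_column):
            lo, hi = bands[b]
            sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
            _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
            mult[j] = np.abs(h) ** 2
        self.mult = mult

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, C, T) -> (B, n_sel, T)."""
        z0 = np.einsum("ck,bct->bkt", self.W.W, x)
        Z = np.fft.irfft(np.fft.rfft(z0, axis=-1) * self.mult, n=self.n_samples, axis=-1)
        return Z.astype(x.dtype)

    def backward(self, gZ: np.ndarray) -> np.ndarray:
        g0 = np.fft.irfft(np.fft.rfft(gZ, axis=-1) * self.mult, n=self.n_samples, axis=-1)
        return np.einsum("ck,bkt->bct", self.W.W, g0).astype(gZ.dtype)

    __call__ = forward


# ---------------------------------------------------------------------------
# training


class GANOptimizers:
    def __init__(self, generator, d_raw, d_fb, config: GANTrainingConfig):
        self.g = nn.Adam(generator.parameters(), lr=config.lr, betas=config.betas)
        d_params = d_raw.parameters() + (d_fb.parameters() if d_fb is not None else [])
        self.d = nn.Adam(d_params, lr=config.lr, betas=config.betas)


def gan_step(generator: Generator, d_raw: Discriminator, d_fb: Discriminator | None,
             real_batch: np.ndarray, projection: SparseProjection | None,
             config: GANTrainingConfig, opts: GANOptimizers, rng) -> dict:
    """One discriminator update and one generator update on a single-class batch.

    Returns the scalar losses {'d_raw', 'd_fb', 'd_total', 'g'}.
    """
    B = real_batch.shape[0]
    real = real_batch.astype(np.float32)[:, None]
    w_phi, w_psi = config.disc_weights
    use_fb = d_fb is not None and projection is not None and w_psi != 0

    # ---- discriminator update (generator output treated as constant)
    z = rng.standard_normal((B, generator.spec.noise_dim)).astype(np.float32)
    fake = generator(z)
    d_raw.zero_grad()
    loss_r_real, g1 = nn.bce_with_logits(d_raw(real), 1.0)
    d_raw.backward(g1)
    loss_r_fake, g2 = nn.bce_with_logits(d_raw(fake), 0.0)
    d_raw.backward(g2)
    loss_d_raw = loss_r_real + loss_r_fake
    loss_d_fb = 0.0
    if d_fb is not None and projection is not None:
        d_fb.zero_grad()
        z_real = projection(real[:, 0])
        z_fake = projection(fake[:, 0])
        loss_f_real, g3 = nn.bce_with_logits(d_fb(z_real), 1.0)
        d_fb.backward(g3)
        loss_f_fake, g4 = nn.bce_with_logits(d_fb(z_fake), 0.0)
        d_fb.backward(g4)
        loss_d_fb = loss_f_real + loss_f_fake
    opts.d.step()

    # ---- generator update (non-saturating loss against both discriminators)
    z = rng.standard_normal((B, generator.spec.noise_dim)).astype(np.float32)
    generator.zero_grad()
    fake = generator(z)
    d_raw.zero_grad()
    loss_g_raw, g5 = nn.bce_with_logits(d_raw(fake), 1.0)
    if w_phi != 0:
        g_fake = w_phi * d_raw.backward(g5)
    else:
        g_fake = np.zeros_like(fake)
    loss_g_fb = 0.0
    if use_fb:
        d_fb.zero_grad()
        z_fake = projection(fake[:, 0])
        loss_g_fb, g6 = nn.bce_with_logits(d_fb(z_fake), 1.0)
        g_fake = g_fake + w_psi * projection.backward(d_fb.backward(g6)[:, 0])[:, None]
    generator.backward(g_fake.astype(np.float32))
    opts.g.step()
    d_raw.zero_grad()
    if d_fb is not None:
        d_fb.zero_grad()

    loss_g = w_phi * loss_g_raw + w_psi * loss_g_fb
    report = {"d_raw": loss_d_raw, "d_fb": loss_d_fb,
              "d_total": loss_d_raw + loss_d_fb, "g": loss_g}
    for k, v in report.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite {k} loss at optimizer step {opts.d.t}")
    return report


def train_fbgan(epochs_of_one_class, W: SparseSpatialFilter | None,
                config: GANTrainingConfig | None = None,
                gen_spec: GeneratorSpec | None = None,
                raw_spec: DiscriminatorSpec | None = None,
                fb_spec: DiscriminatorSpec | None = None,
                fs: float | None = None, bands=DEFAULT_BANDS,
                checkpoint_dir=None):
    """Train one generator on the trials of a single (subject, class).

    Returns ``(generator, history)``; history holds per-epoch mean losses.
    Checkpoints (weights + config + seed) are written every
    ``config.checkpoint_every`` epochs when a directory is given.
    """
    config = config or GANTrainingConfig()
    if isinstance(epochs_of_one_class, EpochSet):
        X = epochs_of_one_class.data
        fs = fs or epochs_of_one_class.fs
        labels = np.unique(epochs_of_one_class.labels)
        if labels.size > 1:
            raise ValueError(f"expected a single class, got {labels.tolist()}")
    else:
        X = np.asarray(epochs_of_one_class)
    if len(X) < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} trials, got {len(X)}")
    C, T = X.shape[1], X.shape[2]
    gen_spec = gen_spec or GeneratorSpec.default()
    if tuple(gen_spec.output_shape) != (C, T):
        raise ValueError(
            f"generator outputs {gen_spec.output_shape} but trials are {(C, T)}")
    rng = np.random.default_rng(config.seed)
    generator = build_generator(gen_spec, seed=int(rng.integers(2 ** 31)))
    d_raw = Discriminator(raw_spec or DiscriminatorSpec.raw_default(C, T),
                          np.random.default_rng(int(rng.integers(2 ** 31))))
    d_fb = None
    projection = None
    if W is not None:
        if fs is None:
            raise ValueError("fs is required to band-filter the FB data")
        projection = SparseProjection(W, fs, T, bands=bands)
        d_fb = Discriminator(fb_spec or DiscriminatorSpec.fb_default(W.n_sel, T),
                             np.random.default_rng(int(rng.integers(2 ** 31))))
    opts = GANOptimizers(generator, d_raw, d_fb, config)

    history = []
    n = len(X)
    for epoch_i in range(1, config.n_epochs + 1):
        perm = rng.permutation(n)
        sums = {"d_raw": 0.0, "d_fb": 0.0, "d_total": 0.0, "g": 0.0}
        n_batches = 0
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            batch = X[perm[start:start + config.batch_size]]
            report = gan_step(generator, d_raw, d_fb, batch, projection,
                              config, opts, rng)
            for k in sums:
                sums[k] += report[k]
            n_batches += 1
        history.append({"epoch": epoch_i,
                        **{k: v / n_batches for k, v in sums.items()}})
        if (checkpoint_dir is not None and config.checkpoint_every
                and epoch_i % config.checkpoint_every == 0):
            save_checkpoint(Path(checkpoint_dir) / f"fbgan_epoch{epoch_i:04d}.npz",
                            generator, config)
    if checkpoint_dir is not None:
        save_checkpoint(Path(checkpoint_dir) / "fbgan_final.npz", generator, config)
    return generator, history


def save_checkpoint(path, generator: Generator, config: GANTrainingConfig):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(config), "spec": _spec_to_dict(generator.spec)}
    np.savez(path, __meta__=json.dumps(meta), **generator.state_dict())


def load_checkpoint(path) -> Generator:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    spec = _spec_from_dict(meta["spec"])
    gen = build_generator(spec, seed=0)
    gen.load_state_dict(state)
    return gen


def _spec_to_dict(spec: GeneratorSpec):
    d = asdict(spec)
    return d


def _spec_from_dict(d):
    layers = tuple(ConvTransSpec(**{**ly, "kernel": tuple(ly["kernel"]),
                                    "stride": tuple(ly["stride"]),
                                    "padding": tuple(ly["padding"]),
                                    "output_padding": tuple(ly["output_padding"])})
                   for ly in d["layers"])
    return GeneratorSpec(noise_dim=d["noise_dim"], fc_out=d["fc_out"],
                         lattice=tuple(d["lattice"]), layers=layers,
                         output_shape=tuple(d["output_shape"]),
                         negative_slope=d["negative_slope"],
                         final_activation=d["final_activation"])


def generate(generator: Generator, n: int, seed: int = 0, class_label: int = 0,
             subject_id: str = "", checkpoint_id: str = "",
             batch_size: int = 16) -> GeneratedEpochSet:
    """Sample ``n`` trials in inference mode; same seed, same samples."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    generator.eval()
    out = []
    for start in range(0, n, batch_size):
        b = min(batch_size, n - start)
        z = rng.standard_normal((b, generator.spec.noise_dim)).astype(np.float32)
        out.append(generator(z)[:, 0])
    generator.train()
    return GeneratedEpochSet(data=np.concatenate(out), class_label=class_label,
                             subject_id=subject_id, seed=seed,
                             checkpoint_id=checkpoint_id)


class FilterBankGAN(BaseEstimator):
    """sklearn-style wrapper: ``fit(X)`` on single-class trials with a fitted
    sparse spatial filter, then ``sample(n, seed)`` for augmentation trials.

    Pass ``gen_spec``/``raw_spec``/``fb_spec`` for scaled-down problems;
    defaults are the full 22 x 1000 architecture.
    """

    def __init__(self, n_epochs=50, lr=1e-4, batch_size=5, disc_weights=(1.0, 1.0),
                 seed=0, gen_spec=None, raw_spec=None, fb_spec=None,
                 bands=DEFAULT_BANDS, fs=250.0):
        self.n_epochs = n_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.disc_weights = disc_weights
        self.seed = seed
        self.gen_spec = gen_spec
        self.raw_spec = raw_spec
        self.fb_spec = fb_spec
        self.bands = bands
        self.fs = fs

    def fit(self, X, y=None, sparse_filter: SparseSpatialFilter | None = None):
        config = GANTrainingConfig(lr=self.lr, batch_size=self.batch_size,
                                   n_epochs=self.n_epochs, seed=self.seed,
                                   disc_weights=self.disc_weights)
        self.generator_, self.history_ = train_fbgan(
            X, sparse_filter, config, gen_spec=self.gen_spec,
            raw_spec=self.raw_spec, fb_spec=self.fb_spec,
            fs=self.fs, bands=self.bands)
        return self

    def sample(self, n, seed=0, class_label=0, subject_id="") -> GeneratedEpochSet:
        return generate(self.generator_, n, seed=seed, class_label=class_label,
                        subject_id=subject_id)
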