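"""Syllable spectrogram preprocessing and a variational autoencoder.

Vocal segments are converted to fixed-size (default 128x128) log-
spectrogram images in [0, 1] and embedded in a low-dimensional latent
space (default 32-D) by a VAE trained with a spherical-Gaussian
observation model whose precision (``model_precision``, default 40)
weights reconstruction against the KL regularizer.

The encoder/decoder are fully-connected stacks implemented directly in
numpy with hand-written backpropagation and Adam — the downstream
statistics consume point latents, not a particular architecture, so the
network is kept deliberately small and dependency-free.  A
``select_top_latents`` helper picks the top-variance latent subset that
explains a target fraction (default 99.5%) of latent variance, mirroring
the usual dimensionality reduction before mixture modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .params import PreprocessParams
from .segmentation import compute_spectrogram, SegmentationParams


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess_segment(
    audio: np.ndarray,
    onset: float,
    offset: float,
    params: PreprocessParams | None = None,
) -> np.ndarray:
    """Convert one syllable to a square log-spectrogram image in [0, 1].

    The STFT log-modulus is clamped to ``[spec_min_val, spec_max_val]``,
    restricted to ``[min_freq, max_freq]``, interpolated onto
    ``image_size`` linearly spaced frequency rows, and the time axis is
    stretched to fill ``image_size`` frames when ``time_stretch`` is set
    (otherwise the syllable occupies a centered block proportional to
    ``duration / max_dur``).  Values are rescaled so the clamp floor maps
    to 0 and the ceiling to 1.  Row 0 is the lowest frequency.
    """
    params = params or PreprocessParams()
    dur = offset - onset
    if dur > params.max_dur + 1e-9:
        raise ValueError(f"duration {dur:.3f}s exceeds max_dur {params.max_dur}s")
    a = int(round(onset * params.fs))
    b = int(round(offset * params.fs))
    seg = np.asarray(audio[a:b], dtype=float)
    if seg.size < params.nperseg:
        seg = np.pad(seg, (0, params.nperseg - seg.size))
    seg_params = SegmentationParams(
        min_freq=params.min_freq,
        max_freq=params.max_freq,
        nperseg=params.nperseg,
        noverlap=params.noverlap,
        spec_min_val=params.spec_min_val,
        spec_max_val=params.spec_max_val,
        fs=params.fs,
    )
    spec, freqs, times = compute_spectrogram(seg, seg_params)
    m = params.image_size
    # frequency axis -> m linear bins
    f_target = np.linspace(params.min_freq, params.max_freq, m)
    spec = np.array(
        [np.interp(f_target, freqs, spec[:, j]) for j in range(spec.shape[1])]
    ).T
    # time axis
    n_frames = spec.shape[1]
    if params.time_stretch or n_frames >= m:
        t_target = np.linspace(0, n_frames - 1, m)
        img = np.array(
            [np.interp(t_target, np.arange(n_frames), spec[i]) for i in range(m)]
        )
    else:
        width = max(1, int(round(m * dur / params.max_dur)))
        t_target = np.linspace(0, n_frames - 1, width)
        block = np.array(
            [np.interp(t_target, np.arange(n_frames), spec[i]) for i in range(m)]
        )
        img = np.full((m, m), params.spec_min_val)
        left = (m - width) // 2
        img[:, left : left + width] = block
    img = (img - params.spec_min_val) / (params.spec_max_val - params.spec_min_val)
    if params.within_syll_normalize and img.max() > 0:
        img = img / img.max()
    return np.clip(img, 0.0, 1.0)


# --------------------------------------------------------------------------
# latent dataset container
# --------------------------------------------------------------------------

@dataclass
class LatentDataset:
    """Per-vocalization latent vectors with cohort ids and timestamps."""

    z: np.ndarray                     # (n, D) latent vectors
    cohort_ids: np.ndarray            # (n,) integer cohort per vocalization
    onsets: np.ndarray | None = None  # (n,) seconds
    days: np.ndarray | None = None    # (n,) integer day index

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.cohort_ids = np.asarray(self.cohort_ids, dtype=int)
        if self.z.ndim != 2 or len(self.cohort_ids) != len(self.z):
            raise ValueError("z must be (n, D) aligned with cohort_ids")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latents must be finite")
        for name in ("onsets", "days"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if len(v) != len(self.z):
                    raise ValueError(f"{name} must align with z")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.z)

    @property
    def n_cohorts(self) -> int:
        return int(self.cohort_ids.max()) + 1 if len(self.cohort_ids) else 0

    def subset(self, mask: np.ndarray) -> "LatentDataset":
        return LatentDataset(
            self.z[mask],
            self.cohort_ids[mask],
            None if self.onsets is None else self.onsets[mask],
            None if self.days is None else self.days[mask],
        )

    def select_dims(self, dims) -> "LatentDataset":
        return LatentDataset(self.z[:, list(dims)], self.cohort_ids, self.onsets, self.days)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("latents", data=self.z.astype(np.float32))
            fh.create_dataset("cohort_ids", data=self.cohort_ids)
            if self.onsets is not None:
                fh.create_dataset("onsets", data=np.asarray(self.onsets, float))
            if self.days is not None:
                fh.create_dataset("days", data=np.asarray(self.days, int))

    @classmethod
    def from_hdf5(cls, path) -> "LatentDataset":
        with h5py.File(path, "r") as fh:
            return cls(
                fh["latents"][()],
                fh["cohort_ids"][()],
                fh["onsets"][()] if "onsets" in fh else None,
                fh["days"][()] if "days" in fh else None,
            )


# --------------------------------------------------------------------------
# VAE
# --------------------------------------------------------------------------

class _Dense:
    """Dense layer with Adam state."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._adam = [np.zeros_like(p) for p in (self.W, self.b, self.W, self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self._gW = self._x.T @ grad
        self._gb = grad.sum(axis=0)
        return grad @ self.W.T

    def step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        mW, mb, vW, vb = self._adam
        for p, g, m, v in ((self.W, self._gW, mW, vW), (self.b, self._gb, mb, vb)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def _relu(x):
    return np.maximum(x, 0.0)


class VAE:
    """Fully-connected variational autoencoder over square images.

    Observation model: x | z ~ Normal(decoder(z), (1/model_precision) I),
    so the per-sample loss is
    ``0.5 * model_precision * ||x - xhat||^2 + KL(q(z|x) || N(0, I))``.
    """

    def __init__(
        self,
        image_size: int = 128,
        latent_dim: int = 32,
        hidden: tuple[int, ...] = (256, 128),
        model_precision: float = 40.0,
        seed: int = 0,
    ):
        self.image_size = image_size
        self.latent_dim = latent_dim
        self.model_precision = float(model_precision)
        self.rng = np.random.default_rng(seed)
        d = image_size * image_size
        dims = (d, *hidden)
        self.enc = [_Dense(dims[i], dims[i + 1], self.rng) for i in range(len(hidden))]
        self.enc_mu = _Dense(dims[-1], latent_dim, self.rng)
        self.enc_lv = _Dense(dims[-1], latent_dim, self.rng)
        rdims = (latent_dim, *hidden[::-1])
        self.dec = [_Dense(rdims[i], rdims[i + 1], self.rng) for i in range(len(hidden))]
        self.dec_out = _Dense(rdims[-1], d, self.rng)
        self._t = 0
        self.trained = False
        self.loss_history: list[float] = []
        self.recon_history: list[float] = []  # mean squared error per epoch

    # ---- forward pieces -------------------------------------------------
    def _encode_forward(self, x: np.ndarray):
        h = x
        acts = []
        for layer in self.enc:
            h = _relu(layer.forward(h))
            acts.append(h)
        return self.enc_mu.forward(h), self.enc_lv.forward(h), acts

    def _decode_forward(self, z: np.ndarray):
        h = z
        acts = []
        for layer in self.dec:
            h = _relu(layer.forward(h))
            acts.append(h)
        return self.dec_out.forward(h), acts

    # ---- public API -----------------------------------------------------
    def train(
        self,
        images: np.ndarray,
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 1e-3,
    ) -> list[float]:
        """Minimize the negative ELBO; returns the per-epoch mean loss."""
        X = self._flatten(images)
        if len(X) < 2:
            raise ValueError("need at least 2 images")
        n = len(X)
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                xb = X[order[start : start + batch_size]]
                losses.append(self._train_step(xb, lr))
            self.loss_history.append(float(np.mean(losses)))
            # deterministic reconstruction error at the posterior mean
            mu, _, _ = self._encode_forward(X)
            xhat, _ = self._decode_forward(mu)
            self.recon_history.append(float(np.mean((xhat - X) ** 2)))
        self.trained = True
        return self.loss_history

    def encode(self, images: np.ndarray) -> np.ndarray:
        """Posterior-mean latents, order preserved."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        mu, _, _ = self._encode_forward(self._flatten(images))
        return mu

    def decode(self, z: np.ndarray) -> np.ndarray:
        xhat, _ = self._decode_forward(np.atleast_2d(z))
        m = self.image_size
        return xhat.reshape(-1, m, m)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(images))

    # ---- internals ------------------------------------------------------
    def _flatten(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        m = self.image_size
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:] != (m, m):
            raise ValueError(f"images must be (n, {m}, {m}), got {images.shape}")
        return images.reshape(len(images), -1)

    def _train_step(self, x: np.ndarray, lr: float) -> float:
        B = len(x)
        lam = self.model_precision
        mu, lv, _ = self._encode_forward(x)
        lv = np.clip(lv, -10.0, 10.0)
        eps = self.rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + std * eps
        xhat, _ = self._decode_forward(z)

        diff = xhat - x
        recon = 0.5 * lam * np.sum(diff * diff) / B
        kl = -0.5 * np.sum(1.0 + lv - mu * mu - np.exp(lv)) / B
        loss = recon + kl

        # backward: decoder
        g = lam * diff / B
        g = self.dec_out.backward(g)
        for layer in reversed(self.dec):
            g = g * (layer._x @ layer.W + layer.b > 0)
            g = layer.backward(g)
        gz = g
        # z = mu + std * eps
        gmu = gz + mu / B
        glv = gz * eps * 0.5 * std + 0.5 * (np.exp(lv) - 1.0) / B
        g = self.enc_mu.backward(gmu) + self.enc_lv.backward(glv)
        for layer in reversed(self.enc):
            g = g * (layer._x @ layer.W + layer.b > 0)
            g = layer.backward(g)

        self._t += 1
        for layer in (*self.enc, self.enc_mu, self.enc_lv, *self.dec, self.dec_out):
            layer.step(lr, self._t)
        return float(loss)


def train_vae(
    images: np.ndarray,
    epochs: int = 50,
    model_precision: float = 40.0,
    latent_dim: int = 32,
    seed: int = 0,
    image_size: int = 128,
    hidden: tuple[int, ...] = (256, 128),
    batch_size: int = 32,
    lr: float = 1e-3,
) -> VAE:
    """Train a VAE on a stack of square spectrogram images."""
    model = VAE(
        image_size=image_size,
        latent_dim=latent_dim,
        hidden=hidden,
        model_precision=model_precision,
        seed=seed,
    )
    model.train(images, epochs=epochs, batch_size=batch_size, lr=lr)
    return model


def encode(
    model: VAE,
    images: np.ndarray,
    cohort_ids: np.ndarray | None = None,
    onsets: np.ndarray | None = None,
    days: np.ndarray | None = None,
) -> LatentDataset:
    """Encode images to a :class:`LatentDataset` of posterior means."""
    z = model.encode(images)
    if cohort_ids is None:
        cohort_ids = np.zeros(len(z), dtype=int)
    return LatentDataset(z, cohort_ids, onsets, days)


# --------------------------------------------------------------------------
# latent selection and outlier flagging
# --------------------------------------------------------------------------

def select_top_latents(
    latents: np.ndarray | LatentDataset, variance_target: float = 0.995
) -> np.ndarray:
    """Smallest top-variance latent subset reaching the variance target.

    Dimensions are sorted by decreasing variance; the returned index
    array is the shortest prefix whose cumulative variance fraction is
    >= ``variance_target``.
    """
    z = latents.z if isinstance(latents, LatentDataset) else np.asarray(latents, float)
    if len(z) < 2:
        raise ValueError("need at least 2 samples")
    var = z.var(axis=0)
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    order = np.argsort(var)[::-1]
    frac = np.cumsum(var[order]) / total
    k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
    return order[:k]


def flag_outliers(z: np.ndarray, max_dist: float = 6.0) -> np.ndarray:
    """Flag latents by Mahalanobis distance from the global mean.

    Uses the diagonal of the sample covariance; returns a boolean mask,
    True where distance > ``max_dist``.  Flagged items are meant to be
    excluded from statistics, not deleted.
    """
    z = np.asarray(z, dtype=float)
    mu = z.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    dist = np.sqrt(np.sum(((z - mu) / sd) ** 2, axis=1))
    return dist > max_dist
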