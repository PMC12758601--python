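"""Discrete vocabulary learning over fragment features.

A vector-quantized autoencoder maps each 74-d fragment vector through an
encoder to a latent ``z_e``, snaps it to the nearest row ``e_k`` of a
learnable codebook (the token is the row index k), and decodes the selected
code back to feature space. Training minimizes

    L = L_recons + L_codebook + beta * L_commit

where the codebook term ``||sg[z_e] - z_q||^2`` moves only code vectors, the
commitment term ``||z_e - sg[z_q]||^2`` moves only the encoder, and the
straight-through estimator carries reconstruction gradients past the
non-differentiable quantization. Two encoders are provided — a multi-head
self-attention encoder over three slot tokens (one per feature block) and an
MLP ablation — plus a k-means vocabulary baseline and a codebook-utilization
diagnostic for collapse monitoring.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, kmeans_plusplus

from ._autodiff import Tensor, straight_through
from .constants import DEFAULT_BETA, DEFAULT_VOCAB_SIZE, N_FEATURES
from .features import Standardization


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class Codebook:
    """The vocabulary: K learnable code vectors of dimension d."""

    vectors: np.ndarray                       # K x d
    feature_standardization: Standardization | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 2:
            raise ValueError("codebook must be a K x d matrix with K >= 2")

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class QuantizationResult:
    z_e: np.ndarray
    token: int
    z_q: np.ndarray
    distance: float


@dataclass(frozen=True)
class LossBreakdown:
    recons: float
    codebook: float
    commit: float
    beta: float

    @property
    def total(self) -> float:
        return self.recons + self.codebook + self.beta * self.commit


@dataclass
class TrainConfig:
    """Hyper-parameters of vocabulary training; every run is seeded."""

    K: int = DEFAULT_VOCAB_SIZE
    d: int = 64
    beta: float = DEFAULT_BETA
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 30
    seed: int = 0
    encoder_kind: str = "attention"     # attention | mlp
    recon_loss: str = "mse"             # mse | kl
    attention_heads: int = 4
    n_slots: int = 3
    hidden: int = 64
    codebook_init: str = "kmeans"       # kmeans | kmeans++ | normal
    #: reconstruction-only epochs before the codebook is initialized; lets
    #: the encoder spread the data in latent space so initial codes land on
    #: real modes instead of on a random encoder's collapsed image
    warmup_epochs: int = 3

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.encoder_kind not in ("attention", "mlp"):
            raise ValueError(f"unknown encoder_kind {self.encoder_kind!r}")
        if self.recon_loss not in ("mse", "kl"):
            raise ValueError(f"unknown recon_loss {self.recon_loss!r}")
        for name in ("K", "d", "learning_rate", "batch_size", "epochs",
                     "attention_heads", "n_slots", "hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# quantization and losses
# ---------------------------------------------------------------------------

def quantize(z_e: np.ndarray, codebook: Codebook) -> QuantizationResult:
    """Nearest-code lookup: k = argmin_j ||z_e - e_j||, lowest index on ties."""
    z_e = np.asarray(z_e, dtype=float)
    if z_e.shape != (codebook.d,):
        raise ValueError(f"latent has shape {z_e.shape}, expected ({codebook.d},)")
    dists = np.linalg.norm(codebook.vectors - z_e, axis=1)
    token = int(np.argmin(dists))   # np.argmin returns the first minimum
    return QuantizationResult(z_e=z_e, token=token,
                              z_q=codebook.vectors[token].copy(),
                              distance=float(dists[token]))


def quantize_batch(z_e: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Token ids for a batch of latents (same tie-break as quantize)."""
    d2 = cdist(np.atleast_2d(z_e), codebook.vectors, "sqeuclidean")
    return d2.argmin(axis=1)


def _distribution_view(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax over the feature axis: the distribution used by the KL loss."""
    z = v - v.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def vq_losses(x: np.ndarray, x_hat: np.ndarray, z_e: np.ndarray,
              z_q: np.ndarray, beta: float = DEFAULT_BETA,
              recon_loss: str = "kl") -> LossBreakdown:
    """Evaluate the three loss terms on (batches of) arrays.

    ``recons`` is KL(p(x) || q(x_hat)) between softmax distribution views of
    input and reconstruction (or mean squared error when configured);
    ``codebook`` and ``commit`` are mean squared L2 distances between latents
    and their selected codes. Gradient routing (stop-gradients and the
    straight-through estimator) is a property of the training graph, not of
    this numeric evaluation.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x, x_hat = np.atleast_2d(x), np.atleast_2d(x_hat)
    z_e, z_q = np.atleast_2d(z_e), np.atleast_2d(z_q)
    if recon_loss == "kl":
        p = _distribution_view(x)
        q = _distribution_view(x_hat)
        recons = float(np.mean(np.sum(p * (np.log(p + 1e-30) - np.log(q + 1e-30)),
                                      axis=-1)))
    elif recon_loss == "mse":
        recons = float(np.mean((x - x_hat) ** 2))
    else:
        raise ValueError(f"unknown recon_loss {recon_loss!r}")
    codebook = float(np.mean(np.sum((z_e - z_q) ** 2, axis=-1)))
    commit = codebook  # numerically identical; they differ only in gradients
    return LossBreakdown(recons=max(recons, 0.0), codebook=codebook,
                         commit=commit, beta=beta)


def codebook_utilization(tokens, K: int) -> float:
    """Fraction of the K code vectors assigned at least once."""
    tokens = np.asarray(tokens, dtype=int)
    if tokens.size and (tokens.min() < 0 or tokens.max() >= K):
        raise ValueError("token id out of range [0, K)")
    return len(np.unique(tokens)) / K


# ---------------------------------------------------------------------------
# encoder / decoder networks
# ---------------------------------------------------------------------------

def _linear_params(rng, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
    w = Tensor(rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)),
               requires_grad=True)
    b = Tensor(np.zeros(n_out), requires_grad=True)
    return w, b


class _MLPEncoder:
    """Two hidden ReLU layers: 74 -> hidden -> hidden -> d."""

    def __init__(self, rng, d: int, hidden: int):
        self.w1, self.b1 = _linear_params(rng, N_FEATURES, hidden)
        self.w2, self.b2 = _linear_params(rng, hidden, hidden)
        self.w3, self.b3 = _linear_params(rng, hidden, d)

    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def __call__(self, x: Tensor) -> Tensor:
        h = (x @ self.w1 + self.b1).relu()
        h = (h @ self.w2 + self.b2).relu()
        return h @ self.w3 + self.b3


class _AttentionEncoder:
    """Slot-attention encoder.

    The 74-d input is linearly projected into T slot tokens of width
    ``hidden`` (one slot per feature block by default), multi-head
    self-attention mixes the slots, and the mean-pooled result is projected
    to the code dimension. Attention lets the encoder weight the composition,
    conservation and geometry blocks against each other per fragment, which
    keeps more of the codebook in play during training.
    """

    def __init__(self, rng, d: int, hidden: int, heads: int, n_slots: int):
        if hidden % heads:
            raise ValueError("hidden must be divisible by attention heads")
        self.h, self.nh, self.T = hidden, heads, n_slots
        self.w_slot, self.b_slot = _linear_params(rng, N_FEATURES,
                                                  n_slots * hidden)
        self.wq, _ = _linear_params(rng, hidden, hidden)
        self.wk, _ = _linear_params(rng, hidden, hidden)
        self.wv, _ = _linear_params(rng, hidden, hidden)
        self.wo, self.bo = _linear_params(rng, hidden, hidden)
        self.w_out, self.b_out = _linear_params(rng, hidden, d)

    def params(self) -> list[Tensor]:
        return [self.w_slot, self.b_slot, self.wq, self.wk, self.wv,
                self.wo, self.bo, self.w_out, self.b_out]

    def __call__(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        h, nh, T = self.h, self.nh, self.T
        dk = h // nh
        slots = (x @ self.w_slot + self.b_slot).reshape(B, T, h)

        def heads(t: Tensor) -> Tensor:
            # (B,T,h) -> (B,nh,T,dk)
            return t.reshape(B, T, nh, dk).transpose((0, 2, 1, 3))

        q, k, v = heads(slots @ self.wq), heads(slots @ self.wk), heads(slots @ self.wv)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dk))
        attn = scores.softmax(axis=-1)
        mixed = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, T, h)
        out = mixed @ self.wo + self.bo + slots          # residual
        pooled = out.mean(axis=1)
        return pooled @ self.w_out + self.b_out


class _Decoder:
    """d -> hidden -> 74 with one ReLU layer."""

    def __init__(self, rng, d: int, hidden: int):
        self.w1, self.b1 = _linear_params(rng, d, hidden)
        self.w2, self.b2 = _linear_params(rng, hidden, N_FEATURES)

    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, z: Tensor) -> Tensor:
        return (z @ self.w1 + self.b1).relu() @ self.w2 + self.b2


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# the VQ-VAE model
# ---------------------------------------------------------------------------

class VQVAE:
    """Encoder + codebook + decoder operating on standardized features."""

    def __init__(self, config: TrainConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        if config.encoder_kind == "attention":
            self.encoder = _AttentionEncoder(rng, config.d, config.hidden,
                                             config.attention_heads,
                                             config.n_slots)
        else:
            self.encoder = _MLPEncoder(rng, config.d, config.hidden)
        self.decoder = _Decoder(rng, config.d, config.hidden)
        self.codes = Tensor(rng.normal(0.0, 1.0, size=(config.K, config.d)),
                            requires_grad=True)
        self._rng = rng
        self._codes_initialized = config.codebook_init == "normal"

    # -- forward pieces ---------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        """Deterministic latent for standardized input(s); returns d-vector(s)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        if x.shape[-1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES}-d input, got {x.shape}")
        z = self.encoder(Tensor(np.atleast_2d(x))).data
        return z[0] if single else z

    def _init_codes_from_batch(self, z: np.ndarray) -> None:
        """k-means++ seeding of the codebook on the first batch's latents;
        mitigates dead codes at the start of training."""
        K = self.config.K
        rs = int(self._rng.integers(2 ** 31))
        if z.shape[0] >= 4 * K:
            # enough points: refine the seeding with a short k-means run
            km = KMeans(n_clusters=K, random_state=rs, n_init=10).fit(z)
            self.codes.data = km.cluster_centers_.astype(float)
        elif z.shape[0] >= K:
            centers, _ = kmeans_plusplus(z, n_clusters=K, random_state=rs)
            self.codes.data = centers.astype(float)
        else:  # fewer points than codes: reuse points, jitter the rest
            idx = self._rng.integers(0, z.shape[0], size=K)
            self.codes.data = z[idx] + self._rng.normal(0, 1e-3, (K, z.shape[1]))
        self._codes_initialized = True

    def reseed_dead_codes(self, z: np.ndarray, tokens: np.ndarray,
                          min_count: int = 1) -> int:
        """Move dead or starving codes onto poorly quantized latents.

        Codes assigned fewer than ``min_count`` latents are re-seeded at
        latents sampled with probability proportional to their squared
        quantization error (k-means++ style), which targets clusters that
        currently share a code. Returns how many codes moved.
        """
        counts = np.bincount(tokens, minlength=self.config.K)
        weak = np.flatnonzero(counts < min_count)
        if weak.size == 0:
            return 0
        d2 = np.sum((z - self.codes.data[tokens]) ** 2, axis=1)
        p = d2 / d2.sum() if d2.sum() > 0 else None
        picks = self._rng.choice(z.shape[0], size=weak.size, replace=False, p=p)
        self.codes.data[weak] = z[picks] + self._rng.normal(
            0, 1e-4, (weak.size, z.shape[1]))
        return int(weak.size)

    def loss_graph(self, x_batch: np.ndarray) -> dict[str, Tensor]:
        """Build the training graph; returns the loss terms as tensors."""
        cfg = self.config
        x = Tensor(np.atleast_2d(np.asarray(x_batch, dtype=float)))
        z_e = self.encoder(x)
        if not self._codes_initialized:
            self._init_codes_from_batch(z_e.data)
        tokens = quantize_batch(z_e.data, Codebook(self.codes.data))
        z_q = self.codes.take_rows(tokens)
        x_hat = self.decoder(straight_through(z_e, z_q))
        if cfg.recon_loss == "mse":
            recons = (x_hat - x).square().mean()
        else:
            p = x.softmax(axis=-1).detach()
            logp = x.log_softmax(axis=-1).detach()
            logq = x_hat.log_softmax(axis=-1)
            recons = (p * (logp - logq)).sum(axis=-1).mean()
        codebook = (z_e.detach() - z_q).square().sum(axis=-1).mean()
        commit = (z_e - z_q.detach()).square().sum(axis=-1).mean()
        total = recons + codebook + cfg.beta * commit
        return {"recons": recons, "codebook": codebook, "commit": commit,
                "total": total, "tokens": tokens}

    def parameters(self) -> list[Tensor]:
        return self.encoder.params() + self.decoder.params() + [self.codes]

    def tokenize_features(self, features: np.ndarray) -> np.ndarray:
        """Token ids for (standardized) feature rows."""
        z = self.encode(np.atleast_2d(features))
        return quantize_batch(z, Codebook(self.codes.data))


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.epochs.append(kw)


def train_vqvae(features: np.ndarray, config: TrainConfig,
                standardization: Standardization | None = None,
                ) -> tuple[Codebook, VQVAE, TrainingLog]:
    """Minibatch training of the VQ-VAE vocabulary on fragment features.

    Features are z-scored with ``standardization`` (fitted here if absent);
    the fitted parameters are stored on the returned codebook so tokenization
    always reuses the training-time scaling. Fully reproducible from
    ``config.seed``.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ValueError(f"features must be m x {N_FEATURES}")
    if not np.isfinite(features).all():
        raise FloatingPointError("non-finite values in the feature matrix")
    if standardization is None:
        standardization = Standardization.fit(features)
    z = standardization.apply(features)
    model = VQVAE(config)
    opt = _Adam(model.parameters(), config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    log = TrainingLog()
    m = z.shape[0]

    # reconstruction-only warmup: train encoder/decoder as a plain
    # autoencoder, then place the initial codebook by k-means over the
    # corpus latents. A randomly initialized encoder can map distinct
    # feature modes on top of each other; codes seeded there stay entangled
    # for the rest of training, so the codebook is initialized only once the
    # latent space is informative.
    warmup = min(config.warmup_epochs, max(config.epochs - 1, 0))
    if config.codebook_init == "normal":
        warmup = 0
    for _ in range(warmup):
        order = rng.permutation(m)
        for lo in range(0, m, config.batch_size):
            x = Tensor(z[order[lo:lo + config.batch_size]])
            x_hat = model.decoder(model.encoder(x))
            if config.recon_loss == "mse":
                loss = (x_hat - x).square().mean()
            else:
                p = x.softmax(axis=-1).detach()
                logp = x.log_softmax(axis=-1).detach()
                loss = (p * (logp - x_hat.log_softmax(axis=-1))).sum(axis=-1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    if warmup and not model._codes_initialized:
        sub = z if m <= 8192 else z[rng.choice(m, 8192, replace=False)]
        model._init_codes_from_batch(model.encode(sub))

    for epoch in range(warmup, config.epochs):
        order = rng.permutation(m)
        sums = {"recons": 0.0, "codebook": 0.0, "commit": 0.0, "total": 0.0}
        tokens_seen: list[np.ndarray] = []
        n_batches = 0
        for lo in range(0, m, config.batch_size):
            batch = z[order[lo:lo + config.batch_size]]
            terms = model.loss_graph(batch)
            total = terms["total"]
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"recons={terms['recons'].data}, "
                    f"codebook={terms['codebook'].data}, "
                    f"commit={terms['commit'].data}")
            opt.zero_grad()
            total.backward()
            opt.step()
            for k in sums:
                sums[k] += float(terms[k].data)
            tokens_seen.append(terms["tokens"])
            n_batches += 1
        tokens = np.concatenate(tokens_seen)
        n_reseeded = 0
        if epoch < int(0.8 * config.epochs):
            # revive dead/starving codes (collapse control); off near the end
            # so the codebook can settle
            sub = z if m <= 4096 else z[rng.choice(m, 4096, replace=False)]
            lat = model.encode(sub)
            min_count = max(1, int(0.1 * sub.shape[0] / config.K))
            n_reseeded = model.reseed_dead_codes(
                lat, quantize_batch(lat, Codebook(model.codes.data)),
                min_count=min_count)
        log.append(epoch=epoch,
                   recons=sums["recons"] / n_batches,
                   codebook=sums["codebook"] / n_batches,
                   commit=sums["commit"] / n_batches,
                   total=sums["total"] / n_batches,
                   utilization=codebook_utilization(tokens, config.K),
                   reseeded=n_reseeded)
    codebook = Codebook(model.codes.data.copy(),
                        feature_standardization=standardization)
    return codebook, model, log


# ---------------------------------------------------------------------------
# k-means vocabulary baseline
# ---------------------------------------------------------------------------

def train_kmeans_vocab(features: np.ndarray, K: int, seed: int,
                       standardization: Standardization | None = None,
                       ) -> Codebook:
    """K centroids in standardized 74-d feature space (no encoder).

    Tokenization against this vocabulary is nearest-centroid with the same
    lowest-index tie-break as :func:`quantize`.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < K:
        raise ValueError(f"need at least K={K} samples, got {features.shape[0]}")
    if standardization is None:
        standardization = Standardization.fit(features)
    z = standardization.apply(features)
    # generous restarts: K-means is prone to cluster-splitting local optima
    km = KMeans(n_clusters=K, random_state=seed, n_init=30).fit(z)
    return Codebook(km.cluster_centers_.astype(float),
                    feature_standardization=standardization)


# ---------------------------------------------------------------------------
# vocabulary artifact I/O
# ---------------------------------------------------------------------------

def _params_to_arrays(obj) -> dict[str, np.ndarray]:
    return {k: t.data for k, t in vars(obj).items() if isinstance(t, Tensor)}


def save_vocabulary(path: str | Path, codebook: Codebook,
                    model: VQVAE | None = None) -> str:
    """Write the vocabulary artifact directory; returns its manifest hash."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "codebook.npy", codebook.vectors)
    manifest = {
        "K": codebook.K,
        "d": codebook.d,
        "kind": "vqvae" if model is not None else "kmeans",
        "standardization": (codebook.feature_standardization.to_dict()
                            if codebook.feature_standardization else None),
        "config": asdict(model.config) if model is not None else None,
        "numpy_version": np.__version__,
    }
    if model is not None:
        np.savez(path / "encoder.npz", **_params_to_arrays(model.encoder))
        np.savez(path / "decoder.npz", **_params_to_arrays(model.decoder))
    blob = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest["manifest_hash"]


@dataclass
class Vocabulary:
    """A loaded vocabulary artifact ready for tokenization."""

    codebook: Codebook
    manifest: dict
    model: VQVAE | None = None

    @property
    def manifest_hash(self) -> str:
        return self.manifest["manifest_hash"]

    @property
    def K(self) -> int:
        return self.codebook.K

    def tokenize_features(self, features: np.ndarray) -> np.ndarray:
        """Standardize, encode (if a VQ-VAE), and quantize feature rows."""
        feats = np.atleast_2d(np.asarray(features, dtype=float))
        if feats.shape[1] != N_FEATURES:
            raise ValueError(f"features must be m x {N_FEATURES}")
        std = self.codebook.feature_standardization
        z = std.apply(feats) if std is not None else feats
        if self.model is not None:
            z = self.model.encode(z)
        return quantize_batch(z, self.codebook)


def load_vocabulary(path: str | Path) -> Vocabulary:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    std = (Standardization.from_dict(manifest["standardization"])
           if manifest.get("standardization") else None)
    codebook = Codebook(np.load(path / "codebook.npy"),
                        feature_standardization=std)
    model = None
    if manifest["kind"] == "vqvae":
        model = VQVAE(TrainConfig(**manifest["config"]))
        enc = np.load(path / "encoder.npz")
        for k, arr in enc.items():
            getattr(model.encoder, k).data = arr.astype(float)
        dec = np.load(path / "decoder.npz")
        for k, arr in dec.items():
            getattr(model.decoder, k).data = arr.astype(float)
        model.codes.data = codebook.vectors.copy()
        model._codes_initialized = True
    return Vocabulary(codebook=codebook, manifest=manifest, model=model)
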