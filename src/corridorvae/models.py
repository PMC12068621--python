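"""Capacity-constrained beta-VAE with optional classifier heads.

The model is a variational autoencoder over binary 13x13 images with a
5-dimensional diagonal-Gaussian latent and a standard-normal prior.  The
training objective is the capacity-controlled form of the beta-VAE loss,

    L = NLL(x | z) + gamma * | KL(q(z|x) || p(z)) - C | + sum_i CE_i(z, y_i),

where NLL is the Bernoulli negative log-likelihood summed over the 169
pixels, C is an information capacity (in nats) annealed from 0 to a target
Cmax during training, gamma penalises deviations of the posterior KL from C,
and each optional classifier head i adds a softmax cross-entropy on its task
labels.  Classifier heads read the *sampled* latent z during training and
the posterior mean at evaluation time.

All forward and backward passes are explicit numpy; the gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .nn import Adam, Dense, LeakyReLU, Param, Sequential, sigmoid, log_softmax, softmax

EPS_PROB = 1e-7  # decoder probabilities are clamped to [EPS_PROB, 1 - EPS_PROB]


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier head on the latent vector.

    The linear head is two stacked affine layers with no activation (an
    affine map overall, so its decision boundary in latent space is linear);
    the nonlinear head interposes a leaky-ReLU.
    """

    kind: str = "linear"  # "linear" | "nonlinear"
    n_classes: int = 2
    hidden_units: int | None = None  # default: 1024 linear, 1500 nonlinear

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "nonlinear"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.n_classes < 2:
            raise ValueError("a classifier needs at least 2 classes")

    @property
    def hidden(self) -> int:
        if self.hidden_units is not None:
            return self.hidden_units
        return 1024 if self.kind == "linear" else 1500


@dataclass(frozen=True)
class ModelSpec:
    """Architecture parameters of the VAE and its heads."""

    latent_dim: int = 5
    input_shape: tuple[int, int] = (13, 13)
    encoder_hidden: tuple[int, ...] = (128, 64)
    decoder_hidden: tuple[int, ...] = (64, 128)
    leaky_alpha: float = 0.01
    classifier_heads: tuple[ClassifierSpec, ...] = ()

    @property
    def n_pixels(self) -> int:
        return self.input_shape[0] * self.input_shape[1]


@dataclass
class PosteriorParams:
    """Diagonal-Gaussian posterior q(z|x): mean and log-variance, (N, d)."""

    mu: np.ndarray
    logvar: np.ndarray


@dataclass
class LossBreakdown:
    reconstruction: float  # batch-mean summed Bernoulli NLL, nats
    kl: float  # batch-mean KL, nats
    capacity_term: float  # gamma * |KL - C|
    classifier_losses: list[float] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.reconstruction + self.capacity_term + sum(self.classifier_losses)


class CorridorVAE:
    """Encoder/decoder/classifier stack with explicit backpropagation."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        a = spec.leaky_alpha
        d = spec.latent_dim

        self.encoder = nn.mlp([spec.n_pixels, *spec.encoder_hidden], rng,
                              alpha=a, final_activation=True)
        trunk_out = spec.encoder_hidden[-1]
        self.mu_head = Dense(trunk_out, d, rng)
        self.logvar_head = Dense(trunk_out, d, rng)
        self.decoder = nn.mlp([d, *spec.decoder_hidden, spec.n_pixels], rng, alpha=a)

        self.heads: list[Sequential] = []
        for hs in spec.classifier_heads:
            if hs.kind == "linear":
                head = Sequential(Dense(d, hs.hidden, rng),
                                  Dense(hs.hidden, hs.n_classes, rng))
            else:
                head = Sequential(Dense(d, hs.hidden, rng), LeakyReLU(a),
                                  Dense(hs.hidden, hs.n_classes, rng))
            self.heads.append(head)

    # -- parameter groups ---------------------------------------------------

    def vae_params(self) -> list[Param]:
        return (self.encoder.params() + self.mu_head.params()
                + self.logvar_head.params() + self.decoder.params())

    def head_params(self) -> list[Param]:
        return [p for h in self.heads for p in h.params()]

    def params(self) -> list[Param]:
        return self.vae_params() + self.head_params()

    # -- forward passes -----------------------------------------------------

    def _flatten(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2 and x.shape == self.spec.input_shape:
            x = x[None]
        if x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
        if x.ndim != 2 or x.shape[1] != self.spec.n_pixels:
            raise ValueError(f"expected 13x13 images, got shape {x.shape}")
        return x

    def encode(self, x: np.ndarray) -> PosteriorParams:
        """Posterior parameters for a batch of images (deterministic)."""
        h = self.encoder.forward(self._flatten(x))
        return PosteriorParams(self.mu_head.forward(h), self.logvar_head.forward(h))

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Pixel probabilities in (0, 1), shape (N, 13, 13)."""
        z = np.atleast_2d(np.asarray(z, dtype=nn.DTYPE))
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(f"latent vectors must have dim {self.spec.latent_dim}")
        p = sigmoid(self.decoder.forward(z))
        p = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
        return p.reshape(z.shape[0], *self.spec.input_shape)

    def classify(self, z: np.ndarray, head: int = 0) -> np.ndarray:
        """Class logits of head ``head`` for latent vectors ``z``."""
        z = np.atleast_2d(np.asarray(z, dtype=nn.DTYPE))
        return self.heads[head].forward(z)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction through the posterior mean."""
        return self.decode(self.encode(x).mu)

    # -- persistence ----------------------------------------------------------

    def _named_params(self) -> dict[str, Param]:
        named = {}
        groups = {"enc": self.encoder.params(),
                  "mu": self.mu_head.params(),
                  "lv": self.logvar_head.params(),
                  "dec": self.decoder.params()}
        for i, h in enumerate(self.heads):
            groups[f"head{i}"] = h.params()
        for g, ps in groups.items():
            for j, p in enumerate(ps):
                named[f"{g}.{j}"] = p
        return named

    def save(self, path: str) -> None:
        """Write weights (npz) plus a YAML sidecar with the architecture."""
        np.savez_compressed(path, **{k: p.value for k, p in self._named_params().items()})
        sidecar = {
            "latent_dim": self.spec.latent_dim,
            "input_shape": list(self.spec.input_shape),
            "encoder_hidden": list(self.spec.encoder_hidden),
            "decoder_hidden": list(self.spec.decoder_hidden),
            "leaky_alpha": self.spec.leaky_alpha,
            "heads": [{"kind": h.kind, "n_classes": h.n_classes,
                       "hidden_units": h.hidden}
                      for h in self.spec.classifier_heads],
        }
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh)

    @classmethod
    def load(cls, path: str) -> "CorridorVAE":
        with open(str(path) + ".yaml") as fh:
            sc = yaml.safe_load(fh)
        spec = ModelSpec(
            latent_dim=sc["latent_dim"],
            input_shape=tuple(sc.get("input_shape", (13, 13))),
            encoder_hidden=tuple(sc["encoder_hidden"]),
            decoder_hidden=tuple(sc["decoder_hidden"]),
            leaky_alpha=sc["leaky_alpha"],
            classifier_heads=tuple(ClassifierSpec(h["kind"], h["n_classes"],
                                                  h["hidden_units"])
                                   for h in sc["heads"]),
        )
        model = cls(spec, seed=0)
        with np.load(path if str(path).endswith(".npz") else str(path)) as z:
            for k, p in model._named_params().items():
                p.value[...] = z[k]
        return model


# ---------------------------------------------------------------------------
# Loss pieces (also usable standalone)


def sample_latent(params: PosteriorParams, rng: np.random.Generator) -> np.ndarray:
    """Reparameterised sample z = mu + exp(logvar/2) * eps."""
    eps = rng.standard_normal(params.mu.shape).astype(params.mu.dtype, copy=False)
    return params.mu + np.exp(0.5 * params.logvar) * eps


def kl_divergence(params: PosteriorParams) -> np.ndarray:
    """KL(q(z|x) || N(0, I)) per sample, summed over latent dimensions (nats)."""
    mu, lv = np.atleast_2d(params.mu), np.atleast_2d(params.logvar)
    return 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv, axis=1)


def kl_per_dimension(params: PosteriorParams) -> np.ndarray:
    """KL contribution of each latent dimension per sample, (N, d)."""
    mu, lv = np.atleast_2d(params.mu), np.atleast_2d(params.logvar)
    return 0.5 * (mu**2 + np.exp(lv) - 1.0 - lv)


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray,
                        reduction: str = "sum") -> np.ndarray:
    """Negative Bernoulli log-likelihood of binary pixels under probabilities.

    ``reduction="sum"`` sums over the 169 pixels (the training form, nats per
    image); ``"mean"`` is the per-pixel mean used for reporting.  Returns one
    value per image.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(x_hat, dtype=float)
    if x.shape != p.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs x_hat {p.shape}")
    if x.ndim == 3:  # batch of images
        x, p = x.reshape(x.shape[0], -1), p.reshape(p.shape[0], -1)
    elif x.ndim == 2 and x.shape[0] == x.shape[1]:  # single square image
        x, p = x.reshape(1, -1), p.reshape(1, -1)
    # else: already a flat (N, n_pixels) batch
    if np.any((p <= 0.0) | (p >= 1.0)):
        p = np.clip(p, EPS_PROB, 1.0 - EPS_PROB)
    nll = -(x * np.log(p) + (1.0 - x) * np.log1p(-p))
    return nll.sum(axis=1) if reduction == "sum" else nll.mean(axis=1)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Batch-mean softmax cross-entropy, nats."""
    ls = log_softmax(np.atleast_2d(logits))
    return float(-ls[np.arange(len(ls)), np.asarray(labels, dtype=int)].mean())


def capacity_term(kl_mean: float, gamma: float, c: float) -> float:
    return gamma * abs(kl_mean - c)


# ---------------------------------------------------------------------------
# Joint forward + backward training step


def training_step(model: CorridorVAE, x: np.ndarray,
                  labels: list[np.ndarray] | None,
                  gamma: float, c: float,
                  rng: np.random.Generator,
                  compute_grads: bool = True) -> LossBreakdown:
    """One forward/backward pass of the full objective on a mini-batch.

    Accumulates gradients into all parameters (VAE and heads).  ``labels``
    holds one integer label array per configured head (None for a pure VAE).
    The batch reduction of every term is the mean.
    """
    X = model._flatten(x)
    B = X.shape[0]
    labels = labels or []
    if len(labels) != len(model.heads):
        raise ValueError(f"model has {len(model.heads)} heads but "
                         f"{len(labels)} label arrays were supplied")

    h = model.encoder.forward(X)
    mu = model.mu_head.forward(h)
    lv = model.logvar_head.forward(h)
    eps = rng.standard_normal(mu.shape).astype(mu.dtype, copy=False)
    std = np.exp(0.5 * lv)
    z = mu + std * eps

    logits_px = model.decoder.forward(z)
    p = np.clip(sigmoid(logits_px), EPS_PROB, 1.0 - EPS_PROB)
    recon = float(-(X * np.log(p) + (1.0 - X) * np.log1p(-p)).sum(axis=1).mean())

    kl_i = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv, axis=1)
    kl_mean = float(kl_i.mean())
    cap = capacity_term(kl_mean, gamma, c)

    head_logits = [model.heads[i].forward(z) for i in range(len(model.heads))]
    ces = [cross_entropy(hl, y) for hl, y in zip(head_logits, labels)]

    out = LossBreakdown(recon, kl_mean, cap, ces)
    if not compute_grads:
        return out

    # backward: reconstruction
    dlogits = (sigmoid(logits_px) - X) / B
    dz = model.decoder.backward(dlogits)
    # heads
    for hl, y, head in zip(head_logits, labels, model.heads):
        sm = softmax(hl)
        sm[np.arange(B), np.asarray(y, dtype=int)] -= 1.0
        dz += head.backward(sm / B)
    # capacity term through the batch-mean KL
    s = gamma * np.sign(kl_mean - c)
    dmu = dz + s * mu / B
    dlv = dz * 0.5 * std * eps + s * 0.5 * (np.exp(lv) - 1.0) / B
    dh = model.mu_head.backward(dmu) + model.logvar_head.backward(dlv)
    model.encoder.backward(dh)
    return out


def classifier_step(model: CorridorVAE, x: np.ndarray, y: np.ndarray,
                    head: int, rng: np.random.Generator) -> float:
    """Cross-entropy step updating only one head (frozen encoder/decoder).

    Used by the sequential (frozen-VAE) and transfer regimes: the latent is
    sampled through the frozen encoder and gradients stop at the head input.
    """
    params = model.encode(x)
    z = sample_latent(params, rng)
    logits = model.heads[head].forward(z)
    ce = cross_entropy(logits, y)
    sm = softmax(logits)
    sm[np.arange(len(z)), np.asarray(y, dtype=int)] -= 1.0
    model.heads[head].backward(sm / len(z))
    return ce
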