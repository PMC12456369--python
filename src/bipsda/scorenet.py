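"""Learned score models: a small fully-connected network trained with
denoising score matching, plus its Adam training loop.

The network parameterizes the noisy-prior score directly as a vector field
s_theta(m, sigma): the noise level is appended to the input vector and
re-appended to the hidden state after the fourth hidden layer. Training
minimizes the standard denoising score-matching objective

    E_{m0, z, t} w(t) || s_theta(m0 + sigma(t) z, sigma(t)) + z / sigma(t) ||^2

with w(t) = sigma(t)^2, i.e. the per-sample residual ||sigma s + z||^2, and
t drawn uniformly on [Tmin, T]. Everything is plain numpy with hand-written
backpropagation.

Learned scores are an approximation-error study tool here: the denoising
covariance (Tweedie-Correlated variant) is never built from a learned score,
because the Jacobian of a learned score is not a reliable covariance
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScoreTrainConfig", "MLPScore", "train_score_model"]


@dataclass
class ScoreTrainConfig:
    n_train: int = 80_000
    width: int = 512
    n_hidden: int = 6
    reinject_after: int = 4  # hidden layer after which sigma is re-appended
    lr: float = 1e-5
    batch_size: int = 8000
    n_iters: int = 50_000
    t_min: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("n_train", "width", "n_hidden", "lr", "batch_size", "n_iters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class MLPScore:
    """Fully-connected score model with tanh activations.

    Callable as ``score(m, sigma)`` with ``m`` of shape ``(n, D)`` or
    ``(D,)`` and scalar ``sigma``; the ``analytic`` flag is False so the
    annealing loop refuses to build Tweedie covariances from it.
    """

    analytic = False

    def __init__(self, dim: int, cfg: ScoreTrainConfig, rng: np.random.Generator):
        self.dim = dim
        self.cfg = cfg
        sizes = []
        fan_in = dim + 1
        for layer in range(cfg.n_hidden):
            sizes.append((fan_in, cfg.width))
            fan_in = cfg.width
            if layer + 1 == cfg.reinject_after and cfg.n_hidden > cfg.reinject_after:
                fan_in += 1
        sizes.append((fan_in, dim))
        self.weights = [
            rng.standard_normal(s) * np.sqrt(1.0 / s[0]) for s in sizes
        ]
        self.biases = [np.zeros(s[1]) for s in sizes]

    # -- forward / backward ------------------------------------------------
    def _forward(self, m: np.ndarray, sigma_col: np.ndarray):
        cfg = self.cfg
        h = np.concatenate([m, sigma_col], axis=1)
        cache = []
        for layer in range(cfg.n_hidden):
            a = h @ self.weights[layer] + self.biases[layer]
            t = np.tanh(a)
            cache.append((h, t))
            h = t
            if layer + 1 == cfg.reinject_after and cfg.n_hidden > cfg.reinject_after:
                h = np.concatenate([h, sigma_col], axis=1)
        cache.append((h, None))
        out = h @ self.weights[-1] + self.biases[-1]
        return out, cache

    def _backward(self, d_out: np.ndarray, cache):
        cfg = self.cfg
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        h_last, _ = cache[-1]
        grads_w[-1] = h_last.T @ d_out
        grads_b[-1] = d_out.sum(axis=0)
        dh = d_out @ self.weights[-1].T
        for layer in range(cfg.n_hidden - 1, -1, -1):
            if layer + 1 == cfg.reinject_after and cfg.n_hidden > cfg.reinject_after:
                dh = dh[:, :-1]  # drop the re-appended sigma column
            h_in, t = cache[layer]
            da = dh * (1.0 - t**2)
            grads_w[layer] = h_in.T @ da
            grads_b[layer] = da.sum(axis=0)
            dh = da @ self.weights[layer].T
        return grads_w, grads_b

    def __call__(self, m: np.ndarray, sigma: float) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        single = m.ndim == 1
        mb = m[None, :] if single else m
        sig = np.asarray(sigma, dtype=float)
        col = np.broadcast_to(np.atleast_1d(sig), (mb.shape[0],))[:, None]
        out, _ = self._forward(mb, np.ascontiguousarray(col))
        return out[0] if single else out

    # -- checkpointing -----------------------------------------------------
    def save(self, path):
        """Write weights + architecture to a single .npz checkpoint."""
        cfg = self.cfg
        meta = np.array(
            [self.dim, cfg.width, cfg.n_hidden, cfg.reinject_after], dtype=int
        )
        arrays = {"meta": meta}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MLPScore":
        data = np.load(path)
        dim, width, n_hidden, reinject = (int(v) for v in data["meta"])
        cfg = ScoreTrainConfig(
            n_train=1, width=width, n_hidden=n_hidden, reinject_after=reinject
        )
        model = cls(dim, cfg, np.random.default_rng(0))
        model.weights = [data[f"w{i}"] for i in range(n_hidden + 1)]
        model.biases = [data[f"b{i}"] for i in range(n_hidden + 1)]
        return model


def dsm_loss(model: MLPScore, m0: np.ndarray, z: np.ndarray, sigma: np.ndarray) -> float:
    """Weighted denoising score-matching loss ||sigma * s + z||^2 (mean)."""
    sig = sigma[:, None]
    s, _ = model._forward(m0 + sig * z, sig)
    return float(np.mean(np.sum((sig * s + z) ** 2, axis=1)))


def train_score_model(
    prior_samples: np.ndarray,
    schedule,
    cfg: ScoreTrainConfig = ScoreTrainConfig(),
) -> MLPScore:
    """Fit the score network by denoising score matching with Adam.

    Per iteration, a minibatch of (sample, z, t) triplets is drawn i.i.d.
    with t uniform on [t_min, T]. Raises on a non-finite loss.
    """
    samples = np.asarray(prior_samples, dtype=float)
    if samples.shape[0] < cfg.n_train:
        raise ValueError(
            f"need {cfg.n_train} training samples, got {samples.shape[0]}"
        )
    samples = samples[: cfg.n_train]
    rng = np.random.default_rng(cfg.seed)
    model = MLPScore(samples.shape[1], cfg, rng)

    # Adam state
    mw = [np.zeros_like(w) for w in model.weights]
    vw = [np.zeros_like(w) for w in model.weights]
    mb_ = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8

    n = samples.shape[0]
    for it in range(1, cfg.n_iters + 1):
        idx = rng.integers(0, n, size=cfg.batch_size)
        m0 = samples[idx]
        z = rng.standard_normal(m0.shape)
        t = rng.uniform(cfg.t_min, schedule.T, size=cfg.batch_size)
        sig = np.array([schedule.sigma(ti) for ti in t]) if not _vectorizable(schedule) else schedule.sigma(t)
        sig_col = sig[:, None]

        s, cache = model._forward(m0 + sig_col * z, sig_col)
        resid = sig_col * s + z
        loss = np.mean(np.sum(resid**2, axis=1))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        d_out = 2.0 * sig_col * resid / cfg.batch_size
        gw, gb = model._backward(d_out, cache)

        corr1 = 1.0 - b1**it
        corr2 = 1.0 - b2**it
        for k in range(len(model.weights)):
            mw[k] = b1 * mw[k] + (1 - b1) * gw[k]
            vw[k] = b2 * vw[k] + (1 - b2) * gw[k] ** 2
            model.weights[k] -= cfg.lr * (mw[k] / corr1) / (np.sqrt(vw[k] / corr2) + eps)
            mb_[k] = b1 * mb_[k] + (1 - b1) * gb[k]
            vb[k] = b2 * vb[k] + (1 - b2) * gb[k] ** 2
            model.biases[k] -= cfg.lr * (mb_[k] / corr1) / (np.sqrt(vb[k] / corr2) + eps)
    return model


def _vectorizable(schedule) -> bool:
    try:
        out = schedule.sigma(np.array([0.5, 1.0]))
        return np.shape(out) == (2,)
    except Exception:
        return False
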