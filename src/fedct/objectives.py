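"""Losses, the Adam optimiser, and the single-role update steps.

The three objectives:

* client (TS-iRadonMAP):  ``||y* - Phi_dual(x)||^2 + eps_k * TV
  + alpha_k * Huber(Phi_i(y~), Phi_m(y~, P))``
* shared model:           ``||y* - Phi_m(y~, P)||^2 + eps_k * TV
  + (1 - alpha_k) * Huber(Phi_m, Phi_i)``
* metamodel:              ``||mu* - Phi_c(mu, P)||^2``

For unpaired clients the fidelity term is dropped and training relies on the
TV prior plus mutual consistency with the broadcast, metadata-informed shared
model.  Mutual targets are treated as constants (no gradient flows into the
partner network), the standard deep-mutual-learning treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import ImageGrid


@dataclass(frozen=True)
class LossWeights:
    """delta: Huber threshold; alpha_k: mutual-learning balance;
    epsilon_k: TV weight (zero for paired clients, 0.1 for unpaired)."""

    delta: float = 0.1
    alpha_k: float = 0.5
    epsilon_k: float = 0.0

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0.0 <= self.alpha_k <= 1.0:
            raise ValueError("alpha_k must lie in [0, 1]")
        if self.epsilon_k < 0:
            raise ValueError("epsilon_k must be nonnegative")


@dataclass(frozen=True)
class OptimizerSettings:
    """Adam settings; momentum is the first-moment decay."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


# ---------------------------------------------------------------------------
# closed-form kernels (numpy, used for analysis and testing; the autodiff
# twins in fedct.autodiff are used inside training graphs)
# ---------------------------------------------------------------------------

def _img_data(x):
    return x.data if isinstance(x, ImageGrid) else np.asarray(x, dtype=np.float64)


def huber_mutual_loss(a_img, b_img, delta: float) -> float:
    """Mean Huber distance between two images: 0.5*a^2 inside |a| <= delta,
    delta*(|a| - 0.5*delta) outside."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    a = _img_data(a_img) - _img_data(b_img)
    if _img_data(a_img).shape != _img_data(b_img).shape:
        raise ValueError("image shapes differ")
    absa = np.abs(a)
    vals = np.where(absa <= delta, 0.5 * a ** 2, delta * (absa - 0.5 * delta))
    return float(vals.mean())


def tv_penalty(img, normalized: bool = True) -> float:
    """Anisotropic total variation: absolute forward differences along both
    axes, summed; divided by the number of differences when ``normalized``."""
    d = _img_data(img)
    dy = np.abs(np.diff(d, axis=-2)).sum()
    dx = np.abs(np.diff(d, axis=-1)).sum()
    total = float(dy + dx)
    if not normalized:
        return total
    n = (d.shape[-2] - 1) * d.shape[-1] + d.shape[-2] * (d.shape[-1] - 1)
    return total / max(n, 1)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam over an ordered name->Tensor parameter mapping."""

    def __init__(self, params, settings: OptimizerSettings):
        self.params = dict(params)
        self.s = settings
        self.m = {k: np.zeros_like(t.data) for k, t in self.params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in self.params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        s = self.s
        b1, b2 = s.momentum, s.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            if s.weight_decay:
                g = g + s.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p.data = p.data - s.learning_rate * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + s.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# update steps
# ---------------------------------------------------------------------------

def _stack_sinos(items) -> Tensor:
    return Tensor(np.stack([it.sino.data for it in items])[:, None]
                  .astype(np.float32))


def _stack_refs(items) -> Tensor:
    return Tensor(np.stack([it.reference.data for it in items])[:, None]
                  .astype(np.float32))


def _cond_tensor(cond, batch: int) -> Tensor:
    return Tensor(np.repeat(cond.as_array()[None, :], batch, axis=0))


def client_update(client, n_iters: int, seed: int) -> List[float]:
    """Local TS-iRadonMAP training (theta_s, theta_i); shared model frozen."""
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(n_iters):
        items = client.sample_batch(rng)
        loss = _client_loss(client, items)
        client.opt_local.zero_grad()
        loss.backward()
        client.opt_local.step()
        trace.append(float(loss.data))
    return trace


def _client_loss(client, items) -> Tensor:
    w = client.weights
    x = _stack_sinos(items)
    y_tilde, y = client.ts(x)
    paired = items[0].reference is not None
    if paired:
        loss = ad.mse(y, _stack_refs(items))
    else:
        loss = Tensor(0.0)
    if w.epsilon_k > 0:
        loss = loss + w.epsilon_k * ad.tv_aniso(y)
    if client.mutual_enabled and w.alpha_k > 0:
        cond = client.cond_tensor(len(items))
        ym = client.shared(Tensor(y_tilde.data), cond)   # frozen target
        loss = loss + w.alpha_k * ad.huber(y - Tensor(ym.data), w.delta)
    return loss


def shared_update(client, n_iters: int, seed: int,
                  model=None, optimizer=None) -> List[float]:
    """Mutual knowledge sharing: update (theta_m, theta_p) with the client's
    TS-iRadonMAP frozen.  ``model``/``optimizer`` default to the client's
    shared model; passing others trains e.g. a local-only shadow copy."""
    model = model or client.shared
    optimizer = optimizer or client.opt_shared
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(n_iters):
        items = client.sample_batch(rng)
        loss = _shared_loss(client, items, model)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        trace.append(float(loss.data))
    return trace


def _shared_loss(client, items, model) -> Tensor:
    w = client.weights
    x = _stack_sinos(items)
    with_frozen = client.ts
    filtered = with_frozen.sino_net(x)
    y_tilde = with_frozen.back_project(filtered)
    yt = Tensor(y_tilde.data)                       # detach: theta_s frozen
    cond = client.cond_tensor(len(items))
    out = model(yt, cond)
    paired = items[0].reference is not None
    if paired:
        loss = ad.mse(out, _stack_refs(items))
    else:
        loss = Tensor(0.0)
    if w.epsilon_k > 0:
        loss = loss + w.epsilon_k * ad.tv_aniso(out)
    if client.mutual_enabled and w.alpha_k < 1.0:
        yi = with_frozen.image_net(yt)
        loss = loss + (1.0 - w.alpha_k) * ad.huber(out - Tensor(yi.data),
                                                   w.delta)
    return loss


def mutual_round(client, n_iters: int, seed: int,
                 shadow_model=None, shadow_optimizer=None):
    """Synchronized per-batch mutual learning: on every batch both the
    dual-domain model and the shared model are updated simultaneously from
    the outputs computed at the current parameters, each treating the
    other's output as a constant target.

    Returns (client_trace, shared_trace).  When a shadow model/optimiser is
    given, the shadow receives the same shared-objective step on the same
    batches (the local-only reference used by the divergence diagnostic).
    """
    rng = np.random.default_rng(seed)
    w = client.weights
    trace_c, trace_s = [], []
    for _ in range(n_iters):
        items = client.sample_batch(rng)
        x = _stack_sinos(items)
        y_tilde, y = client.ts(x)
        yt_const = Tensor(y_tilde.data)
        paired = items[0].reference is not None
        refs = _stack_refs(items) if paired else None
        cond = client.cond_tensor(len(items))

        mutual = client.mutual_enabled
        out = client.shared(yt_const, cond) if (mutual or paired or
                                                w.epsilon_k > 0) else None

        # client objective (theta_s, theta_i)
        lc = ad.mse(y, refs) if paired else Tensor(0.0)
        if w.epsilon_k > 0:
            lc = lc + w.epsilon_k * ad.tv_aniso(y)
        if mutual and w.alpha_k > 0:
            lc = lc + w.alpha_k * ad.huber(y - Tensor(out.data), w.delta)
        client.opt_local.zero_grad()
        lc.backward()

        # shared objective (theta_m, theta_p)
        ls = ad.mse(out, refs) if paired else Tensor(0.0)
        if w.epsilon_k > 0 and out is not None:
            ls = ls + w.epsilon_k * ad.tv_aniso(out)
        if mutual and w.alpha_k < 1.0:
            ls = ls + (1.0 - w.alpha_k) * ad.huber(out - Tensor(y.data),
                                                   w.delta)
        client.opt_shared.zero_grad()
        ls.backward()

        client.opt_local.step()
        client.opt_shared.step()

        if shadow_model is not None:
            sh_out = shadow_model(yt_const, cond)
            lsh = ad.mse(sh_out, refs) if paired else Tensor(0.0)
            if w.epsilon_k > 0:
                lsh = lsh + w.epsilon_k * ad.tv_aniso(sh_out)
            if mutual and w.alpha_k < 1.0:
                lsh = lsh + (1.0 - w.alpha_k) * ad.huber(
                    sh_out - Tensor(y.data), w.delta)
            shadow_optimizer.zero_grad()
            lsh.backward()
            shadow_optimizer.step()

        trace_c.append(float(lc.data))
        trace_s.append(float(ls.data))
    return trace_c, trace_s


def meta_update(meta_model, opt, pool, n_iters: int, seed: int,
                batch_size: int = 1) -> List[float]:
    """Federated metadata training of the metamodel (theta_c, theta_p_c)."""
    if len(pool) == 0:
        raise ValueError("metadata pool is empty")
    rng = np.random.default_rng(seed)
    trace = []
    for _ in range(n_iters):
        idx = rng.integers(0, len(pool), size=batch_size)
        lows = Tensor(np.stack([pool.pairs[i]["low"].data for i in idx])
                      [:, None].astype(np.float32))
        refs = Tensor(np.stack([pool.pairs[i]["ref"].data for i in idx])
                      [:, None].astype(np.float32))
        cond = Tensor(np.stack([pool.pairs[i]["condition"].as_array()
                                for i in idx]))
        out = meta_model(lows, cond)
        loss = ad.mse(out, refs)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return trace
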