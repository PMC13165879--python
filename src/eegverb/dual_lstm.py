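"""The proposed decoder: a 7-layer recurrent network with two LSTM layers.

Architecture (input -> output): the 4-s epoch is consumed as a sequence of
per-step channel frames; each step passes through three fully connected
layers (affine transform X_{i+1} = X_i W + b followed by tanh), then two
stacked LSTM layers scanned over time, and the final step's hidden state is
projected to six logits and softmaxed.

Each LSTM cell uses four gates — input f_i, forget f_f, output f_o and
input-modulation f_m — each computed from the same affine form

    T(x_t, h_{t-1}) = x_t W_x + h_{t-1} W_h + b

with sigmoid on f_i, f_f, f_o and tanh on f_m, and the state update

    c_t = f_f * c_{t-1} + f_i * f_m,      h_t = f_o * tanh(c_t).

Training minimises the per-unit binary cross-entropy summed over the six
output units against one-hot targets (equivalent, up to the complement
terms, to categorical cross-entropy), by seeded mini-batch gradient descent
with global-norm gradient clipping.  The learning rate is either fixed
(default 0.005) or chosen per step by an exact line search along the
negative gradient; at the line-search minimiser successive gradients are
orthogonal.

Everything here is plain NumPy with hand-derived backpropagation through
time; gradients are verified against central differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import TrialSet
from .preprocess import zscore_trials

EPS_PROB = 1e-12
GATE_ORDER = ("input", "forget", "output", "modulation")


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimisation."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class LstmLayerParams:
    """One LSTM layer's gate transforms, stacked [i | f | o | m] column-wise."""

    wx: np.ndarray  # (in_dim, 4H)
    wh: np.ndarray  # (H, 4H)
    b: np.ndarray   # (4H,)

    @property
    def hidden(self) -> int:
        return self.wh.shape[0]


@dataclass
class LstmNetwork:
    """Full parameter container for the 7-layer decoder."""

    input_dim: int
    fc_weights: list[tuple[np.ndarray, np.ndarray]]  # [(W, b), ...]
    lstm_layers: list[LstmLayerParams]
    output_weights: tuple[np.ndarray, np.ndarray]    # (W, b) -> 6 logits
    activation: str = "tanh"   # tanh | linear (linear for unit tests)
    readout: str = "last"      # last | mean

    @property
    def n_classes(self) -> int:
        return self.output_weights[0].shape[1]

    # -- flat-vector view used by line search and gradient checking --------
    def param_arrays(self) -> list[np.ndarray]:
        arrs: list[np.ndarray] = []
        for w, b in self.fc_weights:
            arrs += [w, b]
        for layer in self.lstm_layers:
            arrs += [layer.wx, layer.wh, layer.b]
        arrs += [self.output_weights[0], self.output_weights[1]]
        return arrs

    def get_flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.param_arrays()])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for a in self.param_arrays():
            a[...] = flat[i:i + a.size].reshape(a.shape)
            i += a.size

    def copy(self) -> "LstmNetwork":
        return LstmNetwork(
            self.input_dim,
            [(w.copy(), b.copy()) for w, b in self.fc_weights],
            [LstmLayerParams(l.wx.copy(), l.wh.copy(), l.b.copy())
             for l in self.lstm_layers],
            (self.output_weights[0].copy(), self.output_weights[1].copy()),
            self.activation, self.readout,
        )


def init_network(input_dim: int, fc_sizes=(128, 64, 32), lstm_sizes=(64, 64),
                 n_classes: int = 6, seed: int = 0, activation: str = "tanh",
                 readout: str = "last", zero_init: bool = False) -> LstmNetwork:
    """Seeded uniform(-r, r) initialisation with r = 1/sqrt(fan-in).

    The forget-gate bias starts at +1 (standard stabilisation).
    ``zero_init`` gives the all-zero network used for symmetry tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1247]))

    def u(shape, fan_in):
        if zero_init:
            return np.zeros(shape)
        r = 1.0 / math.sqrt(fan_in)
        return rng.uniform(-r, r, size=shape)

    fc, dim = [], input_dim
    for h in fc_sizes:
        fc.append((u((dim, h), dim), np.zeros(h)))
        dim = h
    lstm = []
    for h in lstm_sizes:
        b = np.zeros(4 * h)
        if not zero_init:
            b[h:2 * h] = 1.0  # forget gate
        lstm.append(LstmLayerParams(u((dim, 4 * h), dim), u((h, 4 * h), h), b))
        dim = h
    out = (u((dim, n_classes), dim), np.zeros(n_classes))
    return LstmNetwork(input_dim, fc, lstm, out, activation, readout)


# ---------------------------------------------------------------------------
# Elementary forward operations
# ---------------------------------------------------------------------------

def fc_forward(x: np.ndarray, layer: tuple[np.ndarray, np.ndarray],
               activation: str = "tanh") -> np.ndarray:
    """Affine transform x W + b followed by the configured nonlinearity."""
    w, b = layer
    if x.shape[-1] != w.shape[0]:
        raise ValueError(f"input dim {x.shape[-1]} != weight rows {w.shape[0]}")
    z = x @ w + b
    return np.tanh(z) if activation == "tanh" else z


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              params: LstmLayerParams) -> tuple[np.ndarray, np.ndarray]:
    """One gated state update; returns (h_t, c_t)."""
    h, c, _ = _lstm_step_cached(x_t, h_prev, c_prev, params)
    return h, c


def _lstm_step_cached(x_t, h_prev, c_prev, params):
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))
            and np.all(np.isfinite(c_prev))):
        raise FloatingPointError("non-finite input to LSTM step")
    hdim = params.hidden
    pre = x_t @ params.wx + h_prev @ params.wh + params.b
    gi = _sigmoid(pre[..., :hdim])
    gf = _sigmoid(pre[..., hdim:2 * hdim])
    go = _sigmoid(pre[..., 2 * hdim:3 * hdim])
    gm = np.tanh(pre[..., 3 * hdim:])
    c_t = gf * c_prev + gi * gm
    tc = np.tanh(c_t)
    h_t = go * tc
    return h_t, c_t, (x_t, h_prev, c_prev, gi, gf, go, gm, c_t, tc)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Sequence forward / backward
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    probs: np.ndarray
    label: int


def frames_from_trials(ts: TrialSet, frame_len: int = 20,
                       standardize: bool = True) -> np.ndarray:
    """Chunk (n, channels, T) epochs into (n, T/frame_len, channels*frame_len).

    The default consumes the 1000-sample trial as 50 non-overlapping
    20-sample frames per channel (flattened), keeping backpropagation
    through time tractable; ``frame_len=1`` gives the raw per-sample
    sequence.
    """
    if standardize:
        ts = zscore_trials(ts)
    n, c, t = ts.data.shape
    if t % frame_len:
        raise ValueError(f"trial length {t} not divisible by frame_len {frame_len}")
    s = t // frame_len
    return ts.data.reshape(n, c, s, frame_len).transpose(0, 2, 1, 3) \
        .reshape(n, s, c * frame_len)


def forward_batch(net: LstmNetwork, x: np.ndarray, want_cache: bool = False):
    """Probabilities for a (batch, steps, features) input stack."""
    if x.ndim != 3 or x.shape[1] == 0:
        raise ValueError("input must be (batch, steps >= 1, features)")
    b, s, _ = x.shape
    # FC stack, vectorised over batch*steps
    a = x.reshape(b * s, -1)
    fc_cache = []
    for layer in net.fc_weights:
        z = a @ layer[0] + layer[1]
        a_next = np.tanh(z) if net.activation == "tanh" else z
        fc_cache.append((a, a_next))
        a = a_next
    seq = a.reshape(b, s, -1)

    lstm_caches, h_seq = [], None
    for layer in net.lstm_layers:
        hdim = layer.hidden
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        caches, outs = [], np.empty((b, s, hdim))
        for t in range(s):
            h, c, cache = _lstm_step_cached(seq[:, t], h, c, layer)
            caches.append(cache)
            outs[:, t] = h
        lstm_caches.append(caches)
        seq = outs
        h_seq = outs

    read = h_seq[:, -1] if net.readout == "last" else h_seq.mean(axis=1)
    logits = read @ net.output_weights[0] + net.output_weights[1]
    probs = softmax(logits)
    if not want_cache:
        return probs
    return probs, (x, fc_cache, lstm_caches, h_seq, read)


def forward(net: LstmNetwork, sequence: np.ndarray) -> Prediction:
    """Classify one trial given as a (steps, features) sequence."""
    probs = forward_batch(net, np.asarray(sequence)[None])[0]
    return Prediction(probs, int(probs.argmax()))


def cross_entropy_loss(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Per-unit binary cross-entropy summed over units, averaged over samples.

    loss = -(1/n) sum_x sum_k [ y ln a + (1 - y) ln(1 - a) ]
    """
    a = np.clip(probs, EPS_PROB, 1.0 - EPS_PROB)
    per = -(onehot * np.log(a) + (1.0 - onehot) * np.log(1.0 - a)).sum(axis=-1)
    return float(per.mean())


def _loss_grad_logits(probs: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """d loss / d logits through the softmax and the per-unit BCE."""
    n = probs.shape[0]
    a = np.clip(probs, EPS_PROB, 1.0 - EPS_PROB)
    g = -(onehot / a - (1.0 - onehot) / (1.0 - a)) / n
    return a * (g - (a * g).sum(axis=-1, keepdims=True))


def backward_batch(net: LstmNetwork, x: np.ndarray, onehot: np.ndarray,
                   return_probs: bool = False):
    """Loss and analytic gradients (same order as ``param_arrays``)."""
    probs, (x_in, fc_cache, lstm_caches, h_seq, read) = \
        forward_batch(net, x, want_cache=True)
    loss = cross_entropy_loss(probs, onehot)
    b, s, _ = x.shape

    wo, bo = net.output_weights
    dlogits = _loss_grad_logits(probs, onehot)
    d_wo = read.T @ dlogits
    d_bo = dlogits.sum(axis=0)
    dread = dlogits @ wo.T

    # gradient into the top LSTM output sequence
    dh_seq = np.zeros_like(h_seq)
    if net.readout == "last":
        dh_seq[:, -1] = dread
    else:
        dh_seq += dread[:, None, :] / s

    lstm_grads: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    dseq = dh_seq
    for li in range(len(net.lstm_layers) - 1, -1, -1):
        layer = net.lstm_layers[li]
        caches = lstm_caches[li]
        hdim = layer.hidden
        d_wx = np.zeros_like(layer.wx)
        d_wh = np.zeros_like(layer.wh)
        d_b = np.zeros_like(layer.b)
        dx_seq = np.empty((b, s, layer.wx.shape[0]))
        dh_next = np.zeros((b, hdim))
        dc_next = np.zeros((b, hdim))
        for t in range(s - 1, -1, -1):
            x_t, h_prev, c_prev, gi, gf, go, gm, c_t, tc = caches[t]
            dh = dseq[:, t] + dh_next
            dgo = dh * tc
            dc = dc_next + dh * go * (1.0 - tc ** 2)
            dgf = dc * c_prev
            dgi = dc * gm
            dgm = dc * gi
            dc_next = dc * gf
            dpre = np.concatenate([
                dgi * gi * (1.0 - gi),
                dgf * gf * (1.0 - gf),
                dgo * go * (1.0 - go),
                dgm * (1.0 - gm ** 2),
            ], axis=-1)
            d_wx += x_t.T @ dpre
            d_wh += h_prev.T @ dpre
            d_b += dpre.sum(axis=0)
            dx_seq[:, t] = dpre @ layer.wx.T
            dh_next = dpre @ layer.wh.T
        lstm_grads.append((d_wx, d_wh, d_b))
        dseq = dx_seq
    lstm_grads.reverse()

    # FC stack backward, vectorised over batch*steps
    da = dseq.reshape(b * s, -1)
    fc_grads: list[tuple[np.ndarray, np.ndarray]] = []
    for li in range(len(net.fc_weights) - 1, -1, -1):
        a_in, a_out = fc_cache[li]
        dz = da * (1.0 - a_out ** 2) if net.activation == "tanh" else da
        fc_grads.append((a_in.T @ dz, dz.sum(axis=0)))
        da = dz @ net.fc_weights[li][0].T
    fc_grads.reverse()

    grads: list[np.ndarray] = []
    for gw, gb in fc_grads:
        grads += [gw, gb]
    for gwx, gwh, gb in lstm_grads:
        grads += [gwx, gwh, gb]
    grads += [d_wo, d_bo]
    if return_probs:
        return loss, grads, probs
    return loss, grads


# ---------------------------------------------------------------------------
# Exact line search on the learning rate
# ---------------------------------------------------------------------------

def exact_line_search(f, x: np.ndarray, g: np.ndarray, alpha_init: float = 1.0,
                      fallback: float | None = None,
                      max_expand: int = 60) -> float:
    """Step size approximately minimising phi(a) = f(x - a g).

    At the minimiser, phi'(a) = -grad f(x - a g) . g = 0: the new gradient
    is orthogonal to the search direction.  Brackets a minimum by geometric
    expansion/contraction and polishes with Brent's method; returns
    ``fallback`` (with a warning) when no bracket is found.
    """
    gnorm = np.linalg.norm(g)
    if gnorm == 0:
        raise ValueError("gradient is zero; line search undefined")

    def phi(a):
        return f(x - a * g)

    phi0 = phi(0.0)
    t = alpha_init
    for _ in range(max_expand):  # shrink until we descend
        if phi(t) < phi0:
            break
        t /= 4.0
    else:
        if fallback is None:
            raise RuntimeError("line search failed to find descent")
        import warnings
        warnings.warn("line search found no descent; using fallback step",
                      stacklevel=2)
        return fallback
    b, c = t, 2.0 * t
    for _ in range(max_expand):  # expand until phi turns upward
        if phi(c) >= phi(b):
            break
        b, c = c, 2.0 * c
    res = minimize_scalar(phi, bracket=(0.0, b, c), method="brent")
    alpha = float(res.x)
    if not np.isfinite(alpha) or alpha <= 0:
        if fallback is None:
            raise RuntimeError("line search returned a non-positive step")
        return fallback
    return alpha


def line_search_lr(net: LstmNetwork, x: np.ndarray, onehot: np.ndarray,
                   grads: list[np.ndarray] | None = None,
                   fallback: float | None = 0.005) -> float:
    """Exact line search on the full-batch loss along the negative gradient."""
    if grads is None:
        _, grads = backward_batch(net, x, onehot)
    g = np.concatenate([a.ravel() for a in grads])
    p0 = net.get_flat()
    probe = net.copy()

    def f(flat):
        probe.set_flat(flat)
        return cross_entropy_loss(forward_batch(probe, x), onehot)

    return exact_line_search(f, p0, g, alpha_init=1.0, fallback=fallback)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.005
    batch_size: int = 32
    max_epochs: int = 50
    seed: int = 0
    lr_mode: str = "fixed"     # fixed | line_search
    clip_norm: float = 5.0
    frame_len: int = 20

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _clip_global(grads: list[np.ndarray], max_norm: float) -> list[np.ndarray]:
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads))
    if max_norm and total > max_norm:
        scale = max_norm / total
        return [g * scale for g in grads]
    return grads


def train(net: LstmNetwork, x: np.ndarray, labels: np.ndarray,
          config: TrainConfig = TrainConfig(),
          x_val: np.ndarray | None = None,
          labels_val: np.ndarray | None = None
          ) -> tuple[LstmNetwork, pd.DataFrame]:
    """Seeded mini-batch gradient descent on the summed-unit cross-entropy.

    ``x`` is a (n, steps, features) frame stack.  Returns the trained
    network (modified in place) and a per-epoch trace of loss and
    accuracies.  Raises :class:`TrainingDivergedError` when the loss goes
    non-finite.
    """
    labels = np.asarray(labels, dtype=int)
    n, k = len(labels), net.n_classes
    onehot = np.eye(k)[labels]
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7A1]))
    rows = []
    for ep in range(config.max_epochs):
        perm = rng.permutation(n)
        ep_loss, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = x[idx], onehot[idx]
            loss, grads, probs = backward_batch(net, xb, yb, return_probs=True)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss non-finite at epoch {ep}, batch starting {start} "
                    f"(lr={config.learning_rate}, mode={config.lr_mode})")
            grads = _clip_global(grads, config.clip_norm)
            if config.lr_mode == "line_search":
                lr = line_search_lr(net, xb, yb, grads,
                                    fallback=config.learning_rate)
            else:
                lr = config.learning_rate
            for p, g in zip(net.param_arrays(), grads):
                p -= lr * g
            ep_loss += loss * len(idx)
            correct += int((probs.argmax(axis=1) == labels[idx]).sum())
        row = {"epoch": ep, "loss": ep_loss / n, "train_acc": correct / n}
        if x_val is not None:
            val_pred = predict_labels(net, x_val)
            row["val_acc"] = float((val_pred == np.asarray(labels_val)).mean())
        rows.append(row)
    return net, pd.DataFrame(rows)


def predict_labels(net: LstmNetwork, x: np.ndarray,
                   batch_size: int = 256) -> np.ndarray:
    """Predicted class indices for a frame stack, in memory-bounded batches."""
    out = []
    for start in range(0, len(x), batch_size):
        out.append(forward_batch(net, x[start:start + batch_size]).argmax(axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


class LstmDecoder:
    """Train/predict wrapper over the recurrent network for the protocols."""

    def __init__(self, fc_sizes=(128, 64, 32), lstm_sizes=(64, 64),
                 config: TrainConfig = TrainConfig()):
        self.fc_sizes, self.lstm_sizes = fc_sizes, lstm_sizes
        self.config = config
        self.net: LstmNetwork | None = None

    def fit(self, train_ts: TrialSet, seed: int = 0) -> "LstmDecoder":
        cfg = replace(self.config, seed=seed)
        x = frames_from_trials(train_ts, cfg.frame_len)
        self.net = init_network(x.shape[2], self.fc_sizes, self.lstm_sizes,
                                n_classes=int(train_ts.labels.max()) + 1,
                                seed=seed)
        self.net, self.trace_ = train(self.net, x, train_ts.labels, cfg)
        return self

    def predict(self, ts: TrialSet) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("decoder not fitted")
        return predict_labels(self.net, frames_from_trials(
            ts, self.config.frame_len))
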