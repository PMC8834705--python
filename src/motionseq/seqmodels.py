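"""Sequence classifiers on keyframe quaternion sequences.

Two families operate directly on the (variable-length) sequences rather
than on DTW feature vectors:

* a discrete-emission hidden Markov model lambda = [N, M, pi, A, B], with
  continuous 68-dim pose frames (17 joints x 4 quaternion components)
  mapped to symbols by a vector-quantisation codebook.  Evaluation uses
  the forward algorithm (per-step scaling), training uses Baum-Welch EM,
  and classification picks the per-class model with the highest
  log-likelihood;
* minimal recurrent networks (LSTM, BiLSTM, GRU) with exact analytic
  backpropagation through time, trained by full-batch gradient descent on
  softmax cross-entropy.

Everything is plain numpy and deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .motion_io import QuaternionSequence

__all__ = [
    "Codebook",
    "HMMModel",
    "RNNModel",
    "fit_codebook",
    "quantize",
    "hmm_forward",
    "hmm_backward",
    "hmm_fit",
    "hmm_classify",
    "init_left_right",
    "rnn_forward",
    "rnn_fit",
    "rnn_predict",
]


# ---------------------------------------------------------------------------
# vector quantisation


@dataclass
class Codebook:
    """k-means centroids over flattened pose frames (M x 68 by default)."""

    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or len(self.centroids) < 1:
            raise ValueError("centroids must be a non-empty 2-D array")
        if len(np.unique(self.centroids, axis=0)) != len(self.centroids):
            raise ValueError("centroids must be distinct")

    @property
    def n_symbols(self) -> int:
        return len(self.centroids)


def _frames_of(motion) -> np.ndarray:
    if isinstance(motion, QuaternionSequence):
        return motion.quat.reshape(motion.n_frames, -1)
    arr = np.asarray(motion, dtype=float)
    return arr.reshape(arr.shape[0], -1)


def fit_codebook(motions, M: int, seed: int = 0) -> Codebook:
    """Fit an M-symbol codebook by k-means on all frames of the motions.

    If fewer than M distinct frames exist, M is reduced to that count
    (dedup guard); M larger than the total frame count is an error.
    """
    X = np.vstack([_frames_of(m) for m in motions])
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > len(X):
        raise ValueError(f"M={M} exceeds total frame count {len(X)}")
    n_unique = len(np.unique(X, axis=0))
    M_eff = min(M, n_unique)
    km = KMeans(n_clusters=M_eff, n_init=5, random_state=seed).fit(X)
    centroids = np.unique(km.cluster_centers_, axis=0)
    return Codebook(centroids)


def quantize(motion, codebook: Codebook) -> np.ndarray:
    """Symbol sequence: index of the nearest centroid per frame."""
    X = _frames_of(motion)
    d2 = ((X[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# hidden Markov model


@dataclass
class HMMModel:
    """Discrete HMM lambda = [N, M, pi, A, B] (rows stochastic)."""

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    fit_log_likelihood: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        N = len(self.pi)
        if self.A.shape != (N, N):
            raise ValueError("A must be N x N")
        if self.B.ndim != 2 or self.B.shape[0] != N:
            raise ValueError("B must be N x M")
        for name, arr in (("pi", self.pi[None, :]), ("A", self.A), ("B", self.B)):
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} must be non-negative")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.pi)

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]


def _check_obs(model: HMMModel, obs) -> np.ndarray:
    obs = np.asarray(obs, dtype=int)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observation sequence must be a non-empty 1-D array")
    if obs.min() < 0 or obs.max() >= model.n_symbols:
        raise ValueError("observation symbols out of codebook range")
    return obs


def _forward_scaled(model: HMMModel, obs: np.ndarray):
    """Scaled forward pass.  Returns (alpha_hat (T,N), scales (T,)); the
    log-likelihood is sum(log(scales))."""
    T, N = len(obs), model.n_states
    alpha = np.empty((T, N))
    scales = np.empty(T)
    a = model.pi * model.B[:, obs[0]]
    for t in range(T):
        if t > 0:
            a = (alpha[t - 1] @ model.A) * model.B[:, obs[t]]
        s = a.sum()
        if s == 0.0:
            scales[t:] = 0.0
            alpha[t:] = 0.0
            return alpha, scales
        alpha[t] = a / s
        scales[t] = s
    return alpha, scales


def hmm_forward(model: HMMModel, obs) -> float:
    """log P(O | lambda) via the forward algorithm with per-step scaling.

    Returns -inf when the model assigns the sequence zero probability.
    """
    obs = _check_obs(model, obs)
    _, scales = _forward_scaled(model, obs)
    if np.any(scales == 0.0):
        return float("-inf")
    return float(np.log(scales).sum())


def hmm_backward(model: HMMModel, obs) -> np.ndarray:
    """Unscaled backward table beta (T x N): beta_T(i) = 1 and
    beta_t(i) = sum_j a_ij b_j(o_{t+1}) beta_{t+1}(j).

    Satisfies sum_i pi_i b_i(o_1) beta_1(i) = P(O | lambda).  Intended for
    short sequences and diagnostics; training uses the scaled variant.
    """
    obs = _check_obs(model, obs)
    T, N = len(obs), model.n_states
    beta = np.empty((T, N))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = model.A @ (model.B[:, obs[t + 1]] * beta[t + 1])
    return beta


def _backward_scaled(model: HMMModel, obs: np.ndarray, scales: np.ndarray) -> np.ndarray:
    T, N = len(obs), model.n_states
    beta = np.empty((T, N))
    beta[T - 1] = 1.0 / scales[T - 1]
    for t in range(T - 2, -1, -1):
        beta[t] = (model.A @ (model.B[:, obs[t + 1]] * beta[t + 1])) / scales[t]
    return beta


def init_left_right(N: int, M: int, seed: int = 0) -> HMMModel:
    """Left-to-right chain with self-loops: the motion is assumed to move
    through N phases monotonically.  Emissions start near-uniform with a
    small seeded perturbation to break symmetry."""
    rng = np.random.default_rng(seed)
    pi = np.zeros(N)
    pi[0] = 1.0
    A = np.zeros((N, N))
    for i in range(N - 1):
        A[i, i] = 0.5
        A[i, i + 1] = 0.5
    A[N - 1, N - 1] = 1.0
    B = np.full((N, M), 1.0) + rng.uniform(0, 0.1, size=(N, M))
    B /= B.sum(axis=1, keepdims=True)
    return HMMModel(pi, A, B)


def _init_full(N: int, M: int, seed: int) -> HMMModel:
    # emissions drawn with a dispersed Dirichlet: near-uniform emission
    # rows are a symmetric fixed point EM cannot escape
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.full(N, 5.0))
    A = rng.dirichlet(np.full(N, 5.0), size=N)
    B = rng.dirichlet(np.full(M, 1.0), size=N)
    return HMMModel(pi, A, B)


def hmm_fit(
    obs_set,
    N: int,
    M: int,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-4,
    topology: str = "left-to-right",
) -> HMMModel:
    """Baum-Welch EM over a set of symbol sequences.

    The total log-likelihood is non-decreasing across iterations; fitting
    stops when the improvement falls below ``tol`` or after ``max_iter``
    iterations.  Structural zeros of the left-to-right topology are
    preserved by the re-estimation.
    """
    obs_set = [np.asarray(o, dtype=int) for o in obs_set]
    if not obs_set:
        raise ValueError("training set must be non-empty")
    for o in obs_set:
        if o.size == 0:
            raise ValueError("observation sequences must be non-empty")
        if o.min() < 0 or o.max() >= M:
            raise ValueError("observation symbols out of range")
    if topology == "left-to-right":
        model = init_left_right(N, M, seed)
    elif topology == "full":
        model = _init_full(N, M, seed)
    else:
        raise ValueError("topology must be 'left-to-right' or 'full'")

    history: list[float] = []
    for _ in range(max_iter):
        pi_acc = np.zeros(N)
        A_num = np.zeros((N, N))
        A_den = np.zeros(N)
        B_num = np.zeros((N, M))
        B_den = np.zeros(N)
        total_ll = 0.0
        for obs in obs_set:
            alpha, scales = _forward_scaled(model, obs)
            if np.any(scales == 0.0):
                total_ll = float("-inf")
                continue
            beta = _backward_scaled(model, obs, scales)
            total_ll += float(np.log(scales).sum())
            T = len(obs)
            gamma = alpha * beta * scales[:, None]  # (T, N), rows sum to 1
            pi_acc += gamma[0]
            for t in range(T - 1):
                xi = (
                    alpha[t][:, None]
                    * model.A
                    * (model.B[:, obs[t + 1]] * beta[t + 1])[None, :]
                )
                A_num += xi
                A_den += gamma[t]
            np.add.at(B_num.T, obs, gamma)
            B_den += gamma.sum(axis=0)
        history.append(total_ll)
        if not np.isfinite(total_ll):
            break
        new_pi = pi_acc / pi_acc.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            new_A = np.where(A_den[:, None] > 0, A_num / np.maximum(A_den, 1e-300)[:, None], model.A)
            new_B = np.where(B_den[:, None] > 0, B_num / np.maximum(B_den, 1e-300)[:, None], model.B)
        # guard stochasticity against accumulated round-off
        new_A /= new_A.sum(axis=1, keepdims=True)
        new_B /= new_B.sum(axis=1, keepdims=True)
        model = HMMModel(new_pi, new_A, new_B)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
            break
    model.fit_log_likelihood = history
    return model


def hmm_classify(models: dict, obs) -> object:
    """argmax over classes of the forward log-likelihood; ties break to
    the lowest class id."""
    if not models:
        raise ValueError("at least one model is required")
    best_class, best_ll = None, -np.inf
    for class_id in sorted(models):
        ll = hmm_forward(models[class_id], obs)
        if ll > best_ll:
            best_class, best_ll = class_id, ll
    if best_class is None:  # all -inf: fall back to lowest class id
        best_class = sorted(models)[0]
    return best_class


# ---------------------------------------------------------------------------
# recurrent networks


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


_LSTM_GATES = ("Wf", "bf", "Wi", "bi", "Wo", "bo", "Wc", "bc")
_GRU_GATES = ("Wr", "br", "Wz", "bz", "Wh", "bh")


@dataclass
class RNNModel:
    """Minimal recurrent classifier: gate weights, affine readout of the
    final hidden state(s), and the training-set feature normalisation."""

    kind: str
    input_dim: int
    hidden_dim: int
    params: dict
    classes: np.ndarray
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None
    loss_history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("lstm", "bilstm", "gru"):
            raise ValueError("kind must be lstm, bilstm or gru")


def _init_gates(names, H: int, D: int, rng) -> dict:
    params = {}
    scale = 1.0 / np.sqrt(H + D)
    for name in names:
        if name.startswith("W"):
            params[name] = rng.normal(0, scale, size=(H, H + D))
        else:
            params[name] = np.zeros(H)
    return params


def _lstm_pass(p: dict, x: np.ndarray, H: int, prefix: str = ""):
    """LSTM recurrence with h_0 = C_0 = 0:

        f_t = sigma(Wf [h_{t-1}, x_t] + bf)        (forget gate)
        i_t = sigma(Wi [h_{t-1}, x_t] + bi)        (input gate)
        o_t = sigma(Wo [h_{t-1}, x_t] + bo)        (output gate)
        C~_t = tanh(Wc [h_{t-1}, x_t] + bc)
        C_t = f_t * C_{t-1} + i_t * C~_t
        h_t = o_t * tanh(C_t)
    """
    T = x.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    cache = []
    for t in range(T):
        z = np.concatenate([h, x[t]])
        f = _sigmoid(p[prefix + "Wf"] @ z + p[prefix + "bf"])
        i = _sigmoid(p[prefix + "Wi"] @ z + p[prefix + "bi"])
        o = _sigmoid(p[prefix + "Wo"] @ z + p[prefix + "bo"])
        g = np.tanh(p[prefix + "Wc"] @ z + p[prefix + "bc"])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        cache.append((z, f, i, o, g, c_prev, tc))
    return h, cache


def _lstm_backward(p: dict, cache, dh: np.ndarray, H: int, grads: dict, prefix: str = "") -> None:
    dc = np.zeros(H)
    for z, f, i, o, g, c_prev, tc in reversed(cache):
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        daf = df * f * (1.0 - f)
        dai = di * i * (1.0 - i)
        dao = do * o * (1.0 - o)
        dag = dg * (1.0 - g**2)
        for name, da in (("Wf", daf), ("Wi", dai), ("Wo", dao), ("Wc", dag)):
            grads[prefix + name] += np.outer(da, z)
            grads[prefix + "b" + name[1]] += da
        dz = (
            p[prefix + "Wf"].T @ daf
            + p[prefix + "Wi"].T @ dai
            + p[prefix + "Wo"].T @ dao
            + p[prefix + "Wc"].T @ dag
        )
        dh = dz[:H]
        dc = dc_next


def _gru_pass(p: dict, x: np.ndarray, H: int):
    """GRU recurrence with h_0 = 0:

        r_t = sigma(Wr [h_{t-1}, x_t] + br)        (reset gate)
        z_t = sigma(Wz [h_{t-1}, x_t] + bz)        (update gate)
        h~_t = tanh(Wh [r_t * h_{t-1}, x_t] + bh)
        h_t = (1 - z_t) * h_{t-1} + z_t * h~_t
    """
    T = x.shape[0]
    h = np.zeros(H)
    cache = []
    for t in range(T):
        z_in = np.concatenate([h, x[t]])
        r = _sigmoid(p["Wr"] @ z_in + p["br"])
        u = _sigmoid(p["Wz"] @ z_in + p["bz"])
        zh = np.concatenate([r * h, x[t]])
        g = np.tanh(p["Wh"] @ zh + p["bh"])
        h_prev = h
        h = (1.0 - u) * h_prev + u * g
        cache.append((z_in, zh, r, u, g, h_prev))
    return h, cache


def _gru_backward(p: dict, cache, dh: np.ndarray, H: int, grads: dict) -> None:
    for z_in, zh, r, u, g, h_prev in reversed(cache):
        du = dh * (g - h_prev)
        dg = dh * u
        dh_prev = dh * (1.0 - u)
        dag = dg * (1.0 - g**2)
        grads["Wh"] += np.outer(dag, zh)
        grads["bh"] += dag
        dzh = p["Wh"].T @ dag
        drh = dzh[:H]
        dr = drh * h_prev
        dh_prev = dh_prev + drh * r
        dau = du * u * (1.0 - u)
        grads["Wz"] += np.outer(dau, z_in)
        grads["bz"] += dau
        dar = dr * r * (1.0 - r)
        grads["Wr"] += np.outer(dar, z_in)
        grads["br"] += dar
        dh_prev = dh_prev + (p["Wz"].T @ dau)[:H] + (p["Wr"].T @ dar)[:H]
        dh = dh_prev


def _final_state(model_kind: str, params: dict, x: np.ndarray, H: int):
    """Final hidden representation fed to the readout, plus caches."""
    if model_kind == "lstm":
        h, cache = _lstm_pass(params, x, H)
        return h, {"fw": cache}
    if model_kind == "gru":
        h, cache = _gru_pass(params, x, H)
        return h, {"fw": cache}
    hf, cf = _lstm_pass(params, x, H, prefix="f_")
    hb, cb = _lstm_pass(params, x[::-1], H, prefix="b_")
    return np.concatenate([hf, hb]), {"fw": cf, "bw": cb}


def rnn_forward(model: RNNModel, x) -> np.ndarray:
    """Class scores (pre-softmax) for one input sequence (T, input_dim)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("input must be a non-empty (T, input_dim) sequence")
    if x.shape[1] != model.input_dim:
        raise ValueError(f"expected input_dim {model.input_dim}, got {x.shape[1]}")
    if model.mu is not None:
        x = (x - model.mu) / model.sd
    h, _ = _final_state(model.kind, model.params, x, model.hidden_dim)
    return model.params["Wy"] @ h + model.params["by"]


def rnn_predict(model: RNNModel, sequences) -> np.ndarray:
    return np.array([model.classes[int(np.argmax(rnn_forward(model, x)))] for x in sequences])


def _loss_and_grads(model: RNNModel, x: np.ndarray, target_idx: int, grads: dict) -> float:
    H = model.hidden_dim
    h, caches = _final_state(model.kind, model.params, x, H)
    scores = model.params["Wy"] @ h + model.params["by"]
    scores = scores - scores.max()
    e = np.exp(scores)
    probs = e / e.sum()
    loss = -float(np.log(max(probs[target_idx], 1e-300)))
    ds = probs.copy()
    ds[target_idx] -= 1.0
    grads["Wy"] += np.outer(ds, h)
    grads["by"] += ds
    dh = model.params["Wy"].T @ ds
    if model.kind == "lstm":
        _lstm_backward(model.params, caches["fw"], dh, H, grads)
    elif model.kind == "gru":
        _gru_backward(model.params, caches["fw"], dh, H, grads)
    else:
        _lstm_backward(model.params, caches["fw"], dh[:H], H, grads, prefix="f_")
        _lstm_backward(model.params, caches["bw"], dh[H:], H, grads, prefix="b_")
    return loss


def sequence_loss_and_gradients(model: RNNModel, x, label) -> tuple[float, dict]:
    """Cross-entropy loss and analytic BPTT gradients for one sequence.

    Exposed so the analytic gradients can be checked against finite
    differences; normalisation (mu/sd) is applied if the model carries it.
    """
    x = np.asarray(x, dtype=float)
    if model.mu is not None:
        x = (x - model.mu) / model.sd
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    idx = int(np.searchsorted(model.classes, label))
    loss = _loss_and_grads(model, x, idx, grads)
    return loss, grads


def _make_params(kind: str, D: int, H: int, C: int, rng) -> dict:
    if kind == "lstm":
        params = _init_gates(_LSTM_GATES, H, D, rng)
        readout_in = H
    elif kind == "gru":
        params = _init_gates(_GRU_GATES, H, D, rng)
        readout_in = H
    else:
        params = {}
        for prefix in ("f_", "b_"):
            for k, v in _init_gates(_LSTM_GATES, H, D, rng).items():
                params[prefix + k] = v
        readout_in = 2 * H
    params["Wy"] = rng.normal(0, 1.0 / np.sqrt(readout_in), size=(C, readout_in))
    params["by"] = np.zeros(C)
    return params


def rnn_fit(
    kind: str,
    sequences,
    labels,
    hidden_dim: int = 32,
    epochs: int = 200,
    learning_rate: float = 0.01,
    seed: int = 0,
    clip_norm: float = 5.0,
    normalize: bool = True,
) -> RNNModel:
    """Train a recurrent classifier by full-batch gradient descent with
    gradient clipping (global norm); deterministic given the seed."""
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    labels = np.asarray(labels)
    if not sequences or len(sequences) != len(labels):
        raise ValueError("sequences and labels must be non-empty and aligned")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    D = sequences[0].shape[1]
    if any(s.ndim != 2 or s.shape[1] != D for s in sequences):
        raise ValueError("all sequences must share the input dimension")
    rng = np.random.default_rng(seed)
    if normalize:
        stacked = np.vstack(sequences)
        mu = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu = sd = None
    model = RNNModel(
        kind=kind,
        input_dim=D,
        hidden_dim=hidden_dim,
        params=_make_params(kind, D, hidden_dim, len(classes), rng),
        classes=classes,
        mu=mu,
        sd=sd,
    )
    targets = np.searchsorted(classes, labels)
    n = len(sequences)
    for _ in range(epochs):
        grads = {k: np.zeros_like(v) for k, v in model.params.items()}
        total = 0.0
        for x, ti in zip(sequences, targets):
            xn = (x - mu) / sd if mu is not None else x
            total += _loss_and_grads(model, xn, int(ti), grads)
        total /= n
        if not np.isfinite(total):
            raise FloatingPointError(
                "training diverged (loss is not finite); reduce learning_rate"
            )
        gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values())) / n
        scale = (1.0 / n) * (clip_norm / gnorm if gnorm > clip_norm else 1.0)
        for k in model.params:
            model.params[k] -= learning_rate * scale * grads[k]
        model.loss_history.append(total)
    return model
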