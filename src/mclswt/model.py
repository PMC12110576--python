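"""Sliding-window transformer (SWT) for 2-class motor-imagery EEG.

Architecture, applied to a trial of T samples x C channels:

1. *Feature extractor* — temporal convolution (kernel ``temporal_kernel``
   x 1, valid, stride 1), spatial convolution (1 x C, collapsing the
   channel axis), batch normalization. Output: ``d_model`` features at
   L' = T - temporal_kernel + 1 time steps. No nonlinearity here; the
   front end plays the role of a learned filter bank + spatial filter.
2. *Windowed multi-head self-attention* — ``n_blocks`` pairs of
   transformer blocks. Each block is LN -> windowed multi-head
   attention -> residual, then LN -> MLP (GELU) -> residual. The first
   block of a pair partitions the L' time steps into contiguous
   windows of length M; the second cyclically shifts the window grid
   by M/2 so neighbouring windows exchange information. Restricting
   attention to windows makes the cost linear in L' instead of
   quadratic (see :func:`attention_cost`).
3. *Head* — elementwise square, average pooling over time, natural
   log, flatten (this flattened vector is the trial *embedding* used
   by the contrastive loss), fully connected layer, softmax.

Everything runs on the package's NumPy autodiff engine; a model is a
configuration plus a dict of named parameter tensors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, layer_norm, matmul
from .montage import EEGTrial

__all__ = [
    "ModelConfig",
    "SWTModel",
    "ModelOutput",
    "partition_windows",
    "attention_cost",
    "windowed_attention",
    "measure_attention_macs",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``d_model`` must be divisible by ``n_heads``; the post-convolution
    sequence length L' must be divisible by ``window_size`` (checked at
    forward time), and ``window_size`` must be even so the cyclic shift
    M/2 is integral.
    """

    temporal_kernel: int = 25
    d_model: int = 40
    n_heads: int = 8
    window_size: int = 8
    n_blocks: int = 1  # pairs of (windowed + shifted) attention blocks
    pool_kernel: int = 75
    pool_stride: int = 15
    mlp_hidden: int | None = None  # default 4 * d_model
    n_classes: int = 2
    n_channels: int = 3
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    ln_eps: float = 1e-5
    log_floor: float = 1e-6  # clamp for log(avgpool(square))
    dtype: str = "float32"

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.window_size % 2 != 0:
            raise ValueError("window_size must be even (cyclic shift is M/2)")
        if self.mlp_hidden is None:
            self.mlp_hidden = 4 * self.d_model
        if self.n_classes != 2:
            raise ValueError("only 2-class (left/right) models are supported")

    def seq_len(self, n_samples: int) -> int:
        if n_samples < self.temporal_kernel:
            raise ValueError(
                f"trial length {n_samples} is shorter than the temporal kernel "
                f"{self.temporal_kernel}"
            )
        return n_samples - self.temporal_kernel + 1

    def n_pool(self, n_samples: int) -> int:
        L = self.seq_len(n_samples)
        if L < self.pool_kernel:
            raise ValueError("sequence shorter than the pooling kernel")
        return (L - self.pool_kernel) // self.pool_stride + 1

    def embedding_dim(self, n_samples: int) -> int:
        return self.d_model * self.n_pool(n_samples)


@dataclass
class ModelOutput:
    """Forward-pass results (autodiff tensors)."""

    probs: Tensor  # (B, 2) softmax probabilities [p_left, p_right]
    logits: Tensor  # (B, 2)
    embedding: Tensor  # (B, embedding_dim): post-log, pre-FC features


def partition_windows(x: np.ndarray, window: int, axis: int = 0) -> np.ndarray:
    """Split a sequence into contiguous non-overlapping windows.

    The length along ``axis`` must be an exact multiple of ``window``
    (no silent padding); concatenating the windows in order
    reconstructs the sequence.
    """
    x = np.asarray(x)
    L = x.shape[axis]
    if window <= 0 or L % window != 0:
        raise ValueError(f"sequence length {L} is not divisible by window size {window}")
    axis = axis % x.ndim
    new_shape = x.shape[:axis] + (L // window, window) + x.shape[axis + 1 :]
    return x.reshape(new_shape)


def attention_cost(L: int, D: int, M: int) -> tuple[int, int]:
    """Multiply–accumulate counts of global vs windowed attention.

    Global multi-head self-attention over a length-L, dimension-D
    sequence costs ``4 L D^2 + 2 L^2 D`` (projections + the two L x L
    score/value products) — quadratic in L. A pair of windowed blocks
    with window M costs ``8 L D^2 + 4 M L D`` — linear in L.
    """
    omega_msa = 4 * L * D**2 + 2 * L**2 * D
    omega_wmsa = 8 * L * D**2 + 4 * M * L * D
    return omega_msa, omega_wmsa


_layer_norm = layer_norm


def windowed_attention(
    x: Tensor,
    wq: Tensor,
    wk: Tensor,
    wv: Tensor,
    wo: Tensor,
    wo_bias: Tensor,
    n_heads: int,
    window: int | None,
    shifted: bool = False,
    counter: list | None = None,
) -> Tensor:
    """Multi-head self-attention restricted to temporal windows.

    ``x`` has shape (B, L, D); ``window=None`` computes global
    attention (a single window of length L). When ``shifted``, the
    window grid is cyclically shifted by half a window before
    partitioning and the output is shifted back, so tokens near window
    boundaries attend across them. Returns the projected attention
    output (no residual, no LN — callers compose those).
    """
    B, L, D = x.shape
    M = L if window is None else window
    if L % M != 0:
        raise ValueError(f"sequence length {L} is not divisible by window size {M}")
    if D % n_heads != 0:
        raise ValueError("feature dimension not divisible by n_heads")
    dh = D // n_heads
    nW = L // M
    if shifted:
        x = x.roll(-(M // 2), axis=1)

    flat = x.reshape(B * L, D)

    def heads(w):
        y = matmul(flat, w, counter)
        return (
            y.reshape(B, nW, M, n_heads, dh)
            .transpose(0, 1, 3, 2, 4)
            .reshape(B * nW * n_heads, M, dh)
        )

    q, k, v = heads(wq), heads(wk), heads(wv)
    scores = matmul(q, k.transpose(0, 2, 1), counter) * (1.0 / np.sqrt(dh))
    att = scores.softmax(axis=-1)
    h = matmul(att, v, counter)
    merged = (
        h.reshape(B, nW, n_heads, M, dh).transpose(0, 1, 3, 2, 4).reshape(B * L, D)
    )
    out = (matmul(merged, wo, counter) + wo_bias).reshape(B, L, D)
    if shifted:
        out = out.roll(M // 2, axis=1)
    return out


class SWTModel:
    """The SWT network: parameters, buffers and the forward pass."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int | None = None):
        self.cfg = cfg
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        dt = np.dtype(cfg.dtype)

        def glorot(*shape):
            fan_in, fan_out = shape[0], shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-lim, lim, size=shape).astype(dt), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape, dtype=dt), requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape, dtype=dt), requires_grad=True)

        D, H = cfg.d_model, cfg.mlp_hidden
        p: dict[str, Tensor] = {
            "ct_w": glorot(cfg.temporal_kernel, D),
            "cs_w": glorot(cfg.n_channels * D, D),
            "bn_gamma": ones(D),
            "bn_beta": zeros(D),
        }
        for b in range(cfg.n_blocks):
            for s, tag in enumerate(("win", "shift")):
                pre = f"block{b}.{tag}."
                p[pre + "ln1_g"] = ones(D)
                p[pre + "ln1_b"] = zeros(D)
                for w in ("wq", "wk", "wv", "wo"):
                    p[pre + w] = glorot(D, D)
                p[pre + "wo_b"] = zeros(D)
                p[pre + "ln2_g"] = ones(D)
                p[pre + "ln2_b"] = zeros(D)
                p[pre + "mlp_w1"] = glorot(D, H)
                p[pre + "mlp_b1"] = zeros(H)
                p[pre + "mlp_w2"] = glorot(H, D)
                p[pre + "mlp_b2"] = zeros(D)
        self.params = p
        self._fc_built_for: int | None = None
        self._rng = rng
        # batch-norm running statistics (buffers, not trained)
        self.bn_mean = np.zeros(D, dtype=dt)
        self.bn_var = np.ones(D, dtype=dt)

    # -- parameter management -------------------------------------------------
    def _ensure_head(self, emb: int) -> None:
        if self._fc_built_for == emb:
            return
        if self._fc_built_for is not None:
            raise ValueError(
                f"model head was built for embedding dim {self._fc_built_for}, "
                f"got input requiring {emb}"
            )
        dt = np.dtype(self.cfg.dtype)
        lim = np.sqrt(6.0 / (emb + self.cfg.n_classes))
        self.params["fc_w"] = Tensor(
            self._rng.uniform(-lim, lim, size=(emb, self.cfg.n_classes)).astype(dt),
            requires_grad=True,
        )
        self.params["fc_b"] = Tensor(np.zeros(self.cfg.n_classes, dtype=dt), requires_grad=True)
        self._fc_built_for = emb

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.params.items()}
        d["__bn_mean"] = self.bn_mean.copy()
        d["__bn_var"] = self.bn_var.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        self.bn_mean = np.asarray(d["__bn_mean"]).copy()
        self.bn_var = np.asarray(d["__bn_var"]).copy()
        for k, v in d.items():
            if k.startswith("__"):
                continue
            if k in self.params:
                self.params[k].data = np.asarray(v).copy()
            else:  # lazily-built head
                self.params[k] = Tensor(np.asarray(v).copy(), requires_grad=True)
        if "fc_w" in self.params:
            self._fc_built_for = self.params["fc_w"].shape[0]

    def trainable(self) -> dict[str, Tensor]:
        return self.params

    # -- forward --------------------------------------------------------------
    def _features(self, x: Tensor, training: bool) -> Tensor:
        """Conv front end + BN: (B, T, C) -> (B, L', D)."""
        cfg = self.cfg
        B, T, C = x.shape
        if C != cfg.n_channels:
            raise ValueError(f"expected {cfg.n_channels} channels, got {C}")
        L = cfg.seq_len(T)
        K, D = cfg.temporal_kernel, cfg.d_model
        win = x.unfold(axis=1, size=K, step=1)  # (B, L, K, C)
        t1 = matmul(win.transpose(0, 1, 3, 2).reshape(B * L * C, K), self.params["ct_w"])
        t1 = t1.reshape(B, L, C, D).reshape(B * L, C * D)
        h = matmul(t1, self.params["cs_w"]).reshape(B, L, D)
        if training:
            mu = h.mean(axis=(0, 1))
            var = (h - mu).square().mean(axis=(0, 1))
            mom = cfg.bn_momentum
            self.bn_mean = ((1 - mom) * self.bn_mean + mom * mu.data).astype(self.bn_mean.dtype)
            self.bn_var = ((1 - mom) * self.bn_var + mom * var.data).astype(self.bn_var.dtype)
        else:
            mu, var = Tensor(self.bn_mean), Tensor(self.bn_var)
        hn = (h - mu) / (var + cfg.bn_eps).sqrt()
        return hn * self.params["bn_gamma"] + self.params["bn_beta"]

    def _attention(self, f: Tensor, counter: list | None = None) -> Tensor:
        cfg = self.cfg
        for b in range(cfg.n_blocks):
            for tag, shifted in (("win", False), ("shift", True)):
                p = {k: self.params[f"block{b}.{tag}.{k}"] for k in (
                    "ln1_g", "ln1_b", "wq", "wk", "wv", "wo", "wo_b",
                    "ln2_g", "ln2_b", "mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2",
                )}
                xn = _layer_norm(f, p["ln1_g"], p["ln1_b"], cfg.ln_eps)
                f = f + windowed_attention(
                    xn, p["wq"], p["wk"], p["wv"], p["wo"], p["wo_b"],
                    cfg.n_heads, cfg.window_size, shifted=shifted, counter=counter,
                )
                yn = _layer_norm(f, p["ln2_g"], p["ln2_b"], cfg.ln_eps)
                mlp = matmul(
                    (matmul(yn.reshape(-1, cfg.d_model), p["mlp_w1"]) + p["mlp_b1"]).gelu(),
                    p["mlp_w2"],
                ) + p["mlp_b2"]
                f = f + mlp.reshape(f.shape)
        return f

    def _head(self, a: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        cfg = self.cfg
        B = a.shape[0]
        pooled = a.square().unfold(axis=1, size=cfg.pool_kernel, step=cfg.pool_stride).mean(axis=2)
        emb = pooled.log(floor=cfg.log_floor).reshape(B, -1)
        self._ensure_head(emb.shape[1])
        logits = matmul(emb, self.params["fc_w"]) + self.params["fc_b"]
        return logits.softmax(axis=-1), logits, emb

    def forward(
        self,
        signals: np.ndarray,
        training: bool = False,
        mac_counter: list | None = None,
    ) -> ModelOutput:
        """Run the network on a batch of raw trials (B, T, C) in microvolts.

        In inference mode the output of each trial is independent of
        the batch composition (batch statistics are only consumed
        during training).
        """
        x = np.asarray(signals, dtype=self.cfg.dtype)
        if x.ndim == 2:
            x = x[None]
        f = self._features(Tensor(x), training)
        a = self._attention(f, counter=mac_counter)
        probs, logits, emb = self._head(a)
        return ModelOutput(probs=probs, logits=logits, embedding=emb)

    def predict_proba(self, trials: "list[EEGTrial] | np.ndarray") -> np.ndarray:
        """Inference-mode class probabilities [p_left, p_right] per trial."""
        sig = trials if isinstance(trials, np.ndarray) else np.stack([t.signal for t in trials])
        return self.forward(sig, training=False).probs.data.copy()


def measure_attention_macs(
    L: int,
    d_model: int,
    n_heads: int,
    window: int | None,
    seed: int = 0,
) -> int:
    """Empirical multiply–accumulate count of one (windowed + shifted) pair.

    Runs the attention layers on a single random length-L sequence and
    tallies the MACs of every matrix product actually executed
    (projections and score/value products). With a window M this is
    8 L D^2 + 4 M L D; with ``window=None`` (global) it is
    4 L D^2 + 2 L^2 D per block.
    """
    rng = np.random.default_rng(seed)
    D = d_model
    x = Tensor(rng.standard_normal((1, L, D)))
    w = {
        k: Tensor(rng.standard_normal((D, D)) / np.sqrt(D)) for k in ("wq", "wk", "wv", "wo")
    }
    bias = Tensor(np.zeros(D))
    counter = [0]
    if window is None:
        windowed_attention(x, w["wq"], w["wk"], w["wv"], w["wo"], bias,
                           n_heads, None, shifted=False, counter=counter)
    else:
        for shifted in (False, True):
            windowed_attention(x, w["wq"], w["wk"], w["wv"], w["wo"], bias,
                               n_heads, window, shifted=shifted, counter=counter)
    return counter[0]


def save_checkpoint(path, model: SWTModel) -> None:
    """Write weights + config to a portable NPZ checkpoint."""
    np.savez(
        path,
        __config=np.array(json.dumps(asdict(model.cfg))),
        **{k.replace(".", "/"): v for k, v in model.state_dict().items()},
    )


def load_checkpoint(path) -> SWTModel:
    with np.load(path, allow_pickle=False) as d:
        cfg = ModelConfig(**json.loads(str(d["__config"])))
        state = {k.replace("/", "."): d[k] for k in d.files if k != "__config"}
    model = SWTModel(cfg, rng=0)
    model.load_state_dict(state)
    return model
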