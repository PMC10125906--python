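"""Size-configurable BERT-style encoder with span-masked MLM pre-training.

The encoder follows the standard transformer encoder block: multi-head
scaled-dot-product self-attention

    head_i = softmax(M W_i^Q (M W_i^K)^T / sqrt(d_k)) . M W_i^V
    MultiHead(M) = Concat(head_1, ..., head_h) W^O

with residual connections, post-layer normalization and a GELU feed-forward
sublayer.  Forward and backward passes are written directly in NumPy (float64)
so that training is exactly reproducible on CPU and small configurations can
be verified element-by-element against brute-force oracles.

Pre-training uses masked language modelling with *span* masking: because
overlapping k-mer tokens leak their neighbours' bases, a masked region always
covers k consecutive tokens, so no masked nucleotide is recoverable from an
unmasked overlapping token.  The default mask rate is 15%.

The pre-training corpus mimics genome-scale corpora at desk scale: a genome
string is tiled left-to-right into non-overlapping pieces, half (in
expectation) of length exactly 510 bp and half of uniform random length in
[10, 509] bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import math

import numpy as np
from scipy.special import erf

from .seqio import DnaSequence, KmerVocabulary, TokenizedSequence, tokenize

LN_EPS = 1e-5
INIT_STD = 0.02

# Corpus piece lengths: half exactly FULL_PIECE, half uniform in [MIN_PIECE, FULL_PIECE - 1].
FULL_PIECE = 510
MIN_PIECE = 10

DEFAULT_MASK_RATE = 0.15


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the encoder.

    The published architecture is 12 layers x 12 heads x 768 dimensions with a
    510-content-token limit; the desk default used throughout the tests is
    2 x 4 x 64 with a 256-token limit.
    """

    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    max_tokens: int = 256
    vocab_size: int = 69
    ffn_dim: int | None = None
    seed: int = 0
    dtype: str = "float64"  # "float32" roughly halves training time on CPU

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.max_tokens < 3:
            raise ValueError("max_tokens must be >= 3")
        if self.ffn_dim is None:
            object.__setattr__(self, "ffn_dim", 4 * self.embed_dim)

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    @classmethod
    def paper_default(cls, vocab_size: int, seed: int = 0) -> "EncoderConfig":
        return cls(
            n_layers=12, n_heads=12, embed_dim=768, max_tokens=510,
            vocab_size=vocab_size, seed=seed,
        )


@dataclass
class EncoderState:
    """Parameters of the encoder: a flat name -> array dict plus its config."""

    config: EncoderConfig
    params: dict[str, np.ndarray]

    def copy(self) -> "EncoderState":
        return EncoderState(self.config, {k: v.copy() for k, v in self.params.items()})


@dataclass(frozen=True)
class MaskedInstance:
    """One MLM training instance: inputs with [MASK]s, targets, positions."""

    input_ids: tuple[int, ...]
    target_ids: tuple[int, ...]
    positions: tuple[int, ...]


def init_encoder(config: EncoderConfig) -> EncoderState:
    """Deterministically initialize encoder parameters under ``config.seed``.

    Weights ~ N(0, 0.02^2); biases zero; layer-norm gains one.  Two inits with
    the same config are parameter-identical.
    """
    rng = np.random.default_rng(config.seed)
    D, F, V = config.embed_dim, config.ffn_dim, config.vocab_size
    P = config.max_tokens + 2  # room for [CLS] and [SEP]
    dt = np.dtype(config.dtype)

    def w(*shape: int) -> np.ndarray:
        return rng.normal(0.0, INIT_STD, size=shape).astype(dt)

    def ones(n: int) -> np.ndarray:
        return np.ones(n, dtype=dt)

    def zeros(n: int) -> np.ndarray:
        return np.zeros(n, dtype=dt)

    p: dict[str, np.ndarray] = {
        "tok_emb": w(V, D),
        "pos_emb": w(P, D),
        "ln_e.g": ones(D),
        "ln_e.b": zeros(D),
    }
    for l in range(config.n_layers):
        pre = f"l{l}."
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = w(D, D)
            p[pre + name.replace("W", "b")] = zeros(D)
        p[pre + "ln1.g"] = ones(D)
        p[pre + "ln1.b"] = zeros(D)
        p[pre + "Wf1"] = w(D, F)
        p[pre + "bf1"] = zeros(F)
        p[pre + "Wf2"] = w(F, D)
        p[pre + "bf2"] = zeros(D)
        p[pre + "ln2.g"] = ones(D)
        p[pre + "ln2.b"] = zeros(D)
    p["mlm.W"] = w(D, V)
    p["mlm.b"] = zeros(V)
    return EncoderState(config, p)


# ---------------------------------------------------------------------------
# numerical primitives
# ---------------------------------------------------------------------------

def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x * (1.0 / math.sqrt(2.0))))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return (0.5 * (1.0 + erf(x * (1.0 / math.sqrt(2.0))))
            + x * np.exp(-0.5 * x * x) * (1.0 / math.sqrt(2.0 * math.pi)))


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_backward(dy: np.ndarray, g: np.ndarray, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    B, T, D = x.shape
    return x.reshape(B, T, h, D // h).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, h, T, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def forward_batch(
    state: EncoderState,
    ids: np.ndarray,
    lengths: np.ndarray,
    need_cache: bool = False,
    drop_rng: np.random.Generator | None = None,
    dropout: float = 0.0,
):
    """Run the encoder on a padded id batch.

    Parameters
    ----------
    ids : (B, T) integer array, right-padded with [PAD].
    lengths : (B,) true token counts (including [CLS]/[SEP]).

    Returns ``(hidden, attentions, cache)`` where hidden is (B, T, D),
    attentions is a list of per-layer (B, h, T, T) row-stochastic maps, and
    cache holds intermediates for :func:`backward_batch` (None unless
    requested).
    """
    cfg = state.config
    p = state.params
    B, T = ids.shape
    if T > cfg.max_tokens + 2:
        raise ValueError(
            f"input of {T} tokens exceeds limit {cfg.max_tokens + 2}; segment long sequences"
        )
    h, dk = cfg.n_heads, cfg.head_dim

    dt = p["tok_emb"].dtype
    key_mask = np.arange(T)[None, :] < lengths[:, None]  # (B, T) True where real
    attn_bias = np.where(key_mask, 0.0, -1e30)[:, None, None, :].astype(dt)  # (B,1,1,T)

    E = p["tok_emb"][ids] + p["pos_emb"][:T][None, :, :]
    X, ln_e_cache = _layernorm(E, p["ln_e.g"], p["ln_e.b"])

    # standard BERT-style dropout on attention probabilities and sublayer
    # outputs, active only when a generator is supplied (training)
    use_drop = drop_rng is not None and dropout > 0.0
    keep = 1.0 - dropout

    def drop_mask(shape):
        return (drop_rng.random(shape) >= dropout).astype(dt) / keep

    attentions = []
    layer_caches = []
    for l in range(cfg.n_layers):
        pre = f"l{l}."
        X0 = X
        Q = X0 @ p[pre + "Wq"] + p[pre + "bq"]
        K = X0 @ p[pre + "Wk"] + p[pre + "bk"]
        V = X0 @ p[pre + "Wv"] + p[pre + "bv"]
        Qh, Kh, Vh = (_split_heads(a, h) for a in (Q, K, V))
        S = Qh @ Kh.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(dk)) + attn_bias
        A = _softmax(S)
        if use_drop:
            m_attn = drop_mask(A.shape)
            m_o = drop_mask((B, T, cfg.embed_dim))
            m_f = drop_mask((B, T, cfg.embed_dim))
        else:
            m_attn = m_o = m_f = None
        Ad = A * m_attn if use_drop else A
        Ctx = _merge_heads(Ad @ Vh)
        O = Ctx @ p[pre + "Wo"] + p[pre + "bo"]
        if use_drop:
            O = O * m_o
        R1 = X0 + O
        X1, ln1_cache = _layernorm(R1, p[pre + "ln1.g"], p[pre + "ln1.b"])
        F1 = X1 @ p[pre + "Wf1"] + p[pre + "bf1"]
        G = _gelu(F1)
        F2 = G @ p[pre + "Wf2"] + p[pre + "bf2"]
        if use_drop:
            F2 = F2 * m_f
        R2 = X1 + F2
        X, ln2_cache = _layernorm(R2, p[pre + "ln2.g"], p[pre + "ln2.b"])
        attentions.append(A)
        if need_cache:
            layer_caches.append((X0, Qh, Kh, Vh, A, Ctx, ln1_cache, X1, F1, G,
                                 ln2_cache, (m_attn, m_o, m_f)))

    cache = None
    if need_cache:
        cache = {"ids": ids, "ln_e": ln_e_cache, "layers": layer_caches, "T": T}
    return X, attentions, cache


def backward_batch(state: EncoderState, cache, dX: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagate a gradient w.r.t. the final hidden states through the encoder."""
    cfg = state.config
    p = state.params
    h, dk = cfg.n_heads, cfg.head_dim
    grads: dict[str, np.ndarray] = {}

    def axsum(a: np.ndarray) -> np.ndarray:
        return a.sum(axis=tuple(range(a.ndim - 1)))

    for l in reversed(range(cfg.n_layers)):
        pre = f"l{l}."
        (X0, Qh, Kh, Vh, A, Ctx, ln1_cache, X1, F1, G, ln2_cache,
         drop_masks) = cache["layers"][l]
        m_attn, m_o, m_f = drop_masks
        dR2, grads[pre + "ln2.g"], grads[pre + "ln2.b"] = _layernorm_backward(
            dX, p[pre + "ln2.g"], ln2_cache
        )
        dF2 = dR2 * m_f if m_f is not None else dR2
        grads[pre + "Wf2"] = np.tensordot(G, dF2, axes=([0, 1], [0, 1]))
        grads[pre + "bf2"] = axsum(dF2)
        dG = dF2 @ p[pre + "Wf2"].T
        dF1 = dG * _gelu_grad(F1)
        grads[pre + "Wf1"] = np.tensordot(X1, dF1, axes=([0, 1], [0, 1]))
        grads[pre + "bf1"] = axsum(dF1)
        dX1 = dR2 + dF1 @ p[pre + "Wf1"].T
        dR1, grads[pre + "ln1.g"], grads[pre + "ln1.b"] = _layernorm_backward(
            dX1, p[pre + "ln1.g"], ln1_cache
        )
        dO = dR1 * m_o if m_o is not None else dR1
        grads[pre + "Wo"] = np.tensordot(Ctx, dO, axes=([0, 1], [0, 1]))
        grads[pre + "bo"] = axsum(dO)
        dCtx = _split_heads(dO @ p[pre + "Wo"].T, h)
        Ad = A * m_attn if m_attn is not None else A
        dAd = dCtx @ Vh.transpose(0, 1, 3, 2)
        dA = dAd * m_attn if m_attn is not None else dAd
        dVh = Ad.transpose(0, 1, 3, 2) @ dCtx
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQh = dS @ Kh * (1.0 / math.sqrt(dk))
        dKh = dS.transpose(0, 1, 3, 2) @ Qh * (1.0 / math.sqrt(dk))
        dQ, dK, dV = (_merge_heads(a) for a in (dQh, dKh, dVh))
        dX = dR1
        for name, d in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            grads[pre + name] = np.tensordot(X0, d, axes=([0, 1], [0, 1]))
            grads[pre + name.replace("W", "b")] = axsum(d)
            dX = dX + d @ p[pre + name].T

    dE, grads["ln_e.g"], grads["ln_e.b"] = _layernorm_backward(dX, p["ln_e.g"], cache["ln_e"])
    ids = cache["ids"]
    dtok = np.zeros_like(p["tok_emb"])
    np.add.at(dtok, ids.ravel(), dE.reshape(-1, dE.shape[-1]))
    grads["tok_emb"] = dtok
    grads["pos_emb"] = np.zeros_like(p["pos_emb"])
    grads["pos_emb"][: cache["T"]] = dE.sum(axis=0)
    return grads


def forward(state: EncoderState, tokens: TokenizedSequence):
    """Encode a single tokenized sequence.

    Returns ``(embeddings, attention)`` where embeddings is (T, embed_dim) and
    attention is (n_layers, n_heads, T, T) with every row summing to 1.
    """
    ids = np.array([tokens.token_ids])
    lengths = np.array([len(tokens.token_ids)])
    H, attns, _ = forward_batch(state, ids, lengths)
    return H[0], np.stack([a[0] for a in attns])


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled weight decay (AdamW) and exponential LR decay.

    Weight decay applies to weight matrices and embeddings only; biases and
    layer-norm parameters are exempt, following standard transformer
    practice.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, lr_decay: float = 1.0,
                 weight_decay: float = 0.0):
        self.lr0 = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.decayed = {k for k, v in params.items()
                        if v.ndim >= 2 or k.endswith("emb")}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k in self.decayed:
                params[k] -= self.lr * self.weight_decay * params[k]

    def decay_epoch(self) -> None:
        self.lr *= self.lr_decay


# ---------------------------------------------------------------------------
# pre-training corpus and span masking
# ---------------------------------------------------------------------------

def make_pretrain_corpus(genome: str, seed: int = 0) -> list[str]:
    """Tile a genome string into non-overlapping MLM corpus pieces.

    Piece lengths are drawn i.i.d.: with probability 1/2 exactly 510 bp and
    with probability 1/2 uniform in [10, 509] bp, so the expected count ratio
    of full to short pieces is 1:1.  A trailing remainder shorter than 10 bp
    is discarded.  Deterministic under *seed*.
    """
    if len(genome) < FULL_PIECE + MIN_PIECE:
        raise ValueError(f"genome shorter than minimum {FULL_PIECE + MIN_PIECE} bp")
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    pos = 0
    n = len(genome)
    while n - pos >= MIN_PIECE:
        if rng.random() < 0.5:
            length = FULL_PIECE
        else:
            length = int(rng.integers(MIN_PIECE, FULL_PIECE))
        length = min(length, n - pos)
        pieces.append(genome[pos : pos + length])
        pos += length
    return pieces


def apply_span_mask(
    tokens: TokenizedSequence,
    vocab: KmerVocabulary,
    rate: float = DEFAULT_MASK_RATE,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bert_mix: bool = False,
) -> MaskedInstance:
    """Mask spans of k consecutive k-mer tokens at the given rate.

    Spans of exactly k tokens (truncated at the right boundary) are placed by
    rejection-sampling non-overlapping start positions until at least
    ``floor(rate * n_kmers)`` tokens are masked, with a minimum of one span.
    [CLS] and [SEP] are never masked.  By default every selected token is
    replaced by [MASK]; with ``bert_mix`` the standard 80/10/10
    mask/random/keep mix is applied instead.
    """
    if not (0 < rate < 1):
        raise ValueError("mask rate must be in (0, 1)")
    k, n = tokens.k, tokens.n_kmers
    if n < k:
        raise ValueError(f"sequence has {n} k-mer tokens, fewer than span width k={k}")
    if rng is None:
        rng = np.random.default_rng(seed)
    target = max(int(np.floor(rate * n)), 1)
    occupied = np.zeros(n, dtype=bool)
    masked = 0
    attempts = 0
    while masked < target and attempts < 100 * n:
        attempts += 1
        start = int(rng.integers(0, n - k + 1))
        if occupied[start : start + k].any():
            continue
        occupied[start : start + k] = True
        masked += k
    if masked < target:
        # rejection sampling starved: sweep the remaining holes left to right,
        # truncating the final span at the boundary if needed
        for start in range(n):
            if masked >= target:
                break
            end = min(start + k, n)
            if not occupied[start:end].any():
                occupied[start:end] = True
                masked += end - start
    if masked < target:
        raise ValueError("mask rate incompatible with sequence length")
    positions = tuple(int(i) + 1 for i in np.flatnonzero(occupied))  # +1 skips [CLS]
    ids = list(tokens.token_ids)
    targets = tuple(ids[i] for i in positions)
    n_kmer_vocab = vocab.size - len(vocab.special_ids)
    for i in positions:
        if bert_mix:
            u = rng.random()
            if u < 0.8:
                ids[i] = vocab.mask_id
            elif u < 0.9:
                ids[i] = len(vocab.special_ids) + int(rng.integers(n_kmer_vocab))
            # else: keep original token
        else:
            ids[i] = vocab.mask_id
    return MaskedInstance(input_ids=tuple(ids), target_ids=targets, positions=positions)


# ---------------------------------------------------------------------------
# MLM training
# ---------------------------------------------------------------------------

def _mlm_loss_and_grad(state: EncoderState, batch: list[MaskedInstance], train: bool = True,
                       drop_rng: np.random.Generator | None = None,
                       dropout: float = 0.0):
    """Cross-entropy over masked positions; returns (loss, n_masked, grads)."""
    p = state.params
    pad = 1  # [PAD] id is 1 by vocabulary construction
    lengths = np.array([len(b.input_ids) for b in batch])
    T = int(lengths.max())
    ids = np.full((len(batch), T), pad, dtype=np.int64)
    for i, b in enumerate(batch):
        ids[i, : lengths[i]] = b.input_ids
    H, _, cache = forward_batch(state, ids, lengths, need_cache=train,
                                drop_rng=drop_rng, dropout=dropout)

    rows, cols, targets = [], [], []
    for i, b in enumerate(batch):
        rows.extend([i] * len(b.positions))
        cols.extend(b.positions)
        targets.extend(b.target_ids)
    rows = np.array(rows)
    cols = np.array(cols)
    targets = np.array(targets)
    Hm = H[rows, cols]  # (M, D)
    logits = Hm @ p["mlm.W"] + p["mlm.b"]
    probs = _softmax(logits)
    M = len(targets)
    loss = -np.log(np.clip(probs[np.arange(M), targets], 1e-300, None)).mean()
    n_correct = int((logits.argmax(axis=1) == targets).sum())
    if not train:
        return loss, M, n_correct, None
    dlogits = probs.copy()
    dlogits[np.arange(M), targets] -= 1.0
    dlogits /= M
    grads = {"mlm.W": Hm.T @ dlogits, "mlm.b": dlogits.sum(axis=0)}
    dH = np.zeros_like(H)
    dH[rows, cols] = dlogits @ p["mlm.W"].T
    grads.update(backward_batch(state, cache, dH))
    return loss, M, n_correct, grads


@dataclass
class MlmHyper:
    """Hyperparameters for MLM pre-training."""

    epochs: int = 3
    batch: int = 32
    lr: float = 1e-4
    lr_decay: float = 1.0
    weight_decay: float = 0.01
    encoder_dropout: float = 0.1
    rate: float = DEFAULT_MASK_RATE
    seed: int = 0
    bert_mix: bool = False


def pretrain_mlm(
    state: EncoderState,
    corpus: Sequence[str],
    vocab: KmerVocabulary,
    hyper: MlmHyper,
    log=None,
) -> EncoderState:
    """Pre-train the encoder on a corpus with span-masked language modelling.

    Each corpus piece is tokenized with *vocab* and truncated to the encoder's
    token limit; masking is re-drawn every epoch.  Returns the updated state
    (the input state is not modified); with ``epochs=0`` the returned state is
    an identical copy.  Per-epoch mean masked-token cross-entropy is passed to
    *log* if given.
    """
    if not corpus:
        raise ValueError("empty pre-training corpus")
    state = state.copy()
    if hyper.epochs == 0:
        return state
    cfg = state.config
    k = vocab.k
    toks: list[TokenizedSequence] = []
    for i, piece in enumerate(corpus):
        if len(piece) < 2 * k:  # need at least one span of k tokens
            continue
        t = tokenize(DnaSequence(id=f"piece{i}", bases=piece), vocab)
        if t.n_kmers > cfg.max_tokens:
            t = TokenizedSequence(
                k=k,
                token_ids=t.token_ids[: cfg.max_tokens + 1] + (vocab.sep_id,),
                bases=piece[: cfg.max_tokens + k - 1],
            )
        toks.append(t)
    if not toks:
        raise ValueError("corpus has no piece long enough to mask")
    rng = np.random.default_rng(hyper.seed)
    opt = Adam(state.params, lr=hyper.lr, lr_decay=hyper.lr_decay,
               weight_decay=hyper.weight_decay)
    # group similar lengths into batches to limit padding waste
    order0 = np.argsort([t.n_kmers for t in toks], kind="stable")
    for epoch in range(hyper.epochs):
        starts = np.arange(0, len(toks), hyper.batch)
        rng.shuffle(starts)
        total, count = 0.0, 0
        for s in starts:
            idx = order0[s : s + hyper.batch]
            batch = [
                apply_span_mask(toks[i], vocab, rate=hyper.rate, rng=rng,
                                bert_mix=hyper.bert_mix)
                for i in idx
            ]
            loss, M, _, grads = _mlm_loss_and_grad(
                state, batch, drop_rng=rng, dropout=hyper.encoder_dropout)
            if not np.isfinite(loss):
                raise FloatingPointError(f"MLM loss diverged at epoch {epoch}")
            opt.step(state.params, grads)
            total += loss * M
            count += M
        opt.decay_epoch()
        if log is not None:
            log(epoch, total / count)
    return state


def mlm_eval(
    state: EncoderState,
    pieces: Sequence[str],
    vocab: KmerVocabulary,
    rate: float = DEFAULT_MASK_RATE,
    seed: int = 0,
) -> tuple[float, float]:
    """Held-out masked-token cross-entropy and accuracy on the given pieces."""
    rng = np.random.default_rng(seed)
    cap = state.config.max_tokens
    k = vocab.k
    total, count, correct = 0.0, 0, 0
    for i in range(0, len(pieces), 32):
        chunk = pieces[i : i + 32]
        batch = []
        for j, piece in enumerate(chunk):
            t = tokenize(DnaSequence(id=f"eval{i + j}", bases=piece), vocab)
            if t.n_kmers > cap:
                t = TokenizedSequence(
                    k=k, token_ids=t.token_ids[: cap + 1] + (vocab.sep_id,),
                    bases=piece[: cap + k - 1])
            batch.append(apply_span_mask(t, vocab, rate=rate, rng=rng))
        loss, M, n_correct, _ = _mlm_loss_and_grad(state, batch, train=False)
        total += loss * M
        count += M
        correct += n_correct
    return total / count, correct / count


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_encoder(state: EncoderState, path: str | Path) -> None:
    """Serialize parameters plus embedded config as an .npz archive."""
    cfg = {k: v for k, v in state.config.__dict__.items()}
    np.savez(path, __config__=json.dumps(cfg), **state.params)


def load_encoder(path: str | Path) -> EncoderState:
    with np.load(path) as z:
        cfg = EncoderConfig(**json.loads(str(z["__config__"])))
        params = {k: z[k] for k in z.files if k != "__config__"}
    return EncoderState(cfg, params)
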