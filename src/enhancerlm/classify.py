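"""Sequence representation, MLP classification head, fine-tuning and ensembling.

Short sequences (those fitting the encoder's token limit) are represented by
the arithmetic mean of the embedding vectors of their k-mer tokens — [CLS]
and [SEP] are excluded.  Long sequences are partitioned left-to-right into
non-overlapping segments of 500 k-mer tokens (the last may be shorter), each
segment is encoded independently with its own [CLS]/[SEP] and mean-pooled,
and the segment means are concatenated and zero-padded to 4 x embed_dim
(3072 at the published 768-dim configuration).

The classifier is a 2-layer perceptron (hidden layer with dropout 0.3,
logistic output).  Training minimizes mean binary cross-entropy plus an L2
penalty on the classifier-head weights,

    Loss = (1/N) sum_i [ -y_i log p_i - (1 - y_i) log(1 - p_i) ] + lambda ||W||_2^2 ,

with Adam and an exponentially decaying learning rate.  A sequence is called
an enhancer iff its predicted probability strictly exceeds the decision
threshold (default 0.55).

Per-scale models (k = 3..6) are combined into a multi-scale ensemble; the
default integration rule averages member probabilities (majority voting is
available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import encoder as enc
from .seqio import DnaSequence, KmerVocabulary, TokenizedSequence, tokenize

DEFAULT_THRESHOLD = 0.55
DEFAULT_DROPOUT = 0.3
PROB_CLAMP = 1e-7
SEGMENT_TOKENS = 500
N_SEGMENTS = 4


@dataclass(frozen=True)
class SequenceRepresentation:
    vector: np.ndarray
    mode: str  # "short" | "long"


@dataclass
class ClassifierHead:
    """2-layer perceptron: hidden (ReLU, dropout) then logistic output unit.

    The hidden size follows the published setup: 25 units for fixed-length
    (short-mode) datasets, 128 for variable-length (long-mode) datasets.
    """

    params: dict[str, np.ndarray]
    dropout: float = DEFAULT_DROPOUT

    @classmethod
    def init(cls, in_dim: int, hidden: int, seed: int = 0,
             dropout: float = DEFAULT_DROPOUT) -> "ClassifierHead":
        rng = np.random.default_rng(seed)
        p = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, 1)),
            "b2": np.zeros(1),
        }
        return cls(params=p, dropout=dropout)

    def copy(self) -> "ClassifierHead":
        return ClassifierHead({k: v.copy() for k, v in self.params.items()}, self.dropout)

    def weight_sq_sum(self) -> float:
        return float((self.params["W1"] ** 2).sum() + (self.params["W2"] ** 2).sum())


def _head_forward(head: ClassifierHead, X: np.ndarray,
                  drop_rng: np.random.Generator | None = None):
    """Forward the head on (B, in_dim); inverted dropout when drop_rng given."""
    p = head.params
    Z1 = X @ p["W1"] + p["b1"]
    Hid = np.maximum(Z1, 0.0)
    if drop_rng is not None and head.dropout > 0:
        keep = (drop_rng.random(Hid.shape) >= head.dropout) / (1.0 - head.dropout)
        Hid = Hid * keep
    else:
        keep = None
    logit = (Hid @ p["W2"] + p["b2"]).ravel()
    prob = 1.0 / (1.0 + np.exp(-logit))
    return prob, (X, Z1, Hid, keep)


def _head_backward(head: ClassifierHead, cache, dlogit: np.ndarray):
    p = head.params
    X, Z1, Hid, keep = cache
    dlogit = dlogit[:, None]
    grads = {"W2": Hid.T @ dlogit, "b2": dlogit.sum(axis=0)}
    dHid = dlogit @ p["W2"].T
    if keep is not None:
        dHid = dHid * keep
    dZ1 = dHid * (Z1 > 0)
    grads["W1"] = X.T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    dX = dZ1 @ p["W1"].T
    return grads, dX


# ---------------------------------------------------------------------------
# representations
# ---------------------------------------------------------------------------

def represent_short(embeddings: np.ndarray, tokens: TokenizedSequence) -> SequenceRepresentation:
    """Mean-pool the k-mer token embeddings of one encoded sequence.

    ``embeddings`` is the (T, embed_dim) encoder output for *tokens*; rows 0
    and T-1 ([CLS], [SEP]) are excluded from the mean.
    """
    if tokens.n_kmers < 1:
        raise ValueError("sequence has no k-mer tokens")
    return SequenceRepresentation(embeddings[1:-1].mean(axis=0), "short")


def segment_tokens(tokens: TokenizedSequence, vocab: KmerVocabulary,
                   seg: int = SEGMENT_TOKENS) -> list[TokenizedSequence]:
    """Split k-mer tokens into consecutive blocks of *seg*, re-adding [CLS]/[SEP]."""
    kmers = tokens.kmer_ids
    out = []
    for i in range(0, len(kmers), seg):
        block = kmers[i : i + seg]
        out.append(TokenizedSequence(
            k=tokens.k,
            token_ids=(vocab.cls_id,) + block + (vocab.sep_id,),
            bases=tokens.bases[i : i + len(block) + tokens.k - 1],
        ))
    return out


def represent_long(
    seq: DnaSequence,
    state: enc.EncoderState,
    vocab: KmerVocabulary,
    segment_len: int = SEGMENT_TOKENS,
) -> SequenceRepresentation:
    """Segment-encode a variable-length sequence into a 4 x embed_dim vector.

    Tokens are split left-to-right into blocks of *segment_len* k-mer tokens
    (the last may be shorter); each block is encoded independently and
    mean-pooled; means are concatenated in order and the vector zero-padded
    to 4 x embed_dim for sequences with fewer than four segments.
    """
    D = state.config.embed_dim
    toks = tokenize(seq, vocab)
    blocks = segment_tokens(toks, vocab, segment_len)[:N_SEGMENTS]
    vec = np.zeros(N_SEGMENTS * D)
    for i, block in enumerate(blocks):
        H, _ = enc.forward(state, block)
        vec[i * D : (i + 1) * D] = H[1:-1].mean(axis=0)
    return SequenceRepresentation(vec, "long")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def compute_loss(y: np.ndarray, p: np.ndarray, lam: float = 0.0,
                 head: ClassifierHead | None = None) -> float:
    """Mean binary cross-entropy plus lambda times the head's summed squared weights."""
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be in {0, 1}")
    p = np.clip(np.asarray(p, dtype=float), PROB_CLAMP, 1.0 - PROB_CLAMP)
    ce = float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())
    reg = lam * head.weight_sq_sum() if head is not None else 0.0
    return ce + reg


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

@dataclass
class FinetuneHyper:
    """Fine-tuning hyperparameters (Adam, exponentially decaying LR)."""

    epochs: int = 30
    batch: int = 32
    lr: float = 1e-3
    head_lr: float = 5e-3
    lr_decay: float = 0.85
    weight_decay: float = 0.01
    encoder_dropout: float = 0.1
    dropout: float = DEFAULT_DROPOUT
    lam: float = 1e-5
    mask_augment: float = 0.15  # span-mask input corruption during training
    seed: int = 0
    freeze_encoder: bool = False


@dataclass
class FineTunedModel:
    """A fine-tuned per-scale model: encoder, head, vocabulary, mode."""

    state: enc.EncoderState
    head: ClassifierHead
    vocab: KmerVocabulary
    mode: str = "short"
    segment_len: int = SEGMENT_TOKENS

    @property
    def k(self) -> int:
        return self.vocab.k


def _pad_batch(toks: list[TokenizedSequence], pad_id: int):
    lengths = np.array([len(t.token_ids) for t in toks])
    T = int(lengths.max())
    ids = np.full((len(toks), T), pad_id, dtype=np.int64)
    for i, t in enumerate(toks):
        ids[i, : lengths[i]] = t.token_ids
    return ids, lengths


def _represent_batch_train(state, toks, pad_id, drop_rng=None, dropout=0.0):
    """Encode a batch with cache and return (reps, pooling info) for backprop."""
    ids, lengths = _pad_batch(toks, pad_id)
    H, _, cache = enc.forward_batch(state, ids, lengths, need_cache=True,
                                    drop_rng=drop_rng, dropout=dropout)
    n_kmers = lengths - 2
    # mean over rows 1..length-2 of each sequence
    mask = (np.arange(ids.shape[1])[None, :] >= 1) & (
        np.arange(ids.shape[1])[None, :] < (lengths - 1)[:, None]
    )
    reps = (H * mask[:, :, None]).sum(axis=1) / n_kmers[:, None]
    return reps, (cache, mask, n_kmers, H.shape)


def finetune(
    state: enc.EncoderState,
    head: ClassifierHead,
    train_seqs: Sequence[DnaSequence],
    train_labels: np.ndarray,
    vocab: KmerVocabulary,
    hyper: FinetuneHyper,
    mode: str = "short",
    log=None,
    val_seqs: Sequence[DnaSequence] | None = None,
    val_labels: np.ndarray | None = None,
) -> FineTunedModel:
    """Fine-tune encoder + head on a labeled dataset.

    With ``hyper.freeze_encoder`` only the head is updated and the encoder
    parameters are returned bitwise unchanged.  ``epochs=0`` returns both
    unchanged.  Currently trains in short mode (one segment per sequence);
    long-mode representation is available for inference via
    :func:`represent_long`.
    """
    labels = np.asarray(train_labels, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    state = state.copy()
    head = head.copy()
    head.dropout = hyper.dropout
    model = FineTunedModel(state=state, head=head, vocab=vocab, mode=mode)
    if hyper.epochs == 0:
        return model
    toks = [tokenize(s, vocab) for s in train_seqs]
    rng = np.random.default_rng(hyper.seed)
    opt_head = enc.Adam(head.params, lr=hyper.head_lr, lr_decay=hyper.lr_decay)
    opt_enc = None
    if not hyper.freeze_encoder:
        opt_enc = enc.Adam(state.params, lr=hyper.lr, lr_decay=hyper.lr_decay,
                           weight_decay=hyper.weight_decay)
    n = len(toks)
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, hyper.batch):
            idx = order[s : s + hyper.batch]
            batch_toks = [toks[i] for i in idx]
            if hyper.mask_augment > 0:
                # span-mask input corruption: the same corruption used for
                # MLM pre-training, applied as augmentation against
                # sequence memorization (labels unchanged)
                corrupted = []
                for t in batch_toks:
                    inst = enc.apply_span_mask(t, vocab, rate=hyper.mask_augment,
                                               rng=rng)
                    corrupted.append(TokenizedSequence(
                        k=t.k, token_ids=inst.input_ids, bases=t.bases))
                batch_toks = corrupted
            y = labels[idx]
            if hyper.freeze_encoder:
                ids, lengths = _pad_batch(batch_toks, vocab.pad_id)
                H, _, _ = enc.forward_batch(state, ids, lengths)
                mask = (np.arange(ids.shape[1])[None, :] >= 1) & (
                    np.arange(ids.shape[1])[None, :] < (lengths - 1)[:, None]
                )
                reps = (H * mask[:, :, None]).sum(axis=1) / (lengths - 2)[:, None]
                pool = None
            else:
                reps, pool = _represent_batch_train(
                    state, batch_toks, vocab.pad_id,
                    drop_rng=rng, dropout=hyper.encoder_dropout)
            prob, hcache = _head_forward(head, reps, drop_rng=rng)
            pc = np.clip(prob, PROB_CLAMP, 1.0 - PROB_CLAMP)
            loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
            loss += hyper.lam * head.weight_sq_sum()
            if not np.isfinite(loss):
                raise FloatingPointError(f"loss diverged at epoch {epoch}")
            total += loss * len(idx)
            dlogit = (prob - y) / len(idx)  # sigmoid + BCE
            hgrads, dreps = _head_backward(head, hcache, dlogit)
            hgrads["W1"] += 2.0 * hyper.lam * head.params["W1"]
            hgrads["W2"] += 2.0 * hyper.lam * head.params["W2"]
            if opt_enc is not None:
                cache, mask, n_kmers, hshape = pool
                dH = np.zeros(hshape, dtype=state.params["tok_emb"].dtype)
                dH += mask[:, :, None] * (dreps / n_kmers[:, None])[:, None, :]
                egrads = enc.backward_batch(state, cache, dH)
                opt_enc.step(state.params, egrads)
            opt_head.step(head.params, hgrads)
        opt_head.decay_epoch()
        if opt_enc is not None:
            opt_enc.decay_epoch()
        if log is not None:
            val_loss = None
            if val_seqs is not None and val_labels is not None:
                vp, _ = predict(model, val_seqs)
                val_loss = compute_loss(val_labels, vp)
            log(epoch, total / n, val_loss)
    return model


def stratified_split(labels: np.ndarray, val_fraction: float = 0.1, seed: int = 0):
    """Stratified validation/training index split (default ratio 1:9)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    val_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.extend(idx[:n_val].tolist())
    val = np.array(sorted(val_idx))
    train = np.array([i for i in range(len(labels)) if i not in set(val_idx)])
    return train, val


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_proba(model: FineTunedModel, seqs: Sequence[DnaSequence],
                  batch: int = 64) -> np.ndarray:
    """Predicted enhancer probability per sequence (dropout off)."""
    vocab = model.vocab
    if model.mode == "long":
        reps = np.stack([
            represent_long(s, model.state, vocab, model.segment_len).vector for s in seqs
        ])
        prob, _ = _head_forward(model.head, reps)
        return prob
    probs = []
    toks = [tokenize(s, vocab) for s in seqs]
    order = np.argsort([len(t.token_ids) for t in toks], kind="stable")
    out = np.empty(len(seqs))
    for s in range(0, len(seqs), batch):
        idx = order[s : s + batch]
        ids, lengths = _pad_batch([toks[i] for i in idx], vocab.pad_id)
        H, _, _ = enc.forward_batch(model.state, ids, lengths)
        mask = (np.arange(ids.shape[1])[None, :] >= 1) & (
            np.arange(ids.shape[1])[None, :] < (lengths - 1)[:, None]
        )
        reps = (H * mask[:, :, None]).sum(axis=1) / (lengths - 2)[:, None]
        prob, _ = _head_forward(model.head, reps)
        out[idx] = prob
    return out


def predict(model: FineTunedModel, seqs: Sequence[DnaSequence],
            threshold: float = DEFAULT_THRESHOLD):
    """Per-sequence (probability, label); label 1 iff probability > threshold."""
    prob = predict_proba(model, seqs)
    return prob, (prob > threshold).astype(int)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: FineTunedModel, path) -> None:
    """Serialize encoder + head + config + vocabulary as one .npz archive."""
    import json

    import numpy as _np

    meta = {
        "k": model.vocab.k,
        "mode": model.mode,
        "segment_len": model.segment_len,
        "dropout": model.head.dropout,
        "config": dict(model.state.config.__dict__),
    }
    payload = {f"enc.{k}": v for k, v in model.state.params.items()}
    payload.update({f"head.{k}": v for k, v in model.head.params.items()})
    _np.savez(path, __meta__=json.dumps(meta), **payload)


def load_model(path) -> FineTunedModel:
    import json

    import numpy as _np

    from .seqio import build_vocabulary

    with _np.load(path) as z:
        meta = json.loads(str(z["__meta__"]))
        enc_params = {k[4:]: z[k] for k in z.files if k.startswith("enc.")}
        head_params = {k[5:]: z[k] for k in z.files if k.startswith("head.")}
    state = enc.EncoderState(enc.EncoderConfig(**meta["config"]), enc_params)
    head = ClassifierHead(params=head_params, dropout=meta["dropout"])
    return FineTunedModel(
        state=state, head=head, vocab=build_vocabulary(meta["k"]),
        mode=meta["mode"], segment_len=meta["segment_len"],
    )


# ---------------------------------------------------------------------------
# multi-scale ensemble
# ---------------------------------------------------------------------------

@dataclass
class ScaleEnsemble:
    """Multi-scale combination of per-k fine-tuned models.

    mode="mean" (default): the ensemble probability is the arithmetic mean of
    member probabilities and the threshold applies to it.  mode="vote": each
    member casts its thresholded label; majority wins, ties go to
    non-enhancer; the reported probability is still the member mean.
    """

    members: dict[int, FineTunedModel]
    mode: str = "mean"
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("ensemble needs at least 2 member models")
        if self.mode not in ("mean", "vote"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")


def ensemble_predict(ensemble: ScaleEnsemble, seqs: Sequence[DnaSequence]):
    """Combined (probability, label) per sequence."""
    member_probs = np.stack([
        predict_proba(m, seqs) for _, m in sorted(ensemble.members.items())
    ])
    prob = member_probs.mean(axis=0)
    if ensemble.mode == "mean":
        labels = (prob > ensemble.threshold).astype(int)
    else:
        votes = (member_probs > ensemble.threshold).sum(axis=0)
        labels = (votes * 2 > member_probs.shape[0]).astype(int)  # tie -> 0
    return prob, labels
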