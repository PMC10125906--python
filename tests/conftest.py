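import numpy as np
import pytest

import enhancerlm as elm
from enhancerlm import classify as cls
from enhancerlm import encoder as enc
from enhancerlm import metrics as met
from enhancerlm import simulate as sim
from enhancerlm.cli import discover_from_model

SEED = 1


@pytest.fixture(scope="session")
def vocab3():
    return elm.build_vocabulary(3)


@pytest.fixture(scope="session")
def desk_state(vocab3):
    """A small randomly-initialized encoder shared by read-only tests."""
    cfg = enc.EncoderConfig(n_layers=2, n_heads=4, embed_dim=64,
                            max_tokens=256, vocab_size=vocab3.size, seed=SEED)
    return enc.init_encoder(cfg)


@pytest.fixture(scope="session")
def e2e_run():
    """Full pipeline at study conditions, run once per session.

    Simulates 300+300 train and test 200-bp sequences with the width-10
    motif planted in 90% of positives; pre-trains a 2-layer/4-head/64-dim
    encoder (k = 6) on a 1 Mb synthetic genome (2 epochs of span-masked
    MLM); fine-tunes 30 epochs; predicts on the test set; and runs
    attention-based motif discovery on the training positives.
    """
    train_seqs, _ = sim.make_dataset(sim.DatasetSpec(n_pos=300, n_neg=300, seed=SEED))
    test_seqs, _ = sim.make_dataset(sim.DatasetSpec(n_pos=300, n_neg=300, seed=SEED + 1000))
    y = np.array([1] * 300 + [0] * 300)
    genome = sim.make_genome(1_000_000, seed=SEED + 2000)
    corpus = enc.make_pretrain_corpus(genome, seed=SEED + 3000)
    vocab = elm.build_vocabulary(6)
    cfg = enc.EncoderConfig(n_layers=2, n_heads=4, embed_dim=64,
                            max_tokens=256, vocab_size=vocab.size,
                            seed=SEED, dtype="float32")
    state = enc.init_encoder(cfg)
    state = enc.pretrain_mlm(state, corpus, vocab, enc.MlmHyper(epochs=2, seed=SEED))
    head = cls.ClassifierHead.init(cfg.embed_dim, 25, seed=SEED)
    model = cls.finetune(state, head, train_seqs, y, vocab,
                         cls.FinetuneHyper(epochs=30, seed=SEED))
    prob, _ = cls.predict(model, test_seqs)
    report = met.evaluate(y, prob)
    _, train_labels = cls.predict(model, train_seqs, threshold=0.5)
    motif_result = discover_from_model(model, train_seqs, y)
    return {
        "model": model,
        "report": report,
        "prob": prob,
        "labels": y,
        "train_acc": float((train_labels == y).mean()),
        "motifs": motif_result,
        "consensus": sim.DEFAULT_CONSENSUS,
    }


def min_hamming_to(consensus: str, discovered: str) -> int:
    """Smallest Hamming distance between *consensus* and any equal-length
    window of *discovered* (inf if discovered is shorter)."""
    W = len(consensus)
    if len(discovered) < W:
        return len(consensus) + 1
    return min(
        sum(a != b for a, b in zip(discovered[i : i + W], consensus))
        for i in range(len(discovered) - W + 1)
    )
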