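"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with scalar loops and exact rational
arithmetic, independent of the package's vectorized implementations.
"""

import math
from fractions import Fraction


def bruteforce_encoder_attention(params, config, token_ids):
    """Scalar-loop recomputation of every layer's attention maps.

    Recomputes embedding lookup, layer normalization, Q/K/V projections,
    scaled dot-product scores, row softmax, head concatenation, output
    projection, residuals and the GELU feed-forward sublayer with plain
    Python floats.  Returns attention as nested lists
    [layer][head][query][key].
    """
    D = config.embed_dim
    h = config.n_heads
    dk = D // h
    T = len(token_ids)
    eps = 1e-5

    def layernorm(rows, g, b):
        out = []
        for row in rows:
            mu = sum(row) / D
            var = sum((x - mu) ** 2 for x in row) / D
            inv = 1.0 / math.sqrt(var + eps)
            out.append([g[j] * (x - mu) * inv + b[j] for j, x in enumerate(row)])
        return out

    def affine(rows, W, b):
        n_out = len(b)
        return [
            [sum(row[i] * W[i][j] for i in range(len(row))) + b[j] for j in range(n_out)]
            for row in rows
        ]

    def gelu(x):
        return 0.5 * x * (1.0 + math.erf(x / math.sqrt(2.0)))

    # embeddings
    X = [
        [params["tok_emb"][tid][j] + params["pos_emb"][t][j] for j in range(D)]
        for t, tid in enumerate(token_ids)
    ]
    X = layernorm(X, params["ln_e.g"], params["ln_e.b"])

    attention = []
    for l in range(config.n_layers):
        pre = f"l{l}."
        Q = affine(X, params[pre + "Wq"], params[pre + "bq"])
        K = affine(X, params[pre + "Wk"], params[pre + "bk"])
        V = affine(X, params[pre + "Wv"], params[pre + "bv"])
        layer_attn = []
        ctx = [[0.0] * D for _ in range(T)]
        for head in range(h):
            lo = head * dk
            head_attn = []
            for q in range(T):
                scores = [
                    sum(Q[q][lo + d] * K[kk][lo + d] for d in range(dk)) / math.sqrt(dk)
                    for kk in range(T)
                ]
                mx = max(scores)
                exps = [math.exp(s - mx) for s in scores]
                z = sum(exps)
                row = [e / z for e in exps]
                head_attn.append(row)
                for d in range(dk):
                    ctx[q][lo + d] = sum(row[kk] * V[kk][lo + d] for kk in range(T))
            layer_attn.append(head_attn)
        attention.append(layer_attn)
        O = affine(ctx, params[pre + "Wo"], params[pre + "bo"])
        R1 = [[X[t][j] + O[t][j] for j in range(D)] for t in range(T)]
        X1 = layernorm(R1, params[pre + "ln1.g"], params[pre + "ln1.b"])
        F1 = affine(X1, params[pre + "Wf1"], params[pre + "bf1"])
        G = [[gelu(x) for x in row] for row in F1]
        F2 = affine(G, params[pre + "Wf2"], params[pre + "bf2"])
        R2 = [[X1[t][j] + F2[t][j] for j in range(D)] for t in range(T)]
        X = layernorm(R2, params[pre + "ln2.g"], params[pre + "ln2.b"])
    return attention


def hypergeom_tail_exact(k, N, K, n) -> Fraction:
    """Exact rational upper tail P(X >= k) of the hypergeometric(N, K, n)."""
    total = math.comb(N, n)
    return Fraction(
        sum(math.comb(K, j) * math.comb(N - K, n - j)
            for j in range(max(k, 0), min(K, n) + 1)),
        total,
    )


def naive_containment(patterns, sequences, labels):
    """Direct substring scan: per-pattern (n, k) presence counts."""
    out = {}
    for pat in patterns:
        n = sum(1 for s in sequences if pat in s.bases)
        k = sum(1 for s, y in zip(sequences, labels) if y == 1 and pat in s.bases)
        out[pat] = (n, k)
    return out


def pairwise_auc(labels, scores) -> float:
    """AUC by exhaustive enumeration of (positive, negative) pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
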