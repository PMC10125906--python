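"""DNA sequence I/O, validation, k-mer vocabularies and overlapping tokenization.

Enhancer sequences are treated as sentences whose words are overlapping
k-mers: a sequence of length ``L`` yields ``L - k + 1`` tokens produced by a
sliding window of size ``k``.  The vocabulary for word size ``k`` holds the
``4**k`` k-mers plus five special tokens ([CLS], [PAD], [UNK], [SEP], [MASK]),
so its size is ``4**k + 5``.

Coordinates are 0-based half-open internally; user-facing reports (candidate
tables, truth tables) use 1-based inclusive coordinates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

DNA_ALPHABET = "ACGT"

#: IUPAC ambiguity codes and the concrete bases they stand for.
IUPAC_CODES = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SPECIAL_TOKENS = ("[CLS]", "[PAD]", "[UNK]", "[SEP]", "[MASK]")


class SequenceError(ValueError):
    """Raised for malformed or unusable DNA input."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence over the alphabet {A, C, G, T}."""

    id: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.bases)


@dataclass(frozen=True)
class KmerVocabulary:
    """Bijection between k-mer/special tokens and integer ids.

    Specials come first in the fixed order [CLS], [PAD], [UNK], [SEP], [MASK]
    so that serialized vocabularies are reproducible; k-mers follow in
    lexicographic order.
    """

    k: int
    token_to_id: dict[str, int]
    id_to_token: tuple[str, ...] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.id_to_token)

    @property
    def cls_id(self) -> int:
        return self.token_to_id["[CLS]"]

    @property
    def pad_id(self) -> int:
        return self.token_to_id["[PAD]"]

    @property
    def unk_id(self) -> int:
        return self.token_to_id["[UNK]"]

    @property
    def sep_id(self) -> int:
        return self.token_to_id["[SEP]"]

    @property
    def mask_id(self) -> int:
        return self.token_to_id["[MASK]"]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.token_to_id[t] for t in SPECIAL_TOKENS)

    def id(self, token: str) -> int:
        return self.token_to_id[token]

    def token(self, token_id: int) -> str:
        return self.id_to_token[token_id]


@dataclass(frozen=True)
class TokenizedSequence:
    """Token ids of one sequence: [CLS], the L-k+1 k-mer ids, [SEP]."""

    k: int
    token_ids: tuple[int, ...]
    bases: str

    @property
    def n_kmers(self) -> int:
        return len(self.token_ids) - 2

    @property
    def kmer_ids(self) -> tuple[int, ...]:
        return self.token_ids[1:-1]


def validate_sequence(
    raw: str,
    policy: str = "reject",
    seed: int | None = None,
    id: str = "seq",
) -> DnaSequence:
    """Validate and normalize a raw nucleotide string.

    policy="reject" refuses any non-ACGT character; policy="replace" swaps
    each IUPAC ambiguity code for a random base among the bases it denotes,
    deterministically under *seed* (used when building pre-training corpora
    from genome assemblies that contain Ns).
    """
    if not raw:
        raise SequenceError("empty sequence")
    if policy not in ("reject", "replace"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    bases = raw.upper()
    bad = set(bases) - set(DNA_ALPHABET) - set(IUPAC_CODES)
    if bad:
        raise SequenceError(f"non-IUPAC characters in sequence {id!r}: {sorted(bad)}")
    if set(bases) <= set(DNA_ALPHABET):
        return DnaSequence(id=id, bases=bases)
    if policy == "reject":
        raise SequenceError(f"ambiguous bases in sequence {id!r} with policy='reject'")
    rng = np.random.default_rng(seed)
    out = [
        b if b in DNA_ALPHABET else IUPAC_CODES[b][rng.integers(len(IUPAC_CODES[b]))]
        for b in bases
    ]
    return DnaSequence(id=id, bases="".join(out))


def build_vocabulary(k: int) -> KmerVocabulary:
    """Build the k-mer vocabulary: 5 special tokens then 4**k k-mers.

    The usual word sizes are 3-6; other k >= 1 work but trigger a warning
    since the vocabulary grows as 4**k.
    """
    if k < 1:
        raise ValueError(f"word size k must be >= 1, got {k}")
    if k not in (3, 4, 5, 6):
        warnings.warn(f"word size k={k} is outside the usual range 3-6", stacklevel=2)
    kmers = ("".join(p) for p in itertools.product(DNA_ALPHABET, repeat=k))
    tokens = SPECIAL_TOKENS + tuple(kmers)
    return KmerVocabulary(
        k=k,
        token_to_id={t: i for i, t in enumerate(tokens)},
        id_to_token=tokens,
    )


def tokenize(seq: DnaSequence, vocab: KmerVocabulary) -> TokenizedSequence:
    """Slide a window of size k over the sequence; prepend [CLS], append [SEP]."""
    k = vocab.k
    if seq.length < k:
        raise SequenceError(
            f"sequence {seq.id!r} of length {seq.length} is shorter than k={k}"
        )
    ids = [vocab.cls_id]
    t2i = vocab.token_to_id
    b = seq.bases
    ids.extend(t2i[b[i : i + k]] for i in range(seq.length - k + 1))
    ids.append(vocab.sep_id)
    return TokenizedSequence(k=k, token_ids=tuple(ids), bases=b)


def detokenize(tokens: TokenizedSequence, vocab: KmerVocabulary) -> str:
    """Reconstruct the nucleotide string from overlapping k-mer tokens."""
    kmers = [vocab.token(i) for i in tokens.kmer_ids]
    if not kmers:
        raise SequenceError("no k-mer tokens to detokenize")
    return kmers[0] + "".join(km[-1] for km in kmers[1:])


# ---------------------------------------------------------------------------
# FASTA and prediction I/O
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    policy: str = "reject",
    seed: int | None = None,
) -> list[DnaSequence]:
    """Read a FASTA file into validated sequences, preserving record order.

    Multi-line records are concatenated.  Duplicate ids are kept but suffixed
    ``.2``, ``.3``, ... with a warning.
    """
    seqs: list[DnaSequence] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = rec.id
        if not rec_id:
            raise SequenceError(f"malformed FASTA header in {path}")
        n = seen.get(rec_id, 0) + 1
        seen[rec_id] = n
        if n > 1:
            warnings.warn(f"duplicate FASTA id {rec_id!r}; suffixing", stacklevel=2)
            rec_id = f"{rec_id}.{n}"
        seqs.append(validate_sequence(str(rec.seq), policy=policy, seed=seed, id=rec_id))
    return seqs


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a sidecar label TSV (id<TAB>label with label in {0,1})."""
    labels: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("id\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise SequenceError(f"malformed label line: {line!r}")
        lab = int(fields[1])
        if lab not in (0, 1):
            raise SequenceError(f"label must be 0 or 1, got {lab}")
        labels[fields[0]] = lab
    return labels


def labels_for(seqs: Sequence[DnaSequence], path: str | Path | None = None) -> np.ndarray:
    """Resolve labels for sequences from a sidecar TSV or header convention.

    The header convention encodes the label as a ``|label=0`` / ``|label=1``
    suffix on the record id.
    """
    if path is not None:
        table = read_labels(path)
        missing = [s.id for s in seqs if s.id not in table]
        if missing:
            raise SequenceError(f"labels missing for ids: {missing[:5]}")
        return np.array([table[s.id] for s in seqs], dtype=int)
    labels = []
    for s in seqs:
        if "|label=" not in s.id:
            raise SequenceError(
                f"no label file given and id {s.id!r} has no '|label=' suffix"
            )
        labels.append(int(s.id.rsplit("|label=", 1)[1]))
    return np.array(labels, dtype=int)


def write_predictions(
    records: Iterable[tuple[str, float, int]],
    path: str | Path,
    precision: int = 6,
) -> None:
    """Write per-sequence predictions as a TSV with columns id, probability, label."""
    lines = ["id\tprobability\tlabel"]
    lines += [f"{rid}\t{prob:.{precision}f}\t{lab}" for rid, prob, lab in records]
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> list[tuple[str, float, int]]:
    """Read a predictions TSV written by :func:`write_predictions`."""
    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        rid, prob, lab = line.split("\t")
        out.append((rid, float(prob), int(lab)))
    return out


def write_fasta(seqs: Iterable[DnaSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences in FASTA, wrapping lines at *width* columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")
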