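"""Synthetic data: background DNA, planted-motif datasets, genome-like corpora.

The generator stands in for benchmark downloads at desk scale.  It emulates
the two benchmark shapes: fixed-length two-class datasets (200 bp, as in
genome-wide enhancer catalogues cropped to a uniform window) and
variable-length datasets (204-2000 bp).  Positive sequences carry one
instance sampled from a planted position-weight matrix at a uniform random
admissible position with a configurable plant probability (default 0.9);
negatives are pure background.  Background is i.i.d. uniform by default; an
order-1 Markov background is available for harder fixtures.

A genome-like background string feeds the MLM corpus splitter for
pre-training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import DNA_ALPHABET, DnaSequence, write_fasta

#: Planted motif used throughout the packaged fixtures: a width-10 motif
#: planted as its exact consensus by default (one-hot PWM; the classic
#: (l,0) planted-motif model).  Noisier instances are available by lowering
#: the per-column strength.
DEFAULT_CONSENSUS = "TGACGTCATC"
DEFAULT_PLANT_PROB = 0.9


def pwm_from_consensus(consensus: str, strength: float = 1.0) -> np.ndarray:
    """A 4 x W PWM putting *strength* on the consensus base per column."""
    if not (0.25 <= strength <= 1.0):
        raise ValueError("strength must be in [0.25, 1]")
    W = len(consensus)
    mat = np.full((4, W), (1.0 - strength) / 3.0)
    for j, b in enumerate(consensus):
        mat[DNA_ALPHABET.index(b), j] = strength
    return mat


@dataclass(frozen=True)
class DatasetSpec:
    """Shape and composition of a synthetic two-class dataset."""

    n_pos: int = 300
    n_neg: int = 300
    length: int = 200
    length_max: int | None = None  # if set: uniform lengths in [length, length_max]
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_pwm: np.ndarray = field(default_factory=lambda: pwm_from_consensus(DEFAULT_CONSENSUS))
    plant_prob: float = DEFAULT_PLANT_PROB
    markov1: np.ndarray | None = None  # optional 4x4 transition matrix
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant probability must be in [0, 1]")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated sequence (1-based inclusive plant coords)."""

    id: str
    label: int
    plant_start: int | None
    plant_end: int | None
    motif_id: str | None


def _sample_bases(rng: np.random.Generator, length: int, freqs,
                  markov1: np.ndarray | None = None) -> str:
    if length < 1:
        raise ValueError("length must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("base frequencies must be 4 non-negative values summing to 1")
    if markov1 is None:
        idx = rng.choice(4, size=length, p=freqs)
    else:
        idx = np.empty(length, dtype=int)
        idx[0] = rng.choice(4, p=freqs)
        for i in range(1, length):
            idx[i] = rng.choice(4, p=markov1[idx[i - 1]])
    return "".join(DNA_ALPHABET[i] for i in idx)


def sample_background(length: int, freqs=(0.25, 0.25, 0.25, 0.25),
                      seed: int = 0, id: str = "bg") -> DnaSequence:
    """An i.i.d. background sequence, deterministic under *seed*."""
    rng = np.random.default_rng(seed)
    return DnaSequence(id=id, bases=_sample_bases(rng, length, freqs))


def sample_motif(pwm: np.ndarray, rng: np.random.Generator) -> str:
    """One motif instance: per-column draw from the PWM."""
    return "".join(
        DNA_ALPHABET[rng.choice(4, p=pwm[:, j] / pwm[:, j].sum())]
        for j in range(pwm.shape[1])
    )


def make_dataset(spec: DatasetSpec) -> tuple[list[DnaSequence], list[TruthRecord]]:
    """Generate a labeled dataset plus its ground-truth table.

    Positives receive one PWM-sampled motif instance at a uniform random
    admissible position with probability ``spec.plant_prob``; negatives are
    pure background.  Ids carry the label as an ``|label=`` suffix so the
    FASTA is self-describing.
    """
    rng = np.random.default_rng(spec.seed)
    W = spec.motif_pwm.shape[1]
    seqs: list[DnaSequence] = []
    truth: list[TruthRecord] = []

    def draw_length() -> int:
        if spec.length_max is None:
            return spec.length
        return int(rng.integers(spec.length, spec.length_max + 1))

    for i in range(spec.n_pos):
        L = draw_length()
        if W > L:
            raise ValueError(f"motif width {W} exceeds sequence length {L}")
        bases = _sample_bases(rng, L, spec.base_freqs, spec.markov1)
        sid = f"pos_{i}|label=1"
        if rng.random() < spec.plant_prob:
            start = int(rng.integers(0, L - W + 1))
            inst = sample_motif(spec.motif_pwm, rng)
            bases = bases[:start] + inst + bases[start + W :]
            truth.append(TruthRecord(sid, 1, start + 1, start + W, "motif_0"))
        else:
            truth.append(TruthRecord(sid, 1, None, None, None))
        seqs.append(DnaSequence(id=sid, bases=bases))
    for i in range(spec.n_neg):
        L = draw_length()
        sid = f"neg_{i}|label=0"
        seqs.append(DnaSequence(id=sid, bases=_sample_bases(rng, L, spec.base_freqs, spec.markov1)))
        truth.append(TruthRecord(sid, 0, None, None, None))
    return seqs, truth


def make_genome(total_length: int, freqs=(0.25, 0.25, 0.25, 0.25),
                seed: int = 0) -> str:
    """A genome-like background string for the MLM corpus splitter."""
    if total_length < 520:
        raise ValueError("genome must be at least 520 bp")
    rng = np.random.default_rng(seed)
    return _sample_bases(rng, total_length, freqs)


def write_dataset(seqs: Sequence[DnaSequence], truth: Sequence[TruthRecord],
                  fasta_path: str | Path, truth_path: str | Path) -> None:
    """Write the FASTA plus the sidecar truth/label TSV."""
    write_fasta(seqs, fasta_path)
    lines = ["id\tlabel\tplant_start\tplant_end\tmotif_id"]
    for t in truth:
        lines.append("\t".join([
            t.id, str(t.label),
            "" if t.plant_start is None else str(t.plant_start),
            "" if t.plant_end is None else str(t.plant_end),
            t.motif_id or "",
        ]))
    Path(truth_path).write_text("\n".join(lines) + "\n")
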