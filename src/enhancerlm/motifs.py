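"""Attention-based motif discovery.

Four steps turn a fine-tuned enhancer language model's attention into
position-weight-matrix motifs:

1. *Nucleotide attention.*  The head matrices of the last encoder layer are
   averaged elementwise; the [CLS]-query row scores each k-mer token's
   importance to the whole sequence.  Each token's attention is split equally
   among its k covered nucleotides, and a nucleotide's weight is the mean of
   the contributions it receives (edge positions are covered by fewer
   tokens).

2. *Candidate patterns.*  Maximal runs of positions whose weight strictly
   exceeds the profile mean, allowing at most one interior position at or
   below the mean (a "gap"), are kept when at least 5 nt long.  Each core is
   expanded by up to 10 nt on both sides (clipped to the sequence) to give
   alignment context; candidates with coincident expanded intervals are
   de-duplicated.

3. *Enrichment filtering.*  For each candidate core substring X, a single
   Aho–Corasick pass counts n = sequences containing X and k = positive
   sequences containing X (per-sequence presence).  The hypergeometric
   upper-tail probability P(X >= k) for drawing n sequences from N with K
   positives is the default statistic; candidates with p < 0.005 are kept.
   (The literal one-minus-single-PMF-term variant is available as
   mode="literal"; it is not a tail probability and is kept only for
   comparison.)  The core drives the test; the expanded substring drives the
   alignment, which is what the expansion exists for.

4. *Grouping and PWMs.*  Candidates are grouped by iterative ungapped
   pairwise alignment around a core member (longest; ties broken by
   frequency then lexicographically); a candidate joins a group when its
   best-offset matches strictly exceed half the overlap length.  Groups with
   fewer than 11 members are discarded; the rest become PWMs by per-column
   base frequencies over covering members, trimmed to columns covered by at
   least half the members.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .seqio import DNA_ALPHABET, DnaSequence, TokenizedSequence

SIGNIFICANCE = 0.005
MIN_CORE_LEN = 5
EXPAND = 10
MIN_GROUP_MEMBERS = 11

BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}


@dataclass(frozen=True)
class NucleotideAttentionProfile:
    """Per-position attention weights w_1..w_L for one sequence."""

    seq_id: str
    weights: np.ndarray


@dataclass(frozen=True)
class CandidatePattern:
    """A high-attention region: core (the tested pattern) plus expansion.

    Intervals are 0-based half-open internally; `as_report_row` emits 1-based
    inclusive coordinates.
    """

    seq_id: str
    core_start: int
    core_end: int
    start: int
    end: int
    core: str
    expanded: str

    def as_report_row(self) -> tuple:
        return (self.seq_id, self.core_start + 1, self.core_end,
                self.start + 1, self.end, self.core)


@dataclass(frozen=True)
class EnrichmentTest:
    """Hypergeometric test of pattern X: k of K positives vs n of N sequences."""

    pattern: str
    K: int
    k: int
    N: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)) or self.n > self.N:
            raise ValueError(f"impossible counts for {self.pattern!r}: "
                             f"k={self.k}, K={self.K}, n={self.n}, N={self.N}")
        if self.n - self.k > self.N - self.K:
            raise ValueError("more negative containments than negatives")


@dataclass
class MotifGroup:
    """Aligned candidate substrings with per-member offsets relative to the core."""

    core: str
    members: list[str]
    offsets: list[int]


@dataclass(frozen=True)
class PWM:
    """4 x W matrix of per-position base frequencies (rows A, C, G, T)."""

    matrix: np.ndarray
    nsites: int

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.matrix.argmax(axis=0))


# ---------------------------------------------------------------------------
# Step 1: nucleotide attention
# ---------------------------------------------------------------------------

def nucleotide_attention(
    attn: np.ndarray, tokens: TokenizedSequence, seq_id: str = "seq"
) -> NucleotideAttentionProfile:
    """Distribute [CLS]-row attention of the last layer onto nucleotides.

    ``attn`` is the (n_layers, n_heads, T, T) attention tensor of one forward
    pass.  The last layer's heads are averaged; entry [0, j] of the average is
    the attention from [CLS] to token j.  Token j (1-based position j in the
    sequence) covers nucleotides j..j+k-1 and contributes a_j / k to each;
    the profile value at a position is the mean of its contributions.
    """
    if attn.ndim != 4:
        raise ValueError("expected attention indexed [layer][head][query][key]")
    k, n = tokens.k, tokens.n_kmers
    L = n + k - 1
    avg = attn[-1].mean(axis=0)  # average heads of the last layer
    cls_row = avg[0, 1 : n + 1]  # [CLS] -> k-mer tokens
    contrib = np.zeros(L)
    count = np.zeros(L, dtype=int)
    for j in range(n):
        contrib[j : j + k] += cls_row[j] / k
        count[j : j + k] += 1
    return NucleotideAttentionProfile(seq_id=seq_id, weights=contrib / count)


# ---------------------------------------------------------------------------
# Step 2: candidate patterns
# ---------------------------------------------------------------------------

def _above_mean_runs(above: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i, L = 0, len(above)
    while i < L:
        if above[i]:
            j = i
            while j < L and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def find_candidates(
    profile: NucleotideAttentionProfile,
    seq: DnaSequence,
    expand: int = EXPAND,
    min_len: int = MIN_CORE_LEN,
) -> list[CandidatePattern]:
    """Extract high-attention pattern candidates from one attention profile.

    Cores are maximal runs of positions strictly above the profile mean,
    optionally bridging exactly one interior at-or-below-mean position; runs
    never start or end on such a gap.  Cores shorter than *min_len* are
    dropped; survivors are expanded by *expand* nt per side (clipped).
    Candidates from one sequence whose expanded intervals coincide are
    de-duplicated (overlapping but distinct candidates are kept separate:
    collapsing them into one long region makes the later pairwise alignment
    ineffective, since members would share only a small fraction of their
    length).
    """
    w = profile.weights
    L = len(w)
    if L != seq.length:
        raise ValueError("profile length does not match sequence length")
    mean = w.mean()
    base_runs = _above_mean_runs(w > mean)
    cores = list(base_runs)
    for (s1, e1), (s2, e2) in zip(base_runs, base_runs[1:]):
        if s2 - e1 == 1:  # exactly one gap position between the runs
            cores.append((s1, e2))
    out = []
    seen: set[tuple[int, int]] = set()
    for s, e in sorted(cores):
        if e - s < min_len:
            continue
        xs, xe = max(0, s - expand), min(L, e + expand)
        if (xs, xe) in seen:
            continue
        seen.add((xs, xe))
        out.append(CandidatePattern(
            seq_id=seq.id, core_start=s, core_end=e, start=xs, end=xe,
            core=seq.bases[s:e], expanded=seq.bases[xs:xe],
        ))
    return out


# ---------------------------------------------------------------------------
# Step 3: Aho–Corasick containment counting and enrichment
# ---------------------------------------------------------------------------

class AhoCorasick:
    """Multi-pattern string automaton (goto/fail/output construction)."""

    def __init__(self, patterns: Sequence[str]):
        if any(not p for p in patterns):
            raise ValueError("empty pattern")
        self.patterns = list(dict.fromkeys(patterns))  # dedupe, keep order
        self.goto: list[dict[str, int]] = [{}]
        self.out: list[set[int]] = [set()]
        for pi, pat in enumerate(self.patterns):
            node = 0
            for ch in pat:
                nxt = self.goto[node].get(ch)
                if nxt is None:
                    self.goto.append({})
                    self.out.append(set())
                    nxt = len(self.goto) - 1
                    self.goto[node][ch] = nxt
                node = nxt
            self.out[node].add(pi)
        self.fail = [0] * len(self.goto)
        queue = deque(self.goto[0].values())
        while queue:
            node = queue.popleft()
            for ch, nxt in self.goto[node].items():
                queue.append(nxt)
                f = self.fail[node]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[nxt] = self.goto[f].get(ch, 0) if self.goto[f].get(ch, 0) != nxt else 0
                self.out[nxt] |= self.out[self.fail[nxt]]

    def found_in(self, text: str) -> set[int]:
        """Indices of patterns occurring at least once in *text*."""
        node = 0
        hits: set[int] = set()
        for ch in text:
            while node and ch not in self.goto[node]:
                node = self.fail[node]
            node = self.goto[node].get(ch, 0)
            if self.out[node]:
                hits |= self.out[node]
        return hits


def count_containing(
    patterns: Sequence[str],
    sequences: Sequence[DnaSequence],
    labels: Sequence[int],
) -> dict[str, tuple[int, int]]:
    """Per-pattern (n, k): sequences / positive sequences containing it.

    One automaton pass over every sequence; presence is per-sequence (capped
    at 1) so that the hypergeometric binomials are well defined.
    """
    if not patterns or not sequences:
        raise ValueError("need non-empty patterns and sequences")
    ac = AhoCorasick(patterns)
    n = Counter()
    k = Counter()
    for seq, lab in zip(sequences, labels):
        for pi in ac.found_in(seq.bases):
            n[pi] += 1
            if lab == 1:
                k[pi] += 1
    return {pat: (n[pi], k[pi]) for pi, pat in enumerate(ac.patterns)}


def enrichment_pvalue(test: EnrichmentTest, mode: str = "survival") -> float:
    """P-value of a candidate pattern's positive-class enrichment.

    mode="survival" (default): hypergeometric upper tail P(X >= k) with N
    sequences, K positives, n containing the pattern.  mode="literal": one
    minus the single PMF term C(K,k) C(N-K,n-k) / C(N,n) — the printed form
    of the test, retained for comparison although it is not a tail
    probability.
    """
    N, K, n, k = test.N, test.K, test.n, test.k
    if mode == "survival":
        return float(hypergeom.sf(k - 1, N, K, n))
    if mode == "literal":
        return float(1.0 - hypergeom.pmf(k, N, K, n))
    raise ValueError(f"unknown p-value mode {mode!r}")


# ---------------------------------------------------------------------------
# Step 4: grouping, alignment, PWMs
# ---------------------------------------------------------------------------

def _best_offset(core: str, cand: str) -> tuple[int, int, int]:
    """Best ungapped alignment of cand against core.

    Returns (matches, overlap, offset) where offset is cand's start relative
    to core's start.  The best offset maximizes matches, then overlap, then
    minimizes |offset|.
    """
    best = (-1, 0, 0)
    for off in range(-(len(cand) - 1), len(core)):
        lo = max(0, off)
        hi = min(len(core), off + len(cand))
        if hi <= lo:
            continue
        matches = sum(1 for i in range(lo, hi) if core[i] == cand[i - off])
        overlap = hi - lo
        key = (matches, overlap, -abs(off))
        if key > (best[0], best[1], -abs(best[2])):
            best = (matches, overlap, off)
    return best


def group_and_align(
    candidates: Sequence[str],
    min_members: int = MIN_GROUP_MEMBERS,
) -> list[MotifGroup]:
    """Group candidate substrings by iterative ungapped pairwise alignment.

    Each round selects a core — the longest remaining substring, ties broken
    by its occurrence count in the remaining candidate list and then
    lexicographically — and assigns every remaining candidate whose
    best-offset matches strictly exceed half the overlap length.  Grouped
    candidates leave the pool; rounds repeat until the pool is empty.  Groups
    with fewer than *min_members* members are discarded.
    """
    pool = list(candidates)
    groups: list[MotifGroup] = []
    while pool:
        freq = Counter(pool)
        core = max(pool, key=lambda s: (len(s), freq[s], [-ord(c) for c in s]))
        group = MotifGroup(core=core, members=[core], offsets=[0])
        rest = []
        first = True
        for cand in pool:
            if first and cand == core:
                first = False  # the core itself joined already
                continue
            matches, overlap, off = _best_offset(core, cand)
            if matches * 2 > overlap:
                group.members.append(cand)
                group.offsets.append(off)
            else:
                rest.append(cand)
        pool = rest
        groups.append(group)
    return [g for g in groups if len(g.members) >= min_members]


def build_pwm(group: MotifGroup, min_coverage: float = 0.5) -> PWM:
    """Per-column base frequencies of a group's aligned members.

    Members are placed at their offsets; each column is normalized by the
    number of members covering it; leading/trailing columns covered by fewer
    than *min_coverage* of the members are trimmed.
    """
    if not group.members:
        raise ValueError("empty motif group")
    lo = min(group.offsets)
    hi = max(off + len(m) for m, off in zip(group.members, group.offsets))
    width = hi - lo
    counts = np.zeros((4, width))
    coverage = np.zeros(width)
    for m, off in zip(group.members, group.offsets):
        for i, ch in enumerate(m):
            col = off - lo + i
            counts[BASE_INDEX[ch], col] += 1
            coverage[col] += 1
    keep = coverage >= min_coverage * len(group.members)
    # trim only from the ends
    idx = np.flatnonzero(keep)
    first, last = int(idx[0]), int(idx[-1])
    counts = counts[:, first : last + 1]
    coverage = coverage[first : last + 1]
    return PWM(matrix=counts / coverage, nsites=len(group.members))


# ---------------------------------------------------------------------------
# orchestration and output
# ---------------------------------------------------------------------------

@dataclass
class MotifDiscoveryResult:
    pwms: list[PWM]
    groups: list[MotifGroup]
    table: list[dict]  # per candidate: seq_id, interval, pattern, n, k, p, kept


def discover_motifs(
    attn_profiles: Sequence[NucleotideAttentionProfile],
    pos_seqs: Sequence[DnaSequence],
    all_seqs: Sequence[DnaSequence],
    labels: Sequence[int],
    significance: float = SIGNIFICANCE,
    pvalue_mode: str = "survival",
    expand: int = EXPAND,
    min_members: int = MIN_GROUP_MEMBERS,
    bonferroni: bool = False,
) -> MotifDiscoveryResult:
    """Run Steps 2-4 given per-positive-sequence attention profiles.

    *attn_profiles* must parallel *pos_seqs* (the positive sequences whose
    attention is mined); containment counting runs over *all_seqs* with
    *labels*.  With *bonferroni* the significance level is divided by the
    number of unique tested patterns (off by default).
    """
    candidates: list[CandidatePattern] = []
    for profile, seq in zip(attn_profiles, pos_seqs):
        candidates.extend(find_candidates(profile, seq, expand=expand))
    if not candidates:
        return MotifDiscoveryResult(pwms=[], groups=[], table=[])
    patterns = [c.core for c in candidates]
    counts = count_containing(patterns, all_seqs, labels)
    N = len(all_seqs)
    K = int(sum(labels))
    alpha = significance / len(counts) if bonferroni else significance
    pvals: dict[str, float] = {}
    for pat, (n, k) in counts.items():
        pvals[pat] = enrichment_pvalue(
            EnrichmentTest(pattern=pat, K=K, k=k, N=N, n=n), mode=pvalue_mode)
    table = []
    for c in candidates:
        n, k = counts[c.core]
        p = pvals[c.core]
        table.append({
            "seq_id": c.seq_id,
            "start": c.core_start + 1,  # 1-based inclusive in reports
            "end": c.core_end,
            "pattern": c.core,
            "n": n, "k": k, "p": p, "kept": p < alpha,
        })
    kept = [c for c in candidates if pvals[c.core] < alpha]
    groups = group_and_align([c.expanded for c in kept], min_members=min_members)
    pwms = [build_pwm(g) for g in groups]
    return MotifDiscoveryResult(pwms=pwms, groups=groups, table=table)


def write_meme(pwms: Sequence[PWM], path: str | Path,
               background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> None:
    """Write PWMs in MEME minimal motif format."""
    if not pwms:
        raise ValueError("no PWMs to write")
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: +", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.3f}" for b, f in zip(DNA_ALPHABET, background)), "",
    ]
    for i, pwm in enumerate(pwms, start=1):
        lines.append(f"MOTIF motif_{i} {pwm.consensus}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {pwm.nsites}"
        )
        for col in pwm.matrix.T:
            lines.append(" " + " ".join(f"{v:.6f}" for v in col))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[PWM]:
    """Parse a MEME minimal motif file back into PWMs (round-trip checking)."""
    pwms = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("letter-probability matrix:"):
            toks = lines[i].split()
            fields = dict(zip(toks[2::2], toks[3::2]))
            w = int(fields["w="])
            nsites = int(fields.get("nsites=", 0))
            mat = np.array([
                [float(x) for x in lines[i + 1 + j].split()] for j in range(w)
            ]).T
            pwms.append(PWM(matrix=mat, nsites=nsites))
            i += w + 1
        else:
            i += 1
    return pwms


def write_candidate_table(table: Sequence[dict], path: str | Path) -> None:
    """Write the per-candidate enrichment table as TSV (1-based intervals)."""
    lines = ["seq_id\tstart\tend\tpattern\tn\tk\tp\tkept"]
    for row in table:
        lines.append(
            f"{row['seq_id']}\t{row['start']}\t{row['end']}\t{row['pattern']}\t"
            f"{row['n']}\t{row['k']}\t{row['p']:.6g}\t{int(row['kept'])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
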