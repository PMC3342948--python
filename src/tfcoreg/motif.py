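"""PSSM motif scanning and enrichment with an adaptive score cutoff.

Regions are scored by the best log-odds window on either strand; a motif's
hit cutoff is not fixed a priori but chosen, per motif, as the observed
score that minimizes the exact binomial p-value for over- OR
under-representation of hits in the foreground regions relative to the
matched random background.  Because that minimization is itself a
selection, a label-permutation calibration of the minimized p-value is
provided as a guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


@dataclass
class PositionWeightMatrix:
    """Motif count matrix (4 x L, rows A,C,G,T) with background frequencies.

    Probabilities are derived with a pseudocount of ``pseudocount`` times
    the column total added per cell, and scores are log2 odds against the
    background.  Ambiguous bases contribute 0 (background odds).
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("counts must be 4 x L with L >= 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.background <= 0) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be strictly positive and sum to 1")
        col_tot = self.counts.sum(axis=0)
        if np.any(col_tot <= 0):
            raise ValueError("every column needs positive total count")
        probs = self.counts + self.pseudocount * col_tot
        self.probs = probs / probs.sum(axis=0)
        # log-odds matrix with an extra all-zero row for ambiguous bases
        lo = np.log2(self.probs / self.background[:, None])
        self.logodds = np.vstack([lo, np.zeros(self.width)])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    @classmethod
    def from_jaspar(cls, text: str, **kwargs) -> "PositionWeightMatrix":
        """Parse JASPAR-style count-matrix text::

            >MA0000.1 NAME
            A [ 1 2 3 ]
            C [ 0 1 0 ]
            ...
        """
        lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
        motif_id = lines[0].lstrip(">").split()[0] if lines[0].startswith(">") else "motif"
        rows = {}
        for ln in lines:
            if ln[0] in BASES and (len(ln) == 1 or not ln[1].isalnum()):
                nums = ln.split("[")[-1].rstrip("]").replace("]", " ").split()
                rows[ln[0]] = [float(x) for x in nums]
        if set(rows) != set(BASES):
            raise ValueError("JASPAR matrix must have A, C, G and T rows")
        counts = np.array([rows[b] for b in BASES])
        return cls(motif_id, counts, **kwargs)

    @classmethod
    def from_consensus(cls, consensus: str, motif_id: str = "consensus",
                       weight: float = 100.0, **kwargs) -> "PositionWeightMatrix":
        """One-hot matrix (count ``weight`` for the consensus base per column)."""
        counts = np.zeros((4, len(consensus)))
        for j, b in enumerate(consensus.upper()):
            counts[_BASE_INDEX[b], j] = weight
        return cls(motif_id, counts, **kwargs)


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4 (scores as background)."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pssm_score(pwm: PositionWeightMatrix, window: str) -> float:
    """Log2-odds score of one window of exactly the motif length."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != motif length {pwm.width}")
    idx = encode(window)
    return float(pwm.logodds[idx, np.arange(pwm.width)].sum())


def _scan_scores(pwm: PositionWeightMatrix, encoded: np.ndarray) -> np.ndarray:
    """Score every window start on the encoded forward sequence."""
    L = pwm.width
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    # gather per-position log-odds and sum over a sliding window
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return pwm.logodds[windows, np.arange(L)].sum(axis=1)


def scan_best(pwm: PositionWeightMatrix, sequence: str, both_strands: bool = True
              ) -> tuple[float, int, str]:
    """Best log-odds window over the sequence (and its reverse complement).

    Returns (score, offset, strand) with offset 0-based on the forward
    sequence (start of the matched window).  Ties break to the leftmost
    offset, forward strand first.
    """
    if len(sequence) < pwm.width:
        raise ValueError("sequence shorter than the motif")
    enc_f = encode(sequence)
    fwd = _scan_scores(pwm, enc_f)
    best_score, best_off, best_strand = -np.inf, 0, "+"
    i = int(np.argmax(fwd))
    best_score, best_off = float(fwd[i]), i
    if both_strands:
        enc_r = encode(reverse_complement(sequence))
        rev = _scan_scores(pwm, enc_r)
        j = int(np.argmax(rev))
        # map reverse-scan offset back onto forward coordinates
        off_r = len(sequence) - pwm.width - j
        if float(rev[j]) > best_score or (
                float(rev[j]) == best_score and off_r < best_off):
            best_score, best_off, best_strand = float(rev[j]), off_r, "-"
    return best_score, best_off, best_strand


@dataclass
class EnrichmentResult:
    motif_id: str
    cutoff: float
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    direction: str  # "over" | "under"
    p_binomial: float
    p_over: float
    p_under: float
    candidate_cutoffs: np.ndarray | None = None
    p_calibrated: float | None = None


def _min_binomial_over_cutoffs(fg: np.ndarray, bg: np.ndarray
                               ) -> tuple[float, float, str, int, int, float, float, np.ndarray]:
    """Scan all distinct observed scores as cutoffs; return the minimizer.

    For each cutoff c: f = #fg >= c out of F, b = #bg >= c out of B; the
    test is Binomial(F, rate) with rate = b/B clamped to
    [1/(2B), 1 - 1/(2B)]; both one-sided tails are computed and the overall
    minimum (cutoff, direction) returned.
    """
    F, B = fg.size, bg.size
    cutoffs = np.unique(np.concatenate([fg, bg]))
    f = F - np.searchsorted(np.sort(fg), cutoffs, "left")
    b = B - np.searchsorted(np.sort(bg), cutoffs, "left")
    rate = np.clip(b / B, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
    p_over = stats.binom.sf(f - 1, F, rate)
    p_under = stats.binom.cdf(f, F, rate)
    best = np.minimum(p_over, p_under)
    i = int(np.argmin(best))
    direction = "over" if p_over[i] <= p_under[i] else "under"
    return (float(cutoffs[i]), float(best[i]), direction, int(f[i]), int(b[i]),
            float(p_over[i]), float(p_under[i]), cutoffs)


def optimal_cutoff_binomial(fg_best_scores, bg_best_scores,
                            motif_id: str = "motif") -> EnrichmentResult:
    """Choose the score cutoff minimizing the binomial enrichment p-value."""
    fg = np.asarray(fg_best_scores, dtype=float)
    bg = np.asarray(bg_best_scores, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both score lists must be non-empty")
    if np.unique(np.concatenate([fg, bg])).size == 1:
        import warnings

        warnings.warn("all scores identical: enrichment is undefined", stacklevel=2)
        return EnrichmentResult(motif_id, float(fg[0]), fg.size, fg.size,
                                bg.size, bg.size, "over", 1.0, 1.0, 1.0)
    cutoff, p, direction, f, b, p_over, p_under, cand = \
        _min_binomial_over_cutoffs(fg, bg)
    return EnrichmentResult(motif_id, cutoff, f, fg.size, b, bg.size,
                            direction, max(p, 5e-324), p_over, p_under, cand)


def calibrate_by_label_permutation(fg_scores, bg_scores, n_perm: int = 200,
                                   seed: int = 0) -> float:
    """Permutation p-value for the cutoff-minimized binomial statistic.

    Pools the region scores, permutes the fg/bg labels ``n_perm`` times,
    re-minimizes over cutoffs each time, and reports
    (1 + #{permuted min-p <= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    observed = _min_binomial_over_cutoffs(fg, bg)[1]
    pooled = np.concatenate([fg, bg])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        pf, pb = pooled[perm[:fg.size]], pooled[perm[fg.size:]]
        if _min_binomial_over_cutoffs(pf, pb)[1] <= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def matched_random_regions(regions: list[GenomicInterval],
                           genome: list[tuple[str, int]], seed: int = 0,
                           exclude: list[GenomicInterval] | None = None,
                           max_tries: int = 10000) -> list[GenomicInterval]:
    """Random intervals matching the input count and length multiset.

    Each output interval is placed uniformly over the genome (weighted by
    placeable positions), rejecting placements that intersect ``exclude``.
    """
    rng = np.random.default_rng(seed)
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclude or []:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for i, region in enumerate(regions):
        L = region.length
        chroms = [(c, n) for c, n in genome if n >= L]
        if not chroms:
            raise ValueError(f"genome too small for a {L} bp region")
        weights = np.array([n - L + 1 for _, n in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(max_tries):
            ci = rng.choice(len(chroms), p=weights)
            chrom, n = chroms[ci]
            start = int(rng.integers(0, n - L + 1))
            candidate = GenomicInterval(chrom, start, start + L, name=f"rand_{i}")
            if not any(candidate.overlaps(x) for x in excl_by_chrom.get(chrom, [])):
                out.append(candidate)
                break
        else:
            raise ValueError("could not place a region outside the excluded set")
    return out


def score_regions(pwm: PositionWeightMatrix, sequences: dict[str, str],
                  both_strands: bool = True) -> np.ndarray:
    """Best score per region, in the mapping's order."""
    return np.array([scan_best(pwm, s, both_strands)[0] for s in sequences.values()])
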