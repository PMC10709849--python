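"""PWM scanning of paired allele windows and motif-level statistics.

The scanner mirrors the FIMO approach: log-odds scores against a 0-order
background, discretized at a fixed granularity, with an *exact* score null
computed by positionwise convolution of the discretized per-position score
distributions.  A hit is significant when its score p-value is strictly
below ``alpha`` and the motif span covers the SNP at the window center.

For a pair of ref/alt windows a single shared anchor (the best significant
hit over both windows and both strands) is chosen, and both windows are
scored at that anchor so that the score change

    score_change = ref_score - alt_score

compares aligned coordinates.  Positive score_change means the reference
allele is the better match for the motif.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import AlleleCount, AllelePairWindows, HetSNP, WINDOW_CENTER, WINDOW_LENGTH

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: Default score discretization step for the exact null, in bits.
DEFAULT_GRANULARITY = 1e-3
#: Default significance threshold on the score p-value (strict <).
DEFAULT_ALPHA = 1e-4


@dataclass(frozen=True)
class PWMModel:
    """A position weight matrix with background and per-position IC.

    ``prob_matrix`` and ``logodds_matrix`` are 4 x width arrays with rows
    in A, C, G, T order; columns of ``prob_matrix`` sum to 1.  Log-odds are
    log2(p / background), in bits.
    """

    name: str
    prob_matrix: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.prob_matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4 or p.shape[1] < 1:
            raise ValueError("prob_matrix must be 4 x width with width >= 1")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("prob_matrix columns must sum to 1")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "prob_matrix", p)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.prob_matrix.shape[1]

    @property
    def logodds_matrix(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.prob_matrix / self.background[:, None])

    @property
    def ic_per_position(self) -> np.ndarray:
        """Information content per position in bits: 2 - entropy (0*log0 := 0)."""
        p = self.prob_matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=0)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.prob_matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWMModel":
        rc = self.prob_matrix[COMPLEMENT_INDEX][:, ::-1]
        return PWMModel(self.name + "_rc", rc, self.background)

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        *,
        name: str = "motif",
        pseudocount: float = 0.1,
        background: np.ndarray | None = None,
    ) -> "PWMModel":
        """Build a PWM from a 4 x width count matrix.

        The pseudocount is distributed over bases in proportion to the
        background: p_bj = (c_bj + pseudocount * bg_b) / (total_j + pseudocount).
        """
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if counts.shape[1] < 1:
            raise ValueError("motif width must be >= 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        totals = counts.sum(axis=0)
        if pseudocount == 0 and np.any(totals == 0):
            raise ValueError("zero-count column requires a positive pseudocount")
        prob = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
        return cls(name, prob, bg)


@dataclass(frozen=True)
class ScoreNull:
    """Exact null distribution of discretized log-odds scores.

    Scores are quantized as round(logodds / granularity); the null is the
    distribution of the integer score sum of a width-w word drawn i.i.d.
    from the background.  ``tail_at(s)`` returns P(score >= s) for an
    integer score s.
    """

    granularity: float
    int_matrix: np.ndarray  # 4 x width, integer scores (int64)
    min_sum: int
    tail: np.ndarray  # tail[i] = P(score >= min_sum + i)

    @property
    def max_sum(self) -> int:
        return self.min_sum + len(self.tail) - 1

    def tail_at(self, int_score: int) -> float:
        if int_score <= self.min_sum:
            return 1.0
        if int_score > self.max_sum:
            return 0.0
        return float(self.tail[int_score - self.min_sum])


def score_pvalue_table(
    pwm: PWMModel, granularity: float = DEFAULT_GRANULARITY
) -> ScoreNull:
    """Exact score-null by positionwise convolution over discretized scores."""
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    lo = pwm.logodds_matrix
    if not np.all(np.isfinite(lo)):
        raise ValueError(
            "log-odds matrix contains -inf; use a positive pseudocount"
        )
    int_matrix = np.rint(lo / granularity).astype(np.int64)
    mins = int_matrix.min(axis=0)
    maxs = int_matrix.max(axis=0)
    min_sum = int(mins.sum())
    max_sum = int(maxs.sum())
    dist = np.zeros(max_sum - min_sum + 1)
    dist[0] = 1.0
    cur_min = 0
    # convolve per-position score distributions under the background
    for j in range(pwm.width):
        nxt = np.zeros_like(dist)
        for b in range(4):
            s = int(int_matrix[b, j] - mins[j])
            p = pwm.background[b]
            if p == 0:
                continue
            if s == 0:
                nxt += p * dist
            else:
                nxt[s:] += p * dist[: len(dist) - s]
        dist = nxt
        cur_min += int(mins[j])
    tail = np.cumsum(dist[::-1])[::-1]
    np.clip(tail, 0.0, 1.0, out=tail)
    return ScoreNull(granularity, int_matrix, min_sum, tail)


@dataclass(frozen=True)
class MotifHit:
    """One significant motif occurrence within a 41-bp window."""

    offset: int
    strand: str
    score: float
    pvalue: float
    covers_center: bool
    window: str  # "ref" or "alt"


@dataclass(frozen=True)
class PairScanResult:
    """Scan outcome for one ref/alt window pair.

    ``in_motif`` is true when a significant hit covers the SNP in either
    window; ``anchor`` is (offset, strand) of the best such hit, at which
    both windows are scored.
    """

    snp: HetSNP
    in_motif: bool
    anchor: tuple[int, str] | None = None
    ref_score: float | None = None
    alt_score: float | None = None
    hits: tuple[MotifHit, ...] = ()

    @property
    def score_change(self) -> float | None:
        if self.ref_score is None or self.alt_score is None:
            return None
        return self.ref_score - self.alt_score


def _int_scores_at_offsets(seq: str, int_matrix: np.ndarray) -> np.ndarray:
    """Integer score at each offset; offsets touching non-ACGT bases get
    the minimum int64 sentinel (treated as -inf)."""
    w = int_matrix.shape[1]
    n = len(seq) - w + 1
    idx = np.array([BASE_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    scores = np.empty(n, dtype=np.int64)
    bad = idx < 0
    for off in range(n):
        sl = idx[off : off + w]
        if bad[off : off + w].any():
            scores[off] = np.iinfo(np.int64).min
        else:
            scores[off] = int_matrix[sl, np.arange(w)].sum()
    return scores


def scan_window(
    seq: str,
    pwm: PWMModel,
    null: ScoreNull,
    *,
    alpha: float = DEFAULT_ALPHA,
    which: str = "ref",
) -> list[MotifHit]:
    """All significant center-covering hits on both strands of one window."""
    w = pwm.width
    if w > len(seq):
        raise ValueError("PWM wider than the scanned window")
    rc_matrix = null.int_matrix[COMPLEMENT_INDEX][:, ::-1]
    hits: list[MotifHit] = []
    for strand, mat in (("+", null.int_matrix), ("-", rc_matrix)):
        ints = _int_scores_at_offsets(seq, mat)
        for off, s in enumerate(ints):
            covers = off <= WINDOW_CENTER <= off + w - 1
            if not covers:
                continue
            if s == np.iinfo(np.int64).min:
                continue
            p = null.tail_at(int(s))
            if p < alpha:
                hits.append(
                    MotifHit(off, strand, float(s) * null.granularity, p, True, which)
                )
    return hits


def _score_at(seq: str, int_matrix: np.ndarray, offset: int, strand: str) -> float:
    w = int_matrix.shape[1]
    mat = int_matrix if strand == "+" else int_matrix[COMPLEMENT_INDEX][:, ::-1]
    idx = [BASE_INDEX.get(c, -1) for c in seq[offset : offset + w]]
    if any(i < 0 for i in idx):
        return float("-inf")
    return float(mat[idx, np.arange(w)].sum())


def scan_pair(
    pair: AllelePairWindows,
    pwm: PWMModel,
    *,
    null: ScoreNull | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> PairScanResult:
    """Scan both windows of a pair and score them at a shared anchor.

    Anchor selection over all significant center-covering hits: maximal
    score, ties broken toward smaller offset, then "+" strand, then the
    ref window.
    """
    if pwm.width > WINDOW_LENGTH:
        raise ValueError("PWM wider than the 41-bp window")
    if null is None:
        null = score_pvalue_table(pwm)
    hits = scan_window(pair.ref_window, pwm, null, alpha=alpha, which="ref")
    hits += scan_window(pair.alt_window, pwm, null, alpha=alpha, which="alt")
    if not hits:
        return PairScanResult(pair.snp, in_motif=False)
    best = min(
        hits,
        key=lambda h: (-h.score, h.offset, 0 if h.strand == "+" else 1,
                       0 if h.window == "ref" else 1),
    )
    anchor = (best.offset, best.strand)
    g = null.granularity
    ref_score = _score_at(pair.ref_window, null.int_matrix, *anchor) * g
    alt_score = _score_at(pair.alt_window, null.int_matrix, *anchor) * g
    return PairScanResult(
        pair.snp,
        in_motif=True,
        anchor=anchor,
        ref_score=ref_score,
        alt_score=alt_score,
        hits=tuple(hits),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Resampling test for ASB enrichment in the motif.

    ``iterations`` control sets of size |ASB| are drawn without replacement
    from the non-ASB pool; z compares the observed in-motif ASB count with
    the control mean/sd, and the p-value is the two-sided normal tail.
    """

    n_asb_in_motif: int
    n_asb_total: int
    n_nonasb_in_motif: int
    n_nonasb_total: int
    control_mean: float
    control_sd: float
    z: float
    pvalue: float
    iterations: int
    degenerate_sd: bool = False


def enrichment_test(
    asb: list[PairScanResult],
    nonasb: list[PairScanResult],
    *,
    iterations: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """ASB-in-motif enrichment against resampled non-ASB control sets."""
    if not asb:
        raise ValueError("need at least one ASB scan result")
    if len(nonasb) < len(asb):
        raise ValueError("non-ASB pool must be at least as large as the ASB set")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = len(asb)
    observed = sum(r.in_motif for r in asb)
    pool = np.fromiter((r.in_motif for r in nonasb), dtype=bool, count=len(nonasb))
    draws = np.empty(iterations, dtype=np.int64)
    for i in range(iterations):
        draws[i] = pool[rng.choice(len(pool), size=k, replace=False)].sum()
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1)) if iterations > 1 else 0.0
    degenerate = False
    if sd == 0.0:
        if observed == mean:
            z, p = 0.0, 1.0
        else:
            degenerate = True
            z = math.inf if observed > mean else -math.inf
            p = float(np.finfo(float).tiny)
    else:
        z = (observed - mean) / sd
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        if z == 0.0:
            p = 1.0
    return EnrichmentResult(
        n_asb_in_motif=int(observed),
        n_asb_total=k,
        n_nonasb_in_motif=int(pool.sum()),
        n_nonasb_total=len(nonasb),
        control_mean=mean,
        control_sd=sd,
        z=z,
        pvalue=p,
        iterations=iterations,
        degenerate_sd=degenerate,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of reference allele ratio vs motif score change."""

    n: int
    r: float | None
    pvalue: float | None
    flag: str = ""


def ratio_score_correlation(
    results: list[tuple[PairScanResult, AlleleCount]],
) -> CorrelationResult:
    """Pearson r of ref_ratio against score_change over in-motif records."""
    pairs = [
        (c.ref_ratio, r.score_change)
        for r, c in results
        if r.in_motif and r.score_change is not None and c.total > 0
    ]
    n = len(pairs)
    if n < 3:
        return CorrelationResult(n, None, None, flag="too_few_records")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(n, None, None, flag="zero_variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(n, float(r), float(p))


@dataclass(frozen=True)
class DisruptionProfile:
    """Per-motif-position disrupted-SNP frequency vs conservation.

    ``freq_per_position[j]`` counts in-motif SNPs whose center base falls on
    motif position j (strand-aware).  ``consistency_ratio`` is the fraction
    of positions where frequency and IC fall on the same side of their
    respective means.
    """

    freq_per_position: np.ndarray
    ic_per_position: np.ndarray
    pearson_r: float | None
    pearson_p: float | None
    consistency_ratio: float
    flag: str = ""


def motif_position_of_center(offset: int, strand: str, width: int) -> int:
    """Motif coordinate of the window-center SNP for a hit at (offset, strand)."""
    pos = WINDOW_CENTER - offset
    if not 0 <= pos < width:
        raise ValueError("hit does not cover the window center")
    return pos if strand == "+" else width - 1 - pos


def disruption_profile(
    results: list[PairScanResult], pwm: PWMModel
) -> DisruptionProfile:
    """Tabulate disrupted positions and correlate with per-position IC."""
    ic = pwm.ic_per_position
    freq = np.zeros(pwm.width)
    for r in results:
        if not r.in_motif or r.anchor is None:
            continue
        off, strand = r.anchor
        freq[motif_position_of_center(off, strand, pwm.width)] += 1
    if freq.sum() == 0:
        return DisruptionProfile(
            freq, ic, None, None, float("nan"), flag="no_in_motif_records"
        )
    high_f = freq >= freq.mean()
    high_i = ic >= ic.mean()
    consistency = float(np.mean(high_f == high_i))
    if pwm.width < 3 or np.ptp(freq) == 0 or np.ptp(ic) == 0:
        return DisruptionProfile(freq, ic, None, None, consistency,
                                 flag="undefined_correlation")
    r, p = stats.pearsonr(freq, ic)
    return DisruptionProfile(freq, ic, float(r), float(p), consistency)
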