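"""Beta-binomial allelic-imbalance test with simulation-based FDR.

Model
-----
Under the no-imbalance null the reference read count at a SNP with total
depth n follows a beta-binomial with success probability fixed at 0.5 and
overdispersion rho in [0, 1).  The symmetric beta shapes are

    a = b = 0.5 * (1 / rho - 1),

so that Var(X) = n/4 * (1 + (n - 1) * rho); rho = 0 degenerates to the
plain binomial(n, 0.5).

The overdispersion is fitted per sample on a fixed grid
{0.0, 0.1, ..., 0.9} by least sum of squared errors (LSSE) between the
empirical reference-allele-ratio histogram and the model-implied expected
histogram averaged over the observed depths.  Two-sided p-values double
the lower tail of min(ref, alt).  Multiple testing is handled by an
explicit simulation: null counts are regenerated at the observed depths,
and FDR(t) compares null to observed p-value exceedance counts over a
sliding threshold; SNPs below the largest threshold with FDR <= 10% are
called ASB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import AlleleCount

#: Candidate overdispersion values; 1.0 is excluded (beta shapes undefined,
#: all probability mass on 0 and n).
RHO_GRID = tuple(round(0.1 * i, 1) for i in range(10))

DEFAULT_FDR_TARGET = 0.10
DEFAULT_N_SIM_ROUNDS = 10
DEFAULT_N_BINS = 21


@dataclass(frozen=True)
class BetaBinomialNull:
    """Symmetric beta-binomial null at success probability 0.5."""

    rho: float
    prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.prob != 0.5:
            raise ValueError("the null fixes the success probability at 0.5")

    @property
    def shape_a(self) -> float:
        if self.rho == 0.0:
            raise ValueError("beta shapes undefined at rho=0 (binomial limit)")
        return 0.5 * (1.0 / self.rho - 1.0)

    shape_b = shape_a


def betabinom_tail(k: int, n: int, null: BetaBinomialNull) -> float:
    """Lower-tail probability P(X <= k) under the beta-binomial null."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if null.rho == 0.0:
        return float(stats.binom.cdf(k, n, null.prob))
    a = null.shape_a
    return float(stats.betabinom.cdf(k, n, a, a))


def two_sided_pvalue(count: AlleleCount, null: BetaBinomialNull) -> float:
    """Two-sided p-value: twice the lower tail of min(ref, alt), capped at 1."""
    if count.total == 0:
        raise ValueError("p-value undefined for zero total count")
    k = min(count.ref_count, count.alt_count)
    return min(1.0, 2.0 * betabinom_tail(k, count.total, null))


def _pvalues(counts_n: np.ndarray, counts_k: np.ndarray, rho: float) -> np.ndarray:
    """Vectorized two-sided p-values for ref counts k at depths n."""
    kmin = np.minimum(counts_k, counts_n - counts_k)
    if rho == 0.0:
        tail = stats.binom.cdf(kmin, counts_n, 0.5)
    else:
        a = 0.5 * (1.0 / rho - 1.0)
        tail = stats.betabinom.cdf(kmin, counts_n, a, a)
    return np.minimum(1.0, 2.0 * tail)


@dataclass(frozen=True)
class OverdispersionFit:
    """Grid LSSE fit of the overdispersion parameter."""

    grid: tuple[float, ...]
    sse_per_r: tuple[float, ...]
    rho_hat: float
    n_bins: int

    @property
    def null(self) -> BetaBinomialNull:
        return BetaBinomialNull(self.rho_hat)


def _expected_ratio_histogram(
    totals: np.ndarray, weights: np.ndarray, rho: float, edges: np.ndarray
) -> np.ndarray:
    """Expected ref-ratio histogram: beta-binomial pmf at each observed
    depth mapped onto the shared ratio bins, averaged over depths."""
    n_bins = len(edges) - 1
    expected = np.zeros(n_bins)
    for n, w in zip(totals, weights):
        k = np.arange(n + 1)
        if rho == 0.0:
            pmf = stats.binom.pmf(k, n, 0.5)
        else:
            a = 0.5 * (1.0 / rho - 1.0)
            pmf = stats.betabinom.pmf(k, n, a, a)
        ratios = k / n
        # np.digitize with right-closed final bin
        idx = np.minimum(np.searchsorted(edges, ratios, side="right") - 1,
                         n_bins - 1)
        expected += w * np.bincount(idx, weights=pmf, minlength=n_bins)
    return expected


def fit_overdispersion(
    counts: list[AlleleCount],
    *,
    grid: tuple[float, ...] = RHO_GRID,
    n_bins: int = DEFAULT_N_BINS,
) -> OverdispersionFit:
    """Pick the grid rho minimizing the SSE between the empirical and
    expected reference-allele-ratio histograms (ties toward smaller rho)."""
    usable = [c for c in counts if c.total > 0]
    if not usable:
        raise ValueError("no counts with positive total")
    ratios = np.array([c.ref_ratio for c in usable])
    totals_all = np.array([c.total for c in usable])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    empirical = np.histogram(ratios, bins=edges)[0] / len(usable)
    uniq, freq = np.unique(totals_all, return_counts=True)
    weights = freq / freq.sum()
    sses = []
    for rho in grid:
        expected = _expected_ratio_histogram(uniq, weights, rho, edges)
        sses.append(float(np.sum((empirical - expected) ** 2)))
    best = int(np.argmin(sses))  # argmin takes the first minimum: smaller rho
    return OverdispersionFit(tuple(grid), tuple(sses), grid[best], n_bins)


def simulate_null_counts(
    totals: list[int] | np.ndarray,
    null: BetaBinomialNull,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw null reference counts at the given depths.

    For rho > 0 each SNP's success probability is drawn from
    Beta(a, a) and the count from a binomial at that probability;
    rho = 0 draws binomial(n, 0.5) directly.  Deterministic given the
    generator state / seed.
    """
    totals = np.asarray(totals, dtype=np.int64)
    if np.any(totals < 1):
        raise ValueError("all totals must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if null.rho == 0.0:
        return rng.binomial(totals, null.prob)
    a = null.shape_a
    p = rng.beta(a, a, size=len(totals))
    return rng.binomial(totals, p)


@dataclass(frozen=True)
class FDRCurve:
    """Simulation-FDR over the sliding thresholds (the observed p-values)."""

    thresholds: tuple[float, ...]
    fdr_at_threshold: tuple[float, ...]
    chosen_threshold: float | None
    target: float

    def is_significant(self, pvalue: float) -> bool:
        return (
            self.chosen_threshold is not None
            and pvalue <= self.chosen_threshold
        )


def fdr_threshold(
    observed_p: np.ndarray | list[float],
    null_p: list[np.ndarray],
    target: float = DEFAULT_FDR_TARGET,
) -> FDRCurve:
    """Sweep the unique observed p-values as candidate cutoffs.

    FDR(t) = (mean over simulation rounds of #{null <= t}) / #{observed <= t},
    clamped to [0, 1]; the chosen threshold is the largest t with
    FDR(t) <= target (None when no cutoff qualifies).
    """
    observed = np.asarray(observed_p, dtype=float)
    if observed.size == 0:
        raise ValueError("observed p-values must be non-empty")
    for i, rnd in enumerate(null_p):
        if len(rnd) != observed.size:
            raise ValueError(
                f"null round {i} has size {len(rnd)} != observed {observed.size}"
            )
    thresholds = np.unique(observed)
    obs_sorted = np.sort(observed)
    n_obs = np.searchsorted(obs_sorted, thresholds, side="right")
    n_null = np.zeros(len(thresholds))
    for rnd in null_p:
        n_null += np.searchsorted(np.sort(np.asarray(rnd, float)),
                                  thresholds, side="right")
    n_null /= max(len(null_p), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs > 0, n_null / n_obs, 0.0)
    fdr = np.clip(fdr, 0.0, 1.0)
    ok = fdr <= target
    chosen = float(thresholds[ok][-1]) if ok.any() else None
    return FDRCurve(
        tuple(float(t) for t in thresholds),
        tuple(float(f) for f in fdr),
        chosen,
        target,
    )


@dataclass(frozen=True)
class ASBCall:
    """Per-SNP verdict: two-sided p-value and the ASB flag."""

    count: AlleleCount
    pvalue: float
    is_asb: bool


@dataclass
class DetectionConfig:
    """Tunable parameters of the detection stage."""

    fdr_target: float = DEFAULT_FDR_TARGET
    n_sim_rounds: int = DEFAULT_N_SIM_ROUNDS
    n_bins: int = DEFAULT_N_BINS
    rho_grid: tuple[float, ...] = RHO_GRID
    #: Fix rho instead of fitting it (None = fit on the grid).
    rho_fixed: float | None = None
    seed: int = 0


@dataclass
class DetectionResult:
    """Everything the detection stage produced for one sample."""

    calls: list[ASBCall]
    fit: OverdispersionFit
    fdr: FDRCurve
    config: DetectionConfig = field(repr=False, default_factory=DetectionConfig)

    @property
    def n_asb(self) -> int:
        return sum(c.is_asb for c in self.calls)


def call_asb(
    counts: list[AlleleCount], config: DetectionConfig | None = None
) -> DetectionResult:
    """Run the full detection stage on depth-filtered counts.

    Fits (or fixes) the overdispersion, computes per-SNP two-sided
    p-values, simulates ``n_sim_rounds`` null datasets at the observed
    depths and the fitted rho, sweeps the FDR curve, and flags SNPs below
    the chosen threshold.  Output is sorted by ascending p-value (ties by
    chromosome and position).
    """
    cfg = config or DetectionConfig()
    if not counts:
        raise ValueError("no counts supplied")
    fit = fit_overdispersion(counts, grid=cfg.rho_grid, n_bins=cfg.n_bins)
    if cfg.rho_fixed is not None:
        fit = OverdispersionFit(fit.grid, fit.sse_per_r, cfg.rho_fixed,
                                cfg.n_bins)
    rho = fit.rho_hat
    null = BetaBinomialNull(rho)
    totals = np.array([c.total for c in counts], dtype=np.int64)
    refs = np.array([c.ref_count for c in counts], dtype=np.int64)
    observed_p = _pvalues(totals, refs, rho)
    rng = np.random.default_rng(cfg.seed)
    null_rounds = []
    for _ in range(cfg.n_sim_rounds):
        sim_k = simulate_null_counts(totals, null, rng)
        null_rounds.append(_pvalues(totals, sim_k, rho))
    curve = fdr_threshold(observed_p, null_rounds, cfg.fdr_target)
    calls = [
        ASBCall(c, float(p), curve.is_significant(float(p)))
        for c, p in zip(counts, observed_p)
    ]
    calls.sort(key=lambda a: (a.pvalue, a.count.snp.chrom, a.count.snp.pos))
    return DetectionResult(calls, fit, curve, cfg)
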