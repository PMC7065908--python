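"""Running-average methylation-expression trend with a permutation null.

The core statistic: genes are ordered by their knockout methylation
delta, grouped into fixed-size overlapping windows ("running-average
bins", consecutive windows sharing 80% of members by default), the
per-bin mean delta (x) and mean log2 fold change (y) are computed, and
an ordinary least-squares line is fit to the binned points.  The fit's
R² — the fraction of variance in binned fold change explained by
methylation change — is the trend statistic.

Because overlapping bins induce strong autocorrelation, the R² is not
referred to an F distribution; instead it is calibrated against an
empirical null built by re-running the identical procedure on repeated
random draws of non-differentially-expressed genes, matched in number to
the DEG set.  The p-value is (r + 1) / (n + 1) where r counts null
repetitions whose R² strictly exceeds the observed one — the standard
add-one permutation estimate, which can never return zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinConfig",
    "BinSeries",
    "TrendFit",
    "PermutationResult",
    "SINGLE_MODEL_BINS",
    "SHARED_SET_BINS",
    "sort_and_bin",
    "n_bins_for",
    "fit_trend",
    "permutation_test",
]


@dataclass(frozen=True)
class BinConfig:
    """Window size and overlap for running-average binning.

    ``bin_size`` genes per window; consecutive windows share
    ``overlap_frac`` of their members, so the window advances by
    ``bin_size * (1 - overlap_frac)`` genes — which must be a whole
    number of genes.
    """

    bin_size: int
    overlap_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError(f"overlap_frac must be in [0, 1), got {self.overlap_frac}")
        step = self.bin_size * (1.0 - self.overlap_frac)
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError(
                f"bin_size={self.bin_size} with overlap_frac={self.overlap_frac} "
                f"gives non-integer step {step}"
            )

    @property
    def step(self) -> int:
        return round(self.bin_size * (1.0 - self.overlap_frac))


#: 25-gene windows advancing 5 genes: used for single-model DEG sets.
SINGLE_MODEL_BINS = BinConfig(bin_size=25, overlap_frac=0.8)
#: 10-gene windows advancing 2 genes: used for smaller shared/common DEG sets.
SHARED_SET_BINS = BinConfig(bin_size=10, overlap_frac=0.8)


@dataclass(frozen=True)
class BinSeries:
    """Ordered overlapping bins with their member ids and mean (x, y)."""

    members: tuple[tuple[str, ...], ...]
    mean_delta: np.ndarray
    mean_log2fc: np.ndarray
    config: BinConfig

    @property
    def n_bins(self) -> int:
        return len(self.members)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "mean_delta": self.mean_delta,
                "mean_log2fc": self.mean_log2fc,
                "member_count": [len(m) for m in self.members],
            }
        )


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    n_bins: int


@dataclass(frozen=True)
class PermutationResult:
    observed_r2: float
    null_r2: np.ndarray
    seed: int | None
    r: int = field(init=False)
    n: int = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        n = int(len(self.null_r2))
        r = int(np.sum(self.null_r2 > self.observed_r2))
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "p", (r + 1) / (n + 1))


def n_bins_for(n_genes: int, config: BinConfig) -> int:
    """Number of complete windows: floor((N - B) / step) + 1.

    Windows that would run past the last gene are not formed, so every
    bin has exactly ``bin_size`` members.
    """
    if n_genes < config.bin_size:
        raise ValueError(
            f"need at least bin_size={config.bin_size} genes, got {n_genes}"
        )
    return (n_genes - config.bin_size) // config.step + 1


def sort_and_bin(genes: pd.DataFrame, config: BinConfig) -> BinSeries:
    """Order genes by methylation delta and form overlapping windows.

    ``genes`` needs columns ``gene_id``, ``delta`` and ``log2fc``, all
    finite.  Sorting is ascending by delta with ties broken by gene_id
    so the binning is deterministic.  Windows start at offsets
    0, step, 2*step, ...; incomplete trailing windows are dropped.
    """
    required = {"gene_id", "delta", "log2fc"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene frame missing columns {sorted(missing)}")
    if not np.isfinite(genes[["delta", "log2fc"]].to_numpy()).all():
        raise ValueError("delta and log2fc must be finite; filter upstream")

    n = len(genes)
    n_bins = n_bins_for(n, config)  # raises if n < bin_size
    ordered = genes.sort_values(["delta", "gene_id"], kind="stable")
    ids = ordered["gene_id"].to_numpy()
    delta = ordered["delta"].to_numpy(dtype=float)
    log2fc = ordered["log2fc"].to_numpy(dtype=float)

    B, step = config.bin_size, config.step
    starts = np.arange(n_bins) * step
    # mean over each window via cumulative sums
    cd = np.concatenate([[0.0], np.cumsum(delta)])
    cf = np.concatenate([[0.0], np.cumsum(log2fc)])
    mean_delta = (cd[starts + B] - cd[starts]) / B
    mean_log2fc = (cf[starts + B] - cf[starts]) / B
    members = tuple(tuple(ids[s : s + B]) for s in starts)
    return BinSeries(
        members=members,
        mean_delta=mean_delta,
        mean_log2fc=mean_log2fc,
        config=config,
    )


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: (slope, intercept, R²)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    if sxx == 0.0:
        raise ValueError("zero variance in x: trend line undefined")
    if syy == 0.0:
        return 0.0, float(ym), 0.0
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = syy - slope * sxy
    return slope, intercept, 1.0 - ss_res / syy


def fit_trend(bins: BinSeries) -> TrendFit:
    """OLS of binned mean log2fc on binned mean delta, with intercept.

    R² = 1 - SS_res / SS_tot, i.e. the squared Pearson correlation of
    the binned points.  Constant y yields R² = 0 with zero slope;
    constant x is an error (the line is undefined).
    """
    if bins.n_bins < 3:
        raise ValueError(f"need >= 3 bins to fit a trend, got {bins.n_bins}")
    slope, intercept, r2 = _ols_r2(bins.mean_delta, bins.mean_log2fc)
    return TrendFit(
        slope=slope, intercept=intercept, r_squared=r2, n_bins=bins.n_bins
    )


def permutation_test(
    deg_genes: pd.DataFrame,
    non_deg_pool: pd.DataFrame,
    config: BinConfig,
    n_reps: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Calibrate the observed trend R² against resampled non-DEG sets.

    Each repetition draws ``len(deg_genes)`` genes from the non-DEG pool
    without replacement (independently across repetitions), applies the
    identical sort/bin/fit procedure, and records its R².  The p-value
    is (r + 1) / (n + 1) with r the number of null R² values strictly
    greater than the observed one.  The seed fully determines the null
    draw sequence.
    """
    n_deg = len(deg_genes)
    if len(non_deg_pool) < n_deg:
        raise ValueError(
            f"non-DEG pool ({len(non_deg_pool)}) smaller than DEG set ({n_deg})"
        )
    observed = fit_trend(sort_and_bin(deg_genes, config)).r_squared

    pool = non_deg_pool.reset_index(drop=True)
    pool_delta = pool["delta"].to_numpy(dtype=float)
    pool_fc = pool["log2fc"].to_numpy(dtype=float)
    if not (np.isfinite(pool_delta).all() and np.isfinite(pool_fc).all()):
        raise ValueError("non-DEG pool has non-finite delta/log2fc")

    B, step = config.bin_size, config.step
    n_bins = n_bins_for(n_deg, config)
    starts = np.arange(n_bins) * step
    rng = np.random.default_rng(seed)
    null_r2 = np.empty(n_reps)
    for i in range(n_reps):
        idx = rng.choice(len(pool), size=n_deg, replace=False)
        d, f = pool_delta[idx], pool_fc[idx]
        order = np.argsort(d, kind="stable")
        d, f = d[order], f[order]
        cd = np.concatenate([[0.0], np.cumsum(d)])
        cf = np.concatenate([[0.0], np.cumsum(f)])
        x = (cd[starts + B] - cd[starts]) / B
        y = (cf[starts + B] - cf[starts]) / B
        try:
            _, _, null_r2[i] = _ols_r2(x, y)
        except ValueError:  # degenerate draw with constant delta
            null_r2[i] = 0.0
    return PermutationResult(observed_r2=observed, null_r2=null_r2, seed=seed)
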