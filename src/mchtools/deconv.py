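"""Marker-based two-population deconvolution of bulk expression.

Bulk RNA-seq of a tissue mixes cell populations; here a dominant
population (~95%, e.g. medium spiny neurons) and a minor one (~5%,
interneurons).  Following the population-specific expression analysis
(PSEA) idea, each sample's abundance of a population is proxied by a
*reference signal*: the mean normalized expression of that population's
marker genes in the sample.  Per gene, bulk expression is regressed on
both reference signals plus signal-by-group interactions; a significant
interaction indicates a knockout effect specific to that population.

Two filtering rounds then select trustworthy population-specific calls:
round 1 keeps well-explained, low-noise genes (R² > 0.6,
|intercept|/mean < 0.5, intercept p > 0.1, all strict); round 2
additionally requires the population's interaction p < 0.05.  The
consistency of the selected genes with an independent bulk DEG list is
scored with a hypergeometric overlap test (exclusive upper tail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HypergeomInput",
    "normalize_expression",
    "build_reference_signals",
    "fit_psea",
    "filter_round1",
    "filter_round2",
    "hypergeom_overlap",
    "R2_MIN",
    "INTERCEPT_RATIO_MAX",
    "INTERCEPT_P_MIN",
    "INTERACTION_ALPHA",
]

# Round-1 thresholds: model fit, relative intercept, intercept p-value.
R2_MIN = 0.6
INTERCEPT_RATIO_MAX = 0.5
INTERCEPT_P_MIN = 0.1
# Round-2 threshold on the population-specific interaction p-value.
INTERACTION_ALPHA = 0.05


@dataclass(frozen=True)
class HypergeomInput:
    """Counts for a gene-set overlap test.

    ``N`` universe genes of which ``K`` are bulk DEGs; ``n`` genes
    selected by deconvolution; ``k`` of those fall in the bulk list.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"need K, n <= N: K={self.K} n={self.n} N={self.N}")
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(f"overlap k={self.k} exceeds min(K={self.K}, n={self.n})")


def normalize_expression(
    counts: pd.DataFrame,
    scale: float = 1e6,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Scale each sample's counts to a fixed total, optionally log(1+x).

    ``counts`` is samples x genes.  Counts-per-scale (CPM when scale is
    1e6) is the default normalization behind the reference signals: the
    population-specific models are linear in population contributions,
    and a log transform breaks that mixture additivity.  ``log_transform``
    is offered for other uses of the normalized matrix.
    """
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total count")
    norm = counts.div(totals, axis=0) * scale
    return np.log1p(norm) if log_transform else norm


def build_reference_signals(
    expr: pd.DataFrame, markers: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-sample, per-population mean of marker-gene expression.

    ``expr`` is a normalized samples x genes matrix; ``markers`` maps
    population name -> marker gene list.  Markers absent from the matrix
    are dropped with a warning; an empty (or fully absent) marker set is
    an error.  Returns a samples x populations frame.
    """
    signals = {}
    for pop, genes in markers.items():
        if not genes:
            raise ValueError(f"population {pop!r} has an empty marker list")
        present = [g for g in genes if g in expr.columns]
        missing = sorted(set(genes) - set(present))
        if missing:
            logger.warning(
                "build_reference_signals: %d/%d markers for %s absent, dropped",
                len(missing), len(genes), pop,
            )
        if not present:
            raise ValueError(f"no markers for population {pop!r} found in matrix")
        signals[pop] = expr[present].mean(axis=1)
    return pd.DataFrame(signals, index=expr.index)


def fit_psea(
    expr: pd.DataFrame,
    signals: pd.DataFrame,
    groups: pd.Series,
    knockout_label: str = "knockout",
) -> pd.DataFrame:
    """Gene-wise population-specific linear models, one per population.

    For each gene and each population, fits

        expression ~ intercept + signal_pop + signal_pop x group

    across samples, where group is 1 for knockout samples and 0 for
    controls.  A separate univariate model per population is required:
    in a two-population mixture the fractions sum to one, so the two
    reference signals together with a constant are collinear and a
    joint model cannot identify the intercept.  In the per-population
    model the intercept absorbs the expression *not* attributable to
    that population, which is exactly the quantity the downstream
    noise filter screens.

    The interaction p-value (two-sided) is the population-specific
    differential p-value.  Returns a frame indexed by gene with
    ``mean_expr`` plus, per population: ``r2_<pop>``,
    ``intercept_<pop>``, ``intercept_p_<pop>``, ``coef_<pop>``,
    ``coef_<pop>_ko`` and ``p_<pop>_ko``.  Genes whose design is
    rank-deficient for a population are flagged ``unfit_<pop>`` and
    excluded from filtering downstream.
    """
    groups = groups.reindex(expr.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    group = (groups == knockout_label).to_numpy(dtype=float)
    n_ctrl, n_ko = int((group == 0).sum()), int((group == 1).sum())
    if n_ctrl < 2 or n_ko < 2:
        raise ValueError(f"need >= 2 samples per group, got {n_ctrl}/{n_ko}")
    signals = signals.reindex(expr.index)
    if signals.std(axis=0).min() == 0:
        raise ValueError("a reference signal is constant across samples")

    designs = {}
    for pop in signals.columns:
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "signal": signals[pop],
                "signal:ko": signals[pop] * group,
            },
            index=signals.index,
        )
        designs[pop] = (X, np.linalg.matrix_rank(X.to_numpy()) < X.shape[1])

    rows = []
    for gene in expr.columns:
        y = expr[gene].to_numpy(dtype=float)
        row = {"gene_id": gene, "mean_expr": float(y.mean())}
        for pop, (X, deficient) in designs.items():
            res = sm.OLS(y, X).fit()
            row[f"unfit_{pop}"] = deficient
            if deficient:
                r2 = np.nan
            elif np.ptp(y) == 0:  # constant gene: nothing to explain
                r2 = 0.0
            else:
                r2 = float(res.rsquared)
            row[f"r2_{pop}"] = r2
            row[f"intercept_{pop}"] = float(res.params["intercept"])
            row[f"intercept_p_{pop}"] = float(res.pvalues["intercept"])
            row[f"coef_{pop}"] = float(res.params["signal"])
            row[f"coef_{pop}_ko"] = float(res.params["signal:ko"])
            row[f"p_{pop}_ko"] = float(res.pvalues["signal:ko"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def _populations(fits: pd.DataFrame) -> list[str]:
    return [c.removeprefix("r2_") for c in fits.columns if c.startswith("r2_")]


def filter_round1(fits: pd.DataFrame, population: str | None = None) -> pd.DataFrame:
    """First filtering round: model quality and noise level.

    Per population, pass iff that population's model has R² > 0.6 and
    |intercept|/mean expression < 0.5 and intercept p > 0.1, all
    inequalities strict.  Zero mean expression fails with reason.
    Adds ``pass_round1_<pop>`` and ``round1_reason_<pop>`` columns
    (reason names the first failed criterion); with ``population`` only
    that population is evaluated.
    """
    out = fits.copy()
    pops = [population] if population else _populations(fits)
    for pop in pops:
        reasons = []
        for _, row in out.iterrows():
            r2 = row[f"r2_{pop}"]
            if row.get(f"unfit_{pop}", False) or not np.isfinite(r2):
                reasons.append("unfit")
            elif not r2 > R2_MIN:
                reasons.append("r_squared")
            elif row["mean_expr"] == 0:
                reasons.append("zero_mean")
            elif (
                not abs(row[f"intercept_{pop}"]) / abs(row["mean_expr"])
                < INTERCEPT_RATIO_MAX
            ):
                reasons.append("intercept/mean")
            elif not row[f"intercept_p_{pop}"] > INTERCEPT_P_MIN:
                reasons.append("intercept_p")
            else:
                reasons.append("")
        out[f"round1_reason_{pop}"] = reasons
        out[f"pass_round1_{pop}"] = [r == "" for r in reasons]
    return out


def filter_round2(fits: pd.DataFrame, population: str) -> pd.DataFrame:
    """Second filtering round: population-specific significance.

    Pass iff the gene passed round 1 for ``population`` and its
    interaction p there is strictly below 0.05.  Adds a
    ``pass_round2_<population>`` column.
    """
    col = f"p_{population}_ko"
    if col not in fits.columns:
        raise ValueError(f"no interaction p-value column {col!r}")
    if f"pass_round1_{population}" not in fits.columns:
        fits = filter_round1(fits, population)
    out = fits.copy()
    out[f"pass_round2_{population}"] = out[f"pass_round1_{population}"] & (
        out[col] < INTERACTION_ALPHA
    )
    return out


def hypergeom_overlap(inp: HypergeomInput) -> float:
    """Exclusive upper-tail hypergeometric p-value, P(X > k).

    X is the overlap when ``n`` genes are drawn without replacement from
    a universe of ``N`` containing ``K`` successes; the reported p is
    the probability of an overlap *strictly greater* than the observed
    ``k`` (the survival function at k).  At k = min(K, n) no larger
    overlap exists and the p-value is exactly 0.
    """
    return float(stats.hypergeom(inp.N, inp.K, inp.n).sf(inp.k))
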