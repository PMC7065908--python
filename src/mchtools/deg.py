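"""Differential-expression tables, DEG classification and overlap.

Consumes per-gene differential-expression statistics (gene id, total
read count, log2 fold change, adjusted p-value) for two knockout models
— here a methylation *writer* knockout and a *reader* knockout — applies
the count filter, classifies genes into the four-way category scheme
(common / model-A-only / model-B-only / non-DEG) at an adjusted-p
threshold, and summarises DEG-set overlap and category-level methylation
distributions.

Differential-expression model fitting itself is out of scope: tables
are consumed as produced by a DE engine (or by the simulator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "DEGCategories",
    "OverlapResult",
    "read_deg_table",
    "filter_low_counts",
    "classify",
    "overlap_stats",
    "overlap_from_counts",
    "split_by_length",
    "category_levels",
]

DEG_COLUMNS = ["gene_id", "total_count", "log2fc", "padj"]

#: Adjusted-p threshold below which a gene is called differentially expressed.
DEFAULT_ALPHA = 0.01
#: Genes with total read counts below this are removed before analysis.
DEFAULT_MIN_TOTAL = 10
#: Default long/short gene-length cut (bases, TSS-to-TES span); configurable.
DEFAULT_LONG_GENE_THRESHOLD = 100_000


@dataclass(frozen=True)
class DEGCategories:
    """Four-way DEG classification across two knockout models.

    The sets are disjoint and their union is the set of evaluable genes
    (adjusted p present in both models and not exactly at ``alpha``).
    """

    common: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]
    non_deg: frozenset[str]
    alpha: float = DEFAULT_ALPHA
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        sets = [self.common, self.a_only, self.b_only, self.non_deg]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("DEG categories must be disjoint")

    @property
    def deg_a(self) -> frozenset[str]:
        """All DEGs in model A (common plus A-only)."""
        return self.common | self.a_only

    @property
    def deg_b(self) -> frozenset[str]:
        return self.common | self.b_only

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (g, name)
            for name, s in (
                ("common", self.common),
                ("a_only", self.a_only),
                ("b_only", self.b_only),
                ("non_deg", self.non_deg),
            )
            for g in sorted(s)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "category"])


@dataclass(frozen=True)
class OverlapResult:
    """DEG-set overlap between two models by inclusion-exclusion."""

    n_a: int
    n_b: int
    n_union: int
    n_intersection: int = field(init=False)
    pct_of_a: float = field(init=False)
    pct_of_b: float = field(init=False)

    def __post_init__(self) -> None:
        n_int = self.n_a + self.n_b - self.n_union
        if not 0 <= n_int <= min(self.n_a, self.n_b):
            raise ValueError(
                f"inconsistent counts: |A|={self.n_a} |B|={self.n_b} "
                f"|A∪B|={self.n_union} imply |A∩B|={n_int}"
            )
        object.__setattr__(self, "n_intersection", n_int)
        object.__setattr__(
            self, "pct_of_a", 100.0 * n_int / self.n_a if self.n_a else float("nan")
        )
        object.__setattr__(
            self, "pct_of_b", 100.0 * n_int / self.n_b if self.n_b else float("nan")
        )


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene DE table (TSV with header; columns gene_id,
    total_count, log2fc, padj; padj may be empty/NA)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DEG table missing columns {sorted(missing)}")
    bad = df["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError(f"{path}: padj values outside [0, 1]")
    return df


def filter_low_counts(
    records: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL
) -> pd.DataFrame:
    """Remove genes whose total read count is below ``min_total``.

    Genes with total read counts less than the threshold are filtered
    out (count logged); the boundary value itself is retained.
    """
    keep = records["total_count"] >= min_total
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_low_counts: removed %d genes with total < %d",
                    n_drop, min_total)
    return records[keep].reset_index(drop=True)


def classify(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    label_a: str = "a",
    label_b: str = "b",
) -> DEGCategories:
    """Classify genes into common / A-only / B-only / non-DEG.

    A gene is a DEG in a model iff its adjusted p there is strictly
    below ``alpha``; non-DEG requires strictly above ``alpha`` in both.
    Genes with missing padj in either model, or padj exactly at the
    threshold, are excluded (counts logged).
    """
    a = deg_a.set_index("gene_id")["padj"]
    b = deg_b.set_index("gene_id")["padj"]
    if a.index.has_duplicates or b.index.has_duplicates:
        raise ValueError("duplicate gene_ids in a DEG table")
    common_idx = a.index.intersection(b.index)
    a, b = a.loc[common_idx], b.loc[common_idx]

    evaluable = a.notna() & b.notna()
    n_na = int((~evaluable).sum())
    if n_na:
        logger.info("classify: %d genes with missing padj excluded", n_na)
    at_threshold = evaluable & ((a == alpha) | (b == alpha))
    n_tie = int(at_threshold.sum())
    if n_tie:
        logger.info("classify: %d genes with padj exactly %g excluded", n_tie, alpha)
    use = evaluable & ~at_threshold
    if not use.any():
        raise ValueError("no evaluable genes (all padj missing or at threshold)")

    a, b = a[use], b[use]
    sig_a, sig_b = a < alpha, b < alpha
    return DEGCategories(
        common=frozenset(a.index[sig_a & sig_b]),
        a_only=frozenset(a.index[sig_a & ~sig_b]),
        b_only=frozenset(a.index[~sig_a & sig_b]),
        non_deg=frozenset(a.index[~sig_a & ~sig_b]),
        alpha=alpha,
        label_a=label_a,
        label_b=label_b,
    )


def overlap_stats(categories: DEGCategories) -> OverlapResult:
    """Overlap summary of the two models' DEG sets."""
    n_a, n_b = len(categories.deg_a), len(categories.deg_b)
    n_union = len(categories.deg_a | categories.deg_b)
    return OverlapResult(n_a=n_a, n_b=n_b, n_union=n_union)


def overlap_from_counts(n_a: int, n_b: int, n_union: int) -> OverlapResult:
    """Overlap summary directly from set sizes via inclusion-exclusion."""
    return OverlapResult(n_a=n_a, n_b=n_b, n_union=n_union)


def split_by_length(
    genes: Mapping[str, GeneAnnotation] | list[GeneAnnotation],
    gene_ids: set[str] | frozenset[str] | None = None,
    threshold_bases: int = DEFAULT_LONG_GENE_THRESHOLD,
) -> dict[str, frozenset[str]]:
    """Partition genes into long vs short by TSS-to-TES span.

    ``long`` iff length >= ``threshold_bases``.  When ``gene_ids`` is
    given, only those genes are split; ids without annotation are
    excluded with a logged count.
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    ids = set(genes) if gene_ids is None else set(gene_ids)
    missing = ids - set(genes)
    if missing:
        logger.info("split_by_length: %d genes lack annotation, excluded",
                    len(missing))
        ids -= missing
    long = frozenset(g for g in ids if genes[g].length >= threshold_bases)
    return {"long": long, "short": frozenset(ids) - long}


def _direction_subset(
    gene_ids: frozenset[str], log2fc: pd.Series, direction: str
) -> frozenset[str]:
    if direction == "all":
        return gene_ids
    fc = log2fc.reindex(sorted(gene_ids))
    if direction == "up":
        return frozenset(fc.index[fc > 0])
    if direction == "down":
        return frozenset(fc.index[fc < 0])
    raise ValueError(f"unknown direction {direction!r}")


def category_levels(
    categories: DEGCategories,
    gene_methylation: pd.DataFrame,
    context_class: Literal["CG", "CH"] = "CH",
    direction: Literal["up", "down", "all"] = "all",
    log2fc: pd.Series | None = None,
) -> pd.DataFrame:
    """Methylation-level distributions per DEG category, with rank tests.

    ``gene_methylation`` is a long frame from
    :meth:`~mchtools.methylome.gene_body_levels`.  For each category the
    summary reports n, median and quartiles of defined levels, plus a
    two-sided Mann-Whitney U p-value against the non-DEG category
    (NaN for non-DEG itself, or when a side has < 2 defined genes — the
    comparison is skipped and logged).  ``direction`` restricts DEG
    categories to up- or down-regulated genes (requires ``log2fc``
    indexed by gene_id).
    """
    levels = (
        gene_methylation[gene_methylation["context_class"] == context_class]
        .set_index("gene_id")["level"]
        .dropna()
    )
    if direction != "all" and log2fc is None:
        raise ValueError("direction-restricted comparison requires log2fc")

    members = {
        "common": categories.common,
        "a_only": categories.a_only,
        "b_only": categories.b_only,
        "non_deg": categories.non_deg,
    }
    values: dict[str, np.ndarray] = {}
    for name, ids in members.items():
        if direction != "all" and name != "non_deg":
            ids = _direction_subset(ids, log2fc, direction)
        values[name] = levels.reindex(sorted(ids)).dropna().to_numpy()

    ref = values["non_deg"]
    rows = []
    for name, vals in values.items():
        q1, med, q3 = (
            np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
        )
        if name == "non_deg" or vals.size < 2 or ref.size < 2:
            if name != "non_deg" and (vals.size < 2 or ref.size < 2):
                logger.info("category_levels: %s vs non_deg skipped (<2 genes)", name)
            p = np.nan
        else:
            p = stats.mannwhitneyu(vals, ref, alternative="two-sided").pvalue
        rows.append((name, vals.size, q1, med, q3, p))
    return pd.DataFrame(
        rows, columns=["category", "n", "q1", "median", "q3", "p_vs_non_deg"]
    )
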