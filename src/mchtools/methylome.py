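"""Per-cytosine methylation calls and gene-body methylation levels.

Reads allc-style per-cytosine call tables, classifies trinucleotide
contexts into CG vs CH (H = A, C or T), and summarises methylation per
gene body as the *weighted* methylation level: the ratio of summed
methylated read counts to summed total read counts over all member
cytosines.  The weighted level is the standard summary for sparse
bisulfite-style data because it does not let low-coverage sites dominate.

Knockout-vs-wild-type differences ("deltas") are computed per gene under
an explicit sign convention, and simple Pearson/Spearman correlation is
exposed for delta-coupling analyses.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "GeneAnnotation",
    "AllcFormatError",
    "read_allc",
    "read_bed",
    "classify_context",
    "site_frame",
    "gene_body_levels",
    "global_level",
    "estimate_nonconversion",
    "methylation_delta",
    "correlate",
]

ContextClass = Literal["CG", "CH"]
DeltaConvention = Literal["ko_minus_wt", "wt_minus_ko"]

_CH_SECOND = frozenset("ACT")
_VALID_BASES = frozenset("ACGT")


class AllcFormatError(ValueError):
    """Raised for a malformed line in an allc-style call table."""


@dataclass(frozen=True)
class SiteRecord:
    """One cytosine's methylation evidence.

    ``pos`` is 1-based, as in allc output; ``context`` is the
    trinucleotide starting at the cytosine; ``mc``/``cov`` are the
    methylated and total read counts.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    mc: int
    cov: int

    def __post_init__(self) -> None:
        if self.cov <= 0:
            raise ValueError(f"cov must be positive, got {self.cov}")
        if not 0 <= self.mc <= self.cov:
            raise ValueError(f"mc={self.mc} outside [0, cov={self.cov}]")
        if len(self.context) != 3 or self.context[0] != "C":
            raise ValueError(f"invalid cytosine context {self.context!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body interval, 0-based half-open (BED convention)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_context(context: str) -> str:
    """Classify a cytosine trinucleotide context as ``CG``, ``CH`` or ``invalid``.

    CG iff the second base is G; CH iff the second base is A, C or T.
    Any context not starting with C, of wrong length, or containing
    non-ACGT letters is ``invalid``.
    """
    if (
        len(context) != 3
        or context[0] != "C"
        or any(b not in _VALID_BASES for b in context)
    ):
        return "invalid"
    return "CG" if context[1] == "G" else "CH"


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    handle = open(path, "rb")
    if handle.read(2) == b"\x1f\x8b":
        handle.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=handle))
    handle.seek(0)
    return io.TextIOWrapper(handle)


def read_allc(path: str | Path) -> Iterator[SiteRecord]:
    """Stream validated :class:`SiteRecord` objects from an allc-style TSV.

    Expected columns: chrom, pos, strand, context, mc, cov; a trailing
    seventh column (the binomial methylation call emitted by some
    callers) is ignored.  A single header line is skipped if the second
    column is not an integer.  Gzip input is detected from the magic
    bytes.  Malformed lines raise :class:`AllcFormatError` naming the
    line number.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AllcFormatError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, context, mc_s, cov_s = fields[:6]
            try:
                pos, mc, cov = int(pos_s), int(mc_s), int(cov_s)
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise AllcFormatError(
                    f"{path}:{lineno}: non-integer pos/mc/cov in {line!r}"
                ) from None
            try:
                yield SiteRecord(chrom, pos, strand, context, mc, cov)
            except ValueError as exc:
                raise AllcFormatError(f"{path}:{lineno}: {exc}") from None


def read_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from a BED6-like TSV.

    Columns: chrom, start, end, gene_id, score (ignored), strand.
    """
    genes: list[GeneAnnotation] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}"
                )
            strand = fields[5] if len(fields) >= 6 else "+"
            genes.append(
                GeneAnnotation(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand,
                )
            )
    return genes


def site_frame(sites: Iterable[SiteRecord] | pd.DataFrame) -> pd.DataFrame:
    """Materialise sites into a DataFrame with a ``context_class`` column."""
    if isinstance(sites, pd.DataFrame):
        df = sites.copy()
        missing = {"chrom", "pos", "context", "mc", "cov"} - set(df.columns)
        if missing:
            raise ValueError(f"site frame missing columns {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [(s.chrom, s.pos, s.strand, s.context, s.mc, s.cov) for s in sites],
            columns=["chrom", "pos", "strand", "context", "mc", "cov"],
        )
    if "context_class" not in df.columns:
        ctx = df["context"].astype(str)
        second = ctx.str[1]
        valid = (ctx.str.len() == 3) & (ctx.str[0] == "C") & ctx.str.fullmatch(
            "[ACGT]{3}"
        )
        df["context_class"] = np.where(
            ~valid, "invalid", np.where(second == "G", "CG", "CH")
        )
    return df


def _class_sites(sites, context_class: str) -> pd.DataFrame:
    df = site_frame(sites)
    if context_class not in ("CG", "CH"):
        raise ValueError(f"unknown context class {context_class!r}")
    return df[df["context_class"] == context_class]


def gene_body_levels(
    sites: Iterable[SiteRecord] | pd.DataFrame,
    genes: Sequence[GeneAnnotation],
    context_class: ContextClass,
) -> pd.DataFrame:
    """Weighted gene-body methylation level per gene for one context class.

    Both strands are pooled; a site falling inside two overlapping genes
    contributes to both.  allc positions are 1-based, annotations 0-based
    half-open, so a site belongs to a gene iff ``start <= pos - 1 < end``.

    Returns a frame indexed like ``genes`` with columns
    ``gene_id, context_class, level, n_sites, total_cov``; ``level`` is
    NaN for genes with zero coverage in this class (e.g. a contig absent
    from the calls) — that is a flag, not an error.
    """
    df = _class_sites(sites, context_class)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cum_mc = np.concatenate(
            [[0], np.cumsum(sub["mc"].to_numpy(dtype=np.int64)[order])]
        )
        cum_cov = np.concatenate(
            [[0], np.cumsum(sub["cov"].to_numpy(dtype=np.int64)[order])]
        )
        by_chrom[str(chrom)] = (pos, cum_mc, cum_cov)

    rows = []
    for g in genes:
        if g.chrom in by_chrom:
            pos, cum_mc, cum_cov = by_chrom[g.chrom]
            # site pos (1-based) in gene iff start+1 <= pos <= end
            lo = np.searchsorted(pos, g.start + 1, side="left")
            hi = np.searchsorted(pos, g.end, side="right")
            mc = int(cum_mc[hi] - cum_mc[lo])
            cov = int(cum_cov[hi] - cum_cov[lo])
            n_sites = int(hi - lo)
        else:
            mc, cov, n_sites = 0, 0, 0
        level = mc / cov if cov > 0 else np.nan
        rows.append((g.gene_id, context_class, level, n_sites, cov))
    return pd.DataFrame(
        rows, columns=["gene_id", "context_class", "level", "n_sites", "total_cov"]
    )


def global_level(
    sites: Iterable[SiteRecord] | pd.DataFrame, context_class: ContextClass
) -> float:
    """Genome-wide weighted methylation level for one context class.

    NaN when the class has zero total coverage.
    """
    df = _class_sites(sites, context_class)
    cov = int(df["cov"].sum())
    if cov == 0:
        return float("nan")
    return float(df["mc"].sum() / cov)


def estimate_nonconversion(
    sites: Iterable[SiteRecord] | pd.DataFrame, spike_contig: str
) -> float | None:
    """Apparent methylation on an unmethylated spike-in contig.

    The spike-in (typically lambda phage DNA) carries no true methylation,
    so its weighted level estimates the bisulfite non-conversion rate.
    The estimate is reported only — levels are never corrected with it.
    Returns None when the spike contig is absent.
    """
    df = site_frame(sites)
    spike = df[df["chrom"] == spike_contig]
    if spike.empty:
        return None
    cov = int(spike["cov"].sum())
    return float(spike["mc"].sum() / cov) if cov > 0 else float("nan")


def methylation_delta(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    convention: DeltaConvention = "ko_minus_wt",
) -> pd.DataFrame:
    """Per-gene methylation differences between genotypes, both contexts.

    ``wt``/``ko`` are long frames as produced by :func:`gene_body_levels`
    (one row per gene per context class).  Genes whose level is undefined
    (NaN) in either genotype for a context are dropped for that context
    with a logged count.  Output columns: ``gene_id, delta_mCH,
    delta_mCG, convention``; switching convention negates both deltas.
    """
    if convention not in ("ko_minus_wt", "wt_minus_ko"):
        raise ValueError(f"unknown delta convention {convention!r}")
    sign = 1.0 if convention == "ko_minus_wt" else -1.0

    def pivot(df: pd.DataFrame) -> pd.DataFrame:
        return df.pivot_table(
            index="gene_id", columns="context_class", values="level", aggfunc="first"
        )

    wt_p, ko_p = pivot(wt), pivot(ko)
    common = wt_p.index.intersection(ko_p.index)
    if common.empty:
        raise ValueError("no gene_ids shared between wild-type and knockout levels")
    wt_p, ko_p = wt_p.loc[common], ko_p.loc[common]

    out = pd.DataFrame({"gene_id": common})
    for ctx, col in (("CH", "delta_mCH"), ("CG", "delta_mCG")):
        if ctx in wt_p.columns and ctx in ko_p.columns:
            delta = sign * (ko_p[ctx] - wt_p[ctx])
            n_drop = int(delta.isna().sum())
            if n_drop:
                logger.info(
                    "methylation_delta: %d genes undefined in m%s dropped", n_drop, ctx
                )
            out[col] = delta.to_numpy()
        else:
            out[col] = np.nan
    out["convention"] = convention
    return out


def correlate(x, y, method: Literal["pearson", "spearman"] = "pearson") -> float:
    """Pearson or Spearman correlation of paired per-gene values.

    NaN pairs are dropped.  Returns NaN when either vector has zero
    variance (the coefficient is undefined).  Requires >= 3 finite pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 finite pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
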