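"""Synthetic data generator emulating the study's data structure.

Produces, from a seed and a parameter set, every input the analysis
consumes: per-gene (and optionally per-cytosine) methylation levels for
a wild-type, a methylation-writer knockout (which loses ~90% of mCH and
~10% of mCG) and a reader knockout (methylation unchanged); two
differential-expression tables whose fold changes carry a planted
linear dependence on the mCH delta; and a two-population bulk RNA-seq
mixture (95%/5%) with marker genes and planted population-specific
knockout effects.  Ground-truth tables are emitted alongside so that
every pipeline stage can be checked for parameter recovery.

Levels are drawn from scaled Beta distributions to respect the [0, 1]
support.  Adjusted p-values are generated directly, consistent with a
gene's planted category, because differential-expression model fitting
is out of scope — the pipeline consumes DE tables, it does not fit them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome import GeneAnnotation

__all__ = [
    "SimulationParams",
    "MethylomeTruth",
    "ExpressionTables",
    "MixtureData",
    "simulate_methylomes",
    "simulate_expression",
    "simulate_mixture",
    "write_allc",
    "write_bed",
    "write_deg_table",
    "emit_methylome",
    "emit_expression",
    "emit_mixture",
]

SPIKE_CONTIG = "lambda_spike"


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the generator, with defaults matching the emulated study.

    Methylation: wild-type gene-body mCH around 4% and mCG around 75%
    (Beta-distributed with the given concentrations); the writer
    knockout removes 90% of mCH and 10% of mCG with per-gene jitter, and
    the per-gene mCH and mCG deltas are coupled at Pearson
    ``delta_coupling_rho``.  Expression: DEG categories sized to the
    observed 86 common / 636 writer-only / 127 reader-only out of ~5000
    analysed genes, with log2 fold change = ``trend_slope`` x mCH delta
    + Gaussian noise for affected genes.  Mixture: two populations at
    95%/5% with per-sample jitter and marker genes per population.
    """

    n_genes: int = 5000
    seed: int = 0

    # wild-type gene-body methylation levels (Beta mean / concentration)
    wt_mch_mean: float = 0.04
    wt_mch_conc: float = 30.0
    wt_mcg_mean: float = 0.75
    wt_mcg_conc: float = 20.0

    # writer-knockout losses, applied multiplicatively with per-gene jitter
    mch_loss_frac: float = 0.9
    mcg_loss_frac: float = 0.1
    loss_jitter_sd: float = 0.1
    delta_coupling_rho: float = 0.5

    # site-level emission
    sites_per_gene_ch: float = 30.0
    sites_per_gene_cg: float = 10.0
    mean_coverage: float = 20.0
    nonconversion: float = 0.01
    n_spike_sites: int = 2000

    # gene geometry (lognormal lengths, genes laid head-to-tail with gaps)
    gene_length_log_mean: float = 9.5
    gene_length_log_sd: float = 1.1
    intergenic_gap: int = 1000

    # expression / DEG structure
    frac_common: float = 86 / 5000
    frac_writer_only: float = 636 / 5000
    frac_reader_only: float = 127 / 5000
    trend_slope: float = 5.0
    noise_sd: float = 0.3
    null_log2fc_sd: float = 0.05
    low_count_frac: float = 0.05
    mean_total_count: float = 500.0

    # two-population mixture
    n_mix_genes: int = 500
    mix_depth_factor: float = 10.0
    n_samples_per_group: int = 6
    population_fractions: tuple[float, float] = (0.95, 0.05)
    fraction_jitter_sd: float = 0.03
    n_markers: int = 10
    n_specific_per_pop: tuple[int, int] = (10, 10)
    effect_log2fc: float = 1.5
    specific_gene_own_mean: float = 300.0
    specific_gene_other_mean: float = 0.5
    count_dispersion: float = 0.001

    def __post_init__(self) -> None:
        for name in ("wt_mch_mean", "wt_mcg_mean", "mch_loss_frac",
                     "mcg_loss_frac", "nonconversion", "low_count_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.delta_coupling_rho <= 1.0:
            raise ValueError("delta_coupling_rho outside [-1, 1]")
        if self.frac_common + self.frac_writer_only + self.frac_reader_only > 1:
            raise ValueError("DEG category fractions sum above 1")
        if abs(sum(self.population_fractions) - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        if 2 * self.n_markers + sum(self.n_specific_per_pop) > self.n_mix_genes:
            raise ValueError("markers + planted effects exceed n_mix_genes")


@dataclass
class MethylomeTruth:
    """Planted per-gene levels plus (optionally) per-site call tables."""

    genes: list[GeneAnnotation]
    truth: pd.DataFrame  # gene_id, wt_mch, ko_mch, wt_mcg, ko_mcg, deltas
    sites: dict[str, pd.DataFrame] | None = None  # genotype -> site frame

    def levels_long(self, genotype: str) -> pd.DataFrame:
        """Planted levels in the long per-gene format of gene_body_levels.

        ``genotype`` is ``wt``, ``writer_ko`` (prefix ``ko`` in truth
        columns) or ``reader_ko`` (identical to wild type).
        """
        col = {"wt": "wt", "writer_ko": "ko", "reader_ko": "wt"}[genotype]
        frames = []
        for ctx, suffix in (("CH", "mch"), ("CG", "mcg")):
            frames.append(pd.DataFrame({
                "gene_id": self.truth["gene_id"],
                "context_class": ctx,
                "level": self.truth[f"{col}_{suffix}"],
                "n_sites": 0,
                "total_cov": 0,
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class ExpressionTables:
    writer: pd.DataFrame
    reader: pd.DataFrame
    truth: pd.DataFrame  # gene_id, category


@dataclass
class MixtureData:
    counts: pd.DataFrame  # genes x samples
    sample_sheet: pd.DataFrame  # sample, group
    markers: dict[str, list[str]]
    truth: pd.DataFrame  # gene_id, population, log2fc of planted effects


def _beta_levels(rng, mean: float, conc: float, n: int) -> np.ndarray:
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=n)


def simulate_methylomes(
    params: SimulationParams, make_sites: bool = False
) -> MethylomeTruth:
    """Draw planted wild-type and writer-knockout methylation levels.

    Wild-type levels come from Beta distributions; writer-knockout mCH
    is wild type scaled by per-gene loss fractions jittered around
    ``mch_loss_frac``.  The mCG delta is constructed as a linear blend
    of the (standardised) mCH delta and independent noise so the two
    deltas have Pearson correlation ``delta_coupling_rho`` by
    construction, then clipped to keep knockout levels inside
    [0, wild type].  With ``make_sites`` the gene levels are realised as
    per-cytosine binomial draws (coverage 1 + Poisson) plus an
    unmethylated spike-in contig at the non-conversion rate.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_genes

    wt_mch = _beta_levels(rng, p.wt_mch_mean, p.wt_mch_conc, n)
    wt_mcg = _beta_levels(rng, p.wt_mcg_mean, p.wt_mcg_conc, n)

    loss_ch = np.clip(
        p.mch_loss_frac * (1.0 + rng.normal(0.0, p.loss_jitter_sd, n)), 0.0, 1.0
    )
    d_mch = loss_ch * wt_mch

    loss_cg = np.clip(
        p.mcg_loss_frac * (1.0 + rng.normal(0.0, p.loss_jitter_sd, n)), 0.0, 1.0
    )
    d_mcg_raw = loss_cg * wt_mcg
    # blend in the standardised mCH delta to plant the coupling
    rho = p.delta_coupling_rho
    if rho != 0.0 and d_mch.std() > 0 and d_mcg_raw.std() > 0:
        z1 = (d_mch - d_mch.mean()) / d_mch.std()
        z2_raw = (d_mcg_raw - d_mcg_raw.mean()) / d_mcg_raw.std()
        z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2_raw
        d_mcg = d_mcg_raw.mean() + d_mcg_raw.std() * z2
    else:
        d_mcg = d_mcg_raw

    ko_mch = np.clip(wt_mch - d_mch, 0.0, wt_mch)
    ko_mcg = np.clip(wt_mcg - d_mcg, 0.0, wt_mcg)

    lengths = np.maximum(
        200, rng.lognormal(p.gene_length_log_mean, p.gene_length_log_sd, n)
    ).astype(np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths + p.intergenic_gap)[:-1]])
    width = len(str(n))
    genes = [
        GeneAnnotation(
            gene_id=f"gene{i:0{width}d}",
            chrom="chr1",
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand="+" if rng.random() < 0.5 else "-",
        )
        for i in range(n)
    ]
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "length": lengths,
        "wt_mch": wt_mch,
        "ko_mch": ko_mch,
        "wt_mcg": wt_mcg,
        "ko_mcg": ko_mcg,
        "delta_mch": ko_mch - wt_mch,
        "delta_mcg": ko_mcg - wt_mcg,
    })
    sites = None
    if make_sites:
        sites = {
            "wt": _draw_sites(rng, genes, wt_mch, wt_mcg, p),
            "writer_ko": _draw_sites(rng, genes, ko_mch, ko_mcg, p),
            "reader_ko": _draw_sites(rng, genes, wt_mch, wt_mcg, p),
        }
    return MethylomeTruth(genes=genes, truth=truth, sites=sites)


def _draw_sites(rng, genes, mch, mcg, p: SimulationParams) -> pd.DataFrame:
    chroms, pos, strands, contexts, mcs, covs = [], [], [], [], [], []
    for i, g in enumerate(genes):
        for level, mean_sites, context in (
            (mch[i], p.sites_per_gene_ch, "CAC"),
            (mcg[i], p.sites_per_gene_cg, "CGT"),
        ):
            k = min(1 + rng.poisson(mean_sites), g.length)
            offsets = np.sort(
                rng.choice(g.length, size=k, replace=False)
            )
            cov = 1 + rng.poisson(p.mean_coverage - 1, size=k)
            mc = rng.binomial(cov, level)
            chroms.extend([g.chrom] * k)
            pos.extend((g.start + 1 + offsets).tolist())  # 1-based
            strands.extend(rng.choice(["+", "-"], size=k).tolist())
            contexts.extend([context] * k)
            mcs.extend(mc.tolist())
            covs.extend(cov.tolist())
    # unmethylated spike-in at the non-conversion rate
    k = p.n_spike_sites
    cov = 1 + rng.poisson(p.mean_coverage - 1, size=k)
    mc = rng.binomial(cov, p.nonconversion)
    chroms.extend([SPIKE_CONTIG] * k)
    pos.extend(range(1, k + 1))
    strands.extend(["+"] * k)
    contexts.extend(["CAC"] * k)
    mcs.extend(mc.tolist())
    covs.extend(cov.tolist())
    return pd.DataFrame({
        "chrom": chroms, "pos": pos, "strand": strands,
        "context": contexts, "mc": mcs, "cov": covs,
    })


def simulate_expression(
    methyl_truth: MethylomeTruth, params: SimulationParams
) -> ExpressionTables:
    """Two DEG tables (writer and reader model) with planted categories.

    Category counts are the rounded fractions of ``n_genes`` (so the
    planted counts are exact, not binomially noisy).  Genes affected in
    a model receive log2fc = trend_slope x mCH delta + Gaussian noise;
    genes in the common category receive the *same* value in both models.
    Adjusted p-values are drawn strictly below/above the 0.01 threshold
    according to category.  Low total counts (below the count filter)
    are planted only on non-DEG genes so the planted category counts
    survive filtering.
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
    truth = methyl_truth.truth
    n = len(truth)
    n_common = round(p.frac_common * n)
    n_wo = round(p.frac_writer_only * n)
    n_ro = round(p.frac_reader_only * n)
    if n_common + n_wo + n_ro > n:
        raise ValueError("category counts exceed number of genes")

    perm = rng.permutation(n)
    category = np.full(n, "non_deg", dtype=object)
    category[perm[:n_common]] = "common"
    category[perm[n_common:n_common + n_wo]] = "writer_only"
    category[perm[n_common + n_wo:n_common + n_wo + n_ro]] = "reader_only"

    delta = truth["delta_mch"].to_numpy()
    affected_fc = p.trend_slope * delta + rng.normal(0.0, p.noise_sd, n)
    null_fc_w = rng.normal(0.0, p.null_log2fc_sd, n)
    null_fc_r = rng.normal(0.0, p.null_log2fc_sd, n)

    in_writer = (category == "common") | (category == "writer_only")
    in_reader = (category == "common") | (category == "reader_only")
    # common genes share one draw; model-only genes get their own noise
    own_fc_r = p.trend_slope * delta + rng.normal(0.0, p.noise_sd, n)
    fc_writer = np.where(in_writer, affected_fc, null_fc_w)
    fc_reader = np.where(
        category == "common", affected_fc,
        np.where(category == "reader_only", own_fc_r, null_fc_r),
    )

    def padj_draws(is_deg: np.ndarray) -> np.ndarray:
        sig = 10.0 ** rng.uniform(-8.0, -2.05, n)
        non = rng.uniform(0.0101, 1.0, n)
        return np.where(is_deg, sig, non)

    padj_writer = padj_draws(in_writer)
    padj_reader = padj_draws(in_reader)

    total = np.maximum(
        10, rng.poisson(p.mean_total_count, n)
    ).astype(np.int64)
    non_deg_idx = np.flatnonzero(category == "non_deg")
    n_low = min(round(p.low_count_frac * n), len(non_deg_idx))
    low_idx = rng.choice(non_deg_idx, size=n_low, replace=False)
    total[low_idx] = rng.integers(0, 10, size=n_low)

    def table(fc, padj) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": truth["gene_id"],
            "total_count": total,
            "log2fc": fc,
            "padj": padj,
        })

    return ExpressionTables(
        writer=table(fc_writer, padj_writer),
        reader=table(fc_reader, padj_reader),
        truth=pd.DataFrame({"gene_id": truth["gene_id"], "category": category}),
    )


def simulate_mixture(params: SimulationParams) -> MixtureData:
    """Bulk counts from a two-population mixture with planted effects.

    Per-sample population fractions are jittered around
    ``population_fractions``; each gene has population-specific mean
    expression (markers are expressed almost exclusively in their own
    population); planted genes change by ``effect_log2fc`` (random sign)
    in one population in the knockout group only.  Counts are
    gamma-Poisson (negative binomial) around the fraction-weighted
    population means.
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 2]))
    n = p.n_mix_genes
    width = len(str(n))
    gene_ids = [f"mgene{i:0{width}d}" for i in range(n)]

    mu = rng.lognormal(np.log(100.0), 1.0, size=(n, 2))
    markers: dict[str, list[str]] = {"pop1": [], "pop2": []}
    for j, pop in enumerate(markers):
        lo = j * p.n_markers
        idx = np.arange(lo, lo + p.n_markers)
        mu[idx, j] = rng.lognormal(np.log(800.0), 0.3, size=p.n_markers)
        mu[idx, 1 - j] = 0.0
        markers[pop] = [gene_ids[i] for i in idx]

    # planted population-specific knockout effects on non-marker genes
    candidates = np.arange(2 * p.n_markers, n)
    chosen = rng.choice(
        candidates, size=sum(p.n_specific_per_pop), replace=False
    )
    effects = []
    offset = 0
    for j, n_eff in enumerate(p.n_specific_per_pop):
        for i in chosen[offset:offset + n_eff]:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects.append((gene_ids[i], f"pop{j + 1}", sign * p.effect_log2fc))
            # population-specific DEGs are enriched in their own population
            mu[i, j] = rng.lognormal(np.log(p.specific_gene_own_mean), 0.4)
            mu[i, 1 - j] = rng.lognormal(np.log(p.specific_gene_other_mean), 0.4)
        offset += n_eff
    truth = pd.DataFrame(effects, columns=["gene_id", "population", "log2fc"])

    n_per = p.n_samples_per_group
    samples = [f"ctrl{i + 1}" for i in range(n_per)] + [
        f"ko{i + 1}" for i in range(n_per)
    ]
    groups = ["control"] * n_per + ["knockout"] * n_per
    f1 = np.clip(
        rng.normal(p.population_fractions[0], p.fraction_jitter_sd, 2 * n_per),
        0.5, 1.0,
    )
    fractions = np.column_stack([f1, 1.0 - f1])

    effect_mult = np.ones((n, 2))
    for g, pop, fc in truth.itertuples(index=False):
        effect_mult[gene_ids.index(g), int(pop[-1]) - 1] = 2.0 ** fc

    counts = np.zeros((n, 2 * n_per), dtype=np.int64)
    for s in range(2 * n_per):
        mu_s = mu * (effect_mult if groups[s] == "knockout" else 1.0)
        mean = (mu_s @ fractions[s]) * p.mix_depth_factor
        lam = rng.gamma(1.0 / p.count_dispersion,
                        mean * p.count_dispersion)
        counts[:, s] = rng.poisson(lam)
    return MixtureData(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        sample_sheet=pd.DataFrame({"sample": samples, "group": groups}),
        markers=markers,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# flat-file emission in the formats the reading modules accept


def write_allc(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "pos", "strand", "context", "mc", "cov"])


def write_bed(genes: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def emit_methylome(mt: MethylomeTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(mt.genes, outdir / "genes.bed")
    mt.truth.to_csv(outdir / "methylome_truth.tsv", sep="\t", index=False)
    if mt.sites is not None:
        for genotype, sites in mt.sites.items():
            write_allc(sites, outdir / f"allc_{genotype}.tsv")


def emit_expression(et: ExpressionTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_deg_table(et.writer, outdir / "deg_writer.tsv")
    write_deg_table(et.reader, outdir / "deg_reader.tsv")
    et.truth.to_csv(outdir / "deg_truth.tsv", sep="\t", index=False)


def emit_mixture(mx: MixtureData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mx.counts.to_csv(outdir / "mixture_counts.tsv", sep="\t",
                     index_label="gene_id")
    mx.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    rows = [(pop, g) for pop, genes in mx.markers.items() for g in genes]
    pd.DataFrame(rows, columns=["population", "gene_id"]).to_csv(
        outdir / "markers.tsv", sep="\t", index=False
    )
    mx.truth.to_csv(outdir / "mixture_truth.tsv", sep="\t", index=False)


def write_params(params: SimulationParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(params), fh, indent=2, default=list)
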