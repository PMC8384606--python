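"""Diversity accounting: per-line SNP counts, elite-vs-exotic contrasts,
binned density tracks, windowed Hudson Fst, and the Evanno delta-K statistic.

Per-line SNP counts follow the de novo calling convention of the emulated
study: a SNP is counted for a line iff the line is homozygous for the
alternative allele (heterozygous calls are excluded with a logged count).
The elite-vs-exotic contrast is the percentage difference of group means,
100 * (exotic - elite) / elite.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genome
from .genotype import GenotypeMatrix, HOM_ALT, HET, MISSING

log = logging.getLogger(__name__)

FST_WINDOW = 500_000


# ---------------------------------------------------------------------------
# per-line counts and contrasts
# ---------------------------------------------------------------------------

def per_line_snp_counts(
    matrix: GenotypeMatrix,
    unit: str = "chromosome",
    subgenome_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """HOM_ALT SNP counts per sample per chromosome or subgenome.

    Returns a DataFrame indexed by sample with one column per unit; subgenome
    counts are sums over the unit's chromosomes.
    """
    if unit not in ("chromosome", "subgenome"):
        raise ValueError("unit must be 'chromosome' or 'subgenome'")
    n_het = int((matrix.calls == HET).sum())
    if n_het:
        log.info("per_line_snp_counts: excluding %d heterozygous calls", n_het)
    hom_alt = (matrix.calls == HOM_ALT).astype(np.int64)
    chroms = matrix.loci["chrom"].to_numpy()
    out = {}
    for chrom in pd.unique(chroms):
        out[chrom] = hom_alt[chroms == chrom].sum(axis=0)
    df = pd.DataFrame(out, index=matrix.samples)
    if unit == "chromosome":
        return df
    subs = {}
    for chrom in df.columns:
        sub = genome.subgenome_of(chrom, subgenome_map)
        subs.setdefault(sub, []).append(chrom)
    return pd.DataFrame(
        {sub: df[cols].sum(axis=1) for sub, cols in sorted(subs.items())}
    )


def density_contrast(elite_mean: float, exotic_mean: float) -> float:
    """Percentage difference of group mean counts: 100*(exotic-elite)/elite.

    Rounded to 2 decimals for reporting; NaN when the elite mean is zero.
    """
    if elite_mean == 0:
        return float("nan")
    return round(100.0 * (exotic_mean - elite_mean) / elite_mean, 2)


def contrast_table(
    counts: pd.DataFrame, elite_samples: Sequence[str], exotic_samples: Sequence[str]
) -> pd.DataFrame:
    """Elite/exotic mean counts and percentage difference per unit column."""
    if not elite_samples or not exotic_samples:
        raise ValueError("both groups must be non-empty")
    rows = []
    for unit in counts.columns:
        elite = float(counts.loc[list(elite_samples), unit].mean())
        exotic = float(counts.loc[list(exotic_samples), unit].mean())
        rows.append((unit, elite, exotic, density_contrast(elite, exotic)))
    return pd.DataFrame(
        rows, columns=["unit", "elite_mean", "exotic_mean", "pct_difference"]
    )


# ---------------------------------------------------------------------------
# binned density
# ---------------------------------------------------------------------------

def binned_density(
    matrix: GenotypeMatrix,
    chrom_sizes: Mapping[str, int],
    bin_width: int = 100_000,
    sample: str | None = None,
) -> pd.DataFrame:
    """SNP counts in fixed-width bins (panel loci, or one line's HOM_ALT calls).

    Returns the full tiling as ``chrom, start, end, count``; the last bin of
    each chromosome is truncated at the chromosome end.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    bins = genome.tile_bins(chrom_sizes, bin_width)
    offset = {}
    acc = 0
    for chrom, length in chrom_sizes.items():
        offset[chrom] = acc
        acc += genome.n_bins(length, bin_width)
    counts = np.zeros(len(bins), dtype=np.int64)
    if matrix.n_loci:
        keep = np.ones(matrix.n_loci, dtype=bool)
        if sample is not None:
            keep = matrix.calls[:, matrix.sample_index(sample)] == HOM_ALT
        chroms = matrix.loci["chrom"].to_numpy()[keep]
        pos0 = matrix.loci["pos"].to_numpy()[keep] - 1
        for chrom in pd.unique(chroms):
            if chrom not in offset:
                raise ValueError(f"chromosome {chrom!r} not in chromosome sizes")
            sel = chroms == chrom
            ids = offset[chrom] + pos0[sel] // bin_width
            counts += np.bincount(ids, minlength=len(bins))
    out = bins.copy()
    out["count"] = counts
    return out


# ---------------------------------------------------------------------------
# windowed Fst
# ---------------------------------------------------------------------------

def _group_allele_stats(
    matrix: GenotypeMatrix, samples: Sequence[str], inbred: bool = True
):
    """Alt-allele frequency and effective allele count per locus for a group.

    With ``inbred`` (default) each line counts as a single allele draw — the
    right sampling model for a panel of homozygous inbred lines, where the
    two alleles of a line are copies, not independent draws.  ``inbred=False``
    uses standard diploid counting (2 alleles per called sample, HET = 1 alt).
    """
    idx = [matrix.sample_index(s) for s in samples]
    sub = matrix.calls[:, idx]
    called = sub != MISSING
    if inbred:
        n_alleles = called.sum(axis=1)
        alt = (sub == HOM_ALT).sum(axis=1) + 0.5 * (sub == HET).sum(axis=1)
    else:
        n_alleles = 2 * called.sum(axis=1)
        alt = 2 * (sub == HOM_ALT).sum(axis=1) + (sub == HET).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles


def hudson_components(p1, n1, p2, n2):
    """Per-SNP Hudson numerator/denominator from allele frequencies/counts.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    SNPs with fewer than 2 alleles observed in either group are unusable
    (returned as NaN).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    num = np.full(p1.shape, np.nan)
    den = np.full(p1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        num[ok] = (
            (p1[ok] - p2[ok]) ** 2
            - p1[ok] * (1 - p1[ok]) / (n1[ok] - 1)
            - p2[ok] * (1 - p2[ok]) / (n2[ok] - 1)
        )
        den[ok] = p1[ok] * (1 - p2[ok]) + p2[ok] * (1 - p1[ok])
    return num, den


def windowed_fst(
    matrix: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    chrom_sizes: Mapping[str, int],
    window: int = FST_WINDOW,
    inbred: bool = True,
) -> pd.DataFrame:
    """Hudson Fst in fixed windows as a ratio of per-SNP sums.

    Windows tile each chromosome from position 0 (0-based half-open).  Per
    window, Fst = sum(num)/sum(den) over usable SNPs; windows without any SNP
    contributing a positive denominator (no polymorphism, no differentiation)
    carry NaN.  ``fst`` is clipped to [0, 1] for reporting; ``fst_raw`` keeps
    the unclipped estimate (slightly negative under no differentiation).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    p1, n1 = _group_allele_stats(matrix, group_a, inbred=inbred)
    p2, n2 = _group_allele_stats(matrix, group_b, inbred=inbred)
    num, den = hudson_components(p1, n1, p2, n2)

    bins = genome.tile_bins(chrom_sizes, window)
    bins = bins.assign(bin_id=np.arange(len(bins)))
    offset = {c: g["bin_id"].iloc[0] for c, g in bins.groupby("chrom", sort=False)}
    chroms = matrix.loci["chrom"].to_numpy()
    pos0 = matrix.loci["pos"].to_numpy() - 1
    ids = np.empty(matrix.n_loci, dtype=np.int64)
    for chrom in pd.unique(chroms):
        if chrom not in offset:
            raise ValueError(f"chromosome {chrom!r} not in chromosome sizes")
        sel = chroms == chrom
        ids[sel] = offset[chrom] + pos0[sel] // window

    usable = ~np.isnan(den) & (den > 0)
    num_sum = np.bincount(ids[usable], weights=num[usable], minlength=len(bins))
    den_sum = np.bincount(ids[usable], weights=den[usable], minlength=len(bins))
    n_snps = np.bincount(ids[usable], minlength=len(bins))

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den_sum > 0, num_sum / np.where(den_sum > 0, den_sum, 1), np.nan)
    out = bins[["chrom", "start", "end"]].copy()
    out["fst_raw"] = raw
    out["fst"] = np.clip(raw, 0.0, 1.0)
    out["n_snps"] = n_snps
    return out


def pseudo_split_control(
    matrix: GenotypeMatrix,
    elite_samples: Sequence[str],
    chrom_sizes: Mapping[str, int],
    seed: int,
    window: int = FST_WINDOW,
) -> tuple[pd.DataFrame, tuple[list[str], list[str]]]:
    """Randomly halve the elite panel and compute windowed Fst between halves.

    The genome-wide mean of ``fst_raw`` operationalises "negligibly small":
    the raw Hudson estimator is unbiased around zero under the null, whereas
    averaging values clipped at 0 would bias the mean upward.
    """
    elite_samples = list(elite_samples)
    if len(elite_samples) < 4:
        raise ValueError("pseudo-split needs at least 4 elite samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(elite_samples))
    half = len(elite_samples) // 2
    a = [elite_samples[i] for i in perm[:half]]
    b = [elite_samples[i] for i in perm[half:]]
    track = windowed_fst(matrix, a, b, chrom_sizes, window=window)
    return track, (a, b)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Evanno delta-K over replicate clustering log-likelihoods.

    ``table`` columns: K, replicate, lnP.  For each interior K (with both
    neighbours present), delta-K is the mean over replicates of
    ``|L(K+1) - 2 L(K) + L(K-1)|`` divided by the standard deviation of
    L(K) across replicates.  Requires >= 3 consecutive K values and >= 2
    replicates; sd(L(K)) == 0 is degenerate and raises.
    """
    required = {"K", "replicate", "lnP"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    ks = sorted(table["K"].unique())
    if len(ks) < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    wide = table.pivot_table(index="replicate", columns="K", values="lnP")
    if wide.isna().any().any():
        raise ValueError("every replicate must have lnP for every K")
    if len(wide) < 2:
        raise ValueError("delta-K needs at least 2 replicates per K")
    rows = []
    for i, k in enumerate(ks):
        mean = float(wide[k].mean())
        sd = float(wide[k].std(ddof=1))
        dk = np.nan
        if 0 < i < len(ks) - 1 and ks[i - 1] == k - 1 and ks[i + 1] == k + 1:
            if sd == 0:
                raise ValueError(f"sd of lnP at K={k} is zero (degenerate replicates)")
            second = (wide[k + 1] - 2 * wide[k] + wide[k - 1]).abs().mean()
            dk = float(second) / sd
        rows.append((k, mean, sd, dk))
    out = pd.DataFrame(rows, columns=["K", "mean_lnP", "sd_lnP", "delta_k"])
    return out


def best_k(evanno: pd.DataFrame) -> int:
    """K with the largest delta-K."""
    valid = evanno.dropna(subset=["delta_k"])
    if valid.empty:
        raise ValueError("no interior K with a delta-K value")
    return int(valid.loc[valid["delta_k"].idxmax(), "K"])
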