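"""Genotype IO and call-level rules for capture-sequencing SNP panels.

The central object is :class:`GenotypeMatrix`: an ordered set of biallelic SNP
loci by an ordered set of samples, with calls in {HOM_REF, HET, HOM_ALT,
MISSING} and optional per-call mapping depth.  Three rules operate on it:

* depth-conditioned homozygous-reference designation — a sample with no
  alternative allele call at a locus is designated homozygous reference if its
  mapping depth there is at least 5, otherwise missing;
* varietal-SNP masking — loci matching a mask set in position *and* allele are
  removed (these are background variants between the breeding germplasm and
  the reference cultivar, not donor material);
* locus filtering — loci with <10% missing data and minor allele frequency
  >=5% are retained for panel-level analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# call codes (int8); MISSING covers both "no call" and "below-depth" states
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

ELITE = "elite"
EXOTIC_GROUPS = ("landrace", "synthetic", "landrace_synthetic", "introgression_line")


@dataclass(frozen=True)
class Locus:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("locus position must be >= 1 (1-based)")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Samples x loci homozygous-SNP call matrix with locus metadata.

    ``loci`` is a DataFrame with columns ``chrom, pos, ref, alt`` (pos
    1-based), one row per locus in genomic order; ``calls`` is an int8 array
    of shape (n_loci, n_samples); ``depth`` an optional int array of the same
    shape.
    """

    loci: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.loci = self.loci.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape must match calls shape")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def take_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            loci=self.loci.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[mask],
            depth=None if self.depth is None else self.depth[mask],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            loci=self.loci.copy(),
            samples=list(self.samples),
            calls=self.calls.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def locus_keys(self) -> set[tuple[str, int, str]]:
        """(chrom, pos, alt) keys for every locus."""
        return set(
            zip(self.loci["chrom"], self.loci["pos"].astype(int), self.loci["alt"])
        )


@dataclass
class PanelMetadata:
    """Sample -> subpopulation labels, with the elite/exotic collapse.

    ``table`` has columns ``sample, group`` and optionally ``n_crosses`` (the
    number of crosses after the primary synthetic cross, used for theoretical
    pedigree-contribution estimates).  Any non-elite group is "exotic".
    """

    table: pd.DataFrame

    def __post_init__(self):
        if "sample" not in self.table.columns or "group" not in self.table.columns:
            raise ValueError("metadata requires 'sample' and 'group' columns")
        bad = set(self.table["group"]) - ({ELITE} | set(EXOTIC_GROUPS))
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def group_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample, "group"]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in metadata")
        return row.iloc[0]

    def elite_samples(self) -> list[str]:
        return list(self.table.loc[self.table["group"] == ELITE, "sample"])

    def exotic_samples(self) -> list[str]:
        return list(self.table.loc[self.table["group"] != ELITE, "sample"])

    def n_crosses(self, sample: str) -> int | None:
        if "n_crosses" not in self.table.columns:
            return None
        row = self.table.loc[self.table["sample"] == sample, "n_crosses"]
        if row.empty or pd.isna(row.iloc[0]):
            return None
        return int(row.iloc[0])

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = set(matrix.samples) - set(self.table["sample"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")


def read_metadata(path) -> PanelMetadata:
    df = pd.read_csv(path, sep="\t")
    return PanelMetadata(df)


def write_metadata(meta: PanelMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def read_vcf(path, chrom_sizes: Mapping[str, int] | None = None) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF into a GenotypeMatrix.

    Multiallelic records and indels are skipped (count logged).  ``./.``
    genotypes load as MISSING; the depth-designation rule can later promote
    them to HOM_REF.  FORMAT/DP is captured when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    calls_rows, depth_rows = [], []
    n_skipped = 0
    has_depth = False
    for var in vcf:
        if (not var.is_snp) or len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if chrom_sizes is not None:
            if var.CHROM not in chrom_sizes:
                raise ValueError(f"chromosome {var.CHROM!r} not in chromosome sizes")
            if var.POS > chrom_sizes[var.CHROM]:
                raise ValueError(
                    f"position {var.CHROM}:{var.POS} beyond chromosome length "
                    f"{chrom_sizes[var.CHROM]}"
                )
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # gts012: 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 UNKNOWN
        gt = np.asarray(var.gt_types, dtype=np.int8)
        row = np.where(gt == 3, np.int8(MISSING), gt)
        calls_rows.append(row)
        try:
            dp = var.format("DP")
        except KeyError:  # DP absent from the FORMAT header entirely
            dp = None
        if dp is not None:
            has_depth = True
            dp = np.asarray(dp).reshape(-1).astype(np.int32)
            dp[dp < 0] = 0  # cyvcf2 encodes missing DP as a large negative int
            depth_rows.append(dp)
        else:
            depth_rows.append(np.zeros(len(samples), dtype=np.int32))
    vcf.close()
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = (
        np.vstack(calls_rows) if calls_rows else np.zeros((0, len(samples)), np.int8)
    )
    depth = np.vstack(depth_rows) if (depth_rows and has_depth) else None
    if depth is not None and len(depth) == 0:
        depth = None
    return GenotypeMatrix(loci=loci, samples=samples, calls=calls, depth=depth)


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path,
    chrom_sizes: Mapping[str, int] | None = None,
    ref_as_nocall: bool = False,
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCFv4.2.

    With ``ref_as_nocall`` homozygous-reference calls are emitted as ``./.``
    (the state of raw de novo calls before depth designation); their DP then
    carries the evidence for the designation rule.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exoscan\n")
        if chrom_sizes:
            for chrom, length in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        has_dp = matrix.depth is not None
        fmt = "GT:DP" if has_dp else "GT"
        loci = matrix.loci
        for i in range(matrix.n_loci):
            row = matrix.calls[i]
            if ref_as_nocall:
                row = np.where(row == HOM_REF, np.int8(MISSING), row)
            fields = [
                str(loci.at[i, "chrom"]),
                str(int(loci.at[i, "pos"])),
                ".",
                str(loci.at[i, "ref"]),
                str(loci.at[i, "alt"]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            if has_dp:
                dp = matrix.depth[i]
                cells = [f"{_GT_STR[int(c)]}:{int(d)}" for c, d in zip(row, dp)]
            else:
                cells = [_GT_STR[int(c)] for c in row]
            fh.write("\t".join(fields) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Call-level rules
# ---------------------------------------------------------------------------

def apply_reference_call_rule(
    matrix: GenotypeMatrix, min_depth: int = 5
) -> GenotypeMatrix:
    """Depth-conditioned homozygous-reference designation.

    Entries with no alternative-allele call (MISSING) and mapping depth
    >= ``min_depth`` become HOM_REF; those below depth stay MISSING.  Existing
    HOM_REF/HET/HOM_ALT calls are untouched.
    """
    nocall = matrix.calls == MISSING
    if matrix.depth is None:
        if nocall.any():
            idx = np.argwhere(nocall)[:10]
            pairs = [
                (matrix.samples[j], f"{matrix.loci.at[i, 'chrom']}:{matrix.loci.at[i, 'pos']}")
                for i, j in idx
            ]
            raise ValueError(
                "depth required to designate no-calls; first affected "
                f"(sample, locus) pairs: {pairs}"
            )
        return matrix.copy()
    out = matrix.copy()
    promote = nocall & (matrix.depth >= min_depth)
    out.calls[promote] = HOM_REF
    return out


def _mask_sites(mask) -> set[tuple[str, int, str]]:
    """Accept a DonorSNPSet-like object (``.sites``) or a plain set of keys."""
    if hasattr(mask, "sites"):
        return mask.sites
    return set(mask)


def mask_varietal_snps(matrix: GenotypeMatrix, mask) -> GenotypeMatrix:
    """Drop loci matching the varietal mask in position and allele.

    A locus is removed iff its (chrom, pos, alt) key is in the mask; the same
    position with a different alt allele is kept.
    """
    sites = _mask_sites(mask)
    if not sites:
        return matrix.copy()
    keys = list(
        zip(matrix.loci["chrom"], matrix.loci["pos"].astype(int), matrix.loci["alt"])
    )
    keep = np.fromiter((k not in sites for k in keys), dtype=bool, count=len(keys))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("mask_varietal_snps: removed %d varietal loci", n_dropped)
    return matrix.take_loci(keep)


def locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus missing fraction and minor allele frequency.

    Missingness is relative to the total sample count.  MAF is computed over
    non-missing calls with HOM_ALT contributing 2 alt alleles and HET 1; a
    locus with every call missing gets MAF 0 (never divides by zero).
    """
    calls = matrix.calls
    n = matrix.n_samples
    n_missing = (calls == MISSING).sum(axis=1)
    n_called = n - n_missing
    alt_alleles = 2 * (calls == HOM_ALT).sum(axis=1) + (calls == HET).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_called > 0, alt_alleles / (2 * np.maximum(n_called, 1)), 0.0)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return pd.DataFrame(
        {
            "missing_frac": n_missing / n,
            "maf": maf,
            "n_called": n_called,
        }
    )


def filter_loci(
    matrix: GenotypeMatrix,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
    return_report: bool = False,
):
    """Retain loci with missing fraction < ``max_missing`` and MAF >= ``min_maf``.

    Returns the filtered matrix, plus a per-dropped-locus report DataFrame
    (``chrom, pos, alt, reason``) when ``return_report`` is set.
    """
    stats = locus_stats(matrix)
    ok_missing = stats["missing_frac"].to_numpy() < max_missing
    ok_maf = stats["maf"].to_numpy() >= min_maf
    keep = ok_missing & ok_maf
    out = matrix.take_loci(keep)
    if not return_report:
        return out
    reasons = np.where(
        ~ok_missing & ~ok_maf,
        "missing+maf",
        np.where(~ok_missing, "missing", np.where(~ok_maf, "maf", "")),
    )
    dropped = matrix.loci.loc[~keep, ["chrom", "pos", "alt"]].copy()
    dropped["reason"] = reasons[~keep]
    return out, dropped.reset_index(drop=True)


def impute_mode(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Optional stub: fill MISSING calls with the per-locus modal call.

    This is a convenience for downstream tools that cannot handle missing
    data; it is NOT part of the analysis rules (the study pipeline used an
    external haplotype-based imputer at this point).
    """
    out = matrix.copy()
    for i in range(out.n_loci):
        row = out.calls[i]
        miss = row == MISSING
        if not miss.any():
            continue
        called = row[~miss]
        if called.size == 0:
            continue
        vals, counts = np.unique(called, return_counts=True)
        out.calls[i, miss] = vals[np.argmax(counts)]
    return out
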