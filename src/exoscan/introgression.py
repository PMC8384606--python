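"""Identity-by-state donor-region detection in fixed 500-kbp bins.

The method: per line, homozygous-alternative SNP calls are binned into 500-kbp
windows, and within each bin the number of SNPs identical by state to a donor
taxon's callset (matching in position and allele) is counted.  A bin is
classified as donor-derived when the line's bin SNP count is at least 5-fold
the mean count for that bin across the elite subpopulation.  Classified bins
are merged into segments, summed into per-line donor fractions of the target
subgenome, and pooled across the panel into a non-redundant donor-bin union.

The 5-fold rule is undefined where the elite baseline is zero; a floor of 1.0
on the baseline and a minimum absolute count of 10 SNPs in the bin guard
against SNP-poor regions classifying on a handful of calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import genome
from .genotype import GenotypeMatrix, HOM_ALT, _mask_sites

log = logging.getLogger(__name__)

DEFAULT_BIN = 500_000
DEFAULT_FOLD = 5.0
DEFAULT_MIN_BASELINE = 1.0
DEFAULT_MIN_COUNT = 10


@dataclass
class DonorSNPSet:
    """Reference-relative variant set for one donor taxon.

    ``sites`` holds (chrom, pos, alt) keys (pos 1-based) for fast identity-by-
    state lookup; ``table`` keeps the full records (chrom, pos, ref, alt).
    """

    name: str
    sites: set[tuple[str, int, str]]
    table: pd.DataFrame = field(repr=False)

    @classmethod
    def from_table(cls, name: str, table: pd.DataFrame) -> "DonorSNPSet":
        table = table.reset_index(drop=True)
        sites = set(zip(table["chrom"], table["pos"].astype(int), table["alt"]))
        return cls(name=name, sites=sites, table=table)

    def __len__(self) -> int:
        return len(self.sites)

    def difference(self, mask) -> "DonorSNPSet":
        """Remove entries present in ``mask`` (position-and-allele match)."""
        other = _mask_sites(mask)
        if not other:
            return DonorSNPSet.from_table(self.name, self.table.copy())
        keys = list(
            zip(self.table["chrom"], self.table["pos"].astype(int), self.table["alt"])
        )
        keep = np.fromiter((k not in other for k in keys), dtype=bool, count=len(keys))
        return DonorSNPSet.from_table(self.name, self.table.loc[keep])


def build_donor_snpset(
    vcf_path,
    name: str,
    mask=None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> DonorSNPSet:
    """Ingest a donor-vs-reference VCF into a DonorSNPSet.

    Only biallelic SNPs are kept (indels/multiallelics logged and skipped);
    entries matching the varietal mask in position and allele are removed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    rows = []
    n_skipped = 0
    for var in vcf:
        if (not var.is_snp) or len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if chrom_sizes is not None and var.CHROM not in chrom_sizes:
            raise ValueError(
                f"donor VCF contig {var.CHROM!r} not in chromosome sizes"
            )
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if n_skipped:
        log.info("build_donor_snpset(%s): skipped %d non-SNP records", name, n_skipped)
    table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    donor = DonorSNPSet.from_table(name, table)
    if mask is not None:
        donor = donor.difference(mask)
    return donor


def write_sites_vcf(
    table: pd.DataFrame,
    path,
    chrom_sizes: Mapping[str, int] | None = None,
    sample_name: str | None = None,
) -> None:
    """Write a (chrom, pos, ref, alt) table as a VCF (site-only or one 1/1 sample)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=exoscan\n")
        if chrom_sizes:
            for chrom, length in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if sample_name:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            header += f"\tFORMAT\t{sample_name}"
        fh.write(header + "\n")
        for _, r in table.iterrows():
            line = f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t."
            if sample_name:
                line += "\tGT\t1/1"
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# binned counting
# ---------------------------------------------------------------------------

def donor_match_flags(matrix: GenotypeMatrix, donor: DonorSNPSet) -> np.ndarray:
    """Per-locus boolean: locus (chrom, pos, alt) is in the donor set."""
    keys = list(
        zip(matrix.loci["chrom"], matrix.loci["pos"].astype(int), matrix.loci["alt"])
    )
    return np.fromiter(
        (k in donor.sites for k in keys), dtype=bool, count=len(keys)
    )


def _bin_frame(chrom_sizes: Mapping[str, int], bin_width: int) -> pd.DataFrame:
    bins = genome.tile_bins(chrom_sizes, bin_width)
    bins["bin_id"] = np.arange(len(bins))
    return bins


def _locus_bin_ids(
    matrix: GenotypeMatrix, bins: pd.DataFrame, bin_width: int
) -> np.ndarray:
    offset = {c: g["bin_id"].iloc[0] for c, g in bins.groupby("chrom", sort=False)}
    chroms = matrix.loci["chrom"].to_numpy()
    pos0 = matrix.loci["pos"].to_numpy() - 1
    ids = np.empty(len(chroms), dtype=np.int64)
    for chrom in pd.unique(chroms):
        if chrom not in offset:
            raise ValueError(f"locus chromosome {chrom!r} not in chromosome sizes")
        sel = chroms == chrom
        ids[sel] = offset[chrom] + pos0[sel] // bin_width
    return ids


def bin_match_profile(
    matrix: GenotypeMatrix,
    sample: str,
    donor: DonorSNPSet,
    chrom_sizes: Mapping[str, int],
    bin_width: int = DEFAULT_BIN,
    match_flags: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bin (total, donor-matching) HOM_ALT SNP counts for one line.

    A SNP counts as matching when the line is HOM_ALT at a locus whose
    (chrom, pos, alt) is in the donor set.  Returns the full bin tiling with
    columns ``chrom, start, end, total, matching``.
    """
    bins = _bin_frame(chrom_sizes, bin_width)
    ids = _locus_bin_ids(matrix, bins, bin_width)
    j = matrix.sample_index(sample)
    hom_alt = matrix.calls[:, j] == HOM_ALT
    if match_flags is None:
        match_flags = donor_match_flags(matrix, donor)
    total = np.bincount(ids[hom_alt], minlength=len(bins))
    matching = np.bincount(ids[hom_alt & match_flags], minlength=len(bins))
    out = bins[["chrom", "start", "end"]].copy()
    out["total"] = total
    out["matching"] = matching
    return out


def elite_baseline(
    matrix: GenotypeMatrix,
    elite_samples: Sequence[str],
    chrom_sizes: Mapping[str, int],
    bin_width: int = DEFAULT_BIN,
) -> pd.DataFrame:
    """Mean per-bin HOM_ALT SNP count across the elite subpopulation."""
    if not elite_samples:
        raise ValueError("elite baseline requires at least one elite line")
    bins = _bin_frame(chrom_sizes, bin_width)
    ids = _locus_bin_ids(matrix, bins, bin_width)
    acc = np.zeros(len(bins), dtype=float)
    for s in elite_samples:
        j = matrix.sample_index(s)
        acc += np.bincount(ids[matrix.calls[:, j] == HOM_ALT], minlength=len(bins))
    out = bins[["chrom", "start", "end"]].copy()
    out["baseline"] = acc / len(elite_samples)
    return out


def classify_donor_bins(
    profile: pd.DataFrame,
    baseline: pd.DataFrame,
    fold: float = DEFAULT_FOLD,
    min_baseline: float = DEFAULT_MIN_BASELINE,
    min_count: int = DEFAULT_MIN_COUNT,
    use_matching: bool = False,
) -> pd.DataFrame:
    """Apply the 5-fold-over-elite-baseline rule per bin.

    A bin is donor-classified iff
    ``count >= fold * max(baseline, min_baseline)`` and ``count >= min_count``,
    where ``count`` is the bin's total SNP count (or the donor-matching count
    with ``use_matching``).  Returns the profile with ``baseline``,
    ``fold_change`` and boolean ``donor`` columns added.
    """
    if len(profile) != len(baseline):
        raise ValueError("profile and baseline must share one bin tiling")
    out = profile.copy()
    base = baseline["baseline"].to_numpy(dtype=float)
    out["baseline"] = base
    count = out["matching" if use_matching else "total"].to_numpy(dtype=float)
    floored = np.maximum(base, min_baseline)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_change"] = np.where(floored > 0, count / floored, np.inf)
    out["donor"] = (count >= fold * floored) & (count >= min_count)
    return out


@dataclass(frozen=True)
class IntrogressionSegment:
    """A contiguous donor-classified interval (bin-aligned, 0-based half-open)."""

    line: str
    donor: str
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_fold_change: float
    mean_match_proportion: float

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_segments(
    classified: pd.DataFrame,
    line: str = "",
    donor: str = "",
    max_gap_bins: int = 0,
) -> list[IntrogressionSegment]:
    """Merge runs of donor bins into segments.

    Runs on the same chromosome separated by at most ``max_gap_bins``
    non-donor bins are joined (gap bins contribute to the span but not to the
    per-segment means).  Default 0: contiguity must come from the data.
    """
    segments: list[IntrogressionSegment] = []
    for chrom, grp in classified.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        donor_idx = np.flatnonzero(grp["donor"].to_numpy())
        if donor_idx.size == 0:
            continue
        runs: list[list[int]] = [[int(donor_idx[0])]]
        for i in donor_idx[1:]:
            if i - runs[-1][-1] - 1 <= max_gap_bins:
                runs[-1].append(int(i))
            else:
                runs.append([int(i)])
        for run in runs:
            rows = grp.loc[run]
            total = rows["total"].to_numpy(dtype=float)
            matching = rows["matching"].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                prop = np.where(total > 0, matching / np.maximum(total, 1), 0.0)
            segments.append(
                IntrogressionSegment(
                    line=line,
                    donor=donor,
                    chrom=chrom,
                    start=int(grp.at[run[0], "start"]),
                    end=int(grp.at[run[-1], "end"]),
                    n_bins=len(run),
                    mean_fold_change=float(rows["fold_change"].mean()),
                    mean_match_proportion=float(prop.mean()),
                )
            )
    return segments


def donor_fraction(
    segments: Iterable[IntrogressionSegment],
    chrom_sizes: Mapping[str, int],
    subgenome: str,
    subgenome_map: Mapping[str, str] | None = None,
) -> float:
    """Percent of a subgenome covered by donor segments."""
    sub_len = genome.subgenome_length(chrom_sizes, subgenome, subgenome_map)
    span = 0
    for seg in segments:
        if genome.subgenome_of(seg.chrom, subgenome_map) != subgenome:
            raise ValueError(
                f"segment on {seg.chrom} is not in subgenome {subgenome!r}"
            )
        span += seg.length
    return 100.0 * span / sub_len


def panel_union(
    per_line_classified: Iterable[pd.DataFrame],
    chrom_sizes: Mapping[str, int] | None = None,
    subgenome: str | None = None,
    subgenome_map: Mapping[str, str] | None = None,
) -> dict:
    """Non-redundant union of donor bins across lines.

    Returns bin count, total span in Gbp (truncated terminal bins contribute
    their true width) and, when chromosome sizes are given, the percent of
    the (sub)genome covered.
    """
    union: dict[tuple[str, int, int], None] = {}
    for classified in per_line_classified:
        for _, r in classified.loc[classified["donor"]].iterrows():
            union[(r["chrom"], int(r["start"]), int(r["end"]))] = None
    span_bp = sum(end - start for _, start, end in union)
    out = {"n_bins": len(union), "span_gbp": round(span_bp / 1e9, 2), "span_bp": span_bp}
    if chrom_sizes is not None:
        if subgenome is not None:
            denom = genome.subgenome_length(chrom_sizes, subgenome, subgenome_map)
        else:
            denom = sum(chrom_sizes.values())
        out["pct_of_genome"] = 100.0 * span_bp / denom
    return out


def theoretical_contribution(n_crosses_after_primary: int) -> float:
    """Expected donor contribution (%) after n crosses: 100 x 0.5^n."""
    if n_crosses_after_primary < 0:
        raise ValueError("number of crosses must be non-negative")
    return 100.0 * 0.5 ** n_crosses_after_primary


def detect_alien(
    matrix: GenotypeMatrix,
    sample: str,
    donor: DonorSNPSet,
    elite_samples: Sequence[str],
    chrom_sizes: Mapping[str, int],
    bin_width: int = DEFAULT_BIN,
    fold: float = DEFAULT_FOLD,
    min_baseline: float = DEFAULT_MIN_BASELINE,
    min_count: int = DEFAULT_MIN_COUNT,
    max_gap_bins: int = 0,
    baseline: pd.DataFrame | None = None,
    use_matching: bool = False,
) -> list[IntrogressionSegment]:
    """One-line donor scan: profile -> classify -> merge for any donor taxon.

    The identical machinery serves the primary donor on its subgenome and
    alien donors (e.g. rye) on any chromosome.
    """
    if baseline is None:
        baseline = elite_baseline(matrix, elite_samples, chrom_sizes, bin_width)
    profile = bin_match_profile(matrix, sample, donor, chrom_sizes, bin_width)
    classified = classify_donor_bins(
        profile, baseline, fold=fold, min_baseline=min_baseline,
        min_count=min_count, use_matching=use_matching,
    )
    return merge_segments(classified, line=sample, donor=donor.name,
                          max_gap_bins=max_gap_bins)


def scan_panel(
    matrix: GenotypeMatrix,
    metadata,
    donor: DonorSNPSet,
    chrom_sizes: Mapping[str, int],
    bin_width: int = DEFAULT_BIN,
    fold: float = DEFAULT_FOLD,
    min_baseline: float = DEFAULT_MIN_BASELINE,
    min_count: int = DEFAULT_MIN_COUNT,
    max_gap_bins: int = 0,
    subgenome: str | None = None,
    subgenome_map: Mapping[str, str] | None = None,
    use_matching: bool = False,
) -> dict:
    """Panel-wide donor scan over every exotic line.

    Returns per-line classified bin tables and segments, per-line donor
    fractions of ``subgenome`` (default: the donor scan is genome-wide, the
    fraction needs a subgenome), the panel union, and theoretical pedigree
    contributions where cross counts are available in the metadata.
    """
    elites = metadata.elite_samples()
    baseline = elite_baseline(matrix, elites, chrom_sizes, bin_width)
    match = donor_match_flags(matrix, donor)
    per_line: dict[str, pd.DataFrame] = {}
    segments: dict[str, list[IntrogressionSegment]] = {}
    fractions: dict[str, float] = {}
    theoretical: dict[str, float] = {}
    for line in metadata.exotic_samples():
        profile = bin_match_profile(
            matrix, line, donor, chrom_sizes, bin_width, match_flags=match
        )
        classified = classify_donor_bins(
            profile, baseline, fold=fold, min_baseline=min_baseline,
            min_count=min_count, use_matching=use_matching,
        )
        per_line[line] = classified
        segments[line] = merge_segments(
            classified, line=line, donor=donor.name, max_gap_bins=max_gap_bins
        )
        if subgenome is not None:
            sub_segs = [
                s for s in segments[line]
                if genome.subgenome_of(s.chrom, subgenome_map) == subgenome
            ]
            fractions[line] = donor_fraction(
                sub_segs, chrom_sizes, subgenome, subgenome_map
            )
        k = metadata.n_crosses(line)
        if k is not None:
            theoretical[line] = theoretical_contribution(k)
    union = panel_union(
        per_line.values(), chrom_sizes, subgenome=subgenome,
        subgenome_map=subgenome_map,
    )
    return {
        "baseline": baseline,
        "classified": per_line,
        "segments": segments,
        "fractions": fractions,
        "theoretical_contribution": theoretical,
        "union": union,
    }


def segments_to_bed(segments: Iterable[IntrogressionSegment]) -> pd.DataFrame:
    """Segments as a BED6-style table (name = line;donor, score = fold)."""
    rows = [
        (
            s.chrom, s.start, s.end, f"{s.line};{s.donor}",
            round(s.mean_fold_change, 3), ".",
        )
        for s in segments
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
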