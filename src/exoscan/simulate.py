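"""Synthetic study generator: wheat panel genotypes, donor sets, spectra, traits.

Emulates the structure of a hexaploid wheat diversity panel in which part of
the panel ("exotic" lines, here the synthetic-derivative subpopulation)
carries chromosome blocks introgressed from a wild-relative donor, on top of
an elite breeding background:

* elite-background SNPs segregate panel-wide at subgenome-specific densities
  of order 10-25 SNPs/Mbp per line;
* each exotic line carries donor blocks on the donor subgenome, produced by a
  pedigree of backcross-style rounds with 1-2 crossovers per chromosome per
  cross, so the expected donor fraction dilutes as 0.5^k with k crosses and
  the material stays block-structured;
* inside donor blocks the line is homozygous-alternative at the donor's
  diverged positions (identity by state with the donor), at a density several
  fold above the elite background;
* varietal noise (reference-vs-germplasm background variation that is not
  donor material) is written both into the panel and into a mask VCF;
* homozygous-reference evidence is encoded the way de novo callers leave it:
  no-call genotypes whose DP carries the depth evidence for the
  reference-designation rule.

The generator also produces leaf reflectance spectra with pigment-driven
absorption features and multi-environment trait tables with configurable
genotype / genotype-by-year / error variance components, so the phenomics
stage is testable against known truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genome
from .genotype import (
    GenotypeMatrix,
    PanelMetadata,
    HOM_ALT,
    HET,
    MISSING,
    write_metadata,
    write_vcf,
)
from .introgression import DonorSNPSet, write_sites_vcf

DEFAULT_CHROMOSOMES: tuple[tuple[str, int, str], ...] = (
    ("chr1A", 90_000_000, "A"),
    ("chr2A", 70_000_000, "A"),
    ("chr3A", 50_000_000, "A"),
    ("chr1B", 100_000_000, "B"),
    ("chr2B", 80_000_000, "B"),
    ("chr3B", 60_000_000, "B"),
    ("chr1D", 90_000_000, "D"),
    ("chr2D", 70_000_000, "D"),
    ("chr3D", 50_000_000, "D"),
)


@dataclass(frozen=True)
class AlienDonor:
    """An extra donor taxon contributing one fixed introgressed interval.

    ``carriers`` is either a count of exotic lines to draw or an explicit
    tuple of line names.  Donor-diverged positions are generated along the
    whole chromosome (the donor callset covers the genome); carriers are
    homozygous-alternative only inside [start, end).  ``snp_rate`` defaults
    higher than the primary donor's: alien taxa such as rye are far more
    diverged from bread wheat than the D-genome progenitor is.
    """

    name: str
    chrom: str
    start: int
    end: int
    carriers: int | tuple[str, ...] = 1
    snp_rate: float = 300.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults follow the structure of the emulated capture-sequencing study:
    per-line elite SNP densities of 16/25/9 SNPs/Mbp on the A/B/D subgenomes,
    donor-diverged density of 150 SNPs/Mbp inside introgressed blocks, 1-2
    crossovers per chromosome per cross, 2-6 crosses after the primary
    synthetic, and realized donor fractions spanning 0.5-43% of the donor
    subgenome.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int, str], ...] = DEFAULT_CHROMOSOMES
    n_elite: int = 20
    n_exotic: int = 10
    elite_snp_rate: Mapping[str, float] = field(
        default_factory=lambda: {"A": 16.0, "B": 25.0, "D": 9.0}
    )
    donor_snp_rate: float = 150.0
    donor_name: str = "Ae_tauschii"
    donor_subgenome: str = "D"
    donor_fraction_range: tuple[float, float] = (0.005, 0.43)
    crossovers_per_chrom_per_cross: tuple[int, int] = (1, 2)
    n_crosses_range: tuple[int, int] = (2, 6)
    min_breakpoint_spacing: int = 2_000_000
    # varietal (reference-vs-germplasm) noise
    varietal_rate: float = 1.0  # scattered panel-wide SNPs per Mbp
    varietal_hotspots: int = 12  # divergent haplotype blocks
    varietal_hotspot_span: int = 2_000_000
    varietal_hotspot_rate: float = 80.0  # SNPs per Mbp inside a block
    varietal_carrier_range: tuple[float, float] = (0.05, 1.0)  # log-uniform
    missing_rate: float = 0.05
    het_rate: float = 0.0
    alien_donors: tuple[AlienDonor, ...] = ()
    # reflectance spectra
    chl_range: tuple[float, float] = (0.3, 0.9)
    car_range: tuple[float, float] = (0.1, 0.4)
    water_range: tuple[float, float] = (0.1, 0.5)
    spectra_noise_sd: float = 0.005
    # trait variance components (trait units squared)
    sigma_g2: float = 2.0
    sigma_ge2: float = 1.0
    sigma_e2: float = 4.0
    trait_mu: float = 50.0
    n_environments: int = 2  # e (years)
    n_reps: int = 4  # r

    def validate(self) -> None:
        if any(length <= 0 for _, length, _ in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        lo, hi = self.donor_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("donor_fraction_range must satisfy 0 <= min <= max <= 1")
        for rate in (
            self.donor_snp_rate,
            self.varietal_rate,
            self.varietal_hotspot_rate,
            *self.elite_snp_rate.values(),
        ):
            if rate < 0:
                raise ValueError("SNP rates must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.chl_range + self.car_range + self.water_range) < 0:
            raise ValueError("pigment parameters must be non-negative")
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_e2) < 0:
            raise ValueError("variance components must be non-negative")
        for chrom, length, sub in self.chromosomes:
            if sub == self.donor_subgenome and length < 4 * self.min_breakpoint_spacing:
                raise ValueError(
                    f"chromosome {chrom} ({length} bp) too short to host the "
                    f"crossover model (needs >= {4 * self.min_breakpoint_spacing} bp)"
                )

    def chrom_sizes(self) -> dict[str, int]:
        return {name: length for name, length, _ in self.chromosomes}

    def subgenome_map(self) -> dict[str, str]:
        return {name: sub for name, _, sub in self.chromosomes}


@dataclass
class TruthSet:
    """Ground truth for recovery tests: implanted segments and fractions.

    ``segments`` columns: line, donor, chrom, start, end (0-based half-open).
    ``fractions`` columns: line, subgenome, fraction (of subgenome length,
    donor material from the primary donor taxon).
    """

    segments: pd.DataFrame
    fractions: pd.DataFrame
    variance_components: dict

    def validate(self, chrom_sizes: Mapping[str, int]) -> None:
        for _, row in self.segments.iterrows():
            if not (0 <= row["start"] < row["end"] <= chrom_sizes[row["chrom"]]):
                raise ValueError(f"truth segment out of bounds: {tuple(row)}")
        for (line, donor, chrom), grp in self.segments.groupby(
            ["line", "donor", "chrom"]
        ):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping truth segments for {line}/{donor}/{chrom}")

    def line_segments(self, line: str, donor: str | None = None) -> pd.DataFrame:
        seg = self.segments[self.segments["line"] == line]
        if donor is not None:
            seg = seg[seg["donor"] == donor]
        return seg.reset_index(drop=True)


@dataclass
class SimulatedPanel:
    """In-memory bundle of all simulated inputs, writable to standard files."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    matrix: GenotypeMatrix  # raw calls: HOM_REF encoded as MISSING with DP evidence
    donors: dict[str, DonorSNPSet]
    varietal_mask: DonorSNPSet
    metadata: PanelMetadata
    truth: TruthSet

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"panel_vcf": outdir / "panel.vcf"}
        write_vcf(self.matrix, paths["panel_vcf"], self.chrom_sizes)
        for name, donor in self.donors.items():
            p = outdir / f"donor_{name}.vcf"
            write_sites_vcf(donor.table, p, self.chrom_sizes, sample_name=name)
            paths[f"donor_{name}"] = p
        paths["mask_vcf"] = outdir / "varietal_mask.vcf"
        write_sites_vcf(self.varietal_mask.table, paths["mask_vcf"], self.chrom_sizes)
        paths["metadata"] = outdir / "metadata.tsv"
        write_metadata(self.metadata, paths["metadata"])
        paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
        genome.write_chrom_sizes(self.chrom_sizes, paths["chrom_sizes"])
        paths["truth_bed"] = outdir / "truth_segments.bed"
        with open(paths["truth_bed"], "w") as fh:
            for _, r in self.truth.segments.iterrows():
                fh.write(
                    f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                    f"{r['line']};{r['donor']}\n"
                )
        return paths


# ---------------------------------------------------------------------------
# pedigree / donor-block machinery
# ---------------------------------------------------------------------------

def _draw_point(rng, length, spacing, forbidden, max_tries=200):
    for _ in range(max_tries):
        p = int(rng.integers(spacing, length - spacing))
        if all(abs(p - q) >= spacing for q in forbidden):
            return p
    return None


def _pedigree_segments(rng, lengths: dict[str, int], k, xo_range, spacing):
    """Donor intervals per chromosome after k backcross-style rounds.

    Starts from a fully-donor subgenome (primary synthetic); each round places
    1-2 crossover points per chromosome (minimum spacing enforced, modelling
    strong crossover interference and the analysis granularity) and keeps each
    resulting donor piece with probability 1/2, so the expected retained
    fraction is 0.5^k.
    """
    segs = {c: [(0, L)] for c, L in lengths.items()}
    for _ in range(k):
        for chrom, L in lengths.items():
            cur = segs[chrom]
            n_xo = int(rng.integers(xo_range[0], xo_range[1] + 1))
            forbidden = [0, L]
            for s, e in cur:
                forbidden.extend((s, e))
            pts = []
            for _ in range(n_xo):
                p = _draw_point(rng, L, spacing, forbidden + pts)
                if p is not None:
                    pts.append(p)
            pieces = []
            for s, e in cur:
                cuts = sorted([s] + [p for p in pts if s < p < e] + [e])
                pieces.extend(zip(cuts[:-1], cuts[1:]))
            segs[chrom] = [pc for pc in pieces if rng.random() < 0.5]
    # merge abutting pieces
    for chrom in segs:
        merged = []
        for s, e in sorted(segs[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        segs[chrom] = merged
    return segs


def _total_span(segs):
    return sum(e - s for parts in segs.values() for s, e in parts)


def _adjust_fraction(rng, segs, lengths, frac_range, spacing):
    """Clip the realized donor fraction into ``frac_range`` by trimming/adding."""
    L_total = sum(lengths.values())
    lo, hi = frac_range
    total = _total_span(segs)
    f = total / L_total
    if lo <= f <= hi:
        return segs
    target = int(round(min(max(f, lo), hi) * L_total))
    if total > target:
        flat = sorted(
            ((e - s, c, s, e) for c, parts in segs.items() for s, e in parts)
        )
        excess = total - target
        keep: dict[str, list[tuple[int, int]]] = {c: [] for c in segs}
        for length, c, s, e in flat:
            if excess >= length:
                excess -= length  # drop whole segment
            elif excess > 0:
                keep[c].append((s, e - excess))  # shorten from the distal end
                excess = 0
            else:
                keep[c].append((s, e))
        segs = {c: sorted(parts) for c, parts in keep.items()}
    else:
        need = target - total
        chroms = list(lengths)
        for _ in range(50):
            if need <= 0:
                break
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = lengths[chrom]
            occupied = sorted(segs[chrom])
            free = []
            prev = 0
            for s, e in occupied + [(L, L)]:
                if s - prev >= 2 * spacing:
                    free.append((prev, s))
                prev = e
            if not free:
                continue
            fs, fe = free[int(rng.integers(len(free)))]
            avail = fe - fs - 2 * (spacing if (fs > 0 or fe < L) else 0)
            if avail <= 0:
                continue
            span = min(need, avail)
            pad = spacing if fs > 0 else 0
            start = fs + pad
            max_start = fe - (spacing if fe < L else 0) - span
            if max_start > start:
                start = int(rng.integers(start, max_start + 1))
            segs[chrom] = sorted(segs[chrom] + [(start, start + span)])
            need -= span
    return segs


def _sample_positions(rng, length, rate_per_mbp, occupied: set, lo=1, hi=None):
    """Poisson-count unique 1-based positions avoiding ``occupied``."""
    hi = hi if hi is not None else length
    n = rng.poisson(rate_per_mbp * (hi - lo + 1) / 1e6)
    if n == 0:
        return np.array([], dtype=np.int64)
    pos = np.unique(rng.integers(lo, hi + 1, size=n))
    pos = pos[~np.isin(pos, np.fromiter(occupied, dtype=np.int64, count=len(occupied)))] if occupied else pos
    occupied.update(int(p) for p in pos)
    return pos


_BASES = np.array(list("ACGT"))


def _alleles(rng, n):
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_i], _BASES[alt_i]


def _in_segments(pos: np.ndarray, segments: Sequence[tuple[int, int]]) -> np.ndarray:
    """Boolean: which 1-based positions fall inside 0-based half-open segments."""
    out = np.zeros(pos.shape, dtype=bool)
    for s, e in segments:
        out |= (pos > s) & (pos <= e)
    return out


# ---------------------------------------------------------------------------
# panel generator
# ---------------------------------------------------------------------------

def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Generate the full synthetic study: genotypes, donor sets, mask, truth.

    Deterministic: identical config (including seed) gives byte-identical
    outputs when written.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    sizes = config.chrom_sizes()
    submap = config.subgenome_map()

    elite_names = [f"elite_{i + 1:02d}" for i in range(config.n_elite)]
    exotic_names = [f"exotic_{i + 1:02d}" for i in range(config.n_exotic)]
    samples = elite_names + exotic_names
    n_samples = len(samples)

    donor_chroms = {
        c: L for c, L in sizes.items() if submap[c] == config.donor_subgenome
    }

    # --- pedigree: donor truth segments per exotic line ------------------
    lo, hi = config.donor_fraction_range
    seg_rows = []
    n_crosses: dict[str, int] = {}
    for line in exotic_names:
        k = int(rng.integers(config.n_crosses_range[0], config.n_crosses_range[1] + 1))
        n_crosses[line] = k
        expected = 0.5 ** k
        if donor_chroms:
            segs = _pedigree_segments(
                rng,
                donor_chroms,
                k,
                config.crossovers_per_chrom_per_cross,
                config.min_breakpoint_spacing,
            )
            if not (lo <= expected <= hi):
                warnings.warn(
                    f"expected donor fraction 0.5^{k}={expected:.4f} outside "
                    f"donor_fraction_range {config.donor_fraction_range}; clipping",
                    stacklevel=2,
                )
            segs = _adjust_fraction(
                rng, segs, donor_chroms, (lo, hi), config.min_breakpoint_spacing
            )
            for chrom, parts in segs.items():
                for s, e in parts:
                    seg_rows.append((line, config.donor_name, chrom, s, e))

    # --- alien donors ----------------------------------------------------
    alien_carriers: dict[str, list[str]] = {}
    for alien in config.alien_donors:
        if alien.chrom not in sizes:
            raise ValueError(f"alien donor chromosome {alien.chrom!r} unknown")
        if isinstance(alien.carriers, int):
            if alien.carriers > len(exotic_names):
                raise ValueError("not enough exotic lines for alien carriers")
            picked = list(
                rng.choice(exotic_names, size=alien.carriers, replace=False)
            )
        else:
            picked = list(alien.carriers)
        alien_carriers[alien.name] = picked
        for line in picked:
            seg_rows.append((line, alien.name, alien.chrom, alien.start, alien.end))

    truth_segments = pd.DataFrame(
        seg_rows, columns=["line", "donor", "chrom", "start", "end"]
    )

    # --- per-chromosome locus assembly -----------------------------------
    line_segs: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for line in exotic_names:
        sub = truth_segments[
            (truth_segments["line"] == line)
            & (truth_segments["donor"] == config.donor_name)
        ]
        line_segs[line] = {
            c: list(zip(g["start"], g["end"])) for c, g in sub.groupby("chrom")
        }

    # varietal hotspot placement (genome-wide)
    chrom_list = list(sizes)
    chrom_w = np.array([sizes[c] for c in chrom_list], dtype=float)
    chrom_w /= chrom_w.sum()
    hotspots: dict[str, list[tuple[int, int, np.ndarray]]] = {c: [] for c in chrom_list}
    qlo, qhi = config.varietal_carrier_range
    for _ in range(config.varietal_hotspots):
        chrom = chrom_list[int(rng.choice(len(chrom_list), p=chrom_w))]
        span = min(config.varietal_hotspot_span, sizes[chrom] // 2)
        start = int(rng.integers(0, sizes[chrom] - span))
        q = 10 ** rng.uniform(math.log10(qlo), math.log10(qhi))
        carriers = rng.random(n_samples) < q
        if not carriers.any():
            carriers[int(rng.integers(n_samples))] = True
        hotspots[chrom].append((start, start + span, carriers))

    loci_frames = []
    calls_blocks = []
    donor_tables: dict[str, list[pd.DataFrame]] = {config.donor_name: []}
    for alien in config.alien_donors:
        donor_tables.setdefault(alien.name, [])
    mask_tables = []

    for chrom in chrom_list:
        L = sizes[chrom]
        sub = submap[chrom]
        occupied: set[int] = set()
        pos_parts, ref_parts, alt_parts, call_parts = [], [], [], []

        # elite-background segregating loci (carrier prob 1/2 per line)
        elite_pos = _sample_positions(
            rng, L, 2.0 * config.elite_snp_rate[sub], occupied
        )
        if elite_pos.size:
            ref, alt = _alleles(rng, elite_pos.size)
            calls = np.where(
                rng.random((elite_pos.size, n_samples)) < 0.5,
                np.int8(HOM_ALT),
                np.int8(MISSING),
            )
            # inside a donor block the haplotype is donor: no elite alleles
            for line, per_chrom in line_segs.items():
                segs = per_chrom.get(chrom)
                if segs:
                    j = samples.index(line)
                    calls[_in_segments(elite_pos, segs), j] = MISSING
            pos_parts.append(elite_pos)
            ref_parts.append(ref)
            alt_parts.append(alt)
            call_parts.append(calls)

        # primary-donor diverged positions (donor callset covers the subgenome)
        if chrom in donor_chroms and config.donor_snp_rate > 0:
            dpos = _sample_positions(rng, L, config.donor_snp_rate, occupied)
            if dpos.size:
                ref, alt = _alleles(rng, dpos.size)
                donor_tables[config.donor_name].append(
                    pd.DataFrame(
                        {"chrom": chrom, "pos": dpos, "ref": ref, "alt": alt}
                    )
                )
                calls = np.full((dpos.size, n_samples), MISSING, dtype=np.int8)
                for line, per_chrom in line_segs.items():
                    segs = per_chrom.get(chrom)
                    if segs:
                        j = samples.index(line)
                        calls[_in_segments(dpos, segs), j] = HOM_ALT
                seen = (calls == HOM_ALT).any(axis=1)  # caller only reports alt loci
                if seen.any():
                    pos_parts.append(dpos[seen])
                    ref_parts.append(ref[seen])
                    alt_parts.append(alt[seen])
                    call_parts.append(calls[seen])

        # alien donors
        for alien in config.alien_donors:
            if alien.chrom != chrom or alien.snp_rate <= 0:
                continue
            apos = _sample_positions(rng, L, alien.snp_rate, occupied)
            if not apos.size:
                continue
            ref, alt = _alleles(rng, apos.size)
            donor_tables[alien.name].append(
                pd.DataFrame({"chrom": chrom, "pos": apos, "ref": ref, "alt": alt})
            )
            calls = np.full((apos.size, n_samples), MISSING, dtype=np.int8)
            inside = _in_segments(apos, [(alien.start, alien.end)])
            for line in alien_carriers[alien.name]:
                calls[inside, samples.index(line)] = HOM_ALT
            seen = (calls == HOM_ALT).any(axis=1)
            if seen.any():
                pos_parts.append(apos[seen])
                ref_parts.append(ref[seen])
                alt_parts.append(alt[seen])
                call_parts.append(calls[seen])

        # varietal noise: scattered panel-wide + haplotype-structured hotspots
        vpos = _sample_positions(rng, L, config.varietal_rate, occupied)
        if vpos.size:
            ref, alt = _alleles(rng, vpos.size)
            mask_tables.append(
                pd.DataFrame({"chrom": chrom, "pos": vpos, "ref": ref, "alt": alt})
            )
            calls = np.full((vpos.size, n_samples), HOM_ALT, dtype=np.int8)
            pos_parts.append(vpos)
            ref_parts.append(ref)
            alt_parts.append(alt)
            call_parts.append(calls)
        for hs_start, hs_end, carriers in hotspots[chrom]:
            hpos = _sample_positions(
                rng, L, config.varietal_hotspot_rate, occupied,
                lo=hs_start + 1, hi=hs_end,
            )
            if not hpos.size:
                continue
            ref, alt = _alleles(rng, hpos.size)
            mask_tables.append(
                pd.DataFrame({"chrom": chrom, "pos": hpos, "ref": ref, "alt": alt})
            )
            calls = np.where(
                carriers[None, :], np.int8(HOM_ALT), np.int8(MISSING)
            ).repeat(hpos.size, axis=0).reshape(hpos.size, n_samples)
            pos_parts.append(hpos)
            ref_parts.append(ref)
            alt_parts.append(alt)
            call_parts.append(calls)

        if not pos_parts:
            continue
        pos = np.concatenate(pos_parts)
        order = np.argsort(pos, kind="stable")
        loci_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[order],
                    "ref": np.concatenate(ref_parts)[order],
                    "alt": np.concatenate(alt_parts)[order],
                }
            )
        )
        calls_blocks.append(np.vstack(call_parts)[order])

    loci = (
        pd.concat(loci_frames, ignore_index=True)
        if loci_frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    )
    calls = (
        np.vstack(calls_blocks)
        if calls_blocks
        else np.zeros((0, n_samples), dtype=np.int8)
    )

    # heterozygotes (error-path fixture only; default rate 0)
    if config.het_rate > 0:
        flip = (calls == HOM_ALT) & (rng.random(calls.shape) < config.het_rate)
        calls[flip] = HET

    # depth evidence + i.i.d. missingness (DP below threshold)
    depth = rng.integers(5, 46, size=calls.shape).astype(np.int32)
    lost = rng.random(calls.shape) < config.missing_rate
    calls[lost] = MISSING
    depth[lost] = rng.integers(0, 5, size=int(lost.sum()))

    matrix = GenotypeMatrix(loci=loci, samples=samples, calls=calls, depth=depth)

    donors = {
        name: DonorSNPSet.from_table(
            name,
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
        )
        for name, tables in donor_tables.items()
    }
    mask_table = (
        pd.concat(mask_tables, ignore_index=True)
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
        if mask_tables
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    )
    varietal_mask = DonorSNPSet.from_table("varietal", mask_table)

    meta = pd.DataFrame(
        {
            "sample": samples,
            "group": ["elite"] * config.n_elite + ["synthetic"] * config.n_exotic,
            "n_crosses": [np.nan] * config.n_elite
            + [n_crosses.get(s, np.nan) for s in exotic_names],
        }
    )

    sub_len = {
        s: sum(L for c, L in sizes.items() if submap[c] == s)
        for s in {v for v in submap.values()}
    }
    frac_rows = []
    for line in exotic_names:
        primary = truth_segments[
            (truth_segments["line"] == line)
            & (truth_segments["donor"] == config.donor_name)
        ]
        span = float((primary["end"] - primary["start"]).sum())
        frac_rows.append(
            (line, config.donor_subgenome, span / sub_len[config.donor_subgenome])
        )
    truth = TruthSet(
        segments=truth_segments,
        fractions=pd.DataFrame(frac_rows, columns=["line", "subgenome", "fraction"]),
        variance_components={
            "sigma_g2": config.sigma_g2,
            "sigma_ge2": config.sigma_ge2,
            "sigma_e2": config.sigma_e2,
        },
    )
    truth.validate(sizes)

    return SimulatedPanel(
        config=config,
        chrom_sizes=sizes,
        matrix=matrix,
        donors=donors,
        varietal_mask=varietal_mask,
        metadata=PanelMetadata(meta),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# reflectance spectra
# ---------------------------------------------------------------------------

WAVELENGTHS = np.arange(350, 2501)


def _gauss(wl, centre, width):
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def simulate_spectra(
    config: SimConfig, n_samples: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leaf reflectance spectra (350-2500 nm, 1-nm grid) with pigment truth.

    Reflectance is a smooth baseline minus Gaussian absorption features:
    chlorophyll deepens the red-edge troughs near 675/700 nm (plus a mild
    green-region effect), carotenoids absorb near 500 nm, and leaf water
    deepens the 1450/1940 nm bands.  Higher chlorophyll therefore lowers
    R675/R700 and raises red-edge ratios such as R750/R700; higher water
    lowers R1450.  Returns (wide spectra table with a ``wavelength_nm``
    column, truth table with per-sample pigment parameters).
    """
    config.validate()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng([int(config.seed), 1])
    wl = WAVELENGTHS.astype(float)
    base = 0.55 - 0.12 * _gauss(wl, 420, 160) - 0.05 * (wl - 350) / 2150
    chl_abs = 0.35 * _gauss(wl, 675, 25) + 0.25 * _gauss(wl, 700, 16) + 0.10 * _gauss(wl, 550, 45)
    car_abs = 0.30 * _gauss(wl, 500, 28) + 0.10 * _gauss(wl, 435, 20)
    water_abs = 0.55 * _gauss(wl, 1450, 55) + 0.35 * _gauss(wl, 1940, 70) + 0.06 * _gauss(wl, 1200, 45)

    names = [f"sample_{i + 1:03d}" for i in range(n_samples)]
    chl = rng.uniform(*config.chl_range, size=n_samples)
    car = rng.uniform(*config.car_range, size=n_samples)
    water = rng.uniform(*config.water_range, size=n_samples)

    data = {"wavelength_nm": WAVELENGTHS}
    for i, name in enumerate(names):
        refl = base - chl[i] * chl_abs - car[i] * car_abs - water[i] * water_abs
        if config.spectra_noise_sd > 0:
            refl = refl + rng.normal(0.0, config.spectra_noise_sd, size=wl.size)
        data[name] = np.clip(refl, 0.01, 0.99)
    spectra = pd.DataFrame(data)
    pigments = pd.DataFrame(
        {"sample": names, "chlorophyll": chl, "carotenoid": car, "water": water}
    )
    return spectra, pigments


# ---------------------------------------------------------------------------
# multi-environment trait tables
# ---------------------------------------------------------------------------

def simulate_traits(
    config: SimConfig, n_genotypes: int, trait: str = "sim_trait"
) -> pd.DataFrame:
    """Long trait table: value = mu + G_g + GY_gy + error, centred normals.

    Genotype effects G_g ~ N(0, sigma_g2), genotype-by-environment effects
    GY_gy ~ N(0, sigma_ge2), residuals ~ N(0, sigma_e2); ``n_environments``
    years x ``n_reps`` replicates per genotype-year.
    """
    config.validate()
    r, e = config.n_reps, config.n_environments
    if r < 1 or e < 1:
        raise ValueError("replicates and environments must both be >= 1")
    if n_genotypes < 1:
        raise ValueError("n_genotypes must be >= 1")
    rng = np.random.default_rng([int(config.seed), 2])
    g_eff = rng.normal(0.0, math.sqrt(config.sigma_g2), size=n_genotypes)
    ge_eff = rng.normal(0.0, math.sqrt(config.sigma_ge2), size=(n_genotypes, e))
    err = rng.normal(0.0, math.sqrt(config.sigma_e2), size=(n_genotypes, e, r))
    values = config.trait_mu + g_eff[:, None, None] + ge_eff[:, :, None] + err
    idx = pd.MultiIndex.from_product(
        [
            [f"geno_{i + 1:04d}" for i in range(n_genotypes)],
            [f"Y{j + 1}" for j in range(e)],
            np.arange(1, r + 1),
        ],
        names=["genotype", "year", "rep"],
    )
    out = pd.DataFrame({"value": values.reshape(-1)}, index=idx).reset_index()
    out.insert(3, "trait", trait)
    return out
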