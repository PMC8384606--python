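"""Donor SNP sets, bin profiles, the 5-fold rule, segments and accounting."""

import numpy as np
import pandas as pd
import pytest

from conftest import truth_bin_coverage
from exoscan import (
    AlienDonor,
    DonorSNPSet,
    SimConfig,
    simulate_panel,
)
from exoscan.genotype import (
    GenotypeMatrix,
    HOM_REF,
    HOM_ALT,
    apply_reference_call_rule,
    mask_varietal_snps,
)
from exoscan.introgression import (
    bin_match_profile,
    build_donor_snpset,
    classify_donor_bins,
    detect_alien,
    donor_fraction,
    elite_baseline,
    merge_segments,
    panel_union,
    scan_panel,
    theoretical_contribution,
    write_sites_vcf,
)


def _donor(entries, name="donor"):
    table = pd.DataFrame(entries, columns=["chrom", "pos", "ref", "alt"])
    return DonorSNPSet.from_table(name, table)


def _matrix(positions, calls, chrom="chr1D", alts=None):
    calls = np.asarray(calls, dtype=np.int8)
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": alts if alts is not None else "G",
        }
    )
    return GenotypeMatrix(
        loci=loci, samples=[f"s{i}" for i in range(calls.shape[1])], calls=calls
    )


class TestDonorSNPSet:
    def test_mask_set_difference(self, tmp_path):
        entries = [
            ("chr1D", 100, "A", "G"),
            ("chr1D", 200, "C", "T"),
            ("chr1D", 300, "G", "A"),
            ("chr2D", 100, "T", "C"),
        ]
        path = tmp_path / "donor.vcf"
        write_sites_vcf(pd.DataFrame(entries, columns=["chrom", "pos", "ref", "alt"]),
                        path, {"chr1D": 1000, "chr2D": 1000})
        donor = build_donor_snpset(path, "tauschii", mask={("chr1D", 200, "T")})
        assert len(donor) == 3
        assert ("chr1D", 200, "T") not in donor.sites

    def test_empty_vcf_and_indel_skip(self, tmp_path):
        path = tmp_path / "donor.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1D\t100\t.\tAT\tA\t.\tPASS\t.\n"
        )
        donor = build_donor_snpset(path, "x")
        assert len(donor) == 0

    def test_contig_mismatch_errors(self, tmp_path):
        path = tmp_path / "donor.vcf"
        write_sites_vcf(
            pd.DataFrame([("chrUn", 5, "A", "G")],
                         columns=["chrom", "pos", "ref", "alt"]),
            path,
        )
        with pytest.raises(ValueError, match="not in chromosome sizes"):
            build_donor_snpset(path, "x", chrom_sizes={"chr1D": 1000})


class TestBinMatchProfile:
    def test_manual_three_snp_bin(self):
        donor = _donor([("chr1D", 100, "A", "G"), ("chr1D", 200, "A", "G")])
        m = _matrix([100, 200, 300], [[HOM_ALT], [HOM_ALT], [HOM_ALT]])
        prof = bin_match_profile(m, "s0", donor, {"chr1D": 500_000})
        assert prof["total"].iloc[0] == 3
        assert prof["matching"].iloc[0] == 2

    def test_all_donor_and_no_donor_extremes(self):
        donor = _donor([("chr1D", 100, "A", "G"), ("chr1D", 200, "A", "G")])
        m = _matrix([100, 200], [[HOM_ALT], [HOM_ALT]])
        prof = bin_match_profile(m, "s0", donor, {"chr1D": 500_000})
        assert prof["matching"].iloc[0] == prof["total"].iloc[0] == 2
        none = bin_match_profile(m, "s0", _donor([]), {"chr1D": 500_000})
        assert none["matching"].sum() == 0

    def test_hom_ref_never_matches(self):
        donor = _donor([("chr1D", 100, "A", "G")])
        m = _matrix([100], [[HOM_REF]])
        prof = bin_match_profile(m, "s0", donor, {"chr1D": 500_000})
        assert prof["total"].iloc[0] == 0 and prof["matching"].iloc[0] == 0


class TestEliteBaseline:
    def test_mean_of_two_lines(self):
        calls = np.asarray(
            [[HOM_ALT, HOM_ALT]] * 4 + [[HOM_ALT, HOM_REF]] * 2, dtype=np.int8
        )
        m = _matrix(100 * (1 + np.arange(6)), calls)
        base = elite_baseline(m, ["s0", "s1"], {"chr1D": 500_000})
        assert base["baseline"].iloc[0] == pytest.approx(5.0)  # (6 + 4) / 2

    def test_single_line_baseline_is_own_counts(self):
        m = _matrix([100, 200], [[HOM_ALT], [HOM_ALT]])
        base = elite_baseline(m, ["s0"], {"chr1D": 500_000})
        assert base["baseline"].iloc[0] == 2.0

    def test_empty_elite_group_errors(self):
        m = _matrix([100], [[HOM_ALT]])
        with pytest.raises(ValueError, match="at least one elite"):
            elite_baseline(m, [], {"chr1D": 500_000})

    def test_simulated_baseline_tracks_configured_rate(
        self, default_sim, masked_matrix
    ):
        base = elite_baseline(
            masked_matrix, default_sim.metadata.elite_samples(),
            default_sim.chrom_sizes,
        )
        d_bins = base[base["chrom"].str.endswith("D")]
        # elite D rate 9 SNPs/Mbp -> ~4.5 per full 500-kbp bin (5% missingness)
        assert base[base["chrom"].str.endswith("D")]["baseline"].mean() == pytest.approx(
            4.5 * 0.95, rel=0.15
        )


class TestClassifyRule:
    def _classified(self, count, baseline, **kw):
        prof = pd.DataFrame(
            {"chrom": ["chr1D"], "start": [0], "end": [500_000],
             "total": [count], "matching": [0]}
        )
        base = pd.DataFrame(
            {"chrom": ["chr1D"], "start": [0], "end": [500_000],
             "baseline": [baseline]}
        )
        return classify_donor_bins(prof, base, **kw)

    @pytest.mark.parametrize(
        "count,baseline,expected",
        [
            (60, 5.0, True),   # 12-fold
            (20, 5.0, False),  # 4-fold, below the 5-fold rule
            (25, 5.0, True),   # exactly 5-fold
            (12, 0.0, True),   # zero baseline: floor of 1.0 and >= 10 SNPs
            (8, 0.0, False),   # passes fold vs floor but under min_count
        ],
    )
    def test_rule_application(self, count, baseline, expected):
        out = self._classified(count, baseline)
        assert bool(out["donor"].iloc[0]) is expected

    def test_fold_monotonicity_never_adds_bins(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(
            {
                "chrom": "chr1D",
                "start": 500_000 * np.arange(50),
                "end": 500_000 * (1 + np.arange(50)),
                "total": rng.integers(0, 80, 50),
                "matching": 0,
            }
        )
        base = prof[["chrom", "start", "end"]].copy()
        base["baseline"] = rng.uniform(0, 10, 50)
        prev = None
        for fold in [2, 5, 8, 12]:
            got = set(np.flatnonzero(
                classify_donor_bins(prof, base, fold=fold)["donor"]
            ))
            if prev is not None:
                assert got <= prev
            prev = got

    def test_use_matching_mode(self):
        prof = pd.DataFrame(
            {"chrom": ["chr1D"], "start": [0], "end": [500_000],
             "total": [60], "matching": [4]}
        )
        base = pd.DataFrame(
            {"chrom": ["chr1D"], "start": [0], "end": [500_000], "baseline": [1.0]}
        )
        assert bool(classify_donor_bins(prof, base)["donor"].iloc[0])
        assert not bool(
            classify_donor_bins(prof, base, use_matching=True)["donor"].iloc[0]
        )


class TestMergeSegments:
    def _classified(self, donor_flags, chrom="chr1D", width=500_000):
        n = len(donor_flags)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": width * np.arange(n),
                "end": width * (1 + np.arange(n)),
                "total": 50,
                "matching": 40,
                "fold_change": 10.0,
                "donor": donor_flags,
            }
        )

    def test_contiguous_run_single_segment(self):
        segs = merge_segments(self._classified([True, True, True, False]))
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 1_500_000)
        assert segs[0].n_bins == 3

    def test_gap_tolerance(self):
        flags = [True, False, True]
        assert len(merge_segments(self._classified(flags))) == 2
        merged = merge_segments(self._classified(flags), max_gap_bins=1)
        assert len(merged) == 1
        assert merged[0].end == 1_500_000

    def test_empty_input(self):
        assert merge_segments(self._classified([False, False])) == []


class TestAccounting:
    def test_donor_fraction_arithmetic(self):
        segs = merge_segments(
            pd.DataFrame(
                {
                    "chrom": "chr1D",
                    "start": 500_000 * np.arange(20),
                    "end": 500_000 * (1 + np.arange(20)),
                    "total": 50,
                    "matching": 45,
                    "fold_change": 10.0,
                    "donor": True,
                }
            )
        )
        pct = donor_fraction(segs, {"chr1D": 100_000_000}, "D")
        assert pct == pytest.approx(10.0)
        assert donor_fraction([], {"chr1D": 100_000_000}, "D") == 0.0

    def test_donor_fraction_wrong_subgenome_errors(self):
        classified = pd.DataFrame(
            {"chrom": ["chr1B"], "start": [0], "end": [500_000], "total": [50],
             "matching": [40], "fold_change": [10.0], "donor": [True]}
        )
        segs = merge_segments(classified)
        with pytest.raises(ValueError):
            donor_fraction(segs, {"chr1B": 1_000_000, "chr1D": 1_000_000}, "D")

    def test_panel_union_span_of_5301_full_bins(self):
        n = 5301
        classified = pd.DataFrame(
            {
                "chrom": "chr1D",
                "start": 500_000 * np.arange(n),
                "end": 500_000 * (1 + np.arange(n)),
                "total": 50,
                "matching": 40,
                "donor": True,
            }
        )
        out = panel_union([classified])
        assert out["n_bins"] == 5301
        assert out["span_gbp"] == 2.65

    def test_union_idempotent_and_additive(self):
        a = pd.DataFrame(
            {"chrom": "chr1D", "start": [0, 500_000], "end": [500_000, 1_000_000],
             "total": 50, "matching": 40, "donor": True}
        )
        b = pd.DataFrame(
            {"chrom": "chr1D", "start": [1_000_000], "end": [1_500_000],
             "total": 50, "matching": 40, "donor": True}
        )
        assert panel_union([a, a])["n_bins"] == 2
        assert panel_union([a, b])["n_bins"] == 3

    def test_truncated_terminal_bin_uses_true_width(self):
        classified = pd.DataFrame(
            {"chrom": ["chr1D"], "start": [500_000], "end": [750_000],
             "total": [50], "matching": [40], "donor": [True]}
        )
        assert panel_union([classified])["span_bp"] == 250_000

    @pytest.mark.parametrize(
        "n,expected", [(0, 100.0), (2, 25.0), (4, 6.25), (6, 1.5625)]
    )
    def test_theoretical_contribution_dilution(self, n, expected):
        assert theoretical_contribution(n) == pytest.approx(expected)

    def test_negative_crosses_rejected(self):
        with pytest.raises(ValueError):
            theoretical_contribution(-1)


class TestRecovery:
    def test_bin_precision_recall_and_fraction_error(self, default_sim, masked_matrix):
        """Default study conditions: bins recovered at >= 0.95 precision and
        recall; per-line donor fraction within 1 percentage point of truth."""
        scan = scan_panel(
            masked_matrix, default_sim.metadata,
            default_sim.donors["Ae_tauschii"], default_sim.chrom_sizes,
            subgenome="D",
        )
        truth = default_sim.truth
        for line, classified in scan["classified"].items():
            segs = truth.line_segments(line, "Ae_tauschii")
            cov = truth_bin_coverage(classified, segs)
            detected = classified["donor"].to_numpy()
            full = cov >= 1.0
            if detected.any():
                precision = (detected & (cov > 0)).sum() / detected.sum()
                assert precision >= 0.95, line
            if full.any():
                recall = (detected & full).sum() / full.sum()
                assert recall >= 0.95, line
            truth_pct = 100.0 * float(
                truth.fractions.set_index("line").loc[line, "fraction"]
            )
            assert abs(scan["fractions"][line] - truth_pct) <= 1.0, line

    def test_segment_boundaries_within_one_bin(self, default_sim, masked_matrix):
        scan = scan_panel(
            masked_matrix, default_sim.metadata,
            default_sim.donors["Ae_tauschii"], default_sim.chrom_sizes,
            subgenome="D",
        )
        width = 500_000
        for line, segs in scan["segments"].items():
            truth = default_sim.truth.line_segments(line, "Ae_tauschii")
            for _, t in truth.iterrows():
                near = [
                    s for s in segs
                    if s.chrom == t["chrom"]
                    and s.start < t["end"] and s.end > t["start"]
                ]
                assert near, (line, dict(t))
                s = max(near, key=lambda s: min(s.end, t["end"]) - max(s.start, t["start"]))
                assert abs(s.start - t["start"]) <= width
                assert abs(s.end - t["end"]) <= width

    def test_specificity_no_donor_lines_have_negligible_union(
        self, null_sim, null_masked
    ):
        scan = scan_panel(
            null_masked, null_sim.metadata, null_sim.donors["Ae_tauschii"],
            null_sim.chrom_sizes, subgenome="D",
        )
        assert scan["union"]["pct_of_genome"] < 1.0

    def test_masking_disabled_strictly_increases_false_positives(
        self, default_sim, masked_matrix
    ):
        designated = apply_reference_call_rule(default_sim.matrix)

        def false_bins(matrix):
            scan = scan_panel(
                matrix, default_sim.metadata, default_sim.donors["Ae_tauschii"],
                default_sim.chrom_sizes, subgenome="D",
            )
            fp = 0
            for line, classified in scan["classified"].items():
                segs = default_sim.truth.line_segments(line, "Ae_tauschii")
                cov = truth_bin_coverage(classified, segs)
                fp += int((classified["donor"].to_numpy() & (cov == 0)).sum())
            return fp

        assert false_bins(designated) > false_bins(masked_matrix)

    def test_fraction_consistency_with_segments(self, default_sim, masked_matrix):
        scan = scan_panel(
            masked_matrix, default_sim.metadata,
            default_sim.donors["Ae_tauschii"], default_sim.chrom_sizes,
            subgenome="D",
        )
        d_len = sum(
            L for c, L in default_sim.chrom_sizes.items() if c.endswith("D")
        )
        for line, segs in scan["segments"].items():
            d_segs = [s for s in segs if s.chrom.endswith("D")]
            expected = 100.0 * sum(s.length for s in d_segs) / d_len
            assert scan["fractions"][line] == pytest.approx(expected)


@pytest.fixture(scope="module")
def alien_sim():
    cfg = SimConfig(
        seed=9,
        alien_donors=(
            AlienDonor("S_cereale", "chr1B", 0, 25_000_000,
                       carriers=("exotic_01", "exotic_02")),
            AlienDonor("T_ponticum", "chr3D", 30_000_000, 50_000_000,
                       carriers=("exotic_03",)),
        ),
    )
    sim = simulate_panel(cfg)
    matrix = mask_varietal_snps(
        apply_reference_call_rule(sim.matrix), sim.varietal_mask
    )
    return sim, matrix


class TestAlienDetection:
    def test_chromosome_start_block_recovered(self, alien_sim):
        sim, matrix = alien_sim
        segs = detect_alien(
            matrix, "exotic_01", sim.donors["S_cereale"],
            sim.metadata.elite_samples(), sim.chrom_sizes,
        )
        b_segs = [s for s in segs if s.chrom == "chr1B"]
        assert b_segs and b_segs[0].start == 0
        assert abs(b_segs[0].end - 25_000_000) <= 500_000

    def test_distal_block_reaches_chromosome_end(self, alien_sim):
        sim, matrix = alien_sim
        segs = detect_alien(
            matrix, "exotic_03", sim.donors["T_ponticum"],
            sim.metadata.elite_samples(), sim.chrom_sizes,
        )
        d_segs = [s for s in segs if s.chrom == "chr3D"]
        assert d_segs
        assert d_segs[-1].end == sim.chrom_sizes["chr3D"]
        assert abs(d_segs[-1].start - 30_000_000) <= 500_000

    def test_elite_line_yields_no_alien_segments(self, alien_sim):
        sim, matrix = alien_sim
        segs = detect_alien(
            matrix, "elite_01", sim.donors["S_cereale"],
            sim.metadata.elite_samples(), sim.chrom_sizes,
        )
        assert segs == []
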