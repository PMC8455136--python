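"""Simulator: parental panel, meiosis model, cohort, and read sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybmap.core import (
    ChromosomeSpec,
    COModel,
    Parent,
    Strain,
    ViabilitySelection,
    default_karyotype,
)
from hybmap import sim_cross
from hybmap.sim_cross import (
    Haplotype,
    make_parental_panel,
    sample_depths,
    simulate_f2_cohort,
    simulate_gamete,
)


class TestParentalPanel:
    def test_zero_density_gives_empty_table(self):
        panel = make_parental_panel([ChromosomeSpec("c", 1_000_000)], 0.0, seed=1)
        assert len(panel) == 0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            make_parental_panel([ChromosomeSpec("c", 1_000_000)], -1.0, seed=1)

    def test_default_karyotype_has_six_chromosome_groups(self):
        panel = make_parental_panel(sites_per_mb=20, seed=1)
        assert panel["chrom"].nunique() == 6  # 2n = 12

    def test_site_count_within_poisson_interval(self):
        # brute-force row count vs Poisson(1000) 99% interval
        panel = make_parental_panel(
            [ChromosomeSpec("c", 10_000_000)], sites_per_mb=100, seed=7
        )
        lo, hi = stats.poisson.ppf([0.005, 0.995], 1000)
        assert lo <= len(panel) <= hi

    def test_sites_are_diagnostic_homozygous_and_sorted(self):
        panel = make_parental_panel(
            [ChromosomeSpec("c", 2_000_000)], sites_per_mb=500, seed=3
        )
        assert panel["pos"].is_monotonic_increasing
        assert panel["pos"].is_unique
        # biallelic with a private allele in exactly one strain
        assert (panel["diag_allele"] != panel["shared_allele"]).all()
        for s in Strain:
            gt = panel[f"gt_{s.name}"].str.split("/", expand=True)
            assert (gt[0] == gt[1]).all()  # homozygous
            is_diag = panel["diag_strain"] == int(s)
            assert (gt.loc[is_diag, 0] == panel.loc[is_diag, "diag_allele"]).all()
            assert (gt.loc[~is_diag, 0] == panel.loc[~is_diag, "shared_allele"]).all()

    def test_diagnostic_strain_assignment_uniform(self):
        panel = make_parental_panel(
            [ChromosomeSpec("c", 10_000_000)], sites_per_mb=1000, seed=5
        )
        counts = panel["diag_strain"].value_counts().reindex([0, 1, 2]).to_numpy()
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4

    def test_determinism(self):
        a = make_parental_panel(sites_per_mb=50, seed=11)
        b = make_parental_panel(sites_per_mb=50, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestMeiosis:
    CHROM = ChromosomeSpec("c", 10_000_000)

    def test_zero_crossovers_transmits_intact_parental_chromosome(self, rng):
        model = COModel(co_per_meiosis=0.0, obligate=False)
        for _ in range(20):
            hap = simulate_gamete((Strain.CA, Strain.WA), self.CHROM, model, rng)
            assert hap.breakpoints == ()
            assert hap.labels in ((Strain.CA,), (Strain.WA,))

    def test_male_x_is_always_intact(self, rng):
        x = ChromosomeSpec("cX", 5_000_000, is_x=True)
        hap = simulate_gamete(
            (Strain.CA, Strain.WA), x, COModel(), rng, male_meiosis=True
        )
        assert hap.breakpoints == () and hap.labels == (Strain.CA,)

    def test_obligate_single_co_yields_half_nonrecombinant(self, rng):
        # half of all chromatids inherited are nonrecombinant when a single
        # CO occurs between two of the four chromatids
        n = 10_000
        nonrec = sum(
            simulate_gamete((Strain.CA, Strain.LR), self.CHROM, COModel(), rng)
            .n_crossovers
            == 0
            for _ in range(n)
        )
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= nonrec <= hi

    def test_suppressed_region_receives_no_breakpoints(self, rng):
        model = COModel(
            suppressed_regions=[("c", 7_500_000, 10_000_000)], arm_weight=3.0
        )
        for _ in range(10_000):
            hap = simulate_gamete((Strain.CA, Strain.WA), self.CHROM, model, rng)
            assert all(not 7_500_000 <= b < 10_000_000 for b in hap.breakpoints)

    def test_segments_tile_and_breakpoints_equal_transitions(self, rng):
        # segment conservation property over a spread of CO models
        for co, arm_w in [(0.0, 1.0), (1.0, 1.0), (3.0, 5.0)]:
            model = COModel(co_per_meiosis=co, obligate=False, arm_weight=arm_w)
            for _ in range(200):
                hap = simulate_gamete((Strain.CA, Strain.WA), self.CHROM, model, rng)
                assert len(hap.labels) == len(hap.breakpoints) + 1
                assert list(hap.breakpoints) == sorted(set(hap.breakpoints))
                for a, b in itertools.pairwise(hap.labels):
                    assert a != b
                assert all(0 < b < self.CHROM.length for b in hap.breakpoints)

    def test_observable_transitions_match_enumeration_oracle(self, rng):
        # Exact E[transitions | k COs] by brute-force enumeration of the
        # 2-of-4 chromatid-exchange process: 0, 0.5, 0.75 for k = 0, 1, 2.
        # Note three-strand double COs cancel transitions, so k = 2 gives
        # 0.75, not 1.0.
        def enum_expectation(k):
            tot = cnt = 0
            for choices in itertools.product(
                itertools.product((0, 1), (2, 3)), repeat=k
            ):
                lab = [[0] * (k + 1), [0] * (k + 1), [1] * (k + 1), [1] * (k + 1)]
                for t, (i, j) in enumerate(choices):
                    lab[i][t + 1 :], lab[j][t + 1 :] = lab[j][t + 1 :], lab[i][t + 1 :]
                for c in range(4):
                    tot += sum(lab[c][s] != lab[c][s + 1] for s in range(k))
                    cnt += 1
            return tot / cnt

        assert enum_expectation(2) == 0.75
        n = 8000
        for k, model in [
            (1, COModel(obligate=True)),
            (2, COModel(obligate=True, double_co_rate=1.0)),
        ]:
            mean_t = np.mean(
                [
                    simulate_gamete(
                        (Strain.CA, Strain.WA), self.CHROM, model, rng
                    ).n_crossovers
                    for _ in range(n)
                ]
            )
            expected = enum_expectation(k)
            # per-chromatid transitions lie in [0, k]: sd of mean < k/(2 sqrt n)
            assert abs(mean_t - expected) < 4 * k / (2 * np.sqrt(n))


class TestCohort:
    def test_default_cohort_size_matches_study(self):
        truth = simulate_f2_cohort(seed=1)
        assert len(truth.f2) == 93

    def test_every_f2_is_xx_with_intact_paternal_x_and_carries_wa(self):
        truth = simulate_f2_cohort(40, seed=2)
        x = [c for c in truth.chromosomes if c.is_x][0]
        for ind in truth.f2:
            pat_x = ind.haplotypes[(x.name, Parent.PATERNAL)]
            assert pat_x.breakpoints == ()
            assert pat_x.labels == (truth.male_x_strain,)
            mat_x = ind.haplotypes[(x.name, Parent.MATERNAL)]
            assert all(s in (Strain.CA, Strain.LR) for s in mat_x.labels)
            assert sim_cross._carries_wa(ind)

    def test_autosomal_genotype_classes_are_mendelian(self):
        # brute-force tally at a mid-chromosome locus vs 1:1:1:1
        truth = simulate_f2_cohort(10_000, seed=3)
        locus = ("ChrIII", 12_000_000)
        counts = np.zeros(4, dtype=int)
        for ind in truth.f2:
            p = ind.haplotypes[(locus[0], Parent.PATERNAL)].label_at(locus[1])
            m = ind.haplotypes[(locus[0], Parent.MATERNAL)].label_at(locus[1])
            counts[int(p) + 2 * (m == Strain.LR)] += 1
        assert stats.chisquare(counts).pvalue > 1e-4

    def test_neutral_selection_is_identity(self):
        sel = ViabilitySelection("ChrI", 1_000_000, Strain.CA, relative_viability=1.0)
        a = simulate_f2_cohort(10, seed=5, selection=None)
        b = simulate_f2_cohort(10, seed=5, selection=sel)
        assert a.to_records() == b.to_records()

    def test_lethal_selection_on_fixed_genotype_errors(self):
        # paternal X is always the male X strain: disfavoring it with
        # viability 0 makes the cohort unfillable
        sel = ViabilitySelection(
            "ChrX", 1_000_000, Strain.CA, Parent.PATERNAL, relative_viability=0.0
        )
        with pytest.raises(RuntimeError, match="cohort"):
            simulate_f2_cohort(5, seed=6, selection=sel, max_attempts_per_f2=20)

    def test_viability_selection_shifts_locus_frequencies(self):
        chrom = [ChromosomeSpec("c1", 20_000_000)]
        sel = ViabilitySelection("c1", 19_000_000, Strain.CA, relative_viability=0.25)
        truth = simulate_f2_cohort(
            4000, chrom, seed=7, selection=sel, require_wa=False
        )
        m = [
            ind.haplotypes[("c1", Parent.MATERNAL)].label_at(19_000_000)
            for ind in truth.f2
        ]
        n_ca = sum(s == Strain.CA for s in m)
        # survivors: CA at locus with probability v/(1+v) = 0.2
        lo, hi = stats.binom.ppf([0.001, 0.999], 4000, 0.2)
        assert lo <= n_ca <= hi


class TestSampleDepths:
    @pytest.fixture()
    def small_truth_and_sites(self):
        chroms = [ChromosomeSpec("c1", 1_000_000)]
        sites = make_parental_panel(chroms, sites_per_mb=2000, seed=1)
        truth = simulate_f2_cohort(30, chroms, seed=2, require_wa=False)
        return truth, sites

    def test_zero_coverage_gives_all_zero_depths(self, small_truth_and_sites):
        truth, sites = small_truth_and_sites
        for dep in sample_depths(truth, sites, coverage=0.0, seed=3):
            assert dep.diag_depth.sum() == 0 and dep.other_depth.sum() == 0

    def test_mean_total_depth_matches_coverage(self, small_truth_and_sites):
        truth, sites = small_truth_and_sites
        totals = np.concatenate(
            [
                dep.diag_depth + dep.other_depth
                for dep in sample_depths(truth, sites, coverage=5.0, seed=4)
            ]
        )
        n = len(totals)  # ~60k site-draws
        assert n > 10_000
        se = np.sqrt(5.0 / n)
        assert abs(totals.mean() - 5.0) < 4 * se

    def test_error_free_homozygote_has_no_foreign_reads(self):
        chroms = [ChromosomeSpec("c1", 500_000)]
        sites = make_parental_panel(chroms, sites_per_mb=2000, seed=5)
        hap = Haplotype((), (Strain.CA,))
        ind = sim_cross.F2Individual(
            "F0",
            {("c1", Parent.PATERNAL): hap, ("c1", Parent.MATERNAL): hap},
        )
        truth = sim_cross.SimTruth(chroms, [ind])
        (dep,) = sample_depths(truth, sites, coverage=10.0, error_rate=0.0, seed=6)
        foreign = sites["diag_strain"].to_numpy() != int(Strain.CA)
        assert dep.diag_depth[foreign].sum() == 0

    @pytest.mark.parametrize("error_rate", [0.0, 0.005, 0.2])
    def test_read_conservation(self, error_rate):
        # reported allele depths must redistribute, never create or lose
        # reads: with one F2 the total-depth draw shares the random stream
        # across error rates, so per-site totals must be identical
        chroms = [ChromosomeSpec("c1", 1_000_000)]
        sites = make_parental_panel(chroms, sites_per_mb=2000, seed=1)
        truth = simulate_f2_cohort(1, chroms, seed=2, require_wa=False)
        (a,) = sample_depths(truth, sites, 4.0, 0.0, seed=9)
        (b,) = sample_depths(truth, sites, 4.0, error_rate, seed=9)
        np.testing.assert_array_equal(
            a.diag_depth + a.other_depth, b.diag_depth + b.other_depth
        )

    def test_determinism(self, small_truth_and_sites):
        truth, sites = small_truth_and_sites
        a = list(sample_depths(truth, sites, 5.0, 0.005, seed=10))
        b = list(sample_depths(truth, sites, 5.0, 0.005, seed=10))
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.diag_depth, db.diag_depth)
            np.testing.assert_array_equal(da.other_depth, db.other_depth)

    def test_invalid_arguments_rejected(self, small_truth_and_sites):
        truth, sites = small_truth_and_sites
        with pytest.raises(ValueError):
            next(sample_depths(truth, sites, coverage=-1.0))
        with pytest.raises(ValueError):
            next(sample_depths(truth, sites, coverage=1.0, error_rate=0.6))
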