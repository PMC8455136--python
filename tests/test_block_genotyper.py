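"""Block binning, depth fractions, the four-way caller, and block filters."""

import numpy as np
import pandas as pd
import pytest

from hybmap.core import ChromosomeSpec, Genotype, Strain, default_karyotype
from hybmap.block_genotyper import (
    ClassifierThresholds,
    REASON_AMBIGUOUS,
    REASON_INCOMPATIBLE_X,
    REASON_LOW_DEPTH,
    REASON_ZERO_DEPTH,
    apply_x_constraint,
    bin_sites,
    call_block_genotype,
    compute_fractions,
    filter_blocks,
    genotype_rules,
    site_block_ids,
)

EMPTY_SITES = pd.DataFrame(columns=["chrom", "pos", "diag_strain"])


class TestBinSites:
    def test_exact_division(self):
        blocks = bin_sites(EMPTY_SITES, [ChromosomeSpec("c", 1_000_000)])
        assert len(blocks) == 10
        assert blocks["end"].iloc[-1] == 1_000_000

    def test_default_genome_tiles_into_1567_blocks(self):
        blocks = bin_sites(EMPTY_SITES, default_karyotype())
        assert len(blocks) == 1567

    def test_short_final_block(self):
        blocks = bin_sites(EMPTY_SITES, [ChromosomeSpec("c", 250_000)])
        assert len(blocks) == 3
        assert blocks["end"].iloc[-1] - blocks["start"].iloc[-1] == 50_000

    def test_boundary_site_goes_to_second_block(self):
        sites = pd.DataFrame(
            [{"chrom": "c", "pos": 100_000, "diag_strain": 0}]
        )
        bid = site_block_ids(sites, [ChromosomeSpec("c", 1_000_000)])
        assert bid[0] == 1  # half-open [start, end)

    def test_out_of_range_site_is_named_in_error(self):
        sites = pd.DataFrame([{"chrom": "c", "pos": 2_000_000, "diag_strain": 0}])
        with pytest.raises(ValueError, match="c:2000000"):
            site_block_ids(sites, [ChromosomeSpec("c", 1_000_000)])

    def test_unknown_chromosome_rejected(self):
        sites = pd.DataFrame([{"chrom": "nope", "pos": 5, "diag_strain": 0}])
        with pytest.raises(ValueError, match="nope"):
            site_block_ids(sites, [ChromosomeSpec("c", 1_000_000)])

    def test_site_counts_per_strain(self):
        sites = pd.DataFrame(
            {
                "chrom": "c",
                "pos": [10, 20, 150_000],
                "diag_strain": [0, 2, 1],
            }
        )
        blocks = bin_sites(sites, [ChromosomeSpec("c", 200_000)])
        assert blocks["n_sites"].tolist() == [2, 1]
        assert blocks["n_sites_CA"].tolist() == [1, 0]
        assert blocks["n_sites_LR"].tolist() == [1, 0]
        assert blocks["n_sites_WA"].tolist() == [0, 1]


class TestFractions:
    def test_fraction_arithmetic(self):
        d, f = compute_fractions(np.array([190.0, 5.0, 5.0]))
        np.testing.assert_allclose(f, [0.95, 0.025, 0.025])

    def test_zero_depth_is_undefined_and_flagged(self):
        _, f = compute_fractions(np.zeros(3))
        assert np.isnan(f).all()
        calls, reasons = call_block_genotype(
            f[None, :], np.zeros((1, 3)), ClassifierThresholds()
        )
        assert calls[0] == int(Genotype.NO_CALL)
        assert reasons[0] == REASON_ZERO_DEPTH

    def test_normalization_whenever_defined(self, rng):
        d = rng.integers(0, 50, size=(500, 3))
        _, f = compute_fractions(d)
        defined = d.sum(axis=1) > 0
        np.testing.assert_allclose(f[defined].sum(axis=1), 1.0)
        assert np.isnan(f[~defined]).all()

    def test_true_heterozygous_block_fractions_center_on_half(self, rng):
        # simulated CA/LR block under the read model: Poisson depth per
        # haplotype at each diagnostic site, no errors, 30x
        n_sites, cov = 300, 30.0
        reps = 1000
        strain_of_site = rng.integers(0, 3, size=(reps, n_sites))
        d = np.zeros((reps, 3))
        for s, hap_strains in ((0, (0,)), (1, ()), (2, (2,))):
            carrying = strain_of_site == s
            lam = cov / 2 * len(hap_strains)
            d[:, s] = rng.poisson(lam * carrying.sum(axis=1))
        _, f = compute_fractions(d)
        assert abs(f[:, 0].mean() - 0.5) < 0.01
        assert abs(f[:, 2].mean() - 0.5) < 0.01
        assert f[:, 1].max() == 0.0


class TestCaller:
    TH = ClassifierThresholds()

    @pytest.mark.parametrize(
        "f,expected",
        [
            ((0.97, 0.01, 0.02), Genotype.CA_CA),
            ((0.48, 0.04, 0.48), Genotype.CA_LR),
            ((0.49, 0.47, 0.04), Genotype.CA_WA),
            ((0.03, 0.50, 0.47), Genotype.WA_LR),
            ((0.40, 0.30, 0.30), Genotype.NO_CALL),
        ],
    )
    def test_rule_examples(self, f, expected):
        calls, reasons = call_block_genotype(
            np.array([f]), np.array([[100, 100, 100]]), self.TH
        )
        assert calls[0] == int(expected)
        if expected is Genotype.NO_CALL:
            assert reasons[0] == REASON_AMBIGUOUS

    def test_low_depth_gate(self):
        calls, reasons = call_block_genotype(
            np.array([[1.0, 0.0, 0.0]]), np.array([[10, 0, 0]]), self.TH
        )
        assert calls[0] == int(Genotype.NO_CALL)
        assert reasons[0] == REASON_LOW_DEPTH

    def test_depth_gate_disabled_restores_call(self):
        th = ClassifierThresholds(min_classified_reads=0)
        calls, _ = call_block_genotype(
            np.array([[1.0, 0.0, 0.0]]), np.array([[10, 0, 0]]), th
        )
        assert calls[0] == int(Genotype.CA_CA)

    def test_unnormalized_fractions_are_an_internal_error(self):
        with pytest.raises(AssertionError):
            call_block_genotype(
                np.array([[0.5, 0.4, 0.2]]), np.array([[50, 40, 20]]), self.TH
            )

    def test_rules_mutually_exclusive_on_dense_simplex_grid(self):
        # every fraction triple at step 0.001 satisfies at most one rule
        step = 0.001
        g = np.arange(0, 1 + step / 2, step)
        ca, wa = np.meshgrid(g, g, indexing="ij")
        lr = 1.0 - ca - wa
        ok = lr >= -1e-12
        f = np.stack([ca[ok], wa[ok], np.clip(lr[ok], 0, 1)], axis=-1)
        rules = genotype_rules(f, self.TH)
        assert rules.sum(axis=0).max() <= 1

    def test_printed_het_rule_direction_rejects_true_heterozygotes(self):
        th = ClassifierThresholds(het_rule="printed")
        calls, _ = call_block_genotype(
            np.array([[0.49, 0.02, 0.49]]), np.array([[500, 20, 500]]), th
        )
        assert calls[0] == int(Genotype.NO_CALL)

    def test_monotonic_low_depth_rate_in_coverage(self, rng):
        # raising coverage never increases the low-depth no-call rate
        n = 3000
        rates = []
        for cov in (0.5, 1.0, 2.0, 5.0, 10.0):
            d = rng.poisson(cov * 20, size=(n, 3))  # ~60 sites split 3 ways
            _, f = compute_fractions(d)
            _, reasons = call_block_genotype(f, d, self.TH)
            rates.append((reasons == REASON_LOW_DEPTH).mean())
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_x_constraint_masks_incompatible_genotypes(self):
        chroms = [ChromosomeSpec("cA", 100_000), ChromosomeSpec("cX", 100_000, is_x=True)]
        blocks = bin_sites(EMPTY_SITES, chroms)
        calls = np.array([[0, 1, 2, 3], [0, 1, 2, 3]], dtype=np.int8)
        reasons = np.zeros_like(calls)
        apply_x_constraint(calls, reasons, blocks, chroms, Strain.CA)
        assert calls[0].tolist() == [0, 1, 2, 3]  # autosome untouched
        assert calls[1].tolist() == [0, -1, 2, -1]  # CA/WA and WA/LR masked
        assert reasons[1][1] == REASON_INCOMPATIBLE_X


class TestFilterBlocks:
    def _blocks(self, n_sites):
        return pd.DataFrame(
            {
                "block_id": range(len(n_sites)),
                "chrom": "c",
                "start": np.arange(len(n_sites)) * 100_000,
                "end": (np.arange(len(n_sites)) + 1) * 100_000,
                "n_sites": n_sites,
            }
        )

    def test_too_few_sites(self):
        blocks = self._blocks([99, 100])
        calls = np.zeros((2, 93), dtype=np.int8)
        out = filter_blocks(blocks, calls, np.ones(2))
        assert out["kept"].tolist() == [False, True]
        assert out["drop_reason"].iloc[0] == "too_few_sites"

    def test_uncalled_fraction_threshold(self):
        blocks = self._blocks([200, 200])
        calls = np.zeros((2, 93), dtype=np.int8)
        calls[0, :29] = -1  # 31.2% uncalled
        calls[1, :27] = -1  # 29.0% uncalled
        out = filter_blocks(blocks, calls, np.ones(2))
        assert out["kept"].tolist() == [False, True]
        assert out["drop_reason"].iloc[0] == "too_many_uncalled"

    def test_distortion_filter_and_combined_reasons(self):
        blocks = self._blocks([50, 200])
        calls = np.zeros((2, 93), dtype=np.int8)
        out = filter_blocks(blocks, calls, np.array([0.0005, 0.5]))
        assert not out["kept"].iloc[0]
        assert out["drop_reason"].iloc[0] == "too_few_sites,distorted"
        assert out["kept"].iloc[1]
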