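"""Segregation-distortion tests and haplotype inheritance-bias profiling.

The double cross predicts 1:1:1:1 genotype classes at any autosomal block
(and 1:1 for the maternal allele on the X, whose paternal component is
fixed). Departures are tested per block with Pearson's chi-square; blocks
distorted at p ≤ 0.001 are excluded from map construction, but distortion
is *reported* on the unfiltered matrix, since biologically coherent
distortion (e.g. inviability of one hybrid genotype) extends over whole
chromosomes. Among nonrecombinant chromatids the two parental haplotypes
should be inherited 1:1; the favored:disfavored ratio quantifies bias, and
a linear trend of favored-haplotype frequency along the chromosome (tested
by permutation) distinguishes localized viability selection from uniform
transmission bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChromosomeSpec, Genotype, Parent, Strain
from .phase_crossovers import decompose_matrix


@dataclass
class DistortionResult:
    block_id: int
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    pvalue: float


def block_distortion_test(
    observed: np.ndarray, expected_proportions: np.ndarray | None = None
) -> DistortionResult:
    """Pearson chi-square of observed genotype-class counts.

    Defaults to uniform expectation over the supplied classes (1:1:1:1 for
    the four autosomal genotypes; pass two counts for the X maternal
    allele). No continuity correction: with ~93 called F2 per block the
    expected counts are ≥ 20.
    """
    obs = np.asarray(observed, dtype=float)
    k = len(obs)
    total = obs.sum()
    if total < 1:
        raise ValueError("need at least one called individual")
    if expected_proportions is None:
        expected_proportions = np.full(k, 1.0 / k)
    else:
        expected_proportions = np.asarray(expected_proportions, dtype=float)
        if abs(expected_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("expected proportions must sum to 1")
    exp = expected_proportions * total
    stat, p = stats.chisquare(obs, exp)
    return DistortionResult(-1, obs, exp, float(stat), k - 1, float(p))


def distortion_table(
    calls: np.ndarray,
    blocks: pd.DataFrame,
    chromosomes: list[ChromosomeSpec],
    male_x_strain: Strain = Strain.CA,
) -> pd.DataFrame:
    """Chi-square distortion test for every block of a call matrix.

    Autosomal blocks: 4 classes, df = 3. X blocks: the paternal allele is
    fixed, so the two admissible genotypes are compared 1:1 (df = 1).
    Blocks with zero called F2 get p = NaN. Vectorized via the chi-square
    survival function.
    """
    x_names = {c.name for c in chromosomes if c.is_x}
    on_x = blocks["chrom"].isin(x_names).to_numpy()
    n_blocks, n_f2 = calls.shape
    counts = np.zeros((n_blocks, 4), dtype=np.int64)
    for g in range(4):
        counts[:, g] = (calls == g).sum(axis=1)
    if male_x_strain == Strain.CA:
        x_classes = [int(Genotype.CA_CA), int(Genotype.CA_LR)]
    else:
        x_classes = [int(Genotype.CA_WA), int(Genotype.WA_LR)]

    total = counts.sum(axis=1).astype(float)
    stat = np.full(n_blocks, np.nan)
    df = np.where(on_x, 1, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        # autosomes: 4 classes
        exp4 = total[:, None] / 4.0
        s4 = ((counts - exp4) ** 2 / exp4).sum(axis=1)
        # X: 2 admissible classes
        cx = counts[:, x_classes]
        totx = cx.sum(axis=1).astype(float)
        exp2 = totx[:, None] / 2.0
        s2 = ((cx - exp2) ** 2 / exp2).sum(axis=1)
    stat = np.where(on_x, s2, s4)
    ok = np.where(on_x, totx, total) >= 1
    pvals = np.full(n_blocks, np.nan)
    pvals[ok] = stats.chi2.sf(stat[ok], df[ok])
    out = blocks[["block_id", "chrom", "start", "end"]].copy()
    for g in range(4):
        out[f"n_{Genotype(g)}".replace("/", "_")] = counts[:, g]
    out["n_called"] = counts.sum(axis=1)
    out["chi2"] = stat
    out["df"] = df
    out["p"] = pvals
    return out


@dataclass
class InheritanceBias:
    chromosome: str
    parent: Parent
    counts: dict[str, int]
    favored: str
    disfavored: str
    ratio: float
    infinite: bool = False


def nonrecombinant_ratio(
    chromatids: pd.DataFrame, chromosome: str, parent: Parent
) -> InheritanceBias:
    """Inheritance ratio between the two parental haplotypes among
    chromatids with zero crossovers on ``chromosome`` from ``parent``.

    Oriented so ratio ≥ 1 (favored:disfavored); an empty disfavored class
    yields an infinite ratio with a flag.
    """
    sub = chromatids[
        (chromatids["chromosome"] == chromosome)
        & (chromatids["parent"] == str(parent))
        & (chromatids["n_crossovers"] == 0)
        & ~chromatids["low_information"]
    ]
    strains = [s.name for s in (Strain.CA, Strain.WA if parent is Parent.PATERNAL else Strain.LR)]
    counts = {s: int((sub["nonrecombinant_strain"] == s).sum()) for s in strains}
    a, b = strains
    if counts[a] >= counts[b]:
        favored, disfavored = a, b
    else:
        favored, disfavored = b, a
    if counts[disfavored] == 0:
        return InheritanceBias(
            chromosome, parent, counts, favored, disfavored, float("inf"), True
        )
    return InheritanceBias(
        chromosome,
        parent,
        counts,
        favored,
        disfavored,
        counts[favored] / counts[disfavored],
        False,
    )


def haplotype_frequency_series(
    calls: np.ndarray,
    blocks: pd.DataFrame,
    chromosome: str,
    parent: Parent,
    strain: Strain,
) -> pd.DataFrame:
    """Per-block frequency of ``strain`` among called haplotypes of
    ``parent`` along ``chromosome`` (physical order)."""
    pat, mat = decompose_matrix(calls)
    labels = pat if parent is Parent.PATERNAL else mat
    sel = blocks.index[blocks["chrom"] == chromosome].to_numpy()
    sel = sel[np.argsort(blocks["start"].to_numpy()[sel], kind="stable")]
    sub = labels[sel]
    called = (sub >= 0).sum(axis=1)
    hits = (sub == int(strain)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(called > 0, hits / np.maximum(called, 1), np.nan)
    return pd.DataFrame(
        {
            "block_id": blocks["block_id"].to_numpy()[sel],
            "pos": ((blocks["start"] + blocks["end"]) / 2).to_numpy()[sel],
            "n_called": called,
            "frequency": freq,
        }
    )


def distortion_gradient(
    frequency: np.ndarray,
    positions: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Least-squares slope of haplotype frequency vs physical position,
    with a label-permutation p-value.

    The permutation test shuffles the frequency series over positions; the
    two-sided p-value is the fraction of permutations with |slope| at least
    the observed (with the +1 correction). Requires ≥ 3 finite bins.
    """
    y = np.asarray(frequency, dtype=float)
    x = np.asarray(positions, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 bins for a gradient")
    xc = x - x.mean()
    denom = (xc**2).sum()
    slope = float((xc * (y - y.mean())).sum() / denom)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(y, (n_permutations, len(y))).copy(), axis=1
    )
    perm_slopes = (perm - y.mean()) @ xc / denom
    p = (np.sum(np.abs(perm_slopes) >= abs(slope) - 1e-15) + 1) / (
        n_permutations + 1
    )
    return {
        "slope": slope,
        "slope_per_mb": slope * 1e6,
        "p": float(p),
        "n_bins": int(len(y)),
    }


def chromatid_gradient_test(
    label_matrix: np.ndarray,
    positions: np.ndarray,
    favored: Strain,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Randomization trend test at chromatid resolution.

    The per-bin frequency series of a cohort is strongly autocorrelated
    (each chromatid spans many bins), so permuting bins is anticonservative
    under the neutral null. Under neutral transmission the cohort is instead
    invariant to relabeling each chromatid's two possible strains
    independently, so the null distribution of the position-weighted
    favored-strain score is generated exactly by random sign flips of the
    per-chromatid statistics. Reports the least-squares slope of the
    frequency series (for orientation) with the sign-flip two-sided
    p-value.

    ``label_matrix``: (n_bins, n_chromatids) strain codes with −1 missing,
    bins in physical order at ``positions``.
    """
    lab = np.asarray(label_matrix)
    x = np.asarray(positions, dtype=float)
    if lab.shape[0] < 3:
        raise ValueError("need at least 3 bins for a gradient")
    xc = x - x.mean()
    called = lab >= 0
    ind = (lab == int(favored)).astype(float)
    # per-chromatid score; flipping a chromatid maps t -> a - t, so center
    t = xc @ np.where(called, ind, 0.0)
    a = xc @ called.astype(float)
    u = t - a / 2.0
    t_obs = u.sum()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_permutations, len(u))) * 2 - 1
    t_null = signs @ u
    p = (np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12) + 1) / (n_permutations + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(
            called.sum(axis=1) > 0,
            ind.sum(axis=1) / np.maximum(called.sum(axis=1), 1),
            np.nan,
        )
    ok = np.isfinite(freq)
    slope = float(
        (xc[ok] * (freq[ok] - freq[ok].mean())).sum() / (xc[ok] ** 2).sum()
    )
    return {
        "slope": slope,
        "slope_per_mb": slope * 1e6,
        "p": float(p),
        "n_bins": int(lab.shape[0]),
        "n_chromatids": int(lab.shape[1]),
    }
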