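"""Meiosis and shallow-sequencing simulator for the three-strain double cross.

Generates, end to end, the inputs the mapping pipeline expects: a panel of
strain-diagnostic biallelic sites with parental depths, F2 diploid genomes
produced by explicit four-chromatid meioses in the two F1 hybrids, and
per-site allele-depth observations at shotgun coverage.

The meiosis model: each crossover involves one chromatid from each homolog
(chosen uniformly among the two sisters), and the transmitted chromatid is
chosen uniformly among the four. With an obligate single crossover this
yields the classic result that half of transmitted chromatids are
nonrecombinant. Crossover positions follow a piecewise-uniform density with
elevated weight on the chromosome arms and zero weight inside suppressed
regions, reflecting the arm-biased, single-crossover meiotic program of
holocentric nematode chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ChromosomeSpec,
    COModel,
    Parent,
    Strain,
    ViabilitySelection,
    default_karyotype,
)

#: Parental sequencing depth means: CA and LR at 86x, WA at 61x.
DEFAULT_PARENT_DEPTH = {Strain.CA: 86.0, Strain.WA: 61.0, Strain.LR: 86.0}

#: Default diagnostic-site density, matching the real cross (~1.4M
#: polymorphic sites over a ~157-Mb genome ≈ 8900/Mb, i.e. ~890 per 100-kb
#: block). Density matters: the classifier's heterozygote balance gate
#: |f_i − f_j| ≤ 0.1 absorbs both Poisson depth noise and the multinomial
#: imbalance of per-strain site counts within a block, and the latter only
#: becomes negligible at realistic site density.
DEFAULT_SITES_PER_MB = 8900.0

DEFAULT_COVERAGE = 5.0
DEFAULT_ERROR_RATE = 0.005
DEFAULT_N_F2 = 93

_NUCS = np.array(list("ACGT"))


@dataclass(frozen=True)
class Haplotype:
    """One transmitted chromatid: strain labels over contiguous segments.

    ``breakpoints`` are the k crossover positions (bp, 0-based, strictly
    increasing); ``labels`` holds the k+1 segment strain labels. Adjacent
    labels always differ, so ``len(breakpoints)`` equals the number of
    strain transitions along the chromatid.
    """

    breakpoints: tuple[int, ...]
    labels: tuple[Strain, ...]

    def label_at(self, pos: int) -> Strain:
        i = int(np.searchsorted(self.breakpoints, pos, side="right"))
        return self.labels[i]

    def labels_at(self, pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints, pos, side="right")
        return np.asarray([int(s) for s in self.labels], dtype=np.int8)[idx]

    @property
    def n_crossovers(self) -> int:
        return len(self.breakpoints)


@dataclass
class F2Individual:
    f2_id: str
    #: (chromosome name, parent) -> Haplotype
    haplotypes: dict[tuple[str, Parent], Haplotype]


@dataclass
class SimTruth:
    """Ground-truth gamete haplotypes for a simulated cohort.

    Every F2 is an XX hermaphrodite; the paternal X is always a single
    intact haplotype (zero breakpoints) because the male's lone X has no
    pairing partner.
    """

    chromosomes: list[ChromosomeSpec]
    f2: list[F2Individual]
    male_x_strain: Strain = Strain.CA

    def to_records(self) -> list[dict]:
        out = []
        for ind in self.f2:
            for (chrom, parent), hap in ind.haplotypes.items():
                out.append(
                    {
                        "f2_id": ind.f2_id,
                        "chromosome": chrom,
                        "parent": str(parent),
                        "breakpoints": list(map(int, hap.breakpoints)),
                        "labels": [s.name for s in hap.labels],
                    }
                )
        return out


# ---------------------------------------------------------------------------
# parental panel


def make_parental_panel(
    chromosomes: Sequence[ChromosomeSpec] | None = None,
    sites_per_mb: float = DEFAULT_SITES_PER_MB,
    seed: int | np.random.Generator = 0,
    depth_means: dict[Strain, float] | None = None,
) -> pd.DataFrame:
    """Simulate the panel of strain-diagnostic biallelic variants.

    Each emitted site is homozygous in all three parents, biallelic, and
    diagnostic for exactly one strain (that strain carries a private
    allele; the other two share the alternative). Diagnostic-strain
    assignment is uniform over the three strains. Parental depths are
    Poisson around per-strain means.

    Returns a DataFrame with columns ``chrom, pos, diag_strain, diag_allele,
    shared_allele, gt_CA, gt_WA, gt_LR, dp_CA, dp_WA, dp_LR`` sorted by
    (chrom, pos), positions 0-based and strictly increasing per chromosome.
    """
    if chromosomes is None:
        chromosomes = default_karyotype()
    if not len(chromosomes):
        raise ValueError("chromosome list must be nonempty")
    if sites_per_mb < 0:
        raise ValueError("sites_per_mb must be >= 0")
    if depth_means is None:
        depth_means = DEFAULT_PARENT_DEPTH
    rng = np.random.default_rng(seed)

    frames = []
    for chrom in chromosomes:
        n = rng.poisson(sites_per_mb * chrom.length / 1e6)
        pos = np.sort(rng.choice(chrom.length, size=min(n, chrom.length), replace=False))
        n = len(pos)
        diag = rng.integers(0, 3, size=n).astype(np.int8)
        shared_idx = rng.integers(0, 4, size=n)
        # diagnostic allele differs from the shared allele
        diag_idx = (shared_idx + rng.integers(1, 4, size=n)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom.name,
                    "pos": pos.astype(np.int64),
                    "diag_strain": diag,
                    "diag_allele": _NUCS[diag_idx],
                    "shared_allele": _NUCS[shared_idx],
                }
            )
        )
    panel = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "diag_strain", "diag_allele", "shared_allele"]
    )
    if not len(panel):
        for s in Strain:
            panel[f"gt_{s.name}"] = pd.Series(dtype=str)
            panel[f"dp_{s.name}"] = pd.Series(dtype=np.int64)
        return panel
    for s in Strain:
        allele = np.where(
            panel["diag_strain"].to_numpy() == int(s),
            panel["diag_allele"].to_numpy(),
            panel["shared_allele"].to_numpy(),
        )
        panel[f"gt_{s.name}"] = pd.Series(allele) + "/" + pd.Series(allele)
        panel[f"dp_{s.name}"] = rng.poisson(depth_means[s], size=len(panel)).astype(
            np.int64
        )
    return panel


# ---------------------------------------------------------------------------
# meiosis


def _co_count(model: COModel, rng: np.random.Generator) -> int:
    if model.obligate:
        k = 1
        if model.double_co_rate > 0 and rng.random() < model.double_co_rate:
            k = 2
        return k
    return int(rng.poisson(model.co_per_meiosis))


def _co_density_segments(
    chrom: ChromosomeSpec, model: COModel
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant CO density: (segment edges, per-segment weights)."""
    b1, b2 = chrom.arm_boundaries
    edges = {0, b1, b2, chrom.length}
    suppressed = []
    for name, lo, hi in model.suppressed_regions:
        if name != chrom.name:
            continue
        lo, hi = max(0, int(lo)), min(chrom.length, int(hi))
        if lo < hi:
            suppressed.append((lo, hi))
            edges.update((lo, hi))
    edges = np.array(sorted(edges), dtype=np.int64)
    mids = (edges[:-1] + edges[1:]) / 2
    w = np.where((mids < b1) | (mids >= b2), model.arm_weight, 1.0)
    for lo, hi in suppressed:
        w[(mids >= lo) & (mids < hi)] = 0.0
    return edges, w


def draw_co_positions(
    k: int, chrom: ChromosomeSpec, model: COModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw k crossover positions from the piecewise-uniform landscape."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    edges, w = _co_density_segments(chrom, model)
    lens = np.diff(edges).astype(float)
    mass = w * lens
    total = mass.sum()
    if total <= 0:
        return np.empty(0, dtype=np.int64)
    seg = rng.choice(len(mass), size=k, p=mass / total)
    pos = edges[seg] + rng.random(k) * lens[seg]
    return np.sort(pos.astype(np.int64))


def simulate_gamete(
    parent_pair: tuple[Strain, Strain],
    chromosome: ChromosomeSpec,
    co_model: COModel,
    rng: np.random.Generator,
    *,
    male_meiosis: bool = False,
    male_x_strain: Strain = Strain.CA,
) -> Haplotype:
    """Simulate one meiosis and return the transmitted chromatid.

    The bivalent holds four chromatids (two sisters per homolog). Each
    crossover exchanges the distal segments of one chromatid from each
    homolog, both chosen uniformly; the transmitted chromatid is drawn
    uniformly from the four. For the X in a male meiosis no exchange is
    possible and the single intact X (``male_x_strain``) is returned.
    """
    a, b = parent_pair
    if chromosome.is_x and male_meiosis:
        return Haplotype((), (male_x_strain,))

    positions = draw_co_positions(_co_count(co_model, rng), chromosome, co_model, rng)
    # chromatids as lists of (segment_start, strain); 0,1 sisters of a; 2,3 of b
    chromatids = [[(0, a)], [(0, a)], [(0, b)], [(0, b)]]
    for x in positions:
        i = int(rng.integers(0, 2))
        j = int(rng.integers(2, 4))
        chromatids[i], chromatids[j] = _exchange(chromatids[i], chromatids[j], int(x))
    transmitted = chromatids[int(rng.integers(0, 4))]
    return _to_haplotype(transmitted)


def _exchange(c1: list, c2: list, x: int) -> tuple[list, list]:
    """Reciprocal exchange of the segments distal to position x."""

    def split(c):
        head = [(s, lab) for s, lab in c if s < x]
        tail = [(s, lab) for s, lab in c if s >= x]
        if not tail or tail[0][0] != x:
            # the segment spanning x continues into the tail
            tail = [(x, head[-1][1])] + tail
        return head, tail

    h1, t1 = split(c1)
    h2, t2 = split(c2)
    return h1 + t2, h2 + t1


def _to_haplotype(segments: list[tuple[int, Strain]]) -> Haplotype:
    """Merge adjacent equal-label segments; breakpoints = label transitions."""
    # drop zero-length segments (two exchanges at the same bp): keep the
    # last segment declared at each start
    dedup: dict[int, Strain] = {}
    for start, lab in segments:
        dedup[start] = lab
    labels: list[Strain] = []
    breaks: list[int] = []
    for start, lab in sorted(dedup.items()):
        if labels and lab == labels[-1]:
            continue
        if labels:
            breaks.append(start)
        labels.append(lab)
    return Haplotype(tuple(breaks), tuple(labels))


# ---------------------------------------------------------------------------
# F2 cohort


def _simulate_f2(
    f2_id: str,
    chromosomes: Sequence[ChromosomeSpec],
    co_models: dict[Parent, COModel],
    male_x_strain: Strain,
    rng: np.random.Generator,
) -> F2Individual:
    haps: dict[tuple[str, Parent], Haplotype] = {}
    for chrom in chromosomes:
        haps[(chrom.name, Parent.PATERNAL)] = simulate_gamete(
            (Strain.CA, Strain.WA),
            chrom,
            co_models[Parent.PATERNAL],
            rng,
            male_meiosis=True,
            male_x_strain=male_x_strain,
        )
        haps[(chrom.name, Parent.MATERNAL)] = simulate_gamete(
            (Strain.CA, Strain.LR), chrom, co_models[Parent.MATERNAL], rng
        )
    return F2Individual(f2_id, haps)


def _carries_wa(ind: F2Individual) -> bool:
    return any(
        Strain.WA in hap.labels
        for (_, parent), hap in ind.haplotypes.items()
        if parent is Parent.PATERNAL
    )


def simulate_f2_cohort(
    n_f2: int = DEFAULT_N_F2,
    chromosomes: Sequence[ChromosomeSpec] | None = None,
    co_models: dict[Parent, COModel] | COModel | None = None,
    selection: ViabilitySelection | None = None,
    seed: int | np.random.Generator = 0,
    *,
    male_x_strain: Strain = Strain.CA,
    require_wa: bool = True,
    max_attempts_per_f2: int = 1000,
) -> SimTruth:
    """Simulate a cohort of XX hermaphrodite F2 from the double cross.

    Each F2 receives one gamete from the CA/WA male (autosomes recombinant,
    X intact ``male_x_strain``) and one from the CA/LR hermaphrodite (all
    chromosomes recombinant). With ``require_wa`` (the study's cross-progeny
    validation) every retained F2 carries a WA haplotype somewhere. Under
    ``selection``, carriers of the disfavored haplotype at the locus survive
    with the stated relative viability; candidates are redrawn until the
    cohort is filled or the attempt budget is exhausted.
    """
    if n_f2 <= 0:
        raise ValueError("n_f2 must be > 0")
    if chromosomes is None:
        chromosomes = default_karyotype()
    if co_models is None:
        co_models = COModel()
    if isinstance(co_models, COModel):
        co_models = {Parent.PATERNAL: co_models, Parent.MATERNAL: co_models}
    rng = np.random.default_rng(seed)

    cohort: list[F2Individual] = []
    attempts = 0
    budget = max_attempts_per_f2 * n_f2
    while len(cohort) < n_f2:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not fill cohort of {n_f2} after {budget} attempts; "
                "selection and/or cross constraints may exclude all candidates"
            )
        ind = _simulate_f2(
            f"F2_{len(cohort):04d}", chromosomes, co_models, male_x_strain, rng
        )
        if require_wa and not _carries_wa(ind):
            continue
        if selection is not None and selection.relative_viability < 1.0:
            hap = ind.haplotypes.get((selection.chromosome, selection.parent))
            if hap is None:
                raise ValueError(
                    f"selection locus on unknown chromosome {selection.chromosome}"
                )
            if hap.label_at(selection.position) == selection.disfavored_strain:
                if rng.random() >= selection.relative_viability:
                    continue
        cohort.append(ind)
    return SimTruth(list(chromosomes), cohort, male_x_strain)


def truth_call_matrix(truth: SimTruth, blocks) -> np.ndarray:
    """Error-free block genotype calls straight from simulated haplotypes.

    Evaluates each F2's parental strain labels at every block midpoint and
    recomposes the four-way genotype; useful as the noiseless upper bound
    for map and distortion analyses. Returns an (n_blocks, n_f2) int8
    matrix of :class:`~hybmap.core.Genotype` codes.
    """
    chrom_arr = blocks["chrom"].to_numpy()
    mids = ((blocks["start"].to_numpy() + blocks["end"].to_numpy()) // 2).astype(
        np.int64
    )
    out = np.empty((len(blocks), len(truth.f2)), dtype=np.int8)
    for j, ind in enumerate(truth.f2):
        pat = np.empty(len(blocks), dtype=np.int8)
        mat = np.empty(len(blocks), dtype=np.int8)
        for chrom in truth.chromosomes:
            mask = chrom_arr == chrom.name
            pat[mask] = ind.haplotypes[(chrom.name, Parent.PATERNAL)].labels_at(
                mids[mask]
            )
            mat[mask] = ind.haplotypes[(chrom.name, Parent.MATERNAL)].labels_at(
                mids[mask]
            )
        # (pat, mat) -> genotype code: CA/CA=0, CA/WA=1, CA/LR=2, WA/LR=3
        out[:, j] = pat + (mat == int(Strain.LR)) * 2
    return out


# ---------------------------------------------------------------------------
# sequencing depths


@dataclass
class F2Depths:
    """Per-site allele depths for one F2, aligned to the sites-table rows.

    ``diag_depth[i]`` is the number of reads reporting the diagnostic allele
    of site i; ``other_depth[i]`` the reads reporting the shared allele.
    """

    f2_id: str
    diag_depth: np.ndarray
    other_depth: np.ndarray

    def to_frame(self, sites: pd.DataFrame, drop_zero: bool = True) -> pd.DataFrame:
        """Long-form records (f2_id, chrom, pos, allele, depth).

        Zero-depth rows are omitted when ``drop_zero`` (readers restore
        them from the sites table), keeping files compact without loss.
        """
        rows = []
        for allele_col, depth in (
            ("diag_allele", self.diag_depth),
            ("shared_allele", self.other_depth),
        ):
            mask = depth > 0 if drop_zero else np.ones(len(depth), bool)
            rows.append(
                pd.DataFrame(
                    {
                        "f2_id": self.f2_id,
                        "chrom": sites["chrom"].to_numpy()[mask],
                        "pos": sites["pos"].to_numpy()[mask],
                        "allele": sites[allele_col].to_numpy()[mask],
                        "depth": depth[mask],
                    }
                )
            )
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _site_strain_labels(
    ind: F2Individual, sites: pd.DataFrame, chromosomes: Sequence[ChromosomeSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """Strain label per haplotype at every site, aligned to sites rows."""
    n = len(sites)
    s_pat = np.full(n, MISSING, dtype=np.int8)
    s_mat = np.full(n, MISSING, dtype=np.int8)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for chrom in chromosomes:
        mask = chrom_arr == chrom.name
        if not mask.any():
            continue
        pos = pos_arr[mask]
        s_pat[mask] = ind.haplotypes[(chrom.name, Parent.PATERNAL)].labels_at(pos)
        s_mat[mask] = ind.haplotypes[(chrom.name, Parent.MATERNAL)].labels_at(pos)
    return s_pat, s_mat


def sample_depths(
    truth: SimTruth,
    sites: pd.DataFrame,
    coverage: float = DEFAULT_COVERAGE,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | np.random.Generator = 0,
) -> Iterator[F2Depths]:
    """Yield per-F2 shallow-sequencing allele depths at the panel sites.

    Per site, each of the two haplotypes contributes Poisson(coverage/2)
    reads carrying its own allele; every read is reported as the opposite
    allele with probability ``error_rate``. Total read count is conserved
    between draw and report.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = len(sites)
    diag = sites["diag_strain"].to_numpy().astype(np.int8)
    for ind in truth.f2:
        s_pat, s_mat = _site_strain_labels(ind, sites, truth.chromosomes)
        r_pat = rng.poisson(coverage / 2.0, size=n)
        r_mat = rng.poisson(coverage / 2.0, size=n)
        match = r_pat * (s_pat == diag) + r_mat * (s_mat == diag)
        nonmatch = r_pat + r_mat - match
        if error_rate > 0:
            diag_reads = rng.binomial(match, 1.0 - error_rate) + rng.binomial(
                nonmatch, error_rate
            )
        else:
            diag_reads = match.copy()
        other_reads = match + nonmatch - diag_reads
        yield F2Depths(ind.f2_id, diag_reads.astype(np.int64), other_reads.astype(np.int64))
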