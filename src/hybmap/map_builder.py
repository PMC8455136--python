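"""Sex-specific genetic maps and Marey tables from phased block genotypes.

Each kept block is treated as a single locus at its physical midpoint, in
assembled reference order. For each pair of adjacent loci the recombination
fraction r is the fraction of chromatids (per parent) whose strain label
differs between the two, among chromatids called at both; cumulative map
position is the running sum of m(r)·100 cM for the chosen mapping function.
With dense 100-kb bins per-interval r is tiny, so the identity (Morgan)
function is the default; Haldane and Kosambi are available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, ChromosomeSpec, Parent

MAPPING_FUNCTIONS = ("morgan", "haldane", "kosambi")


def map_distance(r: np.ndarray, mapping_function: str = "morgan") -> np.ndarray:
    """Map distance in Morgans for interval recombination fraction(s) r."""
    r = np.asarray(r, dtype=float)
    if mapping_function == "morgan":
        return r
    if mapping_function == "haldane":
        return -0.5 * np.log1p(-2.0 * np.minimum(r, 0.5 - 1e-12))
    if mapping_function == "kosambi":
        return 0.25 * np.log((1 + 2 * r) / (1 - 2 * np.minimum(r, 0.5 - 1e-12)))
    raise ValueError(f"unknown mapping function {mapping_function!r}")


def interval_recombination_fraction(
    left: np.ndarray, right: np.ndarray
) -> tuple[float, int, int]:
    """r between two adjacent loci from per-chromatid strain labels.

    ``left``/``right`` are label vectors (MISSING = uncalled). Returns
    ``(r, n_discordant, n_informative)`` over chromatids called at both
    loci; r is capped at 0.5 with a warning; NaN when no chromatid is
    informative.
    """
    left = np.asarray(left)
    right = np.asarray(right)
    both = (left != MISSING) & (right != MISSING)
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0, 0
    disc = int((left[both] != right[both]).sum())
    r = disc / n
    if r > 0.5:
        warnings.warn(
            f"interval recombination fraction {r:.3f} > 0.5; capped", stacklevel=2
        )
        r = 0.5
    return r, disc, n


@dataclass
class GeneticMap:
    """Marey-style map of one chromosome for one parent."""

    chromosome: str
    parent: Parent
    table: pd.DataFrame = field(repr=False)  # bin_mid, r, n_informative, cM
    total_cm: float = 0.0

    @property
    def n_bins(self) -> int:
        return len(self.table)


def build_map(
    label_matrix: np.ndarray,
    block_mids: np.ndarray,
    chromosome: str,
    parent: Parent,
    mapping_function: str = "morgan",
) -> GeneticMap:
    """Build one parent's map of one chromosome.

    ``label_matrix``: (n_kept_blocks, n_chromatids) strain labels in block
    order; ``block_mids``: physical bin midpoints (bp).

    The interval recombination fraction is crossover-based: for each
    chromatid, a crossover is a strain change between consecutive *called*
    bins, assigned to the inter-bin interval containing its midpoint; r of
    interval k is that crossover count over the chromatids informative at
    the interval (a called bin on each side). This reduces to the plain
    adjacent-bin discordance ratio on complete data, but — unlike the
    strictly pairwise ratio — does not lose the crossovers whose mixed-
    haplotype bin is itself uncalled, which is the typical case: a
    crossover inside a bin makes that bin's depth fractions ambiguous.
    Summed interval counts therefore equal the total transition count from
    crossover phasing, and r is capped at 0.5 with a warning. Intervals
    with no informative chromatid contribute 0 cM and carry r = NaN.
    """
    n_bins = label_matrix.shape[0]
    if n_bins < 2:
        warnings.warn(
            f"{chromosome} {parent}: fewer than 2 kept blocks; empty map",
            stacklevel=2,
        )
        return GeneticMap(
            chromosome,
            parent,
            pd.DataFrame(columns=["bin_mid", "r", "n_discordant", "n_informative", "cM"]),
            0.0,
        )
    # interval k lies between bins k-1 and k (k = 1..n_bins-1)
    disc = np.zeros(n_bins, dtype=int)
    ninf = np.zeros(n_bins, dtype=int)
    for c in range(label_matrix.shape[1]):
        vec = label_matrix[:, c]
        called = np.flatnonzero(vec != MISSING)
        if len(called) < 2:
            continue
        # informative at every interval between its outermost called bins
        ninf[called[0] + 1 : called[-1] + 1] += 1
        lab = vec[called]
        for t in np.flatnonzero(lab[:-1] != lab[1:]):
            i, j = called[t], called[t + 1]
            mid = (block_mids[i] + block_mids[j]) / 2.0
            # interval containing the midpoint
            k = int(np.searchsorted(block_mids, mid, side="right"))
            disc[min(max(k, i + 1), j)] += 1
    rs = np.full(n_bins, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs[1:] = np.where(ninf[1:] > 0, disc[1:] / np.maximum(ninf[1:], 1), np.nan)
    if np.nanmax(rs, initial=0.0) > 0.5:
        warnings.warn(
            f"{chromosome} {parent}: interval recombination fraction > 0.5; capped",
            stacklevel=2,
        )
        rs = np.minimum(rs, 0.5)
    step = map_distance(np.nan_to_num(rs, nan=0.0), mapping_function) * 100.0
    step[0] = 0.0
    cm = np.cumsum(step)
    table = pd.DataFrame(
        {
            "bin_mid": block_mids,
            "r": rs,
            "n_discordant": disc,
            "n_informative": ninf,
            "cM": cm,
        }
    )
    return GeneticMap(chromosome, parent, table, float(cm[-1]))


def build_maps(
    calls: np.ndarray,
    blocks: pd.DataFrame,
    chromosomes: list[ChromosomeSpec],
    kept_mask: np.ndarray | None = None,
    mapping_function: str = "morgan",
) -> dict[tuple[str, Parent], GeneticMap]:
    """Maps for every chromosome × parent; no paternal map for the X."""
    from .phase_crossovers import decompose_matrix

    if kept_mask is None:
        kept_mask = np.ones(len(blocks), dtype=bool)
    pat, mat = decompose_matrix(calls)
    chrom_arr = blocks["chrom"].to_numpy()
    starts = blocks["start"].to_numpy()
    ends = blocks["end"].to_numpy()
    maps: dict[tuple[str, Parent], GeneticMap] = {}
    for chrom in chromosomes:
        sel = np.flatnonzero((chrom_arr == chrom.name) & kept_mask)
        order = sel[np.argsort(starts[sel], kind="stable")]
        mids = (starts[order] + ends[order]) / 2.0
        for parent, labels in ((Parent.PATERNAL, pat), (Parent.MATERNAL, mat)):
            if chrom.is_x and parent is Parent.PATERNAL:
                continue  # single intact male X: no map
            maps[(chrom.name, parent)] = build_map(
                labels[order], mids, chrom.name, parent, mapping_function
            )
    return maps


def marey_table(maps: dict[tuple[str, Parent], GeneticMap]) -> pd.DataFrame:
    """Concatenate maps into one long Marey table."""
    frames = []
    for (chrom, parent), gmap in maps.items():
        t = gmap.table.copy()
        t.insert(0, "chromosome", chrom)
        t.insert(1, "parent", str(parent))
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["chromosome", "parent", "bin_mid", "r", "n_discordant",
                     "n_informative", "cM"]
        )
    return pd.concat(frames, ignore_index=True)


def arm_center_summary(gmap: GeneticMap, spec: ChromosomeSpec) -> pd.DataFrame:
    """cM and cM/Mb on the left arm, center, and right arm.

    Cumulative positions at the arm boundaries are linearly interpolated
    between bin midpoints. Also reports the arms:center rate ratio.
    """
    t = gmap.table
    if len(t) < 2:
        raise ValueError("map too short for arm/center summary")
    b1, b2 = spec.arm_boundaries
    mids = t["bin_mid"].to_numpy(dtype=float)
    cm = t["cM"].to_numpy(dtype=float)
    edges = [0.0, float(b1), float(b2), float(spec.length)]
    cm_at = np.interp(edges, mids, cm)
    rows = []
    for name, lo, hi, cma, cmb in zip(
        ("left_arm", "center", "right_arm"),
        edges[:-1],
        edges[1:],
        cm_at[:-1],
        cm_at[1:],
        strict=False,
    ):
        mb = (hi - lo) / 1e6
        rows.append(
            {
                "region": name,
                "start": lo,
                "end": hi,
                "cM": cmb - cma,
                "cM_per_Mb": (cmb - cma) / mb if mb > 0 else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    center_rate = out.loc[out["region"] == "center", "cM_per_Mb"].iloc[0]
    arm_rate = (
        out.loc[out["region"].isin(["left_arm", "right_arm"]), "cM"].sum()
        / ((edges[1] - edges[0] + edges[3] - edges[2]) / 1e6)
    )
    out.attrs["arm_center_ratio"] = (
        arm_rate / center_rate if center_rate > 0 else float("inf")
    )
    return out


def plot_marey(
    maps: dict[tuple[str, Parent], GeneticMap], path: str
) -> None:
    """Write a Marey plot grid (one panel per chromosome, one line per
    parent) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({c for c, _ in maps})
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3 * len(chroms), 3), squeeze=False
    )
    colors = {Parent.PATERNAL: "tab:green", Parent.MATERNAL: "m"}
    for ax, chrom in zip(axes[0], chroms):
        for parent in (Parent.PATERNAL, Parent.MATERNAL):
            gmap = maps.get((chrom, parent))
            if gmap is None or not len(gmap.table):
                continue
            ax.plot(
                gmap.table["bin_mid"] / 1e6,
                gmap.table["cM"],
                ".",
                ms=2,
                color=colors[parent],
                label=str(parent),
            )
        ax.set_title(chrom)
        ax.set_xlabel("physical position (Mb)")
    axes[0][0].set_ylabel("map position (cM)")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
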