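"""Block genotyping of low-coverage F2 samples by allele-depth fractions.

At ~5x coverage individual sites cannot be genotyped, but pooling the reads
that carry strain-diagnostic alleles across a 100-kb block gives three depth
fractions f_CA, f_WA, f_LR (summing to 1) that separate the four possible
F2 genotypes cleanly: a CA/CA block puts essentially all diagnostic reads on
CA (f_CA → 1), a CA/LR block splits them evenly between CA and LR with
almost none on WA, and so on. Reads carrying the shared (non-diagnostic)
allele are uninformative and contribute to no strain's depth.

Genotype rules (mutually exclusive over the fraction simplex):

* ``CA/CA``  iff f_CA > 0.95
* ``CA/WA``  iff f_LR < 0.05 and |f_CA − f_WA| ≤ 0.10
* ``CA/LR``  iff f_WA < 0.05 and |f_CA − f_LR| ≤ 0.10
* ``WA/LR``  iff f_CA < 0.05 and |f_WA − f_LR| ≤ 0.10

anything else is not called. The heterozygote balance condition is
implemented as |f_i − f_j| ≤ 0.10 (the two expected ~0.5 fractions must be
close); the opposite inequality direction, which has circulated in print,
would reject every true heterozygote under diagnostic-allele counting and
is available for comparison via ``het_rule="printed"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, ChromosomeSpec, Genotype, Strain
from .sim_cross import F2Depths

DEFAULT_BLOCK_SIZE = 100_000

#: no-call reason codes (int8); 0 = called
REASON_CALLED = 0
REASON_AMBIGUOUS = 1
REASON_LOW_DEPTH = 2
REASON_ZERO_DEPTH = 3
REASON_INCOMPATIBLE_X = 4
NO_CALL_REASONS = {
    REASON_CALLED: "called",
    REASON_AMBIGUOUS: "ambiguous",
    REASON_LOW_DEPTH: "low_depth",
    REASON_ZERO_DEPTH: "zero_depth",
    REASON_INCOMPATIBLE_X: "incompatible_X",
}


@dataclass
class ClassifierThresholds:
    """Thresholds of the fraction-space genotype classifier.

    ``min_classified_reads`` is a depth gate on the summed diagnostic reads
    in a block (set to 0 for threshold-only behavior).
    """

    homozygote_min_fraction: float = 0.95
    absent_max_fraction: float = 0.05
    het_balance_max: float = 0.10
    min_classified_reads: int = 20
    het_rule: str = "balance"  # or "printed"

    def __post_init__(self) -> None:
        if not 0 < self.absent_max_fraction < self.homozygote_min_fraction <= 1:
            raise ValueError(
                "need 0 < absent_max_fraction < homozygote_min_fraction <= 1"
            )
        if self.het_rule not in ("balance", "printed"):
            raise ValueError("het_rule must be 'balance' or 'printed'")


def bin_sites(
    sites: pd.DataFrame,
    chromosomes: Sequence[ChromosomeSpec],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """Tile each chromosome into non-overlapping blocks and count sites.

    Blocks are half-open ``[start, end)``; the final block of a chromosome
    may be shorter. Returns a DataFrame ``block_id, chrom, start, end,
    n_sites_CA, n_sites_WA, n_sites_LR, n_sites`` with ``block_id`` a
    global 0-based index in (chromosome, start) order. Also assigns a
    ``block_id`` column to ``sites`` (returned copy not required: mapping
    is positional via :func:`site_block_ids`).
    """
    if block_size <= 0:
        raise ValueError("block_size must be > 0")
    rows = []
    offset = 0
    offsets: dict[str, int] = {}
    for chrom in chromosomes:
        n_blocks = -(-chrom.length // block_size)  # ceil
        starts = np.arange(n_blocks, dtype=np.int64) * block_size
        ends = np.minimum(starts + block_size, chrom.length)
        rows.append(
            pd.DataFrame(
                {
                    "block_id": offset + np.arange(n_blocks),
                    "chrom": chrom.name,
                    "start": starts,
                    "end": ends,
                }
            )
        )
        offsets[chrom.name] = offset
        offset += n_blocks
    blocks = pd.concat(rows, ignore_index=True)

    counts = np.zeros((len(blocks), 3), dtype=np.int64)
    if len(sites):
        bid = site_block_ids(sites, chromosomes, block_size)
        for s in Strain:
            mask = sites["diag_strain"].to_numpy() == int(s)
            counts[:, int(s)] = np.bincount(bid[mask], minlength=len(blocks))
    for s in Strain:
        blocks[f"n_sites_{s.name}"] = counts[:, int(s)]
    blocks["n_sites"] = counts.sum(axis=1)
    return blocks


def site_block_ids(
    sites: pd.DataFrame,
    chromosomes: Sequence[ChromosomeSpec],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> np.ndarray:
    """Global block index of every site row; errors on out-of-range sites."""
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    bid = np.full(len(sites), -1, dtype=np.int64)
    offset = 0
    for chrom in chromosomes:
        n_blocks = -(-chrom.length // block_size)
        mask = chrom_arr == chrom.name
        pos = pos_arr[mask]
        if len(pos) and (pos.max() >= chrom.length or pos.min() < 0):
            bad = pos[(pos >= chrom.length) | (pos < 0)][0]
            raise ValueError(
                f"site {chrom.name}:{bad} lies outside chromosome "
                f"[0, {chrom.length})"
            )
        bid[mask] = offset + pos // block_size
        offset += n_blocks
    unknown = bid < 0
    if unknown.any():
        i = int(np.flatnonzero(unknown)[0])
        raise ValueError(
            f"site {chrom_arr[i]}:{pos_arr[i]} is on a chromosome absent from "
            "the chromosome table"
        )
    return bid


# ---------------------------------------------------------------------------
# depth aggregation and fractions


def block_depths(
    depths: F2Depths, sites: pd.DataFrame, block_ids: np.ndarray, n_blocks: int
) -> np.ndarray:
    """Sum diagnostic-allele reads per (block, strain) for one F2.

    Only the site's own diagnostic strain can gain depth from it; shared-
    allele reads count nowhere. Returns an ``(n_blocks, 3)`` int array.
    """
    out = np.zeros((n_blocks, 3), dtype=np.int64)
    diag = sites["diag_strain"].to_numpy()
    for s in Strain:
        mask = diag == int(s)
        out[:, int(s)] = np.bincount(
            block_ids[mask], weights=depths.diag_depth[mask], minlength=n_blocks
        )
    return out


def compute_fractions(depth_triple: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Depth fractions per block: (depths, fractions).

    ``depth_triple`` has shape (..., 3). Where the total is zero the
    fractions are NaN (undefined → no_call(zero_depth) downstream).
    """
    d = np.asarray(depth_triple, dtype=float)
    total = d.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, d / total, np.nan)
    return d, f


def genotype_rules(
    fractions: np.ndarray, thresholds: ClassifierThresholds | None = None
) -> np.ndarray:
    """Raw outcome of the four genotype rules on fraction triples.

    Returns a boolean array of shape ``(4, ...)`` in Genotype order
    (CA/CA, CA/WA, CA/LR, WA/LR) with no exclusivity enforcement — under
    the default thresholds no triple on the simplex satisfies two rules,
    and :func:`call_block_genotype` asserts this at run time.
    """
    if thresholds is None:
        thresholds = ClassifierThresholds()
    f = np.asarray(fractions, dtype=float)
    f_ca, f_wa, f_lr = f[..., 0], f[..., 1], f[..., 2]
    hom = thresholds.homozygote_min_fraction
    absent = thresholds.absent_max_fraction
    bal = thresholds.het_balance_max

    def het(fi, fj):
        if thresholds.het_rule == "balance":
            return np.abs(fi - fj) <= bal
        return np.abs(fi - fj) > bal

    with np.errstate(invalid="ignore"):
        return np.stack(
            [
                f_ca > hom,
                (f_lr < absent) & het(f_ca, f_wa),
                (f_wa < absent) & het(f_ca, f_lr),
                (f_ca < absent) & het(f_wa, f_lr),
            ]
        )


def call_block_genotype(
    fractions: np.ndarray,
    depths: np.ndarray,
    thresholds: ClassifierThresholds | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the four-way genotype rules to fraction triples.

    ``fractions``: (..., 3) array (NaN triple = zero-depth block);
    ``depths``: matching (..., 3) read counts. Returns ``(calls, reasons)``
    int8 arrays: calls hold :class:`~hybmap.core.Genotype` values
    (``NO_CALL`` = −1), reasons the ``REASON_*`` codes.
    """
    if thresholds is None:
        thresholds = ClassifierThresholds()
    f = np.asarray(fractions, dtype=float)
    d = np.asarray(depths)
    total = d.sum(axis=-1)
    defined = np.isfinite(f).all(axis=-1)
    fsum = np.where(defined, f.sum(axis=-1), 1.0)
    if np.any(np.abs(fsum - 1.0) > 1e-9):
        raise AssertionError("fractions do not sum to 1")

    rules = genotype_rules(f, thresholds)
    if thresholds.het_rule == "balance":
        n_sat = rules.sum(axis=0)
        if np.any(n_sat[defined] > 1):
            raise AssertionError(
                "genotype rules are not mutually exclusive under these thresholds"
            )

    calls = np.full(f.shape[:-1], int(Genotype.NO_CALL), dtype=np.int8)
    # first-match priority; a no-op under the balance rule, which is
    # mutually exclusive (asserted above)
    for g, sat in zip(
        (Genotype.CA_CA, Genotype.CA_WA, Genotype.CA_LR, Genotype.WA_LR), rules
    ):
        calls[sat & defined & (calls == int(Genotype.NO_CALL))] = int(g)

    reasons = np.full(f.shape[:-1], REASON_CALLED, dtype=np.int8)
    reasons[(calls == int(Genotype.NO_CALL))] = REASON_AMBIGUOUS
    low = defined & (total < thresholds.min_classified_reads)
    calls[low] = int(Genotype.NO_CALL)
    reasons[low] = REASON_LOW_DEPTH
    calls[~defined] = int(Genotype.NO_CALL)
    reasons[~defined] = REASON_ZERO_DEPTH
    reasons[calls != int(Genotype.NO_CALL)] = REASON_CALLED
    return calls, reasons


def apply_x_constraint(
    calls: np.ndarray,
    reasons: np.ndarray,
    blocks: pd.DataFrame,
    chromosomes: Sequence[ChromosomeSpec],
    male_x_strain: Strain = Strain.CA,
) -> None:
    """No-call X-chromosome genotypes incompatible with the intact male X.

    F2 hermaphrodites inherit the male's single X unrecombined, so an X
    block's paternal component must equal ``male_x_strain``. With a CA male
    X only CA/CA and CA/LR are admissible; with a WA male X only CA/WA and
    WA/LR. Operates in place on the (n_blocks, n_f2) call matrix.
    """
    x_names = {c.name for c in chromosomes if c.is_x}
    if not x_names:
        return
    if male_x_strain == Strain.CA:
        ok = {int(Genotype.CA_CA), int(Genotype.CA_LR)}
    elif male_x_strain == Strain.WA:
        ok = {int(Genotype.CA_WA), int(Genotype.WA_LR)}
    else:
        raise ValueError("male X strain must be CA or WA")
    on_x = blocks["chrom"].isin(x_names).to_numpy()
    bad = on_x[:, None] & (calls >= 0) & ~np.isin(calls, list(ok))
    calls[bad] = int(Genotype.NO_CALL)
    reasons[bad] = REASON_INCOMPATIBLE_X


def genotype_cohort(
    depth_iter: Iterable[F2Depths],
    sites: pd.DataFrame,
    blocks: pd.DataFrame,
    chromosomes: Sequence[ChromosomeSpec],
    thresholds: ClassifierThresholds | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    male_x_strain: Strain = Strain.CA,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Genotype every F2 at every block.

    Returns ``(calls, reasons, depth_tensor, f2_ids)`` where ``calls`` and
    ``reasons`` are (n_blocks, n_f2) int8 matrices and ``depth_tensor`` is
    (n_f2, n_blocks, 3) diagnostic read counts.
    """
    bid = site_block_ids(sites, chromosomes, block_size)
    n_blocks = len(blocks)
    tensors = []
    f2_ids = []
    for dep in depth_iter:
        tensors.append(block_depths(dep, sites, bid, n_blocks))
        f2_ids.append(dep.f2_id)
    depth_tensor = np.stack(tensors) if tensors else np.zeros((0, n_blocks, 3), int)
    d, f = compute_fractions(depth_tensor)
    calls, reasons = call_block_genotype(f, depth_tensor, thresholds)
    calls, reasons = calls.T.copy(), reasons.T.copy()  # -> (n_blocks, n_f2)
    apply_x_constraint(calls, reasons, blocks, chromosomes, male_x_strain)
    return calls, reasons, depth_tensor, f2_ids


# ---------------------------------------------------------------------------
# block filtering


def filter_blocks(
    blocks: pd.DataFrame,
    calls: np.ndarray,
    distortion_pvalues: np.ndarray,
    min_sites: int = 100,
    max_uncalled_fraction: float = 0.30,
    distortion_alpha: float = 0.001,
) -> pd.DataFrame:
    """Apply the three block-level filters.

    A block is kept iff it has at least ``min_sites`` diagnostic sites, at
    most ``max_uncalled_fraction`` of F2 uncalled, and a segregation-
    distortion p-value above ``distortion_alpha``. Returns the blocks table
    with ``kept`` (bool) and ``drop_reason`` columns (reasons combined with
    ``,`` when several apply).
    """
    n_f2 = calls.shape[1]
    uncalled = (calls < 0).sum(axis=1) / max(n_f2, 1)
    too_few = blocks["n_sites"].to_numpy() < min_sites
    too_uncalled = uncalled > max_uncalled_fraction
    distorted = np.asarray(distortion_pvalues) <= distortion_alpha
    out = blocks.copy()
    out["uncalled_fraction"] = uncalled
    out["distortion_p"] = distortion_pvalues
    reasons = []
    for a, b, c in zip(too_few, too_uncalled, distorted):
        r = [
            name
            for flag, name in (
                (a, "too_few_sites"),
                (b, "too_many_uncalled"),
                (c, "distorted"),
            )
            if flag
        ]
        reasons.append(",".join(r))
    out["drop_reason"] = reasons
    out["kept"] = ~(too_few | too_uncalled | distorted)
    return out
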