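"""Phasing of block genotypes into parental haplotypes and crossover calls.

Because WA haplotypes can only arrive through the sperm of the CA/WA male
and LR haplotypes only through ova of the CA/LR hermaphrodite, each of the
four F2 block genotypes decomposes uniquely into a (paternal, maternal)
strain pair, and every genotype transition along a chromosome is a
crossover in exactly one identifiable F1 parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, ChromosomeSpec, Genotype, Parent, Strain

#: genotype -> (paternal strain, maternal strain); a bijection.
DECOMPOSE = {
    Genotype.CA_CA: (Strain.CA, Strain.CA),
    Genotype.CA_WA: (Strain.WA, Strain.CA),
    Genotype.CA_LR: (Strain.CA, Strain.LR),
    Genotype.WA_LR: (Strain.WA, Strain.LR),
}
RECOMPOSE = {v: k for k, v in DECOMPOSE.items()}

#: call code -> paternal / maternal strain codes (−1 for no_call)
_PAT_LUT = np.full(5, MISSING, dtype=np.int8)
_MAT_LUT = np.full(5, MISSING, dtype=np.int8)
for g, (p, m) in DECOMPOSE.items():
    _PAT_LUT[int(g)] = int(p)
    _MAT_LUT[int(g)] = int(m)


def decompose(call: Genotype) -> tuple[Strain, Strain]:
    """Phase one genotype into its (paternal, maternal) strain pair."""
    if call == Genotype.NO_CALL:
        raise ValueError("cannot decompose a no_call")
    return DECOMPOSE[call]


def recompose(paternal: Strain, maternal: Strain) -> Genotype:
    """Inverse of :func:`decompose`."""
    return RECOMPOSE[(paternal, maternal)]


def decompose_matrix(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized phasing of a call matrix; no_call → missing in both."""
    return _PAT_LUT[calls], _MAT_LUT[calls]


@dataclass
class CrossoverCalls:
    """Crossovers of one chromatid: intervals, midpoints, diagnostics."""

    intervals: list[tuple[int, int]]
    midpoints: list[float]
    n_called_blocks: int
    low_information: bool  # fewer than 2 called blocks

    @property
    def n_crossovers(self) -> int:
        return len(self.intervals)


def call_crossovers(
    labels: np.ndarray, block_starts: np.ndarray, block_ends: np.ndarray
) -> CrossoverCalls:
    """Call crossovers along one chromatid's ordered block label vector.

    A crossover is called wherever the strain label changes between two
    consecutive *called* blocks; its interval runs from the end of the left
    called block to the start of the right one, so intervening missing
    blocks widen the interval. Terminal missing blocks generate no
    crossover. The point estimate is the interval midpoint.
    """
    labels = np.asarray(labels)
    called = np.flatnonzero(labels != MISSING)
    if len(called) < 2:
        return CrossoverCalls([], [], len(called), True)
    lab = labels[called]
    change = np.flatnonzero(lab[:-1] != lab[1:])
    intervals = [
        (int(block_ends[called[i]]), int(block_starts[called[i + 1]]))
        for i in change
    ]
    mids = [(a + b) / 2.0 for a, b in intervals]
    return CrossoverCalls(intervals, mids, len(called), False)


def phase_cohort(
    calls: np.ndarray,
    blocks: pd.DataFrame,
    chromosomes: list[ChromosomeSpec],
    f2_ids: list[str],
    *,
    kept_mask: np.ndarray | None = None,
    suspect_co_threshold: int = 3,
) -> pd.DataFrame:
    """Phase a (n_blocks, n_f2) call matrix into per-chromatid records.

    Returns one row per (F2, chromosome, parent) with columns ``f2_id,
    chromosome, parent, n_called_blocks, n_crossovers, recombinant,
    co_intervals, co_midpoints, nonrecombinant_strain, low_information,
    suspect``. No smoothing is applied: every transition between called
    blocks counts, and chromatids with more than ``suspect_co_threshold``
    crossovers are flagged rather than edited.
    """
    if kept_mask is None:
        kept_mask = np.ones(len(blocks), dtype=bool)
    pat, mat = decompose_matrix(calls)
    chrom_arr = blocks["chrom"].to_numpy()
    starts = blocks["start"].to_numpy()
    ends = blocks["end"].to_numpy()
    rows = []
    for chrom in chromosomes:
        sel = np.flatnonzero((chrom_arr == chrom.name) & kept_mask)
        order = sel[np.argsort(starts[sel], kind="stable")]
        b_starts, b_ends = starts[order], ends[order]
        for parent, mat_or_pat in ((Parent.PATERNAL, pat), (Parent.MATERNAL, mat)):
            sub = mat_or_pat[order]
            for j, f2_id in enumerate(f2_ids):
                vec = sub[:, j]
                cc = call_crossovers(vec, b_starts, b_ends)
                called = vec[vec != MISSING]
                nonrec_strain = (
                    Strain(int(called[0])).name
                    if cc.n_crossovers == 0 and len(called)
                    else ""
                )
                rows.append(
                    {
                        "f2_id": f2_id,
                        "chromosome": chrom.name,
                        "parent": str(parent),
                        "is_x": chrom.is_x,
                        "n_called_blocks": cc.n_called_blocks,
                        "n_crossovers": cc.n_crossovers,
                        "recombinant": cc.n_crossovers >= 1,
                        "co_intervals": ";".join(f"{a}-{b}" for a, b in cc.intervals),
                        "co_midpoints": ";".join(f"{m:.1f}" for m in cc.midpoints),
                        "nonrecombinant_strain": nonrec_strain,
                        "low_information": cc.low_information,
                        "suspect": cc.n_crossovers > suspect_co_threshold,
                    }
                )
    return pd.DataFrame(rows)


def tally_chromatids(chromatids: pd.DataFrame) -> dict:
    """Cohort-level crossover summary.

    Fractions are over chromatids with at least two called blocks, and the
    paternal X (a single intact haplotype, never recombinant) is excluded
    from all denominators. Reports per-parent and per-chromosome
    nonrecombinant and double-crossover counts and fractions.
    """
    df = chromatids[
        ~(chromatids["is_x"] & (chromatids["parent"] == str(Parent.PATERNAL)))
        & ~chromatids["low_information"]
    ]
    out: dict = {"n_chromatids": int(len(df))}
    for parent in (Parent.PATERNAL, Parent.MATERNAL):
        sub = df[df["parent"] == str(parent)]
        n = len(sub)
        nonrec = int((sub["n_crossovers"] == 0).sum())
        double = int((sub["n_crossovers"] >= 2).sum())
        out[str(parent)] = {
            "n": n,
            "nonrecombinant": nonrec,
            "nonrecombinant_fraction": nonrec / n if n else float("nan"),
            "double_co": double,
            "double_co_fraction": double / n if n else float("nan"),
            "suspect": int(sub["suspect"].sum()),
        }
    per_chrom = {}
    for (chrom, parent), sub in df.groupby(["chromosome", "parent"]):
        n = len(sub)
        per_chrom[f"{chrom}:{parent}"] = {
            "n": n,
            "nonrecombinant": int((sub["n_crossovers"] == 0).sum()),
            "double_co": int((sub["n_crossovers"] >= 2).sum()),
        }
    out["per_chromosome"] = per_chrom
    return out
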