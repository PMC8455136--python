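"""Selection of cross-informative variant sites from parental tables.

A site is useful for genotyping the double cross when all three parental
strains are homozygous, sequencing depth is unremarkable in all three, the
site is biallelic, and exactly one strain carries a private allele — making
every read of that allele diagnostic for the strain's haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Strain

#: Rejection classes; every non-accepted site falls in exactly one.
REJECTION_REASONS = ("het", "depth", "not_biallelic", "not_diagnostic", "missing")


@dataclass(frozen=True)
class DepthBounds:
    """Per-strain acceptable depth range: mean ± 3 SD, floored at 0."""

    bounds: dict[Strain, tuple[float, float]]

    def __post_init__(self) -> None:
        for s, (lo, hi) in self.bounds.items():
            if lo > hi or hi < 0:
                raise ValueError(f"invalid depth bounds for {s.name}: ({lo}, {hi})")

    def contains(self, strain: Strain, depth: float) -> bool:
        lo, hi = self.bounds[strain]
        return lo <= depth <= hi


def bounds_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Depth window mean ± 3·SD, floored at zero."""
    return (max(0.0, mean - 3.0 * sd), mean + 3.0 * sd)


def compute_depth_bounds(parental: pd.DataFrame) -> DepthBounds:
    """Genome-wide per-strain depth bounds (mean ± 3 SD) from the table."""
    if parental is None or not len(parental):
        raise ValueError("parental site table is empty")
    out = {}
    for s in Strain:
        dp = parental[f"dp_{s.name}"].to_numpy(dtype=float)
        out[s] = bounds_from_moments(dp.mean(), dp.std())
    return DepthBounds(out)


def classify_table(
    parental: pd.DataFrame, bounds: DepthBounds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized site filter.

    Returns ``(accepted, rejected)``. ``accepted`` has columns ``chrom, pos,
    diag_strain, diag_allele, shared_allele``; ``rejected`` carries a
    ``reason`` column with one of :data:`REJECTION_REASONS`. Filters, in
    order: missing genotype, heterozygous parent, depth outside bounds,
    not biallelic, no single diagnostic strain.
    """
    n = len(parental)
    alleles = np.empty((3, n), dtype=object)
    missing = np.zeros(n, dtype=bool)
    het = np.zeros(n, dtype=bool)
    for s in Strain:
        gt = parental[f"gt_{s.name}"].astype(str).to_numpy()
        split = np.char.partition(gt.astype(str), "/")
        a1, a2 = split[:, 0], split[:, 2]
        missing |= (a1 == ".") | (a2 == ".") | (a1 == "") | (a2 == "")
        het |= (a1 != a2) & ~missing
        alleles[int(s)] = a1
    depth_bad = np.zeros(n, dtype=bool)
    for s in Strain:
        lo, hi = bounds.bounds[s]
        dp = parental[f"dp_{s.name}"].to_numpy(dtype=float)
        depth_bad |= (dp < lo) | (dp > hi)

    a_ca, a_wa, a_lr = alleles
    eq_cw = a_ca == a_wa
    eq_cl = a_ca == a_lr
    eq_wl = a_wa == a_lr
    n_pairs_eq = eq_cw.astype(int) + eq_cl.astype(int) + eq_wl.astype(int)
    # three homozygous strains, two alleles <=> exactly one equal pair
    monoallelic = n_pairs_eq == 3
    triallelic = n_pairs_eq == 0
    diag_code = np.full(n, -1, dtype=np.int8)
    diag_code[eq_wl & ~eq_cw] = int(Strain.CA)
    diag_code[eq_cl & ~eq_cw] = int(Strain.WA)
    diag_code[eq_cw & ~eq_cl] = int(Strain.LR)

    reason = np.full(n, "", dtype=object)
    reason[(diag_code < 0) & ~monoallelic & ~triallelic] = "not_diagnostic"
    reason[monoallelic | triallelic] = "not_biallelic"
    reason[depth_bad] = "depth"
    reason[het] = "het"
    reason[missing] = "missing"
    accepted_mask = reason == ""

    shared = np.where(diag_code == int(Strain.CA), a_wa, a_ca)
    diag_allele = np.select(
        [diag_code == int(s) for s in Strain], [a_ca, a_wa, a_lr], default=""
    )
    accepted = pd.DataFrame(
        {
            "chrom": parental["chrom"].to_numpy()[accepted_mask],
            "pos": parental["pos"].to_numpy()[accepted_mask],
            "diag_strain": diag_code[accepted_mask],
            "diag_allele": diag_allele[accepted_mask],
            "shared_allele": shared[accepted_mask],
        }
    ).reset_index(drop=True)
    rejected = parental.loc[~accepted_mask, ["chrom", "pos"]].copy()
    rejected["reason"] = reason[~accepted_mask]
    return accepted, rejected.reset_index(drop=True)


def classify_site(record: pd.Series | dict, bounds: DepthBounds):
    """Classify a single parental site record.

    Returns an accepted-site dict (``chrom, pos, diag_strain, diag_allele,
    shared_allele``) or a rejection dict with a ``reason`` key.
    """
    df = pd.DataFrame([dict(record)])
    accepted, rejected = classify_table(df, bounds)
    if len(accepted):
        row = accepted.iloc[0].to_dict()
        row["diag_strain"] = Strain(int(row["diag_strain"]))
        return row
    return rejected.iloc[0].to_dict()


def tally_informative(sites: pd.DataFrame) -> pd.DataFrame:
    """Counts of accepted sites per diagnostic strain, by chromosome and
    genome-wide (chromosome ``"all"``)."""
    cols = [s.name for s in Strain]
    if not len(sites):
        return pd.DataFrame([{"chrom": "all", **{c: 0 for c in cols}}])
    tab = (
        sites.assign(strain=sites["diag_strain"].map(lambda c: Strain(int(c)).name))
        .pivot_table(index="chrom", columns="strain", values="pos", aggfunc="count", fill_value=0)
        .reindex(columns=cols, fill_value=0)
    )
    tab.loc["all"] = tab.sum()
    return tab.astype(int).reset_index().rename_axis(None, axis=1)
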