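"""Readers and writers for the pipeline's interchange formats.

Conventions: TSV with documented headers is the interchange format; VCF is
accepted for parental variants (1-based positions, per-strain GT:DP); BED
(0-based half-open) for sites and blocks; JSON for summaries, ground truth
and the run manifest; YAML for configuration. All TSV/BED coordinates are
0-based half-open and stated so in file headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ChromosomeSpec, Parent, Strain
from .sim_cross import F2Depths, F2Individual, Haplotype, SimTruth

_COORD_HEADER = "# coordinates: 0-based, half-open\n"


# ---------------------------------------------------------------------------
# parental variants: VCF and TSV


def write_parental_vcf(panel: pd.DataFrame, chromosomes: Sequence[ChromosomeSpec],
                       path: str | Path) -> None:
    """Write the parental panel as a minimal three-sample VCF (GT:DP).

    REF is the shared allele, ALT the diagnostic allele; positions become
    1-based per the VCF spec.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybmap simulated parental panel\n")
        for c in chromosomes:
            fh.write(f"##contig=<ID={c.name},length={c.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCA\tWA\tLR\n"
        )
        for row in panel.itertuples(index=False):
            ref, alt = row.shared_allele, row.diag_allele
            samples = []
            for s in Strain:
                gt = getattr(row, f"gt_{s.name}")
                a1, _, a2 = gt.partition("/")
                code = "/".join(
                    "." if a == "." else ("1" if a == alt else "0") for a in (a1, a2)
                )
                samples.append(f"{code}:{getattr(row, f'dp_{s.name}')}")
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(samples)
                + "\n"
            )


def read_parental_vcf(path: str | Path) -> pd.DataFrame:
    """Read a three-sample parental VCF into the parental table format.

    Samples must be named CA, WA, LR (any order). Multi-allelic records
    are kept (they fall to the ``not_biallelic`` filter downstream when
    three alleles are actually observed among the parents).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in ("CA", "WA", "LR"):
        if name not in samples:
            raise ValueError(f"VCF lacks required sample {name!r}")
    idx = {name: samples.index(name) for name in ("CA", "WA", "LR")}
    rows = []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        gts = var.genotypes  # [allele1, allele2, phased]
        depths = var.format("DP")
        rec = {"chrom": var.CHROM, "pos": var.POS - 1}
        for name in ("CA", "WA", "LR"):
            g = gts[idx[name]]
            a1 = "." if g[0] < 0 else alleles[g[0]]
            a2 = "." if g[1] < 0 else alleles[g[1]]
            rec[f"gt_{name}"] = f"{a1}/{a2}"
            rec[f"dp_{name}"] = (
                int(depths[idx[name]][0]) if depths is not None else 0
            )
        rows.append(rec)
    vcf.close()
    return pd.DataFrame(rows)


def write_parental_tsv(panel: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        panel.to_csv(fh, sep="\t", index=False)


def read_parental_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# sites


def write_sites_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        sites.to_csv(fh, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """Accepted sites as BED: chrom, start, end, name=diag strain."""
    bed = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
            "name": sites["diag_strain"].map(lambda c: Strain(int(c)).name),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_blocks_bed(blocks: pd.DataFrame, path: str | Path) -> None:
    cols = blocks[["chrom", "start", "end", "block_id"]]
    cols.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# F2 depths


def write_depths_tsv(
    depth_iter: Iterable[F2Depths], sites: pd.DataFrame, path: str | Path
) -> None:
    """Long-form per-site allele depths (f2_id, chrom, pos, allele, depth).

    Zero-depth alleles are omitted; readers restore them from the sites
    table. Suited to small simulations — at genome scale keep depths in
    memory or write the block-level tensor instead.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        first = True
        for dep in depth_iter:
            dep.to_frame(sites).to_csv(fh, sep="\t", index=False, header=first)
            first = False


def read_depths_tsv(path: str | Path, sites: pd.DataFrame) -> list[F2Depths]:
    """Inverse of :func:`write_depths_tsv`, aligned to ``sites`` rows.

    Depth records at positions absent from ``sites`` (e.g. sites removed by
    the informative-site filter) are ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    key = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    site_index = pd.Series(np.arange(len(sites)), index=key)
    out = []
    for f2_id, sub in df.groupby("f2_id", sort=True):
        diag = np.zeros(len(sites), dtype=np.int64)
        other = np.zeros(len(sites), dtype=np.int64)
        keys = pd.MultiIndex.from_arrays([sub["chrom"], sub["pos"]])
        idx = site_index.reindex(keys).to_numpy()
        known = np.isfinite(idx)
        idx = idx[known].astype(np.int64)
        depth = sub["depth"].to_numpy()[known]
        is_diag = (
            sub["allele"].to_numpy()[known] == sites["diag_allele"].to_numpy()[idx]
        )
        np.add.at(diag, idx[is_diag], depth[is_diag])
        np.add.at(other, idx[~is_diag], depth[~is_diag])
        out.append(F2Depths(str(f2_id), diag, other))
    return out


# ---------------------------------------------------------------------------
# calls, fractions, maps


def write_call_matrix(
    calls: np.ndarray, blocks: pd.DataFrame, f2_ids: list[str], path: str | Path
) -> None:
    """Call matrix TSV: rows = blocks, one column per F2 (genotype names)."""
    from .core import Genotype

    lut = {int(g): str(g) for g in Genotype}
    df = blocks[["block_id", "chrom", "start", "end"]].copy()
    for j, f2 in enumerate(f2_ids):
        df[f2] = [lut[int(c)] for c in calls[:, j]]
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def read_call_matrix(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    from .core import Genotype

    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["block_id", "chrom", "start", "end"]
    f2_ids = [c for c in df.columns if c not in meta_cols]
    lut = {str(g): int(g) for g in Genotype}
    calls = np.stack(
        [df[f2].map(lut).to_numpy(dtype=np.int8) for f2 in f2_ids], axis=1
    )
    return calls, df[meta_cols], f2_ids


def write_fraction_table(
    depth_tensor: np.ndarray,
    blocks: pd.DataFrame,
    f2_ids: list[str],
    path: str | Path,
) -> None:
    """Long-form per-(F2, block) depths and fractions."""
    from .block_genotyper import compute_fractions

    d, f = compute_fractions(depth_tensor)
    n_f2, n_blocks, _ = depth_tensor.shape
    df = pd.DataFrame(
        {
            "f2_id": np.repeat(f2_ids, n_blocks),
            "block_id": np.tile(blocks["block_id"].to_numpy(), n_f2),
            "depth_CA": d[..., 0].ravel().astype(int),
            "depth_WA": d[..., 1].ravel().astype(int),
            "depth_LR": d[..., 2].ravel().astype(int),
            "f_CA": f[..., 0].ravel(),
            "f_WA": f[..., 1].ravel(),
            "f_LR": f[..., 2].ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# truth, config, manifest


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "male_x_strain": truth.male_x_strain.name,
        "chromosomes": [
            {
                "name": c.name,
                "length": c.length,
                "is_x": c.is_x,
                "arm_boundaries": list(c.arm_boundaries),
            }
            for c in truth.chromosomes
        ],
        "f2": truth.to_records(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    chroms = [
        ChromosomeSpec(
            c["name"], c["length"], c["is_x"], tuple(c["arm_boundaries"])
        )
        for c in payload["chromosomes"]
    ]
    inds: dict[str, F2Individual] = {}
    for rec in payload["f2"]:
        ind = inds.setdefault(rec["f2_id"], F2Individual(rec["f2_id"], {}))
        ind.haplotypes[(rec["chromosome"], Parent(rec["parent"]))] = Haplotype(
            tuple(rec["breakpoints"]), tuple(Strain[s] for s in rec["labels"])
        )
    return SimTruth(chroms, list(inds.values()), Strain[payload["male_x_strain"]])


def read_chromosome_table(path: str | Path) -> list[ChromosomeSpec]:
    """Chromosome table TSV: name, length, is_x, [arm_start, arm_end]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    chroms = []
    for row in df.itertuples(index=False):
        arms = None
        if hasattr(row, "arm_start") and hasattr(row, "arm_end"):
            arms = (int(row.arm_start), int(row.arm_end))
        chroms.append(
            ChromosomeSpec(str(row.name), int(row.length), bool(row.is_x), arms)
        )
    return chroms


def write_chromosome_table(
    chromosomes: Sequence[ChromosomeSpec], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "name": [c.name for c in chromosomes],
            "length": [c.length for c in chromosomes],
            "is_x": [c.is_x for c in chromosomes],
            "arm_start": [c.arm_boundaries[0] for c in chromosomes],
            "arm_end": [c.arm_boundaries[1] for c in chromosomes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (Strain, Parent)):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
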