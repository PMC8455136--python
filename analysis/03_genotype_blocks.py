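"""Genotype the F2 cohort in 100-kb blocks by allele-depth fractions.

Reports the four-way call composition, the no-call rate by reason, and the
block filtering funnel (too few sites / too many uncalled F2 / segregation
distortion at p <= 0.001) — the synthetic analogue of the study's
1567 -> 1398 block funnel.

Writes results/block_funnel.json (and the full per-block filter
table to scratch/block_filter.tsv).
"""

import json

import numpy as np

from common import RESULTS, SCRATCH, get_run
from hybmap.block_genotyper import NO_CALL_REASONS
from hybmap.core import Genotype


def main() -> None:
    res = get_run(seed=0)
    calls, reasons = res.calls, res.call_reasons

    call_mix = {
        str(Genotype(g)): int((calls == g).sum()) for g in (0, 1, 2, 3, -1)
    }
    reason_mix = {
        name: int((reasons == code).sum())
        for code, name in NO_CALL_REASONS.items()
        if code != 0
    }
    kept = res.blocks["kept"]
    funnel = {
        "blocks_total": int(len(res.blocks)),
        "blocks_kept": int(kept.sum()),
        "dropped_by_reason": res.blocks.loc[~kept, "drop_reason"]
        .value_counts()
        .to_dict(),
        "call_composition": call_mix,
        "no_call_by_reason": reason_mix,
        "no_call_rate": float((calls < 0).mean()),
        "median_uncalled_fraction_per_block": float(
            np.median(res.blocks["uncalled_fraction"])
        ),
    }
    (RESULTS / "block_funnel.json").write_text(json.dumps(funnel, indent=1))
    res.blocks.to_csv(SCRATCH / "block_filter.tsv", sep="\t", index=False,
                      float_format="%.4g")

    print(f"blocks kept {funnel['blocks_kept']}/{funnel['blocks_total']} "
          f"(dropped: {funnel['dropped_by_reason']})")
    print(f"call composition: {call_mix}")
    print(f"no-calls by reason: {reason_mix} "
          f"(overall rate {funnel['no_call_rate']:.3f})")


if __name__ == "__main__":
    main()
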