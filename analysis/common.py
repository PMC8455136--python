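"""Shared plumbing for the numbered analysis drivers.

The full-scale study run (93 F2, default karyotype, ~5x coverage) takes
about a minute, so the drivers share one cached result per seed, pickled
under scratch/ (bulky, not part of the deliverable). Small summary tables
go under results/.
"""

from __future__ import annotations

import pickle
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_run(seed: int = 0):
    from hybmap.pipeline import PipelineConfig, run_pipeline

    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cache = SCRATCH / f"study_run_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    print(f"[common] running full pipeline (seed={seed}) ...", file=sys.stderr)
    res = run_pipeline(PipelineConfig(seed=seed))
    with open(cache, "wb") as fh:
        pickle.dump(res, fh)
    return res
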