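#!/usr/bin/env python
"""Run the full estimation pipeline on the exported world.

Reads results/world (from 01_build_world.py), applies the study constants
(confidence 0.45, population coverage >= 50%, cloud drop >= 0.95,
low-count flag < 10), and writes every stage table plus the manifest
under results/run.
"""

import json
import sys

from satdisp.config import RunConfig
from satdisp.pipeline import PipelineInputs, run_pipeline

IN, OUT = "results/world", "results/run"


def main(seed: int = 1) -> None:
    inputs = PipelineInputs.from_dir(IN)
    manifest = run_pipeline(None, RunConfig(seed=seed), OUT, inputs=inputs)
    print("stage funnel:")
    for stage, info in manifest["stages"].items():
        print(f"  {stage}: {json.dumps(info, default=str)}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
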