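#!/usr/bin/env python
"""Run the full pipeline on the toy dataset from 01_simulate.py.

Executes screen → MFE → classify → aggregate → correlate → triples through
the orchestrator and copies the small result tables into results/.
"""

import shutil
from pathlib import Path

from mirbact.pipeline import run_all

ROOT = Path(__file__).resolve().parent.parent
TOY = ROOT / "scratch" / "analysis" / "toy"
RESULTS = ROOT / "results"


def main() -> None:
    config = TOY / "config.toml"
    if not config.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    manifest = run_all(config)
    for name in ("hits.tsv", "cim.tsv", "triples.tsv", "manifest.json"):
        shutil.copy(TOY / "out" / name, RESULTS / f"02_{name}")
    for stage in manifest.stages:
        print(f"{stage['stage']}: {stage['records_in']} in → "
              f"{stage['records_out']} out ({stage['wall_seconds']}s)")
    print(f"tables → {RESULTS}/02_*.tsv")


if __name__ == "__main__":
    main()
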