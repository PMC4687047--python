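"""End-to-end run: simulate a tracking day, then analyse it.

Writes a simulated day (track, DEM, radiation, colony) to a scratch
directory, runs the full pipeline (QC → AGL → trips → thermals →
metrics → aggregates → energetics) and prints the summary report.
"""

import tempfile
from pathlib import Path

from soartrack import SimConfig, simulate_day, write_simulation
from soartrack.pipeline import build_report, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    sim = Path(tmp) / "sim"
    out = Path(tmp) / "out"
    cfg = SimConfig(seed=11, n_trips=3)
    track, truth, radiation = simulate_day(cfg)
    write_simulation(sim, track, truth, radiation, cfg)

    manifest = run_pipeline(
        track_path=sim / "track.csv", dem_path=sim / "dem.asc",
        radiation_path=sim / "radiation.csv", colony_path=sim / "colony.csv",
        out_dir=out)
    print({k: v for k, v in manifest["stages"].items()})
    print()
    print(build_report(out))
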