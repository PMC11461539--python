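"""Compare sensor-derived WDI against the water-balance simulation.

Pairs each plot-date sensor WDI with the simulated WDI of its treatment on
that date and reports R^2, Willmott's index of agreement, and percent RMSE.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from pivotwdi.pipeline import compare_models

parser = argparse.ArgumentParser()
parser.add_argument("--results-dir", type=Path, default=Path("results"))
args = parser.parse_args()

sensor = pd.read_csv(args.results_dir / "wdi_sensor.csv")
sim = pd.read_csv(args.results_dir / "wdi_simulated.csv")
sim["date"] = pd.to_datetime(sim["date"]).dt.date.astype(str)
merged = sensor.merge(sim[["treatment", "date", "wdi_sim"]],
                      on=["treatment", "date"])

stats = compare_models(merged.wdi, merged.wdi_sim)
doc = dataclasses.asdict(stats)
(args.results_dir / "comparison_stats.json").write_text(json.dumps(doc, indent=2))
print(f"sensor vs simulated WDI over {stats.n} plot-dates:")
print(json.dumps(doc, indent=2))
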