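"""Generate the default synthetic season and write every pipeline input.

Produces daily and near-noon hourly weather, the 12-slice pivot layout with
its randomized treatment map, the ground-truth stress/cover table, and the
noisy 30-second sensor logs for all twice-weekly passes.
"""

import argparse
from pathlib import Path

from pivotwdi import io as pio
from pivotwdi.synth import simulate_season

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out-dir", type=Path, default=Path("results/season"))
args = parser.parse_args()

season = simulate_season(args.seed)
args.out_dir.mkdir(parents=True, exist_ok=True)
pio.write_weather(season.daily, args.out_dir / "weather_daily.csv")
pio.write_weather(season.hourly, args.out_dir / "weather_hourly.csv")
pio.write_layout(season.layout, args.out_dir / "layout.yaml")
season.truth.to_csv(args.out_dir / "truth.csv", index=False)
pio.write_sensor_log(season.readings, args.out_dir / "sensor_readings.csv")

rain = season.daily.precip_mm.sum()
print(f"season: {len(season.daily)} days, {rain:.0f} mm rain, "
      f"{len(season.pass_dates)} sensor passes, {len(season.readings)} readings")
for trt, events in sorted(season.schedules.items()):
    total = sum(mm for _, mm in events)
    print(f"  {trt:.0%} ET replacement: {len(events)} irrigation events, {total:.0f} mm")
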