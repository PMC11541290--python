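"""Generate the synthetic 16-year, 5-station monitoring dataset.

The study's raw agency monitoring series is not publicly deposited, so the
whole analysis runs on a structurally faithful synthetic stand-in: monthly
observations of 12 physicochemical/microbiological parameters at two
upstream (ML8-9) and three downstream (ML10-12) stations, 2004-2019, with
annual seasonality, mild trend, lognormal noise and a programmed
downstream pollution enrichment.  Ground truth (the injected signal) is
written alongside so later stages can be judged against it.

Writes results/monitoring/: monitoring.csv, signal_truth.csv.
"""

import sys
from pathlib import Path

from riverwq import io_config, simulate as sim

OUT = Path(__file__).resolve().parent.parent / "results" / "monitoring"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = sim.SimConfig(seed=SEED)
    table, truth = sim.generate_monitoring_table(cfg)
    io_config.write_results(
        {"monitoring": table.data.assign(date=table.data["date"].dt.strftime("%Y-%m")),
         "signal_truth": truth},
        OUT, metadata={"seed": SEED, "n_years": cfg.n_years,
                       "stations": [s for a in cfg.areas.labels for s in cfg.areas[a]]})
    print(f"wrote {len(table.data)} rows for {len(table.stations)} stations, "
          f"{cfg.n_years} years -> {OUT}")
    print("downstream stations carry 1.35-1.45x pollutant enrichment; "
          "warm-season peaks injected for nutrients, TSS and fecal coliform")


if __name__ == "__main__":
    main()
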