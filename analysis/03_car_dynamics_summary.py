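#!/usr/bin/env python
"""Summarize the gridded car dynamics: yearly and quarterly density
changes per city and oblast, from the pipeline's dynamics stage."""

import pandas as pd

RUN = "results/run"


def main() -> None:
    ch = pd.read_csv(f"{RUN}/dynamics/density_changes.csv")
    for level in ("aoi", "oblast"):
        sub = ch[(ch["level"] == level) & (ch["resolution"] == "year")]
        print(f"\nyearly change in average car density, {level} level:")
        for _, r in sub.iterrows():
            if pd.isna(r["pct_change"]):
                print(f"  {r['unit']} {r['period']}: missing ({r['reason']})")
            else:
                print(f"  {r['unit']} {r['period']}: {r['pct_change']:+.1f}% "
                      f"({r['baseline_density']:.1f} -> {r['period_density']:.1f} cars/km^2)")
    q = ch[(ch["level"] == "oblast") & (ch["resolution"] == "quarter")]
    print("\nquarterly oblast changes:")
    print(q[["unit", "period", "pct_change"]].to_string(index=False))


if __name__ == "__main__":
    main()
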