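#!/usr/bin/env python
"""Report the city-level displaced-population estimates, both methods
side by side, against the generator's known scenario multipliers."""

import pandas as pd

from satdisp.config import WorldConfig

RUN = "results/run"


def main() -> None:
    ch = pd.read_csv(f"{RUN}/estimate/change_estimates.csv")
    summ = pd.read_csv(f"{RUN}/estimate/model_summaries.csv")
    scen = WorldConfig().scenario
    city = ch[ch["level"] == "city"]
    print("city-level % population change (mean over matched months):")
    tab = city.groupby(["city", "year", "method"])["pct_change"].mean().unstack()
    for (c, y), row in tab.iterrows():
        truth = 100.0 * (scen.multiplier(y, c) - 1.0)
        print(f"  {c} {y}: ratio {row.get('ratio', float('nan')):+7.1f}%  "
              f"gam {row.get('gam', float('nan')):+7.1f}%  (truth {truth:+.0f}%)")
    print("\nmodel fit per city (smooth regression):")
    for _, r in summ.iterrows():
        tag = "low-confidence" if r.get("gam_low_confidence") else "ok"
        print(f"  {r['city']}: deviance explained "
              f"{r['gam_deviance_explained']:.2f}, R^2 {r['gam_r2']:.2f} [{tag}]")


if __name__ == "__main__":
    main()
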