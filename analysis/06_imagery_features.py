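#!/usr/bin/env python
"""Imagery-feature model on the pipeline's kept images: how resolution,
snow, off-nadir angle, sun elevation and cloud fraction shift detected
car density, with residual diagnostics."""

import pandas as pd

RUN = "results/run"


def main() -> None:
    table = pd.read_csv(f"{RUN}/glm/feature_glm.csv")
    diag = pd.read_csv(f"{RUN}/glm/feature_glm_diagnostics.csv").iloc[0]
    print("log car-density model (estimate [95% CI], p):")
    for _, r in table.iterrows():
        print(f"  {r['parameter']:<16} {r['estimate']:+.3f} "
              f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]  p={r['p_value']:.3g}")
    print("\nresiduals: Jarque-Bera p={:.3f}, Breusch-Pagan p={:.3f}, "
          "lag-1 autocorr {:+.3f}".format(
              diag["jarque_bera_p"], diag["breusch_pagan_p"], diag["lag1_autocorr"]))


if __name__ == "__main__":
    main()
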