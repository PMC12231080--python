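#!/usr/bin/env python
"""Model the aspen Fire Perimeter Effect against weather and season.

Simple linear models of per-fire aspen FPE on each fire-mean weather
covariate, and a penalized smooth of FPE on ignition day-of-year.
"""

from pathlib import Path

import pandas as pd

from fireprogress.models import fit_fpe_covariate_lm, fit_fpe_doy_smooth
from fireprogress.pipeline import RunConfig

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"


def main() -> None:
    cfg = RunConfig.from_yaml(HERE / "config.yaml")
    fires = pd.read_csv(RESULTS / "fires.csv").dropna(subset=["fpe"])

    lm = fit_fpe_covariate_lm(fires, list(cfg.analysis["covariates"]))
    lm.to_csv(RESULTS / "fpe_lm.csv", index=False)
    print("aspen FPE ~ covariate linear models:")
    print(lm.round(4).to_string(index=False))

    if len(fires) >= 20 and fires["doy"].max() - fires["doy"].min() >= 60:
        sm_res = fit_fpe_doy_smooth(fires["fpe"], fires["doy"])
        pd.DataFrame({"doy": sm_res.grid, "fitted": sm_res.fitted,
                      "ci_low": sm_res.ci_low, "ci_high": sm_res.ci_high}) \
            .to_csv(RESULTS / "fpe_doy_smooth.csv", index=False)
        print(f"FPE ~ s(DOY): edf {sm_res.edf:.2f}, p {sm_res.p_value:.3f}, "
              f"r2 {sm_res.r2:.3f} (n = {sm_res.n} fires)")
    else:
        print("FPE ~ s(DOY) smooth skipped: needs >= 20 fires spanning >= 60 days")


if __name__ == "__main__":
    main()
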