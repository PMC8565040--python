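"""Aggregate the survey microdata into the model's tabular inputs.

Reads ``results/data/microdata_*.csv``, collapses them to prevalence
estimates (with cluster-robust standard errors) and interval-censored
consumption tuples (with quality-effects effective sample sizes), and writes
``prevalence.csv`` / ``consumption.csv`` alongside the inputs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from alcmeta.aggregate import SurveyMeta, aggregate_surveys  # noqa: E402


def main():
    d = ROOT / "results" / "data"
    surveys = pd.read_csv(d / "surveys.csv")
    micro, meta = {}, {}
    for r in surveys.itertuples(index=False):
        micro[r.survey_id] = pd.read_csv(d / f"microdata_{r.survey_id}.csv")
        meta[r.survey_id] = SurveyMeta(survey_id=r.survey_id, year=int(r.year),
                                       bias_score=int(r.bias_score),
                                       has_quantity=bool(r.has_quantity))
    prev, cons = aggregate_surveys(micro, meta)
    prev.to_csv(d / "prevalence.csv", index=False)
    out = cons.copy()
    out["uc"] = out["uc"].replace(np.inf, np.nan)
    out.to_csv(d / "consumption.csv", index=False)
    print(f"{len(prev)} prevalence cells, {len(cons)} consumption tuples")
    sums = cons.groupby(["survey_id", "sex", "age_group"])["pc"].sum()
    print(f"pc sums within cells: min {sums.min():.12f}, max {sums.max():.12f}")
    ne = cons.groupby(["survey_id", "sex", "age_group"])["ne"].first()
    print(f"effective sample sizes span {ne.min():.0f}-{ne.max():.0f}")


if __name__ == "__main__":
    main()
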