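"""Posterior draws to report tables: trends, coverage, drinking categories.

Reads the fit from ``results/fit/`` and writes ``trends.csv`` (prevalence
and mean consumption among drinkers per year and sex, with 95% credible
intervals), ``coverage.csv`` / ``relative_coverage.csv`` (survey coverage
and its sex-age deviations) and ``categories.csv`` (light / intermediate /
heavy drinker shares and volume shares) under ``results/tables/``.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from alcmeta.config import RunConfig, load_model_inputs  # noqa: E402
from alcmeta.inference import PosteriorDraws, SamplerConfig  # noqa: E402
from alcmeta.model import Model  # noqa: E402
from alcmeta.postprocess import category_report, coverage_table, trend_table  # noqa: E402


def main():
    cfg = RunConfig(input_dir=str(ROOT / "results" / "data"))
    z = np.load(ROOT / "results" / "fit" / "draws.npz")
    model = Model(load_model_inputs(cfg), cfg.model_config())
    draws = PosteriorDraws(theta=z["theta"], logpost=z["logpost"], model=model,
                           config=SamplerConfig.preset("test"),
                           divergences=int(z["divergences"]))
    out = ROOT / "results" / "tables"
    out.mkdir(parents=True, exist_ok=True)
    trends = trend_table(draws)
    trends.to_csv(out / "trends.csv", index=False)
    surveys, relative = coverage_table(draws)
    surveys.to_csv(out / "coverage.csv", index=False)
    relative.to_csv(out / "relative_coverage.csv", index=False)
    cats = category_report(draws)
    cats.to_csv(out / "categories.csv", index=False)

    truth = json.loads((ROOT / "results" / "data" / "truth.json").read_text())
    true_c = {s["survey_id"]: s["coverage"] for s in truth["surveys"]}
    print("estimated survey coverage (truth in brackets):")
    for r in surveys.itertuples(index=False):
        print(f"  {r.survey_id}: {100*r.coverage:.1f}% "
              f"({100*r.coverage_lo:.1f}-{100*r.coverage_hi:.1f}) "
              f"[{100*true_c[r.survey_id]:.0f}%]")
    last = trends[(trends.sex == "all") & (trends.year == trends.year.max())]
    row = last.iloc[0]
    print(f"final-year totals: prevalence {100*row.prevalence:.1f}% "
          f"({100*row.prevalence_lo:.1f}-{100*row.prevalence_hi:.1f}), "
          f"mean consumption {row.consumption:.1f} g/day "
          f"({row.consumption_lo:.1f}-{row.consumption_hi:.1f})")
    hm = cats[(cats.sex == "male") & (cats.year == cats.year.max())].iloc[0]
    print(f"final-year males: heavy drinkers {100*hm.p_heavy:.1f}% of drinkers, "
          f"{100*hm.volume_heavy:.1f}% of the volume "
          f"(mean {hm.mean_heavy:.1f} g/day)")


if __name__ == "__main__":
    main()
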