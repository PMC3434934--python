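"""Model-average the top set and report effect sizes and importance.

The top set (all models within 4 AICc of the best, strict) is averaged
with Akaike weights: full (shrinkage) averages with unconditional SEs
and normal 95% CIs are the headline numbers, conditional averages are
reported alongside, and each factor's relative importance is its
summed weight across the top set.  Also writes the predicted
establishment-probability curve against climate match from the single
top model.
"""

import warnings
from pathlib import Path

import pandas as pd

from anurainvade.glmm import ConvergenceWarning, RandomStructure, fit_glmm
from anurainvade.multimodel import (enumerate_models, model_average,
                                    rank_models, top_set)
from anurainvade.pipeline import _climate_curve, report_effect_plot_data

ROOT = Path(__file__).resolve().parents[1] / "results"
CANDIDATES = ("distance", "intentionality", "island", "climate_match",
              "larval_stage")


def main() -> None:
    for variant in ("with_size", "without_size"):
        table = pd.read_csv(ROOT / f"analysis_table_{variant}.csv")
        fits = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for spec in enumerate_models(CANDIDATES):
                fits.append(fit_glmm(table, spec, RandomStructure()))
        fits = [f for f in fits if f.converged]
        ranked = rank_models(fits)
        top = top_set(ranked, 4.0)
        avg = model_average(top, fits)
        avg.table.to_csv(ROOT / f"averaged_estimates_{variant}.csv", index=False)
        plot = report_effect_plot_data(avg)
        plot.to_csv(ROOT / f"effect_plot_{variant}.csv", index=False)
        best = next(f for f in fits
                    if f.spec_code == ranked.entries["spec_code"].iloc[0])
        _climate_curve(best, table, 50).to_csv(
            ROOT / f"climate_curve_{variant}.csv", index=False)
        best.variance_components.to_csv(
            ROOT / f"variance_components_{variant}.csv", index=False)

        print(f"{variant}: top set of {len(top)} models "
              f"(of {len(fits)} converged)")
        for row in plot.itertuples():
            ci = f"[{row.ci_low:+.2f}, {row.ci_high:+.2f}]"
            print(f"  {row.coefficient:32s} importance {row.importance:.2f}  "
                  f"estimate {row.estimate:+.2f} {ci}")
        vc = best.variance_components
        print("  variance components (best model): "
              + ", ".join(f"{r.term}={r.variance:.2f}" for r in vc.itertuples()))


if __name__ == "__main__":
    main()
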