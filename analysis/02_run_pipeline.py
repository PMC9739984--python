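"""Run the full footprint analysis on the simulated cohort.

Consumes the tables written by 01_simulate_cohort.py, computes per-person
carbon/water/ecological footprints and their per-1000-kcal standardization,
tertiles, per-food-group contributions, category comparisons and the
tertile-by-covariate correspondence analyses, then prints the headline
medians and which covariates the CA flags as associated.

Run from the repository root, after 01:  python analysis/02_run_pipeline.py
"""

import json
from pathlib import Path

from enf.pipeline import RunConfig, run

COHORT = Path("results/cohort")
OUT = Path("results/analysis")


def main() -> None:
    config = RunConfig(
        coefficients=COHORT / "coefficients.csv",
        composition=COHORT / "composition.csv",
        pq=COHORT / "pq.csv",
        recall=COHORT / "recall.csv",
        covariates=COHORT / "covariates.csv",
        registry=COHORT / "groups.txt",
        dilution=COHORT / "dilution.csv",
        output_dir=OUT,
    )
    summary = run(config)
    print(f"analyzed {summary['n_respondents']} respondents")
    for kind in ("CF", "WF", "EF"):
        entry = summary["footprints"][kind]
        unit = {"CF": "g CO2eq", "WF": "L", "EF": "m2"}[kind]
        print(f"{kind}: median {entry['total']['median']:.1f} {unit}/day, "
              f"{entry['per_1000_kcal']['median']:.1f} per 1000 kcal "
              f"(tertile medians "
              + " / ".join(f"{entry['tertile_medians'][l]:.1f}"
                           for l in ("low", "medium", "high")) + ")")
    verdicts = json.loads((OUT / "ca_verdicts.json").read_text())
    associated = sorted(k for k, v in verdicts.items()
                        if v["verdict"] == "associated")
    print(f"CA associations at alpha=0.05: {len(associated)} of "
          f"{len(verdicts)} footprint x covariate pairs")
    for key in associated:
        print(f"  {key}: p = {verdicts[key]['p_value']:.4f}")


if __name__ == "__main__":
    main()
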