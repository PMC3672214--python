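"""Operating characteristics of the MR chain over replicated synthetic studies.

Three experiments, each on 50,000-individual synthetic studies (five
biomarker cohorts, two 1:4 case-control sets at 2% prevalence, instruments
at the study's effect sizes):

  1. recovery at the study's effect (OR 0.88 per SD, 200 replicates):
     bias, empirical vs delta-method SE, 95% CI coverage;
  2. the null (OR 1.0, 200 replicates): type-I error of the combined test;
  3. directional pleiotropy on one instrument (delta = 0.1 on the log-odds
     scale, 80 replicates) vs the matched clean scenario: inflation of the
     across-instrument heterogeneity diagnostic and of bias.

Writes results/recovery_summary.tsv.
Run from the repository root:  python analysis/03_parameter_recovery.py
"""
import dataclasses
import logging
import warnings
from pathlib import Path

import pandas as pd

from ironmr.simulate import SimulationConfig, recover_parameters

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = SimulationConfig(
    n_individuals=50_000,
    variants=(
        ("rs1800562", 0.07, 0.37),
        ("rs1799945", 0.15, 0.19),
        ("rs855791", 0.45, 0.19),
    ),
    seed=7,
    n_cohorts_biomarker=5,
    n_cohorts_disease=2,
    true_or_per_sd=0.88,
    baseline_prevalence=0.02,
    n_case=200,
    n_control=800,
    biomarker_fraction=0.5,
)


def main() -> None:
    logging.basicConfig(level=logging.WARNING)
    warnings.filterwarnings("ignore", message="replicate")
    rows = []

    effect = recover_parameters(CONFIG, n_replicates=200)
    rows.append(("effect_or_0.88", effect))
    print(
        f"Effect scenario (gamma = {effect.gamma_true:.4f}, "
        f"{effect.n_replicates} replicates): bias {effect.bias:+.4f}, "
        f"coverage {effect.coverage:.1%}, empirical SE {effect.empirical_se:.3f} "
        f"vs mean delta SE {effect.mean_delta_se:.3f}"
    )

    null = recover_parameters(
        dataclasses.replace(CONFIG, true_or_per_sd=1.0), n_replicates=200
    )
    rows.append(("null_or_1.0", null))
    print(
        f"Null scenario: type-I error {null.reject_rate:.1%} at nominal 5%, "
        f"bias {null.bias:+.4f}"
    )

    clean = recover_parameters(CONFIG, n_replicates=80)
    pleio = recover_parameters(
        dataclasses.replace(CONFIG, pleiotropy_delta=(0.0, 0.0, 0.1)), n_replicates=80
    )
    rows.append(("clean_80", clean))
    rows.append(("pleiotropy_delta_0.1", pleio))
    print(
        f"Pleiotropy scenario vs matched clean: mean Q {pleio.mean_q:.2f} vs "
        f"{clean.mean_q:.2f}, mean I² {pleio.mean_i2:.1f}% vs {clean.mean_i2:.1f}%, "
        f"|bias| {abs(pleio.bias):.3f} vs {abs(clean.bias):.3f} - a direct "
        "disease pathway shows up as across-instrument heterogeneity."
    )

    RESULTS.mkdir(exist_ok=True)
    frame = pd.DataFrame(
        {
            "scenario": name,
            "n_replicates": s.n_replicates,
            "gamma_true": s.gamma_true,
            "mean_gamma_hat": s.mean_gamma_hat,
            "bias": s.bias,
            "empirical_se": s.empirical_se,
            "mean_delta_se": s.mean_delta_se,
            "coverage": s.coverage,
            "reject_rate": s.reject_rate,
            "mean_q": s.mean_q,
            "mean_i2": s.mean_i2,
        }
        for name, s in rows
    )
    frame.to_csv(RESULTS / "recovery_summary.tsv", sep="\t", index=False)
    print(f"Summary written to {RESULTS / 'recovery_summary.tsv'}")


if __name__ == "__main__":
    main()
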