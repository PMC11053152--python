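"""Clinical recurrence-risk factors among the PM patients.

Univariate Cox models over the eleven clinical features, Kaplan-Meier median
splits with log-rank tests for the significant ones, and the multivariate
model comparison of continuous vs categorical (>= 16 years) age coding by
global p, AIC and Harrell's C-index.

Reads results/cohort/clinical.csv, writes results/clinical/.
"""

from pathlib import Path

from pptc_protrisk import io as pio
from pptc_protrisk.clinical import (
    compare_age_codings,
    descriptive_stats,
    km_logrank,
    median_split,
    univariate_screen,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    clinical = pio.read_clinical(ROOT / "cohort" / "clinical.csv")
    out = ROOT / "clinical"
    out.mkdir(parents=True, exist_ok=True)

    d = descriptive_stats(clinical)
    print(f"PM cohort: n={d['n']}, events={d['n_events']}, "
          f"mean tumor size {d['mean_tumor_size_cm']:.1f} cm, "
          f"median follow-up {d['median_followup_months']:.0f} months")

    screen = univariate_screen(clinical)
    screen.to_csv(out / "univariate_cox.csv")
    sig = screen[screen["significant"]]
    print(f"univariately significant factors (p<0.05): {list(sig.index) or 'none'}")

    logrank = {}
    for factor in sig.index:
        labels, med = median_split(clinical[factor].to_numpy())
        if len(set(labels)) < 2:
            continue
        _, stat, p = km_logrank(clinical, labels)
        logrank[factor] = {"median": med, "logrank_p": p}
        print(f"  {factor}: median split at {med:g}, log-rank p = {p:.3g}")
    pio.write_json(logrank, out / "median_split_logrank.json")

    cmp_ = compare_age_codings(clinical)
    pio.write_json(
        {
            "winners": cmp_["winners"],
            "continuous": cmp_["continuous"].to_dict(),
            "categorical": cmp_["categorical"].to_dict(),
        },
        out / "age_coding_comparison.json",
    )
    print(f"age coding winners (global p / AIC / C-index): {cmp_['winners']}")


if __name__ == "__main__":
    main()
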