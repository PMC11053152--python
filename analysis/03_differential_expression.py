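"""Differential protein expression between groups.

Calls DEPs for PM vs PB and PM vs AM at the modelling threshold (FC > 1.2)
and the enrichment threshold (FC > 1.5), reports counts and the
direction-aware overlap of the two comparisons, and checks recovery of the
planted differential proteins.

Reads results/{cohort,processed}/, writes results/deps/.
"""

from pathlib import Path

from pptc_protrisk import io as pio
from pptc_protrisk.differential import call_deps, overlap_deps

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    matrix = pio.read_matrix(ROOT / "processed" / "matrix.tsv",
                             ROOT / "processed" / "samples.tsv")
    truth = pio.read_json(ROOT / "cohort" / "truth.json")
    out = ROOT / "deps"
    out.mkdir(parents=True, exist_ok=True)

    tables = {}
    for comparison in (("PM", "PB"), ("PM", "AM")):
        for fc in (1.2, 1.5):
            t = call_deps(matrix, *comparison, fc_threshold=fc, alpha=0.05)
            name = f"{comparison[0]}_vs_{comparison[1]}_fc{fc}"
            t.to_csv(out / f"{name}.csv")
            tables[name] = t
            print(f"{name}: {t.attrs['n_up']} up, {t.attrs['n_down']} down")

    ov = overlap_deps(tables["PM_vs_PB_fc1.5"], tables["PM_vs_AM_fc1.5"])
    print(f"co-regulated in both comparisons at FC>1.5: {len(ov['co_regulated'])}")

    planted = set(truth["dep_effects"]) | set(truth["signal_coefs"])
    called = set(tables["PM_vs_PB_fc1.2"].query("call != 'ns'").index)
    print(f"planted differential proteins recovered at FC>1.2: "
          f"{len(called & set(truth['dep_effects']))}/{len(truth['dep_effects'])}; "
          f"false calls: {len(called - planted)}")


if __name__ == "__main__":
    main()
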