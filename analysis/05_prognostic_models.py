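"""Train and compare the five prognostic recurrence models.

CliCox and CliRsf use the eleven clinical features; ProtCox (LASSO-selected),
ProtRsf and CliProtRsf (100-repeat permutation-importance stability
selection) draw proteins from the PM-vs-PB DEP pool at FC > 1.2 computed on
the training patients only.  Each model is tuned by grid search with 3-fold
cross-validation on the 60% training split and evaluated by Harrell's
C-index on train / CV / held-out test patients.

Reads results/{cohort,processed,deps}/, writes results/models/.
"""

from pathlib import Path

import pandas as pd

from pptc_protrisk import io as pio
from pptc_protrisk import models as M
from pptc_protrisk.containers import CLINICAL_FEATURES
from pptc_protrisk.differential import call_deps

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240915
RSF_GRID = {"n_estimators": [150, 300], "max_features": ["sqrt"],
            "min_samples_leaf": [6, 15]}
STABILITY = dict(n_repeats=100, top_k=50, min_count=50)


def main():
    matrix = pio.read_matrix(ROOT / "processed" / "matrix.tsv",
                             ROOT / "processed" / "samples.tsv")
    clinical = pio.read_clinical(ROOT / "cohort" / "clinical.csv")
    out = ROOT / "models"
    out.mkdir(parents=True, exist_ok=True)

    split = M.split_train_test(clinical, 0.6, seed=SEED, stratify=True)
    pio.write_json({"train": split.train_ids, "test": split.test_ids},
                   out / "split.json")
    print(f"split: {len(split.train_ids)} train / {len(split.test_ids)} test")

    deps = call_deps(matrix, "PM", "PB", fc_threshold=1.2,
                     sample_subsets={"PM": split.train_ids})
    pool = list(deps.index[deps["call"] != "ns"])
    print(f"protein feature pool (train-set DEPs at FC>1.2): {len(pool)}")

    prot = matrix.values.loc[pool, clinical.index].T
    clin = clinical[CLINICAL_FEATURES].astype(float)
    pools = {
        "CliCox": clin, "CliRsf": clin, "ProtCox": prot, "ProtRsf": prot,
        "CliProtRsf": pd.concat([clin, prot], axis=1),
    }

    y_tr = clinical.loc[split.train_ids]
    y_te = clinical.loc[split.test_ids]
    rows = []
    for name in M.MODEL_NAMES:
        X_all = pools[name]
        grid = RSF_GRID if name.endswith("Rsf") else {}
        model = M.build_model(
            name, X_all.loc[split.train_ids], y_tr["event"], y_tr["time"],
            seed=SEED, hyper_grid=grid,
            stability_kwargs=dict(STABILITY) if name in ("ProtRsf", "CliProtRsf")
            else None,
        )
        rows.append({
            "model": name,
            "n_features": len(model.features),
            "train": M.evaluate_cindex(model, X_all.loc[split.train_ids],
                                       y_tr["event"], y_tr["time"]),
            "cv": model.cv_cindex,
            "test": M.evaluate_cindex(model, X_all.loc[split.test_ids],
                                      y_te["event"], y_te["time"]),
        })
        if hasattr(model.selection, "counts"):
            model.selection.counts.rename("count").to_csv(
                out / f"stability_counts_{name}.csv")
        pd.Series(model.features).to_csv(out / f"panel_{name}.csv", index=False)
        print(f"{name}: {len(model.features)} features, "
              f"C train/cv/test = {rows[-1]['train']:.3f}/"
              f"{rows[-1]['cv']:.3f}/{rows[-1]['test']:.3f}")

    table = pd.DataFrame(rows).set_index("model")
    table.to_csv(out / "cindex_table.csv")
    best = table["test"].idxmax()
    print(f"best test C-index: {best} ({table.loc[best, 'test']:.3f})")


if __name__ == "__main__":
    main()
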