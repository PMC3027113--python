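"""Train and evaluate the disease/polymorphism classifier end to end.

Generates a synthetic study with a planted disease signal on site closeness
(positive) and entropy (negative), runs the grid-searched 5-fold
cross-validation, and reports the pooled metrics and the most important
features. Sized to finish in about a minute.
"""

import tempfile
from pathlib import Path

from psnvar import (SimConfig, TuneGrid, cross_validate, featurize_table,
                    gen_dataset, permutation_importance, read_aux_tables,
                    read_variant_table, select_top_k, train)

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(n_proteins=8, residues_range=(50, 90), n_saps=600, seed=4)
    out = gen_dataset(cfg, tmp)
    records = read_variant_table(out.variants_path)
    aux = read_aux_tables(out.sasa_path, out.aggregation_path, out.hla_path)
    feats, _ = featurize_table(records, Path(tmp) / "structures",
                               Path(tmp) / "profiles", aux)

y = feats["label"]
X = feats.drop(columns=["label"])
cv = cross_validate(X, y, TuneGrid(ntree_values=(100, 200),
                                   mtry_values=(2, 6), seed=4))
p = cv.pooled.as_dict()
print(f"best grid point: ntree={cv.best_ntree}, mtry={cv.best_mtry}")
print(f"pooled 5-fold CV: sensitivity {p['sensitivity']:.1f}%  "
      f"specificity {p['specificity']:.1f}%  accuracy {p['accuracy']:.1f}%  "
      f"MCC {p['mcc']:.3f}")

forest = train(X, y, ntree=cv.best_ntree, mtry=cv.best_mtry, seed=4)
imp = permutation_importance(forest, X, y, reps=10, seed=4)
print("top-5 features by permutation importance:", select_top_k(imp, 5))
print("\nThe planted signal ties disease to high closeness and low entropy; "
      "both should appear in the top-5 list, showing the protocol recovers "
      "the structural determinants it was built to detect.")
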