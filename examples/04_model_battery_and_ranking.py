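"""Train SVM and neural-net-ensemble batteries and rank them by parsimony.

Ten models per type are built from distinct derived seeds: stratified test
split, genetic-algorithm descriptor selection, training (with verification-
set early stopping for the ensembles), and nine-indicator evaluation
(Youden J, MCC, accuracy on train/test/all).  Models are ranked by
S = train metrics + test metrics + 100*N_min/N + 100*D_min/D, rewarding
accuracy achieved with few neurons and few descriptors.
"""

import phenobar as pb
from phenobar.mlmodels import battery_summary, rank_models, run_model_battery

records = pb.study_compound_table()
compounds = pb.experimental_drugs(records) + pb.experimental_counterions(records)
wells = pb.simulate_screen(compounds, seed=1)
normalized = pb.normalize_screen(wells)
class_of = {c.compound_id: c.class_label for c in records}
barcodes = pb.barcode_matrix(normalized, class_of)
culled, _ = pb.cull_model_descriptors(barcodes)
prepped = pb.standardize(culled)

for model_type in ("svm", "anne"):
    battery = run_model_battery(prepped, model_type, 10, master_seed=3)
    ranking = rank_models(battery, model_type)
    best = next(r for r in battery if r.model_id == ranking.best_model_id)
    mean_acc, se_acc = battery_summary(battery)["test_accuracy"]
    print(f"{model_type.upper()}: best model {best.model_id} "
          f"(D={best.n_descriptors}"
          + (f", N={best.n_neurons}" if best.n_neurons else "") + ")")
    print(f"  best test accuracy {best.metrics_test.accuracy:.1f}%, "
          f"battery mean {mean_acc:.1f}% (SE {se_acc:.1f})")
    if best.misclassified_ids:
        print(f"  misclassified: {', '.join(best.misclassified_ids)}")
# The ranking prefers the smallest model among equally accurate ones; a
# perfect test score with 3-4 descriptors is typical on the synthetic screen.
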