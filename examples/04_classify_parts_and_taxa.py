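"""Random-Forest classification of plant parts (RFp) and taxon-part classes
(RFtp).

Uses a reduced tuning grid so the example runs in seconds; the package default
is the full 54-combination grid (mtry x ntree x maxnodes x nodesize) scored by
10-fold cross-validation. Parts are expected to classify at least as well as
taxon-part classes: collapsing to parts merges exactly the hard within-genus
distinctions (Bn/Bp catkins, Sh/Sp stems).
"""

from spectradiet import (
    PreprocessConfig,
    RFConfig,
    SyntheticConfig,
    build_feature_table,
    generate_dataset,
    preprocess_sample,
    run_classification,
)
from spectradiet.pipeline import _group_replicates

spectra, metas = generate_dataset(SyntheticConfig(n_samples_per_class=12, seed=0))
averaged = [
    preprocess_sample(reps, PreprocessConfig())
    for reps in _group_replicates(spectra).values()
]
fast = RFConfig(cv_folds=5, mtry_grid=(5,), ntree_grid=(100, 300),
                maxnodes_grid=(100,), nodesize_grid=(1,), seed=0)

for name, mode in (("RFp (5 parts)", "part"), ("RFtp (8 taxon-parts)", "taxon_part")):
    table = build_feature_table(averaged, metas, label_mode=mode)
    report, result, _ = run_classification(table, fast)
    lo, hi = report.ci95
    print(f"{name}: accuracy {report.overall_accuracy:.3f} "
          f"(95% CI {lo:.3f}-{hi:.3f}), kappa {report.kappa:.3f}, "
          f"OOB error {report.oob_error_pct:.2f}%")

top = list(report.importances.items())[:3]
print("\nmost important bands for RFtp (mean decrease in accuracy):")
for band, importance in top:
    print(f"  {band}: {importance:.4f}")
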