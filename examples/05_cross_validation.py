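"""Stratified 10-fold evaluation of a classifier on framework features.

Positives here carry a planted lysine enrichment (+1.5 log-odds), so a
counts-based model should separate the classes well; the same run on
unshifted data hovers at AUC 0.5.
"""

from ampfeat import FeatureSpec, generate_synthetic, run_cv

spec = FeatureSpec(("conform", "no_reduction"), ("counts",), (1,))  # 27 features

signal = generate_synthetic(153, 250, composition_shift={"K": 1.5}, seed=7)
report = run_cv(signal, spec, model_name="rf", k=10, seed=7)
row = report.to_table_row()
print(f"planted signal: Nfeat={row['Nfeat']} "
      f"Acc={row['Accuracy']:.3f} F1={row['F1 score']:.3f} "
      f"AUC={row['AUC ROC']:.3f} MCC={row['MCC']:.3f}")

null = generate_synthetic(153, 250, center_residues=None, seed=7)
report0 = run_cv(null, spec, model_name="logistic", k=10, seed=7)
print(f"no signal:      AUC={report0.aggregate['auc_roc']:.3f} (chance is 0.5)")
# The gap between the two AUCs is the generator's planted effect; with no
# class-dependent composition the cross-validated AUC stays at chance,
# showing the pipeline leaks no label information.
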