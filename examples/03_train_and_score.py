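"""Train the boosted-tree expression model and score it on held-out chr8.

Expression is log10(x + 1e-4); the model is gradient-boosted regression
trees on the flattened tensors; the score is the Spearman rank correlation
between predicted and observed log-expression on the held-out chromosome.
"""

from spex import (
    ModelConfig,
    build_all_tensors,
    evaluate_spearman,
    fixture_distal_effect,
    make_design,
    simulate,
    strip_spatial,
    train,
)

sim = simulate(fixture_distal_effect())
spatial = build_all_tensors(sim.genes, sim.predictor(), sim.contacts)
baseline = {g: strip_spatial(t) for g, t in spatial.items()}

for name, tensors in [("baseline (F×10)", baseline), ("spatial (F×11)", spatial)]:
    design = make_design(tensors, sim.expression, sim.gene_chroms)
    model = train(design, ModelConfig(seed=0))
    rho = evaluate_spearman(model, design.X_test, design.y_test)
    print(f"{name}: test Spearman = {rho:.3f} "
          f"({len(design.train_genes)} train, {len(design.test_genes)} test genes)")

print("\nThe gap is the value of the contact map: the baseline cannot see the "
      "distal enhancer signal that drives expression for looped genes.")
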