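"""Train a coverage-matched random forest on simulated data and genotype
fresh simulated samples.

A desk-scale run (60 training samples at 10x) so the script finishes in
about a minute; the full study conditions (240 samples at 30x, five seed
replicates) are what scripts/acceptance.py reproduces.
"""

from svkg import build_kmer_index, default_blueprint, generate_haplotype_panel, predict
from svkg.dataset import simulate_dataset
from svkg.genotyper import FAST_GRID, TrainingConfig, train
from svkg.kmers import KmerFeatureVector

panel = generate_haplotype_panel(default_blueprint())
index = build_kmer_index(panel)

train_set = simulate_dataset(panel, index, n_samples=60, coverage=10.0, seed=1)
model = train(train_set, config=TrainingConfig(grid=FAST_GRID))
best = max(model.cv_report, key=lambda r: r["mean_accuracy"])
print(f"chosen hyperparameters: {model.chosen_params}")
print(f"cross-validation accuracy: {best['mean_accuracy']:.3f} "
      f"± {best['sd_accuracy']:.3f} over 5 folds")

test_set = simulate_dataset(panel, index, n_samples=12, coverage=10.0, seed=2)
correct = 0
for i in range(test_set.n_samples):
    vec = KmerFeatureVector(
        index_hash=test_set.index_hash, counts=test_set.X[i],
        sample_id=test_set.sample_ids[i],
    )
    label, probs, flag = predict(model, vec)
    truth = test_set.labels[i]
    correct += label == truth
    print(f"{vec.sample_id}: truth {truth}, predicted {label} "
          f"(p={probs[label]:.2f}, {flag})")
print(f"\n{correct}/{test_set.n_samples} correct on fresh simulated samples")
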