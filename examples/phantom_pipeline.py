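"""Train ResMini end to end on synthetic brain-slice phantoms.

Generates separable three-class phantoms (95x79, the study's image size),
trains for a few epochs and reports held-out accuracy with the confusion
matrix.  With morphology separation >= 1 the classes differ in brain size,
cortical-ring thickness and ventricle radius, and the network should reach
high held-out accuracy within ~10 epochs.
"""

from resmini.experiments import run_phantom_experiment

result = run_phantom_experiment(train_per_class=30, val_per_class=6,
                                test_per_class=10, separation=1.5,
                                epochs=10, seed=7)

print(f"trained on {result.n_train} phantoms, tested on {result.n_test}")
print(f"final training loss: {result.history.train_loss[-1]:.4f}")
print(f"held-out accuracy:   {result.metrics.accuracy:.3f}")
print(f"macro recall:        {result.metrics.macro_recall:.3f}")
print("confusion matrix (rows = true, cols = predicted):")
for name, row in zip(result.confusion.class_names, result.confusion.counts):
    print(f"  {name:<10} {row}")
print("\nAn accuracy near 1.0 means the network recovered the morphological "
      "class signal from noisy phantoms; chance would be 0.333.")
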