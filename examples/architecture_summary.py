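"""Print the ResMini layer plan, its parameter total and the economy ratios.

The per-layer table comes from the symbolic plan (no weights are built);
the comparison uses the published totals of BHCnet and ResNet-18.
"""

from resmini import (BHCNET_TOTAL_PARAMETERS, ResMiniConfig,
                     build_resnet18_baseline, parameter_ratio_percent,
                     summarize)

config = ResMiniConfig()  # f=9, grayscale 95x79 input, 3 classes
summary = summarize(config)
print(summary.as_text())

baseline = build_resnet18_baseline(num_classes=3)
print(f"\nResNet-18 baseline total: {baseline.total_parameters:,} "
      f"({baseline.weighted_layer_count} weighted layers)")
print("ResMini / BHCnet:   "
      f"{parameter_ratio_percent(summary.total_parameters, BHCNET_TOTAL_PARAMETERS):.2f}%")
print("ResMini / ResNet-18: "
      f"{parameter_ratio_percent(summary.total_parameters, baseline.total_parameters):.2f}%")
print("\nResMini carries ~99k parameters -- about half of BHCnet and under "
      "1% of ResNet-18 -- at a depth of 10 weighted layers.")
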