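"""Architecture accounting: parameters, FLOPs and the headline savings.

Counts the trainable parameters and one-forward-pass MACs of the
parallel-ViT baseline network (6 layers x 2 branches of ViT-Base) and
the cross-parallel network (7 layers, 1 DD layer, activation block) at
224x224 input, under the convention calibrated on the published
inter-row deltas, and prints the relative reductions.
"""

from cptseg.accounting import account, calibrate_convention
from cptseg.published import reference_configs, row_config

rows = [(cfg, pm, fg if i < 6 else None)
        for i, (cfg, pm, fg) in enumerate(reference_configs())]
calibration = calibrate_convention(rows)
conv = calibration.convention
print(f"calibrated convention: {conv.describe()}")
print(f"residual on printed deltas: {calibration.max_rel_error:.2%}\n")

baseline = account(row_config("parallel_vit", 6, 2, 0, 0), conv)
cpt = account(row_config("cpt", 7, 2, 1, 0), conv)

for name, rep in (("parallel ViT-B 6x2", baseline), ("C-PT 7L/2B/1DD", cpt)):
    print(f"{name:>20}: {rep.params_millions:7.2f} M params, "
          f"{rep.flops_giga:6.2f} GFLOPs @224")
    for comp, p, f in rep.breakdown:
        print(f"{'':>22}{comp:<12} {p:7.2f} M  {f:6.2f} G")

print(f"\nparameter reduction: "
      f"{100 * (1 - cpt.params_millions / baseline.params_millions):.1f}%")
print(f"FLOP reduction:      "
      f"{100 * (1 - cpt.flops_giga / baseline.flops_giga):.1f}%")
print("(the cross-parallel block drops the 2*d*d_mlp feed-forward weights, "
      "paying back a smaller DD-layer cost)")
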