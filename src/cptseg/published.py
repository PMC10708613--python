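"""Published parameter/FLOP budgets for this architecture family.

These are the reported complexity figures (Params in "M", FLOPs in "G")
for the parallel-ViT and cross-parallel variants of the hybrid
segmentation network at 224x224 input, as printed by the original
evaluation.  They serve two purposes:

* :func:`cptseg.accounting.calibrate_convention` uses the *inter-row
  deltas* (which depend only on the transformer stack, not on the
  unreported CNN/decoder truncation) to recover the counting convention
  behind the printed figures;
* the default CNN/decoder widths of :class:`cptseg.networks.NetworkConfig`
  were reconstructed so the full-network budgets land on these totals.

Each row: variant, transformer depth/parallelism/dd/mlp, printed totals.
"""

from __future__ import annotations

from .cpt_module import CPTConfig
from .networks import NetworkConfig

# (variant, depth, parallelism, dd_layers, mlp_layers, params_M, flops_G@224)
REFERENCE_ROWS: list[tuple[str, int, int, int, int, float, float | None]] = [
    # parallel ViT-B, depth experiment
    ("parallel_vit", 5, 2, 0, 0, 75.39, 21.95),
    ("parallel_vit", 6, 2, 0, 0, 88.91, 24.73),
    ("parallel_vit", 7, 2, 0, 0, 102.43, 27.51),
    # cross-parallel, depth experiment (1 DD, activation block)
    ("cpt", 5, 2, 1, 0, 47.28, 16.18),
    ("cpt", 6, 2, 1, 0, 55.17, 17.80),
    ("cpt", 7, 2, 1, 0, 63.07, 19.43),
    ("cpt", 8, 2, 1, 0, 70.96, 21.05),
    ("cpt", 9, 2, 1, 0, 78.86, 22.68),
    # DD ablation (activation block, depth 6-8)
    ("cpt", 6, 2, 0, 0, 34.89, 13.64),
    ("cpt", 7, 2, 0, 0, 39.41, 14.57),
    ("cpt", 8, 2, 0, 0, 43.93, 15.51),
    ("cpt", 6, 2, 2, 0, 75.45, 21.96),
    ("cpt", 7, 2, 2, 0, 86.72, 24.28),
    ("cpt", 8, 2, 2, 0, 97.99, 26.61),
    # MLP ablation (1 DD, depth 6-8)
    ("cpt", 6, 2, 1, 1, 82.19, 23.35),
    ("cpt", 7, 2, 1, 1, 94.59, 25.90),
    ("cpt", 6, 2, 1, 2, 109.22, 28.90),
    ("cpt", 7, 2, 1, 2, 126.13, 32.38),
]


def row_config(variant: str, depth: int, parallelism: int,
               dd_layers: int, mlp_layers: int,
               image_size: int = 224) -> NetworkConfig:
    """Default-width network config for one published row."""
    tf = CPTConfig(depth=depth, parallelism=parallelism,
                   dd_layers=dd_layers, mlp_layers=mlp_layers)
    return NetworkConfig(variant=variant, image_size=image_size, transformer=tf)


def reference_configs(image_size: int = 224):
    """All published rows as ``(config, params_M, flops_G)`` triples."""
    return [(row_config(v, d, p, dd, mlp, image_size), pm, fg)
            for v, d, p, dd, mlp, pm, fg in REFERENCE_ROWS]
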