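"""Fused vs unimodal chapter prediction with a paired DeLong comparison.

Runs one complete seed of the study: cohort -> dual-loss autoencoder ->
latents -> phase-2 fusion classifier for the circulatory chapter (IX),
next to its image-only and tabular-only ablations.  Prints the three
held-out AUCs and the DeLong p-value of the fused model against the weaker
unimodal one.  Fusion should match or beat both branches.
"""

from perifuse.experiments import run_seed

result = run_seed(seed=1, n_subjects=400)
print(f"fused test AUC        {result.fused_auc:.3f}")
print(f"image-only test AUC   {result.image_only_auc:.3f}")
print(f"tabular-only test AUC {result.tabular_only_auc:.3f}")
print(
    "DeLong fused vs weaker unimodal: "
    f"p = {result.delong_fused_vs_weaker_p:.4f} "
    f"({'significant' if result.delong_fused_vs_weaker_p < 0.05 else 'not significant'} at 0.05)"
)
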