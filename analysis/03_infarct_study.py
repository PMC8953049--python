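"""Infarct sizing: Otsu-stratified PET vs TTC stain on matched phantoms.

Six subjects carry a 25% infarct wedge (zero vascular signal).  Each is
sized two ways — three-class Otsu stratification of the mid short-axis PET
slice (low class = infarct) and color-threshold segmentation of a matched
synthetic TTC stain photograph — and the per-method mean +/- SE is
reported, mirroring the published cross-method comparison.  A small PSF
sweep then shows the partial-volume overestimation of the PET estimate.
"""

from dataclasses import replace
from pathlib import Path

from vascupet import InfarctSpec, infarct_percentage, make_lv_phantom
from vascupet.pipeline import default_infarct_config, run_infarct_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

cfg = default_infarct_config(seed=1)
table, summary = run_infarct_study(cfg, out_dir=OUT)
print(f"infarct study (n={len(table)}, true wedge 25%):")
print(table.round(2).to_string(index=False))
for _, row in summary.iterrows():
    print(f"{row['method']}: mean = {row['mean']:.2f}%, SE = {row['se']:.2f}")

print("\nPSF sweep (one subject): partial-volume effect on the PET estimate")
for sigma in (0.0, 1.0, 2.0, 3.0):
    spec = replace(cfg.base_spec, psf_sigma_mm=sigma,
                   infarct=InfarctSpec(extent_deg=90.0, activity_scale=0.0), seed=42)
    ph = make_lv_phantom(spec, "rest")
    est = infarct_percentage(ph.diastolic_gate, ph.myocardium_mask, spec.grid_shape[2] // 2)
    print(f"  psf sigma = {sigma:.1f} mm -> infarct {est.infarct_pct:.2f}% (truth 25%)")
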