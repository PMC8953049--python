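"""Generate the reference phantom set used by the downstream analyses.

Writes a rest/stress gated LV pair, a rest/stress brain pair, and a
TTC-stained slice image (with its ground-truth label mask summarised in a
sidecar) under results/phantoms/, each with its generating spec for
provenance.  Every downstream script regenerates what it needs from specs,
so this is illustrative output, not a dependency.
"""

import json
from dataclasses import replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from vascupet import InfarctSpec, PhantomSpec, make_brain_phantom, make_lv_phantom, make_ttc_image
from vascupet.image_io import write_mask, write_volume
from vascupet.phantom import save_gated_phantom

OUT = Path(__file__).resolve().parents[1] / "results" / "phantoms"
OUT.mkdir(parents=True, exist_ok=True)

base = PhantomSpec(noise="poisson", dwell_scale=1.0, seed=20220227)

lv_spec = replace(base, vasodilation_delta=0.523)
for mode in ("rest", "stress"):
    ph = make_lv_phantom(lv_spec, mode)
    save_gated_phantom(ph, OUT, prefix=f"lv_{mode}")
    print(
        f"LV {mode}: {len(ph.gates)} gates, shell={ph.myocardium_mask.voxel_count} vox, "
        f"chamber={ph.chamber_mask.voxel_count} vox, "
        f"shell mean={ph.diastolic_gate.values[ph.myocardium_mask.values].mean():.1f} Bq/mL"
    )

brain_spec = replace(base, vasodilation_delta=0.722)
for mode in ("rest", "stress"):
    vol, mask = make_brain_phantom(brain_spec, mode)
    write_volume(vol, OUT / f"brain_{mode}.nii.gz")
    write_mask(mask, OUT / f"brain_{mode}_mask.nii.gz")
    print(f"brain {mode}: mean={vol.values[mask.values].mean():.1f} Bq/mL over {mask.voxel_count} vox")
brain_spec.to_json(OUT / "brain_spec.json")

infarct_spec = replace(base, infarct=InfarctSpec(extent_deg=90.0, activity_scale=0.0))
save_gated_phantom(make_lv_phantom(infarct_spec, "rest"), OUT, prefix="lv_infarct")

img, labels = make_ttc_image(wedge_fraction=0.25, image_size=256, seed=base.seed)
iio.imwrite(OUT / "ttc_slice.png", img)
(OUT / "ttc_slice_truth.json").write_text(
    json.dumps(
        {
            "wedge_fraction": 0.25,
            "viable_pixels": int(np.sum(labels == 1)),
            "infarct_pixels": int(np.sum(labels == 2)),
        },
        indent=2,
    )
)
print(f"wrote phantom set to {OUT}")
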