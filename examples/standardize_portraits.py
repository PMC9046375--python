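"""Standardize a directory of heterogeneous raw portraits.

Builds three synthetic raw photos of different sizes and orientations,
then runs the batch standardizer with coordinate-based rotation clicks
and bounding boxes (the scriptable stand-in for the GUI steps).
"""

import tempfile
from pathlib import Path

import numpy as np

from richroster import FixtureSpec, StandardizationParams, render_roster, standardize_batch
from richroster.imgio import load_image, save_image

workdir = Path(tempfile.mkdtemp())
raw = workdir / "RawPhotos"

# three raw photos: one fine, one upscaled, one rotated on its side
portraits = render_roster(FixtureSpec(n_recipients=3))
(aaa, bbb, ccc) = portraits.values()
save_image(aaa, raw / "AA0.jpg")
save_image(np.repeat(np.repeat(bbb, 3, axis=0), 3, axis=1), raw / "BA1.jpg")
tilted = np.rot90(ccc)  # needs a 90-degree CW fix
save_image(tilted, raw / "CA2.jpg")

params = StandardizationParams(size_out=200, asr=1.25, border_px=4)
written = standardize_batch(
    raw,
    workdir / "StandardizedPhotos",
    params,
    rotations={"CA2": (tilted.shape[1] - 1, 0)},  # upper-right click -> 90 CW
)

for pid, path in written.items():
    h, w, _ = load_image(path).shape
    print(f"{pid}: {w}x{h} px written to {path.name}")
print("Every output is size_out x round(size_out*asr) =",
      f"{params.out_width}x{params.out_height} px with a {params.border_px}-px black frame.")
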