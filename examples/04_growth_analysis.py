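"""Relative growth rates across a multiplexed image series.

Writes a synthetic 6-timepoint series to disk, runs the full pipeline
(timestamp parsing, layout detection on the first image, hull
segmentation, per-unit areas), and fits the relative growth rate (RGR) of
each unit as the slope of ln(area) over time in days.
"""

import tempfile
from pathlib import Path

from hullseg import RunConfig, run_series
from hullseg.config import LayoutConfig
from hullseg.fixtures import FixtureSpec, make_image_series, write_series

spec = FixtureSpec(seed=3, rows=2, cols=3, groups=2, rgr=0.25, noise_sigma=0.03)
series = make_image_series(spec)

with tempfile.TemporaryDirectory() as tmp:
    img_dir = Path(tmp) / "imgs"
    write_series(series, img_dir, write_masks=False)
    cfg = RunConfig(
        images=str(img_dir),
        vertices=[list(map(float, v)) for v in spec.hull_vertices],
        delta=5.0,
        out_dir=str(Path(tmp) / "out"),
        layout=LayoutConfig(
            r_min=spec.marker_radius - 4, r_max=spec.marker_radius + 4,
            expected_n=spec.n_units, cut_distance=spec.recommended_cut,
        ),
    )
    result = run_series(cfg)

print(result.fits[["unit", "group", "rgr", "r_squared", "flags"]].to_string(index=False))
print()
print(result.groups.to_string(index=False))
print(f"\ngenerating rate was {spec.rgr}/day with sigma={spec.noise_sigma} noise")
# Each unit's fitted RGR sits near the generating 0.25/day; the group
# table reports mean +/- SD over unflagged units per tray.
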