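"""Virtual-4C viewpoint profile and publication-style figures.

Selects all interactions touching a viewpoint region, bins the partner
signal across a window, and renders the profile plus the dataset summary
panels and an arc diagram (SVG files in ./example_output/).
"""

from pathlib import Path

from chromlink import GenomicRange, viewpoint
from chromlink.fixtures import FixtureConfig, generate_interactions
from chromlink.plotting import arc_plot_data, render_arcs, render_summary, render_viewpoint

out = Path("example_output")
out.mkdir(exist_ok=True)

iset, _ = generate_interactions(FixtureConfig(seed=0, n_interactions=800))

region = GenomicRange("chr1", 100_000, 400_000)
window = GenomicRange("chr1", 1, 2_000_000)
profile = viewpoint(iset, region, window, bin_width=20_000, mode="midpoint")
print(f"viewpoint total signal: {int(profile.signal.sum())} counts "
      f"across {len(profile.bins)} bins")
render_viewpoint(profile, out / "viewpoint.svg", format="svg")

data = render_summary(iset, out / "summary.svg", format="svg")
print("cis/trans table:\n", data["cis_trans"].to_string(index=False))

spec = arc_plot_data(iset, window, height_by="counts")
print(f"arc diagram: {len(spec.arcs)} pairs in the window")
render_arcs(spec, out / "arcs.svg", format="svg", log_height=True)

print(f"figures written under {out}/")
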