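"""Circular layout: concentric annuli sharing one angular domain.

Taxa sit on sectors starting at 12 o'clock and proceeding clockwise, with
angular gaps at group boundaries; a group band, a heatmap ring and an outer
bar ring share the same sectors. Printed angles verify the convention.
"""

import math
from pathlib import Path

import numpy as np

from plotalign import (
    CircleLayout,
    GroupBar,
    Heatmap,
    Summary,
    angular_position,
    write_svg,
)

out = Path("scratch")
out.mkdir(exist_ok=True)

rng = np.random.default_rng(2)
n = 16
ids = tuple(f"t{i:02d}" for i in range(n))
values = rng.normal(0, 1, (3, n))
groups = {t: f"g{(i * 2) // n + 1}" for i, t in enumerate(ids)}

c = CircleLayout(ids=ids, r_inner=0.3, gap_angle=0.08, radial_gap=0.02)
c.group_by(groups)
c.add(GroupBar(), size=0.2)
c.add(Heatmap(values, col_ids=ids), size=1.0)
c.add(Summary({t: float(abs(values[:, i]).mean()) for i, t in enumerate(ids)},
              geom="bar"), size=0.5)
fig = c.assemble()
write_svg(fig, out / "circle.svg")

domain = fig.panels["groups"].x_domain
first = domain.display_ids[0]
s, e = angular_position(domain, first, gap_angle=0.08)
print(f"first sector: starts at {s:.4f} rad ({math.degrees(s):.1f} deg, "
      f"12 o'clock), width {s - e:.4f} rad")
widths = [angular_position(domain, i, 0.08) for i in ids]
total = sum(a - b for a, b in widths) + 2 * 0.08
print(f"sector widths + gaps = {total:.12f} rad (2*pi = {2 * math.pi:.12f})")
print("wrote", out / "circle.svg")
# The two groups are separated by angular gaps at both boundaries, and the
# sectors plus gaps tile the full turn exactly.
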