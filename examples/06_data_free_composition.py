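"""Data-free composition: a scatter with axis-aligned marginal panels.

No observation domain is shared here; instead the composer unifies the
continuous axis limits of aligned panels (union of their declared ranges)
so the marginal boxplots line up with the scatter exactly.
"""

from pathlib import Path

import numpy as np

from plotalign import Scatter, compose_grid, write_svg
from plotalign.gallery import _marginal_box_patch

out = Path("scratch")
out.mkdir(exist_ok=True)

rng = np.random.default_rng(4)
x = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
y = np.concatenate([rng.normal(0, 1, 40), rng.normal(-2, 1, 40)])
sc = Scatter(x, y).to_patch()
top = _marginal_box_patch(x, sc.own_limits("x"), horizontal=True)
right = _marginal_box_patch(y, sc.own_limits("y"), horizontal=False)

fig = compose_grid([[top, None], [sc, right]],
                   widths=[1.0, 0.22], heights=[0.22, 1.0], gap=0.02)
write_svg(fig, out / "marginal_scatter.svg")

print("scatter x-limits:", tuple(round(v, 3) for v in fig.panels[(1, 0)].xlim))
print("top marginal x-limits:", tuple(round(v, 3)
                                      for v in fig.panels[(0, 0)].xlim))
print("wrote", out / "marginal_scatter.svg")
# Both panels report the same unified x-limits, so the marginal box sits
# exactly over the scatter's x range.
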