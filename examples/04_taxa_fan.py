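"""One-to-many links: differential phyla fanned out to their genera.

The left panel shows phylum-level mean abundances, the right panel the
genus level; ribbon fans connect each highlighted phylum to every genus it
contains (explicit one-to-many pairs, polygon geometry).
"""

from pathlib import Path

from plotalign import DiscretePalette, StackLayout, Summary, synth_abundance, write_svg

out = Path("scratch")
out.mkdir(exist_ok=True)

taxa = {
    "Bacteroidetes": ("Bacteroides", "Prevotella", "Alistipes"),
    "Firmicutes": ("Clostridium", "Lactobacillus"),
    "Fusobacteria": ("Fusobacterium",),
}
ab = synth_abundance(10, ("COAD", "STAD"), taxa,
                     group_effect={"STAD": {"Fusobacteria": 3.0}}, seed=5)
phyla = list(ab.phylum.col_ids)
genera = list(ab.genus.col_ids)
pal = DiscretePalette.for_labels(phyla, title="phylum")

stack = StackLayout("horizontal", ids=phyla, gap=0.3)
stack.add(Summary({p: float(ab.phylum.values[:, j].mean())
                   for j, p in enumerate(phyla)}, geom="bar",
                  fill={p: pal(p) for p in phyla}), name="phyla")
stack.add_free(Summary({g: float(ab.genus.values[:, j].mean())
                        for j, g in enumerate(genera)}, geom="bar",
                       fill={g: pal(p) for p, gs in ab.hierarchy.items()
                             for g in gs}),
               order=genera, name="genera")
n_ribbons = 0
for p in ("Bacteroidetes", "Fusobacteria"):
    pairs = tuple((p, g) for g in ab.hierarchy[p])
    stack.link("phyla", "genera", geometry="polygon", pairing=pairs)
    n_ribbons += len(pairs)
fig = stack.assemble(size_in=(6.0, 4.5))
write_svg(fig, out / "taxa_fan.svg")

print("phyla:", len(phyla), "genera:", len(genera))
print("fan ribbons drawn:", n_ribbons,
      "(3 from Bacteroidetes, 1 from Fusobacteria)")
print("wrote", out / "taxa_fan.svg")
# Each ribbon spans the phylum's full interval on the left and one genus
# interval on the right: a one-to-many fan.
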