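"""Crosswise (bump-chart) links between two orderings of the same taxa.

Two side-by-side panels order the same phyla by their within-cohort mean
abundance; ribbons connect each phylum to itself across the gap, crossing
wherever the rank changed. The printed ranks show which crossings to expect.
"""

from pathlib import Path

from plotalign import StackLayout, Summary, DiscretePalette, synth_abundance, write_svg

out = Path("scratch")
out.mkdir(exist_ok=True)

taxa = {
    "Bacteroidetes": ("Bacteroides",),
    "Firmicutes": ("Clostridium",),
    "Proteobacteria": ("Escherichia",),
    "Fusobacteria": ("Fusobacterium",),
}
ab = synth_abundance(12, ("COAD", "STAD"), taxa,
                     group_effect={"STAD": {"Fusobacteria": 4.0}}, seed=3)
phyla = list(ab.phylum.col_ids)
pal = DiscretePalette.for_labels(phyla, title="phylum")

means = {}
for grp in ("COAD", "STAD"):
    rows = [i for i, s in enumerate(ab.phylum.row_ids)
            if ab.sample_groups[s] == grp]
    means[grp] = {p: float(ab.phylum.values[rows, j].mean())
                  for j, p in enumerate(phyla)}
orders = {g: sorted(phyla, key=lambda p: -means[g][p]) for g in means}

stack = StackLayout("horizontal", ids=phyla, gap=0.25)
for grp in ("COAD", "STAD"):
    stack.add_free(Summary(means[grp], geom="bar",
                           fill={p: pal(p) for p in phyla}),
                   order=orders[grp], name=grp)
stack.link("COAD", "STAD", geometry="polygon", pairing="by_id")
fig = stack.assemble(size_in=(6.0, 4.0))
write_svg(fig, out / "rank_links.svg")

for grp in orders:
    print(f"{grp} rank order:", " > ".join(orders[grp]))
print("wrote", out / "rank_links.svg")
# A phylum whose rank differs between the two cohorts gets a crossing
# ribbon; identical ranks give parallel ribbons.
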