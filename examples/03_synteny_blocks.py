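"""Core-gene synteny between two genomes: dot plot points and collinear blocks.

Two gene->position maps are intersected into dot-plot points; maximal
monotone chains are the collinear blocks.  A segmental inversion shows up as
an "inverted" block: positions increasing in one genome, decreasing in the
other — the negative-slope arrangement seen in a synteny dot plot.
"""

from epvkit import build_dotplot, find_collinear_blocks

# genome A: 12 shared core genes in order; genome B: first 6 collinear,
# last 6 inverted as a block near the terminus
map_a = {f"core{i:02d}": 5_000 + 4_000 * i for i in range(12)}
map_b = {}
for i in range(6):
    map_b[f"core{i:02d}"] = 8_000 + 3_500 * i
for i in range(6, 12):
    map_b[f"core{i:02d}"] = 95_000 - 4_200 * (i - 6)

points = build_dotplot(map_a, map_b, "genomeA", "genomeB")
print(f"{len(points.points)} shared core genes")

blocks = find_collinear_blocks(points, min_genes=4)
for b in blocks:
    print(
        f"{b.orientation:8s} block of {b.size} genes: "
        f"A {b.span_a[0]/1e3:.0f}-{b.span_a[1]/1e3:.0f} kb vs "
        f"B {b.span_b[0]/1e3:.0f}-{b.span_b[1]/1e3:.0f} kb"
    )
print(
    "-> the inverted block is the signature of a large inversion between the"
    " two genomes; block size is the length of the longest monotone chain."
)
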