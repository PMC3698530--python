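"""Haplotype network with frequency-styled edges, emitted as DOT.

Alleles at two loci become nodes; each haplotype above the display
threshold draws a connecting line. With a bold threshold instead, every
haplotype is drawn — bold above it, dotted below — and alleles of
interest are highlighted in red. Pipe the output to ``dot -Tsvg`` to
render.
"""

from hlapop import HaplotypeFrequencySpectrum, build_graph, parse_allele, to_dot

freqs = {
    ("B*57:01", "DRB1*07:01"): 0.02,
    ("B*08:01", "DRB1*03:01"): 0.005,
    ("B*07:02", "DRB1*15:01"): 0.975,
}
spectrum = HaplotypeFrequencySpectrum(
    loci=("B", "DRB1"),
    freqs={(parse_allele(a), parse_allele(b)): f for (a, b), f in freqs.items()},
)

g = build_graph(
    [(spectrum, "ENW")],
    display_threshold=0.0,
    bold_threshold=0.01,
    highlight=["B*57:01", "DRB1*07:01"],
)
print(to_dot(g))
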