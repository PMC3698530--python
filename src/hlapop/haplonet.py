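"""Haplotype networks: allele nodes joined by frequency-styled edges.

Two display conventions are supported, matching common practice for HLA
haplotype figures:

* a *display threshold*: only haplotypes above the threshold draw a
  connecting line (e.g. "frequencies over 5%");
* a *bold threshold* (with display threshold 0): every haplotype draws a
  line, bold above the threshold and dotted below (e.g. bold over 1%).

Thresholds compare with strict ``>``. Graphs serialise to deterministic
GraphViz DOT; alleles of interest (e.g. DILI-associated) render as red
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InputError
from .haplotypes import HaplotypeFrequencySpectrum

Node = tuple[str, str]  # (locus, allele name)


@dataclass(frozen=True)
class HaploEdge:
    a: Node
    b: Node
    frequency: float
    style: str  # solid | bold | dotted
    source: str = "user"


@dataclass
class HaploGraph:
    """Allele-node multigraph with frequency-styled edges."""

    nodes: set[Node] = field(default_factory=set)
    edges: list[HaploEdge] = field(default_factory=list)
    highlight: set[str] = field(default_factory=set)  # allele names

    def add_edge(self, edge: HaploEdge) -> None:
        if edge.a == edge.b:
            raise InputError(f"self-edge on {edge.a}")
        if edge.a[0] == edge.b[0]:
            raise InputError(
                f"edge endpoints at the same locus {edge.a[0]}"
            )
        self.nodes.add(edge.a)
        self.nodes.add(edge.b)
        self.edges.append(edge)


def _style_for(
    frequency: float, display_threshold: float, bold_threshold: float | None
) -> str | None:
    """Edge style as a pure function of frequency and thresholds.

    Returns None when the edge is not drawn at all.
    """
    if frequency <= display_threshold:
        return None
    if bold_threshold is None:
        return "solid"
    return "bold" if frequency > bold_threshold else "dotted"


def build_graph(
    spectra: Iterable[tuple[HaplotypeFrequencySpectrum, str]],
    display_threshold: float = 0.05,
    bold_threshold: float | None = None,
    highlight: Sequence[str] = (),
) -> HaploGraph:
    """Build a haplotype network from labelled two-locus spectra.

    ``spectra`` is an iterable of (spectrum, source_label) pairs; sources
    contributing the same allele pair draw parallel edges tagged by label,
    never averaged.
    """
    g = HaploGraph(highlight=set(highlight))
    for spectrum, source in spectra:
        if len(spectrum.loci) != 2:
            raise InputError(
                f"haplotype network needs 2-locus spectra, got arity "
                f"{len(spectrum.loci)}"
            )
        locus_a, locus_b = spectrum.loci
        for hap, freq in spectrum.freqs.items():
            style = _style_for(freq, display_threshold, bold_threshold)
            if style is None:
                continue
            g.add_edge(
                HaploEdge(
                    a=(locus_a, hap[0].name),
                    b=(locus_b, hap[1].name),
                    frequency=freq,
                    style=style,
                    source=source,
                )
            )
    return g


_STYLE_ATTRS = {
    "solid": 'style=solid',
    "bold": 'style=bold, penwidth=2',
    "dotted": 'style=dotted',
}


def to_dot(g: HaploGraph) -> str:
    """Serialise to GraphViz DOT, byte-deterministically.

    Nodes are labelled with the allele name; highlighted alleles are drawn
    red. Nodes and edges are emitted in lexicographic order so identical
    graphs produce identical text.
    """
    lines = ["graph haplotypes {", "  node [shape=ellipse];"]
    for locus, allele in sorted(g.nodes):
        attrs = [f'label="{allele}"']
        if allele in g.highlight:
            attrs.append("color=red")
            attrs.append("fontcolor=red")
        lines.append(f'  "{allele}" [{", ".join(attrs)}];')
    edge_keys = sorted(
        g.edges,
        key=lambda e: (e.a, e.b, e.source, e.frequency, e.style),
    )
    for e in edge_keys:
        attrs = (
            f'{_STYLE_ATTRS[e.style]}, label="{e.frequency:.3f}", '
            f'tooltip="{e.source}"'
        )
        lines.append(f'  "{e.a[1]}" -- "{e.b[1]}" [{attrs}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
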