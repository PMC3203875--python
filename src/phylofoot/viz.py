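"""SVG figures: annotated homology-based alignment, tree logos, colours.

Species are told apart by a colour gradient along the leaves of the
tree: evolutionarily close species get similar hues, and nodes close to
the root are drawn darker than nodes close to the leaves.  The annotated
alignment draws each cross-species homolog group once, with
species-coloured overlays (thick where a displayed pattern supports the
site, thin for plain extant predictions).
"""

from __future__ import annotations

import colorsys
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

from .alignmap import Alignment, GenomeAnchor
from .exceptions import TreeError
from .export import anchor_to_genome, pattern_palette
from .homology import HomologGroup
from .parsimony import SpeciesTree
from .patterns import Pattern, rank_and_filter

#: Default cap on the number of patterns drawn, keeping figures readable.
DEFAULT_MAX_PATTERNS = 10

#: Hue arc assigned to the leaves; capped below a full turn so the first
#: and last leaves stay distinguishable.
DEFAULT_HUE_ARC = (0.0, 0.75)


@dataclass
class ColorAssignment:
    """Per-node HSV colours: hue follows the leaf gradient, value grows
    with distance from the root (root darkest)."""

    hsv: dict[int, tuple[float, float, float]]

    def hex(self, node_id: int) -> str:
        h, s, v = self.hsv[node_id]
        r, g, b = colorsys.hsv_to_rgb(h, s, v)
        return f"#{round(r*255):02x}{round(g*255):02x}{round(b*255):02x}"

    def value(self, node_id: int) -> float:
        return self.hsv[node_id][2]

    def hue(self, node_id: int) -> float:
        return self.hsv[node_id][0]


def assign_colors(
    tree: SpeciesTree,
    hue_arc: tuple[float, float] = DEFAULT_HUE_ARC,
    saturation: float = 0.65,
    value_range: tuple[float, float] = (0.45, 0.95),
) -> ColorAssignment:
    """Gradient colours: leaf i of n gets hue arc position i/(n-1);
    internal nodes average their descendant leaves' hues; value scales
    with depth so the root is darkest."""
    leaves = tree.leaves
    n = len(leaves)
    lo, hi = hue_arc
    leaf_hue = {
        leaf: lo + (hi - lo) * (i / (n - 1) if n > 1 else 0.0)
        for i, leaf in enumerate(leaves)
    }
    depth = [0] * tree.n_nodes
    for v in range(1, tree.n_nodes):
        depth[v] = depth[tree.parent[v]] + 1
    max_depth = max(depth) or 1
    v_lo, v_hi = value_range
    hsv = {}
    hues: dict[int, float] = {}
    for node in tree.postorder:
        if tree.is_leaf(node):
            hues[node] = leaf_hue[node]
        else:
            child_h = [hues[c] for c in tree.children[node]]
            hues[node] = sum(child_h) / len(child_h)
    for node in range(tree.n_nodes):
        val = v_lo + (v_hi - v_lo) * depth[node] / max_depth
        if tree.is_leaf(node):
            val = v_hi  # leaves brightest regardless of imbalance
        hsv[node] = (hues[node] % 1.0, saturation, val)
    return ColorAssignment(hsv=hsv)


def _svg_root(width: float, height: float) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": f"{width:g}",
            "height": f"{height:g}",
            "viewBox": f"0 0 {width:g} {height:g}",
        },
    )


def _rect(parent, x, y, w, h, fill, **attrs):
    a = {"x": f"{x:g}", "y": f"{y:g}", "width": f"{w:g}", "height": f"{h:g}",
         "fill": fill}
    a.update({k.replace("_", "-"): str(v) for k, v in attrs.items()})
    return ET.SubElement(parent, "rect", a)


def _text(parent, x, y, content, size=9, **attrs):
    a = {"x": f"{x:g}", "y": f"{y:g}", "font-size": str(size),
         "font-family": "sans-serif"}
    a.update({k.replace("_", "-"): str(v) for k, v in attrs.items()})
    el = ET.SubElement(parent, "text", a)
    el.text = str(content)
    return el


def _line(parent, x1, y1, x2, y2, stroke="#444", width=1.0):
    return ET.SubElement(parent, "line", {
        "x1": f"{x1:g}", "y1": f"{y1:g}", "x2": f"{x2:g}", "y2": f"{y2:g}",
        "stroke": stroke, "stroke-width": f"{width:g}",
    })


def _rgb_to_hex(rgb: str) -> str:
    r, g, b = (int(x) for x in rgb.split(","))
    return f"#{r:02x}{g:02x}{b:02x}"


def select_display_patterns(
    patterns: Sequence[Pattern], max_patterns: int = DEFAULT_MAX_PATTERNS
) -> list[Pattern]:
    """The first ``max_patterns`` patterns ordered by branch length score."""
    return rank_and_filter(list(patterns), by="bls", top_n=max_patterns)


def render_homology_figure(
    alignment: Alignment,
    groups: Mapping[Hashable, HomologGroup],
    patterns: Sequence[Pattern],
    colors: ColorAssignment,
    tree: SpeciesTree,
    anchor: GenomeAnchor | None = None,
    max_patterns: int = DEFAULT_MAX_PATTERNS,
    per_species: bool = False,
) -> str:
    """Render the annotated alignment as SVG.

    Homology-based view (default): one glyph per homolog group, labelled
    with the combined TF name, strand (when uniform), middle alignment
    coordinate and bp length (when uniform); species-coloured overlays
    under each glyph, drawn thick where one of the displayed patterns is
    supported by that species and thin for plain extant predictions.
    The tree panel shows split leaf boxes (left: colours of patterns
    gained at the node; right: species gradient colour) with a "+" on
    gain nodes.  ``per_species=True`` gives the alignment-based variant:
    one glyph row per species, overlays reduced to the thick
    pattern-colour segments.  At most ``max_patterns`` patterns (by BLS)
    are shown.
    """
    shown = select_display_patterns(patterns, max_patterns)
    palette = [_rgb_to_hex(c) for c in pattern_palette(len(shown))]
    pat_color = {p.pattern_id: palette[i] for i, p in enumerate(shown)}
    # characters -> patterns supporting them (for overlays)
    char_patterns: dict[Hashable, list[Pattern]] = {}
    for p in shown:
        for c in p.members:
            char_patterns.setdefault(c, []).append(p)
    gains_at_node: dict[int, list[Pattern]] = {}
    for p in shown:
        gains_at_node.setdefault(p.origin_node, []).append(p)

    row_h = 18
    tree_w = 150
    scale = max(4.0, 700 / max(alignment.alignment_length, 1))
    aln_w = alignment.alignment_length * scale
    species_list = alignment.species
    glyph_rows = species_list if per_species else ["all"]
    header_h = 40
    glyph_area_h = len(glyph_rows) * 3 * row_h
    tree_area_h = len(species_list) * row_h
    legend_h = (len(species_list) + len(shown)) * 12 + 30
    width = tree_w + aln_w + 40
    height = header_h + glyph_area_h + tree_area_h + legend_h + 40

    svg = _svg_root(width, height)
    x0 = tree_w + 20

    # --- coordinate ruler ---
    ruler = ET.SubElement(svg, "g", {"class": "ruler"})
    _line(ruler, x0, header_h - 14, x0 + aln_w, header_h - 14)
    step = max(10, alignment.alignment_length // 8 or 1)
    for col in range(1, alignment.alignment_length + 1, step):
        x = x0 + (col - 1) * scale
        _line(ruler, x, header_h - 18, x, header_h - 10)
        _text(ruler, x, header_h - 20, col, size=7)
        if anchor is not None:
            pos = None
            from .alignmap import aln_to_seq
            ref = alignment.reference_species
            pos = aln_to_seq(alignment, ref, col)
            if pos is not None:
                _, gstart, _ = anchor_to_genome(pos, 1, anchor)
                _text(ruler, x, header_h - 29, f"{anchor.chrom}:{gstart + 1}",
                      size=6, fill="#777")

    # --- glyph layer ---
    glyphs = ET.SubElement(svg, "g", {"class": "glyphs"})
    for row_i, row_key in enumerate(glyph_rows):
        y_base = header_h + row_i * 3 * row_h
        for cid in sorted(groups, key=lambda c: (groups[c].footprint_s, str(c))):
            grp = groups[cid]
            if per_species and row_key not in grp.species:
                continue
            gx = x0 + (grp.footprint_s - 1) * scale
            gw = max((grp.footprint_e - grp.footprint_s + 1) * scale, 2)
            strands = {c.strand for c in grp.clusters.values()}
            lengths = {c.l for c in grp.clusters.values()}
            label = grp.name
            if len(strands) == 1 and (st := strands.pop()) in "+-":
                label += f" {st}"
            label += f" @{(grp.footprint_s + grp.footprint_e) // 2}"
            if len(lengths) == 1:
                label += f" {lengths.pop()}bp"
            mss = max(c.mss for c in grp.clusters.values())
            shade = 0.35 + 0.65 * mss  # glyph intensity encodes mss
            grey = round(235 - 180 * shade)
            _rect(glyphs, gx, y_base + row_h, gw, row_h * 0.8,
                  f"rgb({grey},{grey},{grey})", stroke="#333", stroke_width=0.5,
                  **{"class": "glyph"})
            _text(glyphs, gx, y_base + row_h - 3, label, size=8)
            # species overlays
            overlay_species = [row_key] if per_species else sorted(grp.species)
            seg_w = gw / max(len(overlay_species), 1)
            for k, sp in enumerate(overlay_species):
                leaf_id = tree.leaf_ids.get(sp)
                if leaf_id is None:
                    continue
                supported = any(
                    sp in p.supporting_species for p in char_patterns.get(cid, [])
                )
                if per_species and not supported:
                    continue
                thick = 6 if supported else 2.5
                fill = colors.hex(leaf_id)
                if supported:
                    pats = [p for p in char_patterns.get(cid, [])
                            if sp in p.supporting_species]
                    fill = pat_color[pats[0].pattern_id]
                _rect(glyphs, gx + k * seg_w, y_base + row_h * 1.9, seg_w,
                      thick, fill, **{"class": "overlay"})

    # --- tree panel: split leaf boxes ---
    panel = ET.SubElement(svg, "g", {"class": "tree-panel"})
    y_tree = header_h + glyph_area_h + 10
    for i, sp in enumerate(species_list):
        leaf_id = tree.leaf_ids.get(sp)
        y = y_tree + i * row_h
        if leaf_id is None:
            _text(panel, 30, y + 10, sp, size=8)
            continue
        gained = gains_at_node.get(leaf_id, [])
        half = 7
        if gained:
            seg = 2 * half / len(gained)
            for k, p in enumerate(gained):
                _rect(panel, 10, y + k * seg, half, seg, pat_color[p.pattern_id])
        else:
            _rect(panel, 10, y, half, 2 * half, "#dddddd")
        _rect(panel, 10 + half, y, half, 2 * half, colors.hex(leaf_id))
        if gained:
            _text(panel, 10 + 2 * half + 2, y + 11, "+", size=10, fill="#c00")
        supported = [p for p in shown if sp in p.supporting_species]
        for k, p in enumerate(supported):
            _rect(panel, 34 + k * 9, y + 3, 7, 8, pat_color[p.pattern_id])
        _text(panel, 36 + len(supported) * 9 + 4, y + 11, sp, size=8)
    # internal gain nodes (ancestral origins) listed under the leaves
    y_anc = y_tree + len(species_list) * row_h + 4
    anc = [(n, ps) for n, ps in sorted(gains_at_node.items())
           if not tree.is_leaf(n)]
    for j, (node, ps) in enumerate(anc):
        y = y_anc + j * 12
        for k, p in enumerate(ps):
            _rect(panel, 10 + k * 9, y, 7, 8, pat_color[p.pattern_id])
        _text(panel, 10 + len(ps) * 9 + 4, y + 8,
              f"+ gained at {tree.names[node]}", size=7)

    # --- legend ---
    legend = ET.SubElement(svg, "g", {"class": "legend"})
    y_leg = y_anc + len(anc) * 12 + 16
    _text(legend, 10, y_leg, "Species", size=9, font_weight="bold")
    for i, sp in enumerate(species_list):
        y = y_leg + 8 + i * 12
        leaf_id = tree.leaf_ids.get(sp)
        fill = colors.hex(leaf_id) if leaf_id is not None else "#999"
        _rect(legend, 10, y, 9, 9, fill, **{"class": "legend-species"})
        _text(legend, 24, y + 8, sp, size=8)
    xp = 160
    _text(legend, xp, y_leg, "Patterns", size=9, font_weight="bold")
    for i, p in enumerate(shown):
        y = y_leg + 8 + i * 12
        _rect(legend, xp, y, 9, 9, pat_color[p.pattern_id],
              **{"class": "legend-pattern"})
        _text(legend, xp + 14, y + 8,
              f"pattern {p.pattern_id} (BLS={p.bls:.3g}, "
              f"origin {tree.names[p.origin_node]})", size=8)

    return ET.tostring(svg, encoding="unicode")


def _tree_layout(tree: SpeciesTree) -> dict[int, tuple[float, float]]:
    """Leaves evenly spaced in y, x from cumulative depth."""
    depth = [0.0] * tree.n_nodes
    for v in range(1, tree.n_nodes):
        depth[v] = depth[tree.parent[v]] + 1.0
    max_d = max(depth) or 1.0
    pos: dict[int, tuple[float, float]] = {}
    leaf_y = {leaf: i for i, leaf in enumerate(tree.leaves)}
    for v in tree.postorder:
        if tree.is_leaf(v):
            pos[v] = (depth[v] / max_d, float(leaf_y[v]))
        else:
            ys = [pos[c][1] for c in tree.children[v]]
            pos[v] = (depth[v] / max_d, sum(ys) / len(ys))
    return pos


def render_tree_logo(
    pattern: Pattern,
    tree: SpeciesTree,
    colors: ColorAssignment,
    pattern_color: str = "#cc2288",
    width: float = 180,
    height: float | None = None,
) -> str:
    """Miniature species tree for one pattern.

    The ancestral origin node(s) and every leaf carrying the full
    pattern are filled with the pattern colour; all other nodes stay
    neutral.  The more leaves highlighted — and the more distant they
    are — the higher the pattern's branch length score.
    """
    if not 0 <= pattern.origin_node < tree.n_nodes:
        raise TreeError(f"unknown origin node {pattern.origin_node}")
    for sp in pattern.supporting_species:
        if sp not in tree.leaf_ids:
            raise TreeError(f"unknown supporting species {sp!r}")
    n_leaves = len(tree.leaves)
    height = height or (n_leaves * 16 + 20)
    pos = _tree_layout(tree)
    pad, x_span = 10, width - 70
    y_step = (height - 2 * pad) / max(n_leaves - 1, 1)

    def xy(v: int) -> tuple[float, float]:
        fx, fy = pos[v]
        return pad + fx * x_span, pad + fy * y_step

    svg = _svg_root(width, height)
    edges = ET.SubElement(svg, "g", {"class": "edges"})
    for v in range(1, tree.n_nodes):
        x1, y1 = xy(tree.parent[v])
        x2, y2 = xy(v)
        _line(edges, x1, y1, x1, y2)
        _line(edges, x1, y2, x2, y2)
    nodes = ET.SubElement(svg, "g", {"class": "nodes"})
    highlight = {pattern.origin_node} | {
        tree.leaf_ids[sp] for sp in pattern.supporting_species
    }
    for v in range(tree.n_nodes):
        x, y = xy(v)
        fill = pattern_color if v in highlight else "#bbbbbb"
        cls = "node-highlight" if v in highlight else "node"
        ET.SubElement(nodes, "circle", {
            "cx": f"{x:g}", "cy": f"{y:g}", "r": "4", "fill": fill,
            "class": cls,
        })
        if tree.is_leaf(v):
            _text(nodes, x + 7, y + 3, tree.names[v], size=8)
    return ET.tostring(svg, encoding="unicode")


def render_pattern_logo(
    pattern: Pattern,
    alignment: Alignment,
    groups: Mapping[Hashable, HomologGroup],
    colors: ColorAssignment,
    tree: SpeciesTree,
    anchor: GenomeAnchor | None = None,
) -> str:
    """Miniature alignment figure restricted to one pattern's members."""
    sub = {c: groups[c] for c in pattern.members}
    return render_homology_figure(
        alignment, sub, [pattern], colors, tree, anchor=anchor, max_patterns=1
    )
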