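"""Annotation-driven SVG tree figures.

Numeric annotation columns can drive visual attributes — branch width,
branch color, label text height — through linear format mappings, the
package's take on automatically formatting a tree from its data.  All
distances are specified in millimeters or DTP points (1 pt = 1/72 inch =
25.4/72 mm) and the SVG document is emitted with true-mm dimensions, so a
figure prints at exactly the designed size.

Layout rules: terminals occupy consecutive vertical slots in child order;
an internal node sits at the mean of its children's slots; horizontal
position is cumulative branch length (phylogram/chronogram) or uniform
unit depth (cladogram).  A chronogram aligns terminal tips at the right
edge and draws its scale bar right-to-left in time units.  Labels never
collide with branches because each above/below label slot reserves its own
text-height band per branch (simple banding, not a general collision-free
placement engine).

Output is deterministic: the same tree, style and mappings yield
byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

from .model import NUMERIC, Node, Tree, TreeError
from .treeio import format_number

__all__ = [
    "MM_PER_PT",
    "FormatMapping",
    "LabelSpec",
    "RenderStyle",
    "Layout",
    "layout",
    "apply_format_mappings",
    "render",
]

MM_PER_PT = 25.4 / 72.0  # exact DTP-point conversion

_ATTRIBUTES = ("branch-width", "branch-color", "label-text-height")


@dataclass
class FormatMapping:
    """Linear map from a numeric column to a visual attribute.

    ``f(v) = out_min + (v - v_min) * (out_max - out_min) / (v_max - v_min)``
    with values outside the domain clamped; a degenerate domain
    (``v_min == v_max``) maps everything to ``out_min``.  The domain is the
    column's min/max when ``domain`` is ``None``.  Colors interpolate per
    RGB channel independently, rounded half-up to integers.  A branch with
    a missing value keeps the document default for the attribute.
    """

    column_id: str
    attribute: str
    out_min: float = 0.3
    out_max: float = 3.0
    color_min: Tuple[int, int, int] = (0, 0, 0)
    color_max: Tuple[int, int, int] = (255, 0, 0)
    domain: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.attribute not in _ATTRIBUTES:
            raise ValueError(f"unknown attribute {self.attribute!r}; "
                             f"expected one of {_ATTRIBUTES}")
        if self.out_min > self.out_max:
            raise ValueError("out_min must not exceed out_max")


@dataclass
class LabelSpec:
    """One label column: where it sits and how its numbers are printed.

    ``wrapper`` brackets the text — the conventional way to distinguish
    conflicting support values, e.g. ``("(", ")")``.
    """

    column_id: str
    position: str = "above"  # above | below
    decimals: Optional[int] = None  # None: minimal decimal representation
    wrapper: Optional[Tuple[str, str]] = None

    def __post_init__(self):
        if self.position not in ("above", "below"):
            raise ValueError("label position must be 'above' or 'below'")

    def format(self, value) -> str:
        if isinstance(value, float) and self.decimals is not None:
            text = f"{value:.{self.decimals}f}"
        elif isinstance(value, float):
            text = format_number(value)
        else:
            text = str(value)
        if self.wrapper:
            text = self.wrapper[0] + text + self.wrapper[1]
        return text


@dataclass
class RenderStyle:
    """Document-level rendering options.

    All distance fields are in ``units`` (``"mm"`` or ``"pt"``);
    ``scale_factor`` proportionally rescales every coordinate and size.
    """

    mode: str = "cladogram"  # cladogram | phylogram | chronogram
    units: str = "mm"
    line_width: float = 0.3
    text_height: float = 3.0
    tip_spacing: float = 5.0
    depth_step: float = 10.0     # per unit depth (cladogram)
    length_scale: float = 30.0   # per branch-length unit (phylogram)
    root_stem: float = 2.0
    margin: float = 5.0
    label_columns: list = field(default_factory=list)  # [LabelSpec, ...]
    scale_bar: bool = False
    tick_interval: float = 0.1   # in branch-length units
    scale_bar_text: str = ""
    scale_factor: float = 1.0

    def __post_init__(self):
        if self.mode not in ("cladogram", "phylogram", "chronogram"):
            raise ValueError(f"unknown view mode {self.mode!r}")
        if self.units not in ("mm", "pt"):
            raise ValueError("units must be 'mm' or 'pt'")

    def in_mm(self) -> "RenderStyle":
        """A copy with every distance converted to millimeters."""
        if self.units == "mm":
            return self
        f = MM_PER_PT
        return replace(self, units="mm", line_width=self.line_width * f,
                       text_height=self.text_height * f,
                       tip_spacing=self.tip_spacing * f,
                       depth_step=self.depth_step * f,
                       length_scale=self.length_scale * f,
                       root_stem=self.root_stem * f, margin=self.margin * f)


@dataclass
class Layout:
    """Abstract node positions: ``y`` in terminal slots, ``x`` in depth
    units (cladogram) or branch-length units (phylogram/chronogram)."""

    x: dict  # id(node) -> float
    y: dict  # id(node) -> float
    max_x: float
    n_tips: int

    def position(self, node: Node):
        return self.x[id(node)], self.y[id(node)]


def layout(tree: Tree, style: RenderStyle) -> Layout:
    """Compute abstract positions for every node under the style's mode."""
    xs: dict = {}
    ys: dict = {}
    slot = 0

    def place(node: Node, depth_x: float):
        nonlocal slot
        if style.mode == "cladogram":
            x = depth_x + 1.0 if node.parent is not None else 0.0
        else:
            if node.parent is not None and node.branch.length is None:
                raise TreeError(
                    f"{style.mode} requires branch lengths; missing above "
                    f"{sorted(tree.leafset(node))}")
            x = depth_x + (node.branch.length or 0.0)
        xs[id(node)] = x
        if node.is_terminal:
            ys[id(node)] = float(slot)
            slot += 1
        else:
            for c in node.children:
                place(c, x)
            ys[id(node)] = (ys[id(node.children[0])]
                            + ys[id(node.children[-1])]) / 2.0

    place(tree.root, 0.0)
    max_x = max(xs.values())
    if style.mode == "chronogram":
        for t in tree.root.terminals():
            xs[id(t)] = max_x
    return Layout(x=xs, y=ys, max_x=max_x, n_tips=slot)


def apply_format_mappings(tree: Tree, mappings: Sequence[FormatMapping]) -> dict:
    """Resolve mapped visual attributes per branch.

    Returns ``{id(node): {attribute: value}}``; widths/heights are floats in
    mm, colors are ``#rrggbb`` strings.  Branches with missing values are
    simply absent for that attribute."""
    resolved: dict = {}
    for m in mappings:
        col = tree.column(m.column_id)
        if col.value_type != NUMERIC:
            raise TreeError(f"mapping column {m.column_id!r} is not numeric")
        values = [(nd, nd.branch.annotations.get(m.column_id))
                  for nd in tree.nodes()]
        present = [v for _, v in values if v is not None]
        if m.domain is not None:
            vmin, vmax = m.domain
        else:
            if not present:
                raise TreeError(
                    f"column {m.column_id!r} has no values; cannot infer "
                    "an automatic domain")
            vmin, vmax = min(present), max(present)
        span = vmax - vmin
        for nd, v in values:
            if v is None:
                continue
            if span == 0:
                t = 0.0
            else:
                t = (min(max(v, vmin), vmax) - vmin) / span
            attrs = resolved.setdefault(id(nd), {})
            if m.attribute == "branch-color":
                rgb = tuple(
                    int((lo + t * (hi - lo)) + 0.5)
                    for lo, hi in zip(m.color_min, m.color_max))
                attrs[m.attribute] = "#%02x%02x%02x" % rgb
            else:
                attrs[m.attribute] = m.out_min + t * (m.out_max - m.out_min)
    return resolved


def _fmt(v: float) -> str:
    s = f"{v:.4f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def _esc(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def render(tree: Tree, style: Optional[RenderStyle] = None,
           mappings: Sequence[FormatMapping] = ()) -> str:
    """Render the tree to an SVG 1.1 document string (true-mm dimensions)."""
    style = (style or RenderStyle()).in_mm()
    lay = layout(tree, style)
    attrs = apply_format_mappings(tree, mappings)
    s = style.scale_factor

    xscale = style.depth_step if style.mode == "cladogram" else style.length_scale

    def X(node: Node) -> float:
        return (style.margin + style.root_stem + lay.x[id(node)] * xscale) * s

    def Y(node: Node) -> float:
        return (style.margin + lay.y[id(node)] * style.tip_spacing) * s

    tip_names = [t.name for t in tree.root.terminals()]
    label_space = (max(len(n) for n in tip_names) * style.text_height * 0.62
                   + 2.0)
    width = (style.margin * 2 + style.root_stem + lay.max_x * xscale
             + label_space) * s
    bar_space = (style.text_height * 3.0 if style.scale_bar
                 and style.mode != "cladogram" else 0.0)
    height = (style.margin * 2 + max(lay.n_tips - 1, 0) * style.tip_spacing
              + style.text_height + bar_space) * s

    out = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}mm" height="{_fmt(height)}mm" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">')

    # branches: one rectilinear path per node, root stem included
    for nd in tree.nodes():
        x1, y = X(nd), Y(nd)
        x0 = X(nd.parent) if nd.parent is not None else style.margin * s
        a = attrs.get(id(nd), {})
        w = a.get("branch-width", style.line_width) * s
        color = a.get("branch-color", "#000000")
        d = f"M {_fmt(x0)} {_fmt(y)} L {_fmt(x1)} {_fmt(y)}"
        if nd.children:
            cy0, cy1 = Y(nd.children[0]), Y(nd.children[-1])
            d += f" M {_fmt(x1)} {_fmt(cy0)} L {_fmt(x1)} {_fmt(cy1)}"
        out.append(f'<path class="branch" d="{d}" fill="none" '
                   f'stroke="{color}" stroke-width="{_fmt(w)}"/>')

    # terminal labels
    th = style.text_height
    for nd in tree.root.terminals():
        out.append(
            f'<text class="tip-label" x="{_fmt(X(nd) + 1.5 * s)}" '
            f'y="{_fmt(Y(nd) + 0.35 * th * s)}" '
            f'font-size="{_fmt(th * s)}">{_esc(nd.name)}</text>')

    # branch labels with per-branch above/below banding
    for nd in tree.nodes():
        if nd.parent is None:
            continue
        a = attrs.get(id(nd), {})
        lth = a.get("label-text-height", th)
        mid_x = (X(nd.parent) + X(nd)) / 2.0
        band = {"above": 0, "below": 0}
        for spec in style.label_columns:
            if spec.column_id not in tree.columns:
                continue
            v = nd.branch.annotations.get(spec.column_id)
            if v is None:
                continue
            band[spec.position] += 1
            k = band[spec.position]
            if spec.position == "above":
                ly = Y(nd) - ((k - 1) * lth + 0.3 * lth) * s
            else:
                ly = Y(nd) + (k * lth + 0.3 * lth) * s
            out.append(
                f'<text class="branch-label" x="{_fmt(mid_x)}" '
                f'y="{_fmt(ly)}" text-anchor="middle" '
                f'font-size="{_fmt(lth * s)}">{_esc(spec.format(v))}</text>')

    # scale bar (phylogram: left-to-right; chronogram: right edge leftward)
    if style.scale_bar and style.mode != "cladogram" and lay.max_x > 0:
        bar_y = height - style.margin * s - th * s
        bar_len = lay.max_x * xscale * s
        if style.mode == "chronogram":
            bx1 = (style.margin + style.root_stem + lay.max_x * xscale) * s
            bx0 = bx1 - bar_len
        else:
            bx0 = (style.margin + style.root_stem) * s
            bx1 = bx0 + bar_len
        out.append(f'<path class="scale-bar" d="M {_fmt(bx0)} {_fmt(bar_y)} '
                   f'L {_fmt(bx1)} {_fmt(bar_y)}" stroke="#000000" '
                   f'stroke-width="{_fmt(style.line_width * s)}"/>')
        tick = style.tick_interval
        if tick > 0:
            n_ticks = int(lay.max_x / tick + 1e-9) + 1
            for i in range(n_ticks):
                u = i * tick
                if style.mode == "chronogram":
                    tx = bx1 - u * xscale * s
                else:
                    tx = bx0 + u * xscale * s
                out.append(
                    f'<path class="scale-tick" d="M {_fmt(tx)} {_fmt(bar_y)} '
                    f'L {_fmt(tx)} {_fmt(bar_y + th * 0.4 * s)}" '
                    f'stroke="#000000" '
                    f'stroke-width="{_fmt(style.line_width * s)}"/>')
                out.append(
                    f'<text class="scale-label" x="{_fmt(tx)}" '
                    f'y="{_fmt(bar_y + th * 1.5 * s)}" text-anchor="middle" '
                    f'font-size="{_fmt(th * 0.8 * s)}">'
                    f'{_esc(format_number(float(u)))}</text>')
        if style.scale_bar_text:
            out.append(
                f'<text class="scale-units" x="{_fmt((bx0 + bx1) / 2)}" '
                f'y="{_fmt(bar_y + th * 2.6 * s)}" text-anchor="middle" '
                f'font-size="{_fmt(th * 0.8 * s)}">'
                f'{_esc(style.scale_bar_text)}</text>')

    out.append("</svg>")
    return "\n".join(out) + "\n"
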