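"""Deterministic three-layer figure geometry and rendering.

The figure stacks an association scatter (-log10 p against position), a gene
track (arrowed gene spans on a regional plot, the focal transcript's
exon/CDS/UTR boxes on a genic plot) and a 45-degree rotated triangle LD
heatmap, joined by linking lines.  The triangle uses equal index spacing
(Haploview convention); linking lines absorb the genomic-to-index
distortion.  All geometry is computed into a :class:`FigureSpec` with no
randomness, then rendered with matplotlib.
"""

from __future__ import annotations

import bisect
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .ld_core import LDMatrix, MatchResult
from .regions import PlotScope, neglog10

__all__ = [
    "ColorScale",
    "HighlightRule",
    "HighlightSpec",
    "LinkSpec",
    "FigureSpec",
    "triangle_coords",
    "ld_color",
    "build_figure_spec",
    "linking_lines",
    "render",
    "render_regional",
    "render_genic",
    "read_highlight",
    "read_marker_list",
]

# R-style gray ramp for the five LD bins (0,.2], (.2,.4], (.4,.6], (.6,.8], (.8,1]
DEFAULT_COLORS = ("#CFCFCF", "#9C9C9C", "#696969", "#1C1C1C", "#030303")
DEFAULT_BOUNDS = (0.2, 0.4, 0.6, 0.8, 1.0)

_R_GRAY = re.compile(r"^(?:gray|grey)(\d{1,3})$")


def normalize_color(color: str) -> str:
    """Accept R-style grayNN/greyNN names alongside matplotlib colors."""
    m = _R_GRAY.match(str(color).strip().lower())
    if m and 0 <= int(m.group(1)) <= 100:
        v = round(int(m.group(1)) * 255 / 100)
        return f"#{v:02X}{v:02X}{v:02X}"
    return color


@dataclass(frozen=True)
class ColorScale:
    """Five-bin LD color scale; bin k covers (bounds[k-1], bounds[k]], 0 -> bin 0."""

    bounds: tuple = DEFAULT_BOUNDS
    colors: tuple = DEFAULT_COLORS
    na_color: str = "#FFFFFF"

    def __post_init__(self):
        if len(self.bounds) != 5 or len(self.colors) != 5:
            raise ValueError("a ColorScale has exactly 5 bins")
        if list(self.bounds) != sorted(set(self.bounds)) or self.bounds[-1] != 1.0:
            raise ValueError("bounds must be strictly increasing and end at 1.0")
        object.__setattr__(self, "colors",
                           tuple(normalize_color(c) for c in self.colors))
        object.__setattr__(self, "na_color", normalize_color(self.na_color))

    def bin_index(self, value: float) -> int:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"LD value must be in [0, 1], got {value}")
        return min(bisect.bisect_left(self.bounds, value), 4)


def ld_color(value: float, scale: ColorScale) -> str:
    """Color for an LD value: first bin whose upper bound >= value; NaN -> na_color."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return scale.na_color
    return scale.colors[scale.bin_index(float(value))]


@dataclass(frozen=True)
class HighlightRule:
    """Style override for one marker, selected by name or by (chrom, pos)."""

    marker: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    shape: str = "o"
    color: str = "#D62728"
    size: float = 1.0

    def matches(self, name: str, chrom: str, pos: int) -> bool:
        if self.marker is not None:
            return self.marker == name
        return str(self.chrom) == str(chrom) and int(self.pos) == int(pos)


@dataclass
class HighlightSpec:
    rules: list = field(default_factory=list)

    def resolve(self, scope: PlotScope):
        """Map marker name -> rule; rules matching nothing are reported."""
        out, unmatched = {}, []
        rows = list(scope.assoc.itertuples(index=False))
        for rule in self.rules:
            hits = [r.marker for r in rows
                    if rule.matches(r.marker, r.chrom, r.pos)]
            if not hits:
                unmatched.append(rule)
                continue
            for name in hits:
                out[name] = rule
        return out, unmatched


@dataclass
class LinkSpec:
    """Marker selections for the two linking-line segments.

    ``link2gene`` selects scatter-to-gene-track segments, ``link2ld``
    gene-track-to-LD-matrix segments; None means "use the significant set".
    """

    link2gene: Optional[list] = None
    link2ld: Optional[list] = None


def triangle_coords(i: int, j: int, n: int, y0: float = 0.0) -> tuple:
    """Diamond cell for pair (i, j) of an n-marker triangle, in index units.

    The cell is centred at x = (i + j)/2, y = y0 - (j - i)/2 with
    half-diagonal 1/2; cells tile the half-matrix triangle without overlap.
    Returns the 4 vertices (left, top, right, bottom).
    """
    if not 0 <= i < j < n:
        raise ValueError(f"need 0 <= i < j < n, got i={i}, j={j}, n={n}")
    cx = (i + j) / 2.0
    cy = y0 - (j - i) / 2.0
    return ((cx - 0.5, cy), (cx, cy + 0.5), (cx + 0.5, cy), (cx, cy - 0.5))


@dataclass(frozen=True)
class ScatterPoint:
    marker: str
    x: float
    y: float
    color: str
    size: float
    shape: str
    is_lead: bool = False


@dataclass(frozen=True)
class GeneGlyph:
    gene_id: str
    start: int
    end: int
    strand: str
    y: float


@dataclass(frozen=True)
class FeatureBox:
    kind: str
    start: int
    end: int
    y0: float
    y1: float


@dataclass(frozen=True)
class LDMarkerPos:
    """One LD-panel marker: its triangle index and both x coordinates."""

    name: str
    index: int
    genomic_x: float
    ld_x: float


@dataclass(frozen=True)
class Diamond:
    i: int
    j: int
    value: float
    color: str
    vertices: tuple  # data coordinates


@dataclass
class FigureSpec:
    """Fully resolved figure geometry; identical inputs give identical specs."""

    chrom: str
    left: int
    right: int
    mode: str                      # "regional" | "genic"
    layers: dict                   # layer name -> (ylo, yhi)
    scatter: list
    threshold: Optional[float]
    gene_glyphs: list
    feature_boxes: list
    intron_segments: list
    tx_strand: Optional[str]
    ld_markers: list
    diamonds: list
    polylines: list                # list of tuples of (x, y)
    labels: list                   # list of (text, x, y)
    measure: str = "r2"


def _assign_lanes(genes, span: int):
    """Greedy lane assignment by start position to avoid arrow overplotting."""
    gap = max(1, span // 100)
    lanes_end = []
    assignment = []
    for g in sorted(genes, key=lambda g: (g.start, g.end, g.gene_id)):
        lane = None
        for k, last in enumerate(lanes_end):
            if g.start > last + gap:
                lane = k
                break
        if lane is None:
            lane = len(lanes_end)
            lanes_end.append(g.end)
        else:
            lanes_end[lane] = g.end
        assignment.append((g, lane))
    return assignment, max(1, len(lanes_end))


def _repel_labels(labels, span: float, ymax: float, iterations: int = 30):
    """Deterministic vertical label repulsion with a fixed iteration count."""
    labels = sorted(labels, key=lambda t: (t[1], t[0]))
    out = [list(t) for t in labels]
    min_dx = 0.03 * span
    min_dy = 0.05 * ymax
    for _ in range(iterations):
        moved = False
        for a in range(len(out)):
            for b in range(a + 1, len(out)):
                if (abs(out[a][1] - out[b][1]) < min_dx
                        and abs(out[a][2] - out[b][2]) < min_dy):
                    out[b][2] += 0.5 * min_dy
                    moved = True
        if not moved:
            break
    return [tuple(t) for t in out]


def _ld_index_map(scope: PlotScope, ld: Optional[LDMatrix],
                  matched: Optional[MatchResult]):
    """Triangle index for each in-scope association marker (None if absent)."""
    if ld is None or ld.n_markers == 0:
        return {row.marker: None for row in scope.assoc.itertuples(index=False)}
    if matched is not None:
        return dict(matched.mapping)
    lookup = {(str(m.chrom), m.pos): k for k, m in enumerate(ld.markers)}
    return {
        row.marker: lookup.get((str(row.chrom), int(row.pos)))
        for row in scope.assoc.itertuples(index=False)
    }


def build_figure_spec(scope: PlotScope, ld: Optional[LDMatrix] = None,
                      lead_ld: Optional[Sequence] = None, *,
                      mode: str = "regional",
                      scale: Optional[ColorScale] = None,
                      highlight: Optional[HighlightSpec] = None,
                      links: Optional[LinkSpec] = None,
                      matched: Optional[MatchResult] = None,
                      leadsnp: bool = True,
                      triangle: bool = True,
                      leadsnp_size: float = 1.0,
                      point_size: float = 25.0) -> FigureSpec:
    """Compute the full three-layer geometry for one figure.

    ``lead_ld`` is the lead-SNP LD vector (list of LDResult) used to color
    scatter points when ``leadsnp`` is true; ``matched`` carries the
    cross-panel marker matching when the LD genotypes differ from the
    association genotypes.  The result is deterministic in its inputs.
    """
    if mode not in {"regional", "genic"}:
        raise ValueError(f"mode must be 'regional' or 'genic', got {mode!r}")
    scale = scale or ColorScale()
    region = scope.region
    left, right = region.left, region.right
    span = right - left
    df = scope.assoc.sort_values(["pos", "marker"], kind="mergesort")

    logp = df["p"].map(neglog10).to_numpy()
    thr = scope.threshold
    ymax = max(float(logp.max()), thr or 0.0, 1.0) * 1.05

    layers = {"scatter": (0.0, ymax),
              "gene": (-0.18 * ymax, -0.04 * ymax)}

    use_triangle = triangle and ld is not None and ld.n_markers >= 2
    ld_markers, diamonds = [], []
    if use_triangle:
        n = ld.n_markers
        hunit = span / n
        vunit = 1.6 * ymax / n
        ld_top = -0.24 * ymax
        depth = ((n - 1) / 2 + 0.5) * vunit
        layers["ld"] = (ld_top - depth, ld_top)
        for k, m in enumerate(ld.markers):
            ld_markers.append(LDMarkerPos(
                m.name, k, float(m.pos), left + (k + 0.5) * hunit
            ))
        vals = ld.values()
        for pi, pj, v in zip(ld.pair_i, ld.pair_j, vals):
            verts_idx = triangle_coords(int(pi), int(pj), n)
            verts = tuple(
                (left + (u + 0.5) * hunit, ld_top + w * vunit)
                for u, w in verts_idx
            )
            value = float(v)
            diamonds.append(Diamond(int(pi), int(pj), value,
                                    ld_color(value, scale), verts))

    # lead-SNP r2 per marker, keyed by (chrom, pos)
    lead_r2 = {}
    if lead_ld is not None:
        for res in lead_ld:
            key = (str(res.marker_j.chrom), res.marker_j.pos)
            lead_r2[key] = res.r2 if res.status == "ok" else float("nan")

    hl_map, hl_unmatched = ({}, [])
    if highlight is not None:
        hl_map, hl_unmatched = highlight.resolve(scope)
        for rule in hl_unmatched:
            warnings.warn(f"highlight selector matched no marker in scope: {rule}")

    lead_name = scope.lead.marker if scope.lead is not None else None
    scatter = []
    for row, lp in zip(df.itertuples(index=False), logp):
        is_lead = leadsnp and row.marker == lead_name
        if leadsnp and scope.lead is not None:
            if is_lead:
                color = "#D62728"
            else:
                key = (str(row.chrom), int(row.pos))
                color = ld_color(lead_r2.get(key, float("nan")), scale)
        else:
            color = "#4C72B0"
        size = point_size * (leadsnp_size if is_lead else 1.0)
        shape = "o"
        if row.marker in hl_map:
            rule = hl_map[row.marker]
            color, shape = rule.color, rule.shape
            size = point_size * rule.size
        scatter.append(ScatterPoint(row.marker, float(row.pos), float(lp),
                                    color, float(size), shape, is_lead))

    gene_glyphs, feature_boxes, intron_segments, tx_strand = [], [], [], None
    gylo, gyhi = layers["gene"]
    if mode == "regional":
        assignment, n_lanes = _assign_lanes(scope.genes, span)
        lane_h = (gyhi - gylo) / n_lanes
        for g, lane in assignment:
            y = gyhi - (lane + 0.5) * lane_h
            gene_glyphs.append(GeneGlyph(g.gene_id, g.start, g.end, g.strand, y))
    else:
        tx = scope.focal_transcript
        if tx is None:
            raise ValueError("genic mode needs scope.focal_transcript")
        tx_strand = tx.strand
        mid = 0.5 * (gylo + gyhi)
        h = gyhi - gylo
        heights = {"exon": 0.5 * h, "CDS": 0.7 * h,
                   "five_prime_UTR": 0.3 * h, "three_prime_UTR": 0.3 * h}
        for kind, fs, fe in sorted(tx.features, key=lambda f: (f[1], f[2], f[0])):
            hh = heights.get(kind, 0.5 * h) / 2
            feature_boxes.append(FeatureBox(kind, fs, fe, mid - hh, mid + hh))
        exons = sorted((fs, fe) for kind, fs, fe in tx.features if kind == "exon")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 > e0 + 1:
                intron_segments.append(((e0, mid), (s1, mid)))

    # linking lines
    idx_map = _ld_index_map(scope, ld if use_triangle else None, matched)
    ld_x = {lm.index: lm.ld_x for lm in ld_markers}
    ld_top_y = layers["ld"][1] if use_triangle else None
    significant = scope.significant or set()
    links = links or LinkSpec()
    names_in_scope = set(df["marker"])

    def _resolve_selection(sel):
        if sel is None:
            return set(significant)
        out = set()
        for name in sel:
            if name in names_in_scope:
                out.add(name)
            else:
                warnings.warn(f"link selector {name!r} is not in scope; skipped")
        return out

    seg_a = _resolve_selection(links.link2gene)
    seg_b = _resolve_selection(links.link2ld)

    point_by_name = {p.marker: p for p in scatter}
    polylines = []
    for name in sorted(seg_a | seg_b,
                       key=lambda nm: (point_by_name[nm].x, nm)):
        p = point_by_name[name]
        pts = []
        if name in seg_a:
            pts = [(p.x, p.y), (p.x, gylo)]
        tri_idx = idx_map.get(name)
        if name in seg_b and use_triangle and tri_idx is not None:
            if not pts:
                pts = [(p.x, gylo)]
            pts.append((ld_x[tri_idx], ld_top_y))
        if len(pts) >= 2:
            polylines.append(tuple(pts))

    labels = []
    if leadsnp and scope.lead is not None and lead_name in point_by_name:
        p = point_by_name[lead_name]
        labels.append((lead_name, p.x, p.y + 0.04 * ymax))
    for name in sorted(hl_map):
        if name == lead_name:
            continue
        p = point_by_name[name]
        labels.append((name, p.x, p.y + 0.04 * ymax))
    labels = _repel_labels(labels, span, ymax)

    fig_spec = FigureSpec(
        chrom=str(region.chrom), left=left, right=right, mode=mode,
        layers=layers, scatter=scatter, threshold=thr,
        gene_glyphs=gene_glyphs, feature_boxes=feature_boxes,
        intron_segments=intron_segments, tx_strand=tx_strand,
        ld_markers=ld_markers, diamonds=diamonds, polylines=polylines,
        labels=labels, measure=ld.measure if ld is not None else "r2",
    )
    _check_spec(fig_spec)
    return fig_spec


def _check_spec(spec: FigureSpec) -> None:
    """Invariants: marker order isomorphism and finite geometry."""
    by_x = sorted(spec.ld_markers, key=lambda m: m.genomic_x)
    by_i = sorted(spec.ld_markers, key=lambda m: m.index)
    if [m.index for m in by_x] != [m.index for m in by_i]:
        raise AssertionError("genomic order and triangle index order diverge")
    for pl in spec.polylines:
        for x, y in pl:
            if not (np.isfinite(x) and np.isfinite(y)):
                raise AssertionError("non-finite linking-line geometry")


def linking_lines(scope: PlotScope, spec: FigureSpec) -> list:
    """The linking polylines of a computed figure spec."""
    return list(spec.polylines)


# ---------------------------------------------------------------------------
# rendering

def render(spec: FigureSpec, out: Union[str, Path], dpi: int = 150,
           figsize: tuple = (9.0, 7.0)) -> Path:
    """Draw a FigureSpec to PNG/SVG/PDF (chosen by file extension)."""
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection, PolyCollection

    out = Path(out)
    with plt.rc_context({"svg.hashsalt": "gwaslink"}):
        fig, ax = plt.subplots(figsize=figsize)
        try:
            if spec.diamonds:
                ax.add_collection(PolyCollection(
                    [d.vertices for d in spec.diamonds],
                    facecolors=[d.color for d in spec.diamonds],
                    edgecolors="none", zorder=1,
                ))
            if spec.polylines:
                ax.add_collection(LineCollection(
                    spec.polylines, colors="#888888", linewidths=0.8, zorder=2,
                ))
            if spec.threshold is not None:
                ax.hlines(spec.threshold, spec.left, spec.right,
                          colors="#555555", linestyles="dashed",
                          linewidths=0.9, zorder=2)
            # scatter grouped by shape so each group is one artist
            shapes = sorted({p.shape for p in spec.scatter})
            for shape in shapes:
                pts = [p for p in spec.scatter if p.shape == shape]
                ax.scatter([p.x for p in pts], [p.y for p in pts],
                           s=[p.size for p in pts],
                           c=[p.color for p in pts],
                           marker=shape, edgecolors="#333333",
                           linewidths=0.3, zorder=3)
            for g in spec.gene_glyphs:
                x0, x1 = (g.start, g.end) if g.strand == "+" else (g.end, g.start)
                ax.annotate(
                    "", xy=(x1, g.y), xytext=(x0, g.y),
                    arrowprops=dict(arrowstyle="-|>", color="#2A6F4E",
                                    linewidth=1.4, shrinkA=0, shrinkB=0),
                    zorder=3,
                )
            if spec.intron_segments:
                ax.add_collection(LineCollection(
                    spec.intron_segments, colors="#2A6F4E",
                    linewidths=0.9, zorder=2,
                ))
            fills = {"exon": "#5B9BD5", "CDS": "#2A6F4E",
                     "five_prime_UTR": "#C8A2C8", "three_prime_UTR": "#C8A2C8"}
            for b in spec.feature_boxes:
                ax.add_patch(plt.Rectangle(
                    (b.start, b.y0), b.end - b.start + 1, b.y1 - b.y0,
                    facecolor=fills.get(b.kind, "#999999"),
                    edgecolor="none", zorder={"exon": 3}.get(b.kind, 4),
                ))
            if spec.tx_strand is not None and spec.feature_boxes:
                glo, ghi = spec.layers["gene"]
                ax.text(spec.right, ghi,
                        "5'→3'" if spec.tx_strand == "+" else "3'←5'",
                        ha="right", va="bottom", fontsize=8, color="#2A6F4E")
            for text, x, y in spec.labels:
                ax.annotate(text, (x, y), fontsize=8, ha="center",
                            va="bottom", zorder=5)

            ymax = spec.layers["scatter"][1]
            ylo = min(lo for lo, _ in spec.layers.values())
            ax.set_xlim(spec.left, spec.right)
            ax.set_ylim(ylo - 0.03 * ymax, ymax)
            step = max(1, int(np.ceil(ymax / 6)))
            ax.set_yticks(np.arange(0, ymax + 1e-9, step))
            ax.set_xlabel(f"Position on chromosome {spec.chrom} (bp)")
            ax.set_ylabel(r"$-\log_{10}(P)$")
            for side in ("top", "right"):
                ax.spines[side].set_visible(False)
            fig.tight_layout()
            meta = None
            if out.suffix.lower() == ".svg":
                meta = {"Date": None}
            elif out.suffix.lower() == ".pdf":
                meta = {"CreationDate": None}
            fig.savefig(out, dpi=dpi, metadata=meta)
        finally:
            plt.close(fig)
    return out


def render_regional(scope: PlotScope, ld: Optional[LDMatrix],
                    lead_ld: Optional[Sequence], out: Union[str, Path],
                    **style) -> FigureSpec:
    """Build and render a regional plot; returns the computed FigureSpec."""
    spec = build_figure_spec(scope, ld, lead_ld, mode="regional", **style)
    render(spec, out)
    return spec


def render_genic(scope: PlotScope, ld: Optional[LDMatrix],
                 out: Union[str, Path], lead_ld: Optional[Sequence] = None,
                 triangle_ld: bool = True, leadsnp: bool = True,
                 **style) -> FigureSpec:
    """Build and render a single-gene plot with the transcript structure track."""
    spec = build_figure_spec(scope, ld, lead_ld, mode="genic",
                             triangle=triangle_ld, leadsnp=leadsnp, **style)
    render(spec, out)
    return spec


# ---------------------------------------------------------------------------
# small input files for highlight / link selections

def read_highlight(path: Union[str, Path]) -> HighlightSpec:
    """Read highlight rules from a delimited table.

    Columns: ``marker`` (or ``chrom`` + ``pos``) plus optional ``shape``,
    ``color``, ``size``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    rules = []
    for _, row in df.iterrows():
        get = lambda key, default=None: (
            row[cols[key]] if key in cols else default)
        rules.append(HighlightRule(
            marker=str(get("marker")) if "marker" in cols else None,
            chrom=str(get("chrom")) if "chrom" in cols else None,
            pos=int(get("pos")) if "pos" in cols else None,
            shape=str(get("shape", "o") or "o"),
            color=str(get("color", "#D62728") or "#D62728"),
            size=float(get("size", 1.0) or 1.0),
        ))
    return HighlightSpec(rules=rules)


def read_marker_list(path: Union[str, Path]) -> list:
    """Read a one-marker-per-line selection file (optional 'marker' header)."""
    names = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip().split("\t")[0].split(",")[0].strip()
            if tok and tok.lower() != "marker":
                names.append(tok)
    return names
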