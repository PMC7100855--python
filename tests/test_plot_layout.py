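"""Figure geometry: triangle tiling, color bins, linking lines, determinism."""

import numpy as np
import pytest

import gwaslink as gl
from gwaslink.ld_core import ld_matrix, lead_snp_ld
from gwaslink.plot_layout import (
    ColorScale,
    HighlightRule,
    HighlightSpec,
    LinkSpec,
    build_figure_spec,
    ld_color,
    normalize_color,
    render,
    triangle_coords,
)


class TestTriangleCoords:
    def test_adjacent_pair_topmost_cell(self):
        verts = triangle_coords(0, 1, 10)
        xs = [v[0] for v in verts]
        ys = [v[1] for v in verts]
        assert (sum(xs) / 4, sum(ys) / 4) == (0.5, -0.5)

    def test_apex_cell(self):
        n = 10
        verts = triangle_coords(0, n - 1, n)
        assert sum(v[0] for v in verts) / 4 == (n - 1) / 2
        assert sum(v[1] for v in verts) / 4 == -(n - 1) / 2

    def test_contract_violation(self):
        with pytest.raises(ValueError):
            triangle_coords(3, 3, 5)
        with pytest.raises(ValueError):
            triangle_coords(2, 1, 5)

    def test_n4_tiles_disjointly(self):
        from shapely.geometry import Polygon
        from shapely.ops import unary_union

        polys = [Polygon(triangle_coords(i, j, 4))
                 for i in range(4) for j in range(i + 1, 4)]
        assert len(polys) == 6
        union = unary_union(polys)
        # each diamond has area 1/2; a disjoint union preserves the total
        assert union.area == pytest.approx(6 * 0.5, rel=1e-9)


class TestColorScale:
    def test_bin_assignment(self):
        s = ColorScale()
        assert ld_color(0.35, s) == s.colors[1]   # (0.2, 0.4] bin
        assert ld_color(0.0, s) == s.colors[0]
        assert ld_color(1.0, s) == s.colors[4]
        assert ld_color(0.2, s) == s.colors[0]    # upper bound inclusive

    def test_custom_colors_keep_bin_index(self):
        custom = ColorScale(colors=("a", "b", "c", "d", "e"))
        default = ColorScale()
        for v in (0.0, 0.15, 0.35, 0.61, 0.99):
            assert custom.bin_index(v) == default.bin_index(v)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ld_color(1.5, ColorScale())

    def test_nan_maps_to_na_color(self):
        s = ColorScale(na_color="#123456")
        assert ld_color(float("nan"), s) == "#123456"

    def test_r_gray_names_accepted(self):
        assert normalize_color("gray81") == "#CFCFCF"
        assert normalize_color("grey1") == "#030303"
        s = ColorScale(colors=("gray81", "gray61", "gray41", "gray11", "gray1"))
        assert s.colors == ("#CFCFCF", "#9C9C9C", "#696969", "#1C1C1C", "#030303")


@pytest.fixture(scope="module")
def figure_inputs(scope5, locus):
    gt = locus["gt"]
    region = scope5.region
    panel = gt.markers_in_region(region.chrom, region.left, region.right)
    ld = ld_matrix(gt, panel)
    lead_ld = lead_snp_ld(gt, (scope5.lead.chrom, scope5.lead.pos), panel)
    return scope5, ld, lead_ld


class TestFigureSpec:
    def test_deterministic_reproduction(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        a = build_figure_spec(scope, ld, lead_ld, leadsnp_size=2.0)
        b = build_figure_spec(scope, ld, lead_ld, leadsnp_size=2.0)
        assert a == b

    def test_marker_order_isomorphism(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        spec = build_figure_spec(scope, ld, lead_ld)
        by_x = [m.index for m in sorted(spec.ld_markers,
                                        key=lambda m: m.genomic_x)]
        assert by_x == sorted(by_x)

    def test_diamond_count(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        spec = build_figure_spec(scope, ld, lead_ld)
        n = ld.n_markers
        assert len(spec.diamonds) == n * (n - 1) // 2

    def test_default_linking_lines_are_significant_set(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        spec = build_figure_spec(scope, ld, lead_ld)
        assert len(spec.polylines) == len(scope.significant)
        # two-segment polylines: scatter -> gene baseline -> LD top
        for pl in spec.polylines:
            assert len(pl) == 3

    def test_polyline_endpoints_inside_layers(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        spec = build_figure_spec(scope, ld, lead_ld)
        s_lo, s_hi = spec.layers["scatter"]
        g_lo, g_hi = spec.layers["gene"]
        ld_lo, ld_hi = spec.layers["ld"]
        for pl in spec.polylines:
            ys = [y for _, y in pl]
            assert s_lo <= ys[0] <= s_hi
            assert g_lo <= ys[1] <= g_hi
            assert ld_lo <= ys[-1] <= ld_hi or ys[-1] == g_lo

    def test_link2ld_restriction(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        one = sorted(scope.significant)[0]
        spec = build_figure_spec(
            scope, ld, lead_ld,
            links=LinkSpec(link2gene=[], link2ld=[one]),
        )
        assert len(spec.polylines) == 1
        assert len(spec.polylines[0]) == 2  # gene baseline -> LD only

    def test_cross_panel_unmatched_truncates_at_gene_track(self, figure_inputs,
                                                           locus, cross_panel):
        scope, _, lead_ld = figure_inputs
        gt2 = cross_panel["gt"]
        region = scope.region
        panel = gt2.markers_in_region(region.chrom, region.left, region.right)
        ld2 = ld_matrix(gt2, panel)
        matched = gl.match_markers(scope.assoc, gt2, panel)
        spec = build_figure_spec(scope, ld2, lead_ld, matched=matched)
        g_lo, _ = spec.layers["gene"]
        truncated = [pl for pl in spec.polylines if pl[-1][1] == g_lo]
        full = [pl for pl in spec.polylines if len(pl) == 3]
        # every second marker is shared, so both kinds must occur
        assert truncated and full

    def test_leadsnp_size_scales_lead_glyph(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        s1 = build_figure_spec(scope, ld, lead_ld, leadsnp_size=1.0)
        s2 = build_figure_spec(scope, ld, lead_ld, leadsnp_size=2.0)
        lead1 = next(p for p in s1.scatter if p.is_lead)
        lead2 = next(p for p in s2.scatter if p.is_lead)
        other = next(p for p in s2.scatter if not p.is_lead)
        assert lead2.size == pytest.approx(2 * lead1.size)
        assert lead1.size == pytest.approx(other.size)

    def test_highlight_overrides_style(self, figure_inputs):
        scope, ld, lead_ld = figure_inputs
        name = sorted(set(scope.assoc["marker"]) - {scope.lead.marker})[0]
        hl = HighlightSpec([HighlightRule(marker=name, shape="D",
                                          color="#00AA00", size=1.5)])
        spec = build_figure_spec(scope, ld, lead_ld, highlight=hl)
        pt = next(p for p in spec.scatter if p.marker == name)
        assert (pt.shape, pt.color) == ("D", "#00AA00")


class TestGenicLayout:
    @pytest.fixture()
    def genic_scope(self, locus):
        ann = locus["ann"]
        # pick a transcript guaranteed to cover association markers
        for tid, tx in ann.transcripts.items():
            scope = None
            try:
                scope = gl.resolve_genic(locus["assoc"], ann,
                                         gl.GenicSpec(tid, up=2000, down=2000))
            except gl.EmptyScopeError:
                continue
            if len(scope.assoc) >= 3:
                scope.threshold = 8.0
                scope.significant = gl.filter_significant(scope, 8.0)
                scope.lead = gl.find_lead(scope)
                return scope
        pytest.fail("no transcript with enough markers in the fixture")

    def test_feature_boxes_match_transcript(self, genic_scope, locus):
        spec = build_figure_spec(genic_scope, None, None, mode="genic",
                                 triangle=False, leadsnp=False)
        tx = genic_scope.focal_transcript
        exons = sorted((s, e) for k, s, e in tx.features if k == "exon")
        boxes = sorted((b.start, b.end) for b in spec.feature_boxes
                       if b.kind == "exon")
        assert boxes == exons
        assert len(spec.intron_segments) == len(exons) - 1

    def test_triangle_suppressed(self, genic_scope, locus):
        gt = locus["gt"]
        region = genic_scope.region
        panel = gt.markers_in_region(region.chrom, region.left, region.right)
        ld = ld_matrix(gt, panel)
        spec = build_figure_spec(genic_scope, ld, None, mode="genic",
                                 triangle=False, leadsnp=False)
        assert spec.diamonds == [] and "ld" not in spec.layers


class TestRender:
    def test_svg_rerender_byte_identical(self, figure_inputs, tmp_path):
        scope, ld, lead_ld = figure_inputs
        spec = build_figure_spec(scope, ld, lead_ld, leadsnp_size=2.0)
        a = tmp_path / "a.svg"
        b = tmp_path / "b.svg"
        render(spec, a)
        render(spec, b)
        assert a.read_bytes() == b.read_bytes()

    def test_png_and_pdf_outputs(self, figure_inputs, tmp_path):
        scope, ld, lead_ld = figure_inputs
        spec = build_figure_spec(scope, ld, lead_ld)
        for name in ("fig.png", "fig.pdf"):
            out = tmp_path / name
            render(spec, out)
            assert out.stat().st_size > 0

    def test_no_linking_lines_when_nothing_significant(self, figure_inputs,
                                                       tmp_path):
        scope, ld, lead_ld = figure_inputs
        import copy
        quiet = copy.copy(scope)
        quiet.threshold = 50.0
        quiet.significant = gl.filter_significant(quiet, 50.0)
        spec = build_figure_spec(quiet, ld, lead_ld)
        assert spec.polylines == []
        render(spec, tmp_path / "quiet.png")
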