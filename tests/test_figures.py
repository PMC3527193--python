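"""Figure specification builders, rasterization and the batch runner."""

import hashlib

import numpy as np
import pandas as pd
import pytest

import gwasfig as g
from gwasfig.errors import (
    EmptyInputError,
    LookupError_,
    OptionError,
    ValidationError,
)
from gwasfig.figures import plan_batch


class TestManhattanSpec:
    def test_one_series_per_chromosome_no_lines(self, toy_table):
        spec = g.build_manhattan_spec(toy_table, "Trait1")
        assert len(spec.series) == 3
        assert spec.ref_lines == [] and spec.bands == []

    def test_threshold_line_position(self, toy_table):
        style = g.StyleOptions(threshold_p=5e-8)
        spec = g.build_manhattan_spec(toy_table, "Trait1", style=style)
        (line,) = spec.ref_lines
        assert line.y == pytest.approx(7.30103, abs=1e-5)

    def test_cutoff_excludes_markers(self, toy_table):
        style = g.StyleOptions(cutoff_p=0.01)
        spec = g.build_manhattan_spec(toy_table, "Trait1", style=style)
        assert spec.n_points == 2  # only {1e-8, 1e-3} survive

    def test_shading_band_below_threshold(self, toy_table):
        style = g.StyleOptions(threshold_p=1e-4, shade_below_threshold=True)
        spec = g.build_manhattan_spec(toy_table, "Trait1", style=style)
        (band,) = spec.bands
        assert (band.y_lo, band.y_hi) == (0.0, pytest.approx(4.0))

    def test_palette_alternates(self, toy_table):
        spec = g.build_manhattan_spec(
            toy_table, "Trait1", style=g.StyleOptions(chrom_colors="template1"))
        colors = [s.color for s in spec.series]
        assert colors[0] == colors[2] != colors[1]

    def test_proportional_sizes_attached(self, toy_table):
        style = g.StyleOptions(
            size_rule=g.MarkerSizeRule(mode="proportional", size_min=2, size_max=8))
        spec = g.build_manhattan_spec(toy_table, "Trait1", style=style)
        sizes = np.concatenate([s.sizes for s in spec.series if s.n_points])
        assert sizes.max() == 8.0 and sizes.min() == 2.0

    def test_unknown_trait_rejected(self, toy_table):
        with pytest.raises(LookupError_):
            g.build_manhattan_spec(toy_table, "nope")

    def test_raw_trait_rejected(self):
        frame = pd.DataFrame({"snp": ["a"], "chrom": ["1"], "position": [1],
                              "maf": [0.2]})
        t = g.GwasTable(frame=frame, trait_names=("maf",),
                        column_kinds={"maf": "raw"})
        with pytest.raises(OptionError):
            g.build_manhattan_spec(t, "maf")


class TestQqSpec:
    def test_identity_line_plus_points(self):
        s = g.qq_series([0.5])
        spec = g.build_qq_spec(s)
        identity, points = spec.series
        assert identity.mode == "connected_lines"
        assert points.n_points == s.n == 1
        assert identity.x[-1] == identity.y[-1] == s.expected.max()

    def test_exact_quantiles_land_on_identity(self):
        s = g.qq_series([0.125, 0.375, 0.625, 0.875])
        spec = g.build_qq_spec(s)
        points = spec.series[1]
        np.testing.assert_allclose(points.y, points.x, rtol=1e-12)

    def test_point_count_conserved(self, small_sim_table):
        s = g.qq_series(small_sim_table.trait_values("Trait1"))
        assert g.build_qq_spec(s).series[1].n_points == s.n


class TestChromosomeSpec:
    @pytest.mark.parametrize("connect,mode",
                             [(True, "connected_lines"), (False, "symbols")])
    def test_connect_lines_toggle(self, toy_table, connect, mode):
        spec = g.build_chromosome_spec(
            toy_table, "Trait1", "1", g.StyleOptions(connect_lines=connect))
        (series,) = spec.series
        assert series.mode == mode

    def test_x_is_bp_within_span(self, toy_table):
        spec = g.build_chromosome_spec(toy_table, "Trait1", "1")
        (series,) = spec.series
        assert series.x.min() == 100 and series.x.max() == 1100

    def test_missing_chromosome(self, toy_table):
        with pytest.raises(LookupError_):
            g.build_chromosome_spec(toy_table, "Trait1", "99")

    def test_no_plottable_markers_is_empty_figure_error(self, toy_table):
        # trait1 on chrom 3 holds only a missing value
        with pytest.raises(EmptyInputError):
            g.build_chromosome_spec(toy_table, "Trait1", "3")


class TestMultiTraitSpec:
    def make_table(self):
        frame = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(4)],
            "chrom": ["1"] * 4,
            "position": [10, 20, 30, 40],
            "A": [0.5, 0.01, 0.2, 0.9],
            "B": [0.3, 0.6, 1e-5, 0.8],
            "maf": [0.1, 0.2, 0.3, 0.4],
        })
        return g.GwasTable(frame=frame, trait_names=("A", "B", "maf"),
                           column_kinds={"maf": "raw"})

    def test_three_traits_two_axes(self):
        t = self.make_table()
        a = g.AxisAssignment(
            traits={"A": g.TraitAxis("Y1"), "B": g.TraitAxis("Y1"),
                    "maf": g.TraitAxis("Y2")},
            y2=g.AxisOptions(scale="raw"))
        spec = g.build_multitrait_spec(t, "1", a)
        assert len(spec.series) == 3
        assert {s.axis for s in spec.series} == {"Y1", "Y2"}
        assert spec.y2 is not None

    def test_trait_selection(self):
        t = self.make_table()
        a = g.AxisAssignment(
            traits={"A": g.TraitAxis(enabled=True),
                    "B": g.TraitAxis(enabled=False),
                    "maf": g.TraitAxis(enabled=False)})
        spec = g.build_multitrait_spec(t, "1", a)
        assert [s.label for s in spec.series] == ["A"]

    def test_all_disabled_rejected(self):
        t = self.make_table()
        a = g.AxisAssignment(traits={"A": g.TraitAxis(enabled=False)})
        with pytest.raises(OptionError):
            g.build_multitrait_spec(t, "1", a)

    def test_per_axis_threshold_lines(self):
        t = self.make_table()
        a = g.AxisAssignment(
            traits={"A": g.TraitAxis("Y1"), "B": g.TraitAxis("Y2")},
            y1=g.AxisOptions(threshold_p=1e-2),
            y2=g.AxisOptions(threshold_p=1e-4))
        spec = g.build_multitrait_spec(t, "1", a)
        assert len(spec.ref_lines) == 2
        y = {r.axis: r.y for r in spec.ref_lines}
        assert y["Y1"] == pytest.approx(2.0) and y["Y2"] == pytest.approx(4.0)

    def test_per_axis_cutoff(self):
        t = self.make_table()
        a = g.AxisAssignment(
            traits={"A": g.TraitAxis("Y1"), "B": g.TraitAxis("Y2")},
            y1=g.AxisOptions(cutoff_p=0.05),
            y2=g.AxisOptions(cutoff_p=1e-3))
        spec = g.build_multitrait_spec(t, "1", a)
        by = {s.label: s for s in spec.series}
        assert by["A"].n_points == 1  # only p=0.01 passes Y1 cutoff
        assert by["B"].n_points == 1  # only p=1e-5 passes Y2 cutoff

    def test_raw_column_untransformed(self):
        t = self.make_table()
        a = g.AxisAssignment(
            traits={"maf": g.TraitAxis("Y2")}, y2=g.AxisOptions(scale="raw"))
        spec = g.build_multitrait_spec(t, "1", a)
        np.testing.assert_array_equal(spec.series[0].y, [0.1, 0.2, 0.3, 0.4])


class TestEpisnpSpec:
    @pytest.fixture
    def etable(self):
        return g.simulate_episnp_table(
            g.GenoSimConfig(n_individuals=60, n_markers=120, seed=9), n_chrom=2)

    def test_default_mode_four_series_two_axes(self, etable):
        spec = g.build_episnp_spec(etable, chrom="1")
        assert len(spec.series) == 4
        assert [s.axis for s in spec.series] == ["Y1", "Y1", "Y1", "Y2"]
        assert spec.series[3].label == "sample size"

    def test_sorted_effect_is_monotone(self, etable):
        spec = g.build_episnp_spec(etable, sort_by="additive")
        additive = next(s for s in spec.series if s.label == "additive")
        assert (np.diff(additive.y) <= 1e-12).all()  # -log10 P decreasing

    def test_sort_reorders_all_series_consistently(self, etable):
        spec = g.build_episnp_spec(etable, sort_by="dominance")
        frame = etable.frame.sort_values("p_dominance", kind="stable")
        np.testing.assert_array_equal(
            spec.series[3].y, frame["n_obs"].to_numpy(dtype=float))

    @pytest.mark.parametrize("connect,mode",
                             [(True, "connected_lines"), (False, "symbols")])
    def test_connect_toggle(self, etable, connect, mode):
        spec = g.build_episnp_spec(etable, chrom="1", connect_lines=connect)
        assert all(s.mode == mode for s in spec.series)

    def test_unknown_sort_key(self, etable):
        with pytest.raises(OptionError):
            g.build_episnp_spec(etable, sort_by="epistatic")

    def test_chrom_or_sort_required(self, etable):
        with pytest.raises(OptionError):
            g.build_episnp_spec(etable)


class TestSpecIntegrity:
    def test_series_must_reference_declared_axis(self):
        with pytest.raises(ValidationError):
            g.FigureSpec(
                title="bad", xaxis=g.figures.XAxisDesc(),
                y1=g.figures.AxisDesc(),
                series=[g.Series("s", np.array([1.0]), np.array([1.0]),
                                 axis="Y2")])

    def test_xy_length_mismatch(self):
        with pytest.raises(ValidationError):
            g.FigureSpec(
                title="bad", xaxis=g.figures.XAxisDesc(),
                y1=g.figures.AxisDesc(),
                series=[g.Series("s", np.array([1.0, 2.0]), np.array([1.0]))])

    def test_generated_specs_validate(self, small_sim_table):
        lay = g.compute_layout(small_sim_table)
        for trait in small_sim_table.trait_names:
            g.build_manhattan_spec(small_sim_table, trait, lay).validate()
            g.build_qq_spec(
                g.qq_series(small_sim_table.trait_values(trait))).validate()

    def test_no_plotted_point_violates_cutoff(self, small_sim_table):
        cutoff = 0.3
        style = g.StyleOptions(cutoff_p=cutoff)
        spec = g.build_manhattan_spec(small_sim_table, "Trait1", style=style)
        floor = -np.log10(cutoff)
        for s in spec.series:
            assert (s.y >= floor - 1e-12).all()


class TestRasterize:
    def test_nonempty_output_all_formats(self, toy_table, tmp_path):
        spec = g.build_manhattan_spec(toy_table, "Trait1")
        for fmt in ("png", "svg", "pdf"):
            path = g.rasterize(spec, tmp_path / f"f.{fmt}")
            assert path.stat().st_size > 0

    def test_aspect_ratio_default_height(self, toy_table, tmp_path):
        from PIL import Image

        spec = g.build_manhattan_spec(toy_table, "Trait1")  # 2:1 aspect
        g.rasterize(spec, tmp_path / "f.png", width_px=600)
        assert Image.open(tmp_path / "f.png").size == (600, 300)

    def test_byte_determinism(self, toy_table, tmp_path):
        spec = g.build_manhattan_spec(toy_table, "Trait1")
        digests = set()
        for i in range(2):
            p = g.rasterize(spec, tmp_path / f"f{i}.png", width_px=400)
            digests.add(hashlib.sha256(p.read_bytes()).hexdigest())
        assert len(digests) == 1

    def test_unsupported_format(self, toy_table, tmp_path):
        spec = g.build_manhattan_spec(toy_table, "Trait1")
        with pytest.raises(OptionError):
            g.rasterize(spec, tmp_path / "f.bmp")


class TestBatchRun:
    def test_plan_matches_graph_count_formula(self):
        for n in range(1, 6):
            for c in range(1, 7):
                t = g.simulate_pvalue_table(
                    g.SimConfig(n_chrom=c, markers_per_chrom=5, n_traits=n,
                                seed=n * 10 + c))
                jobs = plan_batch(t, g.BatchOptions(outdir="x"))
                assert len(jobs) == g.count_graphs(n, c)

    def test_small_batch_produces_n_c_plus_2_files(self, tmp_path):
        t = g.simulate_pvalue_table(
            g.SimConfig(n_chrom=3, markers_per_chrom=10, n_traits=2, seed=1))
        manifest = g.batch_run(
            t, options=g.BatchOptions(outdir=tmp_path, width_px=200))
        assert len(manifest) == g.count_graphs(2, 3) == 10
        kinds = [e.kind for e in manifest]
        assert kinds.count("manhattan") == 2 and kinds.count("qq") == 2
        assert kinds.count("chromosome") == 6
        for e in manifest:
            assert (tmp_path / e.path).exists() or tmp_path.joinpath(e.path).exists()
        assert (tmp_path / "MANIFEST.txt").exists()

    def test_kinds_can_be_disabled(self, tmp_path):
        t = g.simulate_pvalue_table(
            g.SimConfig(n_chrom=3, markers_per_chrom=10, n_traits=2, seed=1))
        manifest = g.batch_run(
            t, options=g.BatchOptions(outdir=tmp_path, width_px=200,
                                      kinds=frozenset({"chromosome"})))
        assert len(manifest) == 6

    def test_unknown_only_table_counts_one_block(self, tmp_path):
        frame = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": ["0"] * 3,
                              "position": [900, 5, 40], "P": [0.1, 0.2, 0.3]})
        t = g.GwasTable(frame=frame, trait_names=("P",))
        manifest = g.batch_run(
            t, options=g.BatchOptions(outdir=tmp_path, width_px=200))
        # the unknown block is one chromosome graph: 1 * (1 + 2) files
        assert len(manifest) == 3

    def test_filenames_deterministic(self, tmp_path):
        t = g.simulate_pvalue_table(
            g.SimConfig(n_chrom=2, markers_per_chrom=5, n_traits=1, seed=2))
        manifest = g.batch_run(
            t, options=g.BatchOptions(outdir=tmp_path, width_px=200))
        names = sorted(p.name for p in tmp_path.glob("*.png"))
        assert names == sorted(
            f"Trait1__{k}__{c}.png"
            for k, c in [("manhattan", "all"), ("qq", "all"),
                         ("chromosome", "1"), ("chromosome", "2")])
        assert len(manifest) == 4
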