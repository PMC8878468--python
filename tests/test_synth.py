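import numpy as np
import pytest
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from cytogate.synth import (
    ArtifactTruth,
    CellTruth,
    CompoundKineticsSpec,
    PlateDesign,
    RenderParams,
    SimulationParams,
    TruthError,
    WellAssignment,
    make_cells,
    make_precipitate,
    render_field,
    sample_cells_for_well,
    simulate_plate,
)
from cytogate.synth.kinetics import STATE_COLUMNS


def two_dmso(extra=None):
    wells = {
        "B02": WellAssignment(None, 0.0, "dmso_control"),
        "B03": WellAssignment(None, 0.0, "dmso_control"),
    }
    wells.update(extra or {})
    return wells


class TestTruthTypes:
    def test_pyknosed_subclass_iff_pyknosed(self):
        with pytest.raises(TruthError):
            CellTruth(0, (1, 1), nucleus_class="healthy", pyknosed_subclass="mitotic")
        with pytest.raises(TruthError):
            CellTruth(0, (1, 1), nucleus_class="pyknosed", pyknosed_subclass="n/a")

    def test_phenotypes_only_for_healthy_nuclei(self):
        with pytest.raises(TruthError):
            CellTruth(0, (1, 1), nucleus_class="fragmented", tubulin_effect=True)
        CellTruth(0, (1, 1), nucleus_class="healthy", tubulin_effect=True)

    def test_artifact_scale_must_exceed_one(self):
        with pytest.raises(TruthError):
            ArtifactTruth("precipitate", np.ones((4, 4), bool), 0.9)

    def test_kinetic_class_orders_halving_time(self):
        times = [
            CompoundKineticsSpec(1.0, kinetic_class=k).potency_halving_time
            for k in ("rapid", "intermediate", "slow")
        ]
        assert times[0] < times[1] < times[2]

    def test_outer_wells_rejected(self):
        with pytest.raises(TruthError, match="outer"):
            PlateDesign(two_dmso({"A01": WellAssignment("c", 1.0)}), [0.0])

    def test_needs_two_dmso_wells(self):
        with pytest.raises(TruthError, match="dmso"):
            PlateDesign({"B02": WellAssignment(None, 0.0, "dmso_control")}, [0.0])


class TestRenderField:
    def test_empty_field(self, small_params):
        field, masks = render_field([], params=small_params, seed=0)
        assert masks["nuclei"].n_objects == 0
        assert field.projection("hoechst").shape == small_params.shape

    def test_bit_exact_determinism(self, rng, small_params):
        cells = make_cells(50, rng, small_params, min_distance=25)
        f1, _ = render_field(cells, params=small_params, seed=11)
        f2, _ = render_field(cells, params=small_params, seed=11)
        for ch in f1.channels:
            assert np.array_equal(f1.channels[ch], f2.channels[ch])
        f3, _ = render_field(cells, params=small_params, seed=12)
        assert not np.array_equal(f3.channels["hoechst"], f1.channels["hoechst"])

    def test_center_outside_field_errors(self, small_params):
        with pytest.raises(TruthError):
            render_field([CellTruth(0, (9999.0, 5.0))], params=small_params, seed=0)

    def test_packing_limit_rejection(self, small_params):
        cells = [CellTruth(0, (50.0, 50.0)), CellTruth(1, (52.0, 50.0))]
        with pytest.raises(TruthError, match="packing"):
            render_field(cells, params=small_params, seed=0)

    def test_precipitate_is_single_hot_component(self, rng, medium_params):
        # derived check recomputed from the rendered array itself
        cells = make_cells(10, rng, medium_params, min_distance=45)
        art = make_precipitate(medium_params.shape, (330.0, 330.0), rng, intensity_scale=8.0)
        field, masks = render_field(cells, [art], params=medium_params, seed=2)
        proj = field.projection("hoechst").astype(float)
        nuc = masks["nuclei"].labels
        nuclear_means = [proj[nuc == k].mean() for k in range(1, 11)]
        med = np.median(nuclear_means)
        bright = cc_label(proj > 2.0 * med)
        hot = [
            p.label for p in regionprops(bright, intensity_image=proj)
            if p.intensity_mean > 4.0 * med and p.area > 20
        ]
        assert len(hot) == 1
        hot_mask = bright == hot[0]
        assert (hot_mask & art.footprint).sum() / art.footprint.sum() > 0.5


class TestSimulatePlate:
    def make_design(self, extra=None, timepoints=(0.0, 12.0, 24.0), mode="viability"):
        return PlateDesign(two_dmso(extra), list(timepoints), mode)

    def test_dmso_grows(self):
        design = self.make_design()
        healthy = np.zeros((20, 3))
        for seed in range(20):
            res = simulate_plate(design, {}, seed=seed)
            healthy[seed] = res.wells["B02"].records["healthy"].to_numpy()
        means = healthy.mean(axis=0)
        assert means[0] < means[1] < means[2]
        # expectation matches basal rate within sampling error
        expected = 200 * 1.03**12
        assert abs(means[1] - expected) / expected < 0.05

    def test_conservation(self):
        design = self.make_design(
            {"B04": WellAssignment("c", 10.0)}, timepoints=(0.0, 24.0, 48.0)
        )
        res = simulate_plate(design, {"c": CompoundKineticsSpec(1.0, kinetic_class="rapid")}, 3)
        df = res.truth_table
        totals = df[STATE_COLUMNS].sum(axis=1) + df["cleared"]
        assert (totals == df["total_created"]).all()

    def test_determinism(self):
        design = self.make_design({"B04": WellAssignment("c", 1.0)})
        kin = {"c": CompoundKineticsSpec(1.0)}
        t1 = simulate_plate(design, kin, seed=5).truth_table
        t2 = simulate_plate(design, kin, seed=5).truth_table
        assert t1.equals(t2)

    def test_missing_kinetics_errors(self):
        design = self.make_design({"B04": WellAssignment("c", 1.0)})
        with pytest.raises(TruthError, match="kinetics"):
            simulate_plate(design, {}, seed=0)

    def test_healthy_fraction_monotone_in_concentration(self):
        spec = CompoundKineticsSpec(1.0, kinetic_class="intermediate")
        concs = [0.1, 1.0, 10.0, 100.0]

        # exact expectation of the chain: E[h_{t+1}] = E[h_t](1 + b - p_exit)
        def expected_healthy(conc, hours=24):
            h = 200.0
            for t in range(hours):
                p_exit = 1.0 - np.exp(-spec.exit_hazard(conc, float(t)))
                h *= 1.0 + 0.030 - p_exit
            return h

        exp_h = [expected_healthy(c) for c in concs]
        assert np.all(np.diff(exp_h) < 0)

        # Monte-Carlo agrees within sampling tolerance
        design_cols = ["B04", "B05", "B06", "B07"]
        extra = {w: WellAssignment("c", c) for w, c in zip(design_cols, concs)}
        design = self.make_design(extra, timepoints=(0.0, 24.0))
        frac = np.zeros((15, len(concs)))
        for seed in range(15):
            res = simulate_plate(design, {"c": spec}, seed=seed)
            for j, w in enumerate(design_cols):
                counts = res.wells[w].counts_at(24.0)
                frac[seed, j] = counts["healthy"] / sum(counts.values())
        means = frac.mean(axis=0)
        assert np.all(np.diff(means) <= 0.02)

    def test_rapid_kills_before_slow(self):
        extra = {
            "B04": WellAssignment("rapid", 10.0),
            "B05": WellAssignment("slow", 10.0),
        }
        design = self.make_design(extra, timepoints=tuple(np.arange(0.0, 49.0, 4.0)))
        kin = {
            "rapid": CompoundKineticsSpec(1.0, kinetic_class="rapid"),
            "slow": CompoundKineticsSpec(1.0, kinetic_class="slow"),
        }
        wins = 0
        n = 30
        for seed in range(n):
            res = simulate_plate(design, kin, seed=seed)
            dmso = res.wells["B02"].records.set_index("timepoint")["healthy"]

            def crossing(well):
                rec = res.wells[well].records.set_index("timepoint")["healthy"]
                norm = rec / dmso
                below = norm[norm < 0.5]
                return below.index.min() if len(below) else np.inf

            if crossing("B04") < crossing("B05"):
                wins += 1
        assert wins / n >= 0.95

    def test_g1_arrest_raises_red_fraction(self):
        extra = {"B04": WellAssignment("arrester", 1.0)}
        design = self.make_design(extra, timepoints=(0.0, 18.0), mode="fucci")
        kin = {
            "arrester": CompoundKineticsSpec(
                1.0, kinetic_class="slow", cell_cycle_action="g1_arrest"
            )
        }
        res = simulate_plate(design, kin, seed=7)

        def red_frac(well):
            row = res.wells[well].records
            row = row[row["timepoint"] == 18.0].iloc[0]
            labeled = row["fucci_red"] + row["fucci_green"] + row["fucci_yellow"]
            return row["fucci_red"] / labeled

        assert red_frac("B04") > red_frac("B02")

    def test_sampled_cells_match_mix(self, rng, medium_params):
        design = self.make_design({"B04": WellAssignment("c", 10.0)}, timepoints=(0.0, 24.0))
        res = simulate_plate(design, {"c": CompoundKineticsSpec(1.0, kinetic_class="rapid")}, 1)
        traj = res.wells["B04"]
        cells = sample_cells_for_well(traj, 24.0, rng, medium_params, max_cells=60)
        assert 0 < len(cells) <= 62
        counts = traj.counts_at(24.0)
        frac_truth = counts["healthy"] / sum(counts.values())
        frac_cells = np.mean([c.viability_class == "healthy" for c in cells])
        assert abs(frac_cells - frac_truth) < 0.1
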