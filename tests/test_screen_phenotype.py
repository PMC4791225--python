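import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itrkit.errors import ValidationError
from itrkit.screen_phenotype import (
    N_COLS,
    N_ROWS,
    PlateGrid,
    call_hits,
    default_control_mask,
    differentiation_stats,
    gene_log2fc,
    loess_normalize,
    parse_well,
    robust_z,
    well_name,
    well_results,
)


def flat_plate(value=1e5, plate_id="p"):
    return PlateGrid(plate_id=plate_id, values=np.full((N_ROWS, N_COLS), value))


def bilinear_plate(amplitude=0.8, baseline=17.0):
    rows, cols = np.indices((N_ROWS, N_COLS))
    u_r = rows / (N_ROWS - 1) - 0.5
    u_c = cols / (N_COLS - 1) - 0.5
    log2 = baseline + amplitude * (0.7 * u_r - 1.1 * u_c + 0.9 * u_r * u_c)
    return PlateGrid(plate_id="grad", values=2.0**log2)


class TestControlMask:
    def test_default_masks_lines_1_2_23_24(self):
        mask = default_control_mask()
        assert mask[:, [0, 1, 22, 23]].all()
        assert not mask[:, 2:22].any()

    def test_well_names_roundtrip(self):
        for r in (0, 7, 15):
            for c in (0, 11, 23):
                assert parse_well(well_name(r, c)) == (r, c)


class TestLoessNormalize:
    def test_flat_plate_unchanged(self):
        corrected = loess_normalize(flat_plate(2.0**10))
        sample = corrected.values[corrected.sample_mask]
        assert np.allclose(sample, 10.0, atol=1e-9)

    def test_exact_bilinear_gradient_removed(self):
        plate = bilinear_plate()
        pre = np.log2(plate.values)[plate.sample_mask].var()
        corrected = loess_normalize(plate)
        post = corrected.values[corrected.sample_mask].var()
        assert post / pre < 1e-6

    def test_planted_hits_survive_correction(self):
        """Gradient plus 16 planted -1.5 log2 wells: the hits' corrected
        residuals stay <= -1.2 while non-hits sit within +/- 0.2."""
        plate = bilinear_plate(amplitude=0.5)
        rng = np.random.default_rng(5)
        sample_wells = np.argwhere(plate.sample_mask)
        hit_idx = rng.choice(len(sample_wells), 16, replace=False)
        log2 = np.log2(plate.values)
        for i in hit_idx:
            r, c = sample_wells[i]
            log2[r, c] -= 1.5
        plate = PlateGrid(plate_id="hits", values=2.0**log2)
        corrected = loess_normalize(plate)
        med = np.median(corrected.values[corrected.sample_mask])
        resid = corrected.values - med
        hits = {tuple(sample_wells[i]) for i in hit_idx}
        for r, c in sample_wells:
            if (r, c) in hits:
                assert resid[r, c] <= -1.2
            else:
                assert abs(resid[r, c]) <= 0.2

    def test_idempotent_up_to_tolerance(self):
        plate = bilinear_plate()
        once = loess_normalize(plate)
        again = loess_normalize(
            PlateGrid(plate_id="again", values=2.0 ** once.values)
        )
        delta = np.abs(again.values - once.values)[once.sample_mask]
        assert delta.max() < 1e-6

    def test_nonpositive_wells_dropped_with_warning(self):
        plate = flat_plate()
        vals = plate.values.copy()
        vals[5, 10] = 0.0
        plate = PlateGrid(plate_id="p", values=vals)
        with pytest.warns(UserWarning, match="non-positive"):
            corrected = loess_normalize(plate)
        assert np.isnan(corrected.values[5, 10])
        assert np.isfinite(corrected.values[corrected.sample_mask]).sum() == (
            corrected.sample_mask.sum() - 1
        )

    def test_all_control_plate_rejected(self):
        plate = flat_plate()
        plate.control_mask[:] = True
        with pytest.raises(ValidationError):
            loess_normalize(plate)

    def test_bad_span_rejected(self):
        with pytest.raises(ValidationError):
            loess_normalize(flat_plate(), span=0.0)


class TestRobustZ:
    def test_hand_example(self):
        z, flag = robust_z([1, 2, 3, 4, 5])
        assert not flag
        assert np.allclose(
            np.round(z, 3), [-1.349, -0.674, 0.0, 0.674, 1.349]
        )

    def test_median_maps_to_zero(self):
        z, _ = robust_z([3.0, 5.0, 7.0])
        assert z[1] == 0.0

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, flag = robust_z([2.0, 2.0, 2.0])
        assert flag and np.all(z == 0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            robust_z([1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.integers(-1000, 1000), min_size=3, max_size=30, unique=True
        ),
        shift=st.floats(-100, 100),
        scale=st.floats(0.1, 10),
    )
    def test_shift_invariant_scale_equivariant(self, values, shift, scale):
        x = np.array(values) / 7.3  # unique values, non-degenerate MAD
        z0, f0 = robust_z(x)
        z1, f1 = robust_z(x + shift)
        z2, f2 = robust_z(x * scale)
        if f0:
            return  # degenerate scale: all-zero convention
        assert np.allclose(z0, z1, atol=1e-6)
        assert np.allclose(z0, z2, atol=1e-6)


class TestCallHits:
    @pytest.mark.parametrize(
        "fc,expected",
        [(-1.0, "decreased"), (1.0, "increased"), (0.99, "none"), (-0.99, "none")],
    )
    def test_inclusive_boundary(self, fc, expected):
        df = pd.DataFrame({"gene": ["G"], "log2fc": [fc]})
        assert call_hits(df).loc[0, "hit"] == expected

    def test_matches_scan_oracle_and_antisymmetry(self, rng):
        fc = rng.normal(0, 1.2, size=200)
        df = pd.DataFrame({"gene": [f"G{i}" for i in range(200)], "log2fc": fc})
        hits = call_hits(df)
        for v, flag in zip(fc, hits["hit"]):
            expected = "decreased" if v <= -1 else "increased" if v >= 1 else "none"
            assert flag == expected
        flipped = call_hits(df.assign(log2fc=-df["log2fc"]))
        swap = {"decreased": "increased", "increased": "decreased", "none": "none"}
        assert list(flipped["hit"]) == [swap[h] for h in hits["hit"]]

    def test_positive_threshold_required(self):
        with pytest.raises(ValidationError):
            call_hits(pd.DataFrame({"gene": [], "log2fc": []}), threshold=0)


class TestWellAndGeneResults:
    def test_requires_corrected_plate(self):
        with pytest.raises(ValidationError):
            well_results(flat_plate())

    def test_gene_aggregation_over_replicate_plates(self):
        annotation = {}
        mask = default_control_mask()
        for r in range(N_ROWS):
            for c in range(N_COLS):
                role = "neg_ctrl" if mask[r, c] else "sample"
                gene = "CTRL" if mask[r, c] else f"G{r}_{c}"
                annotation[well_name(r, c)] = (gene, role)
        plates = []
        for shift in (0.0, 0.2):
            vals = np.full((N_ROWS, N_COLS), 10.0)
            vals[4, 10] = 8.0 + shift  # same gene well on both replicates
            plates.append(
                PlateGrid(
                    plate_id=f"p{shift}", values=vals, annotation=annotation,
                    log2_scale=True,
                )
            )
        with pytest.warns(UserWarning, match="MAD is 0"):  # flat toy plates
            genes = gene_log2fc(plates)
        row = genes[genes.gene == "G4_10"].iloc[0]
        assert row.n_wells == 2
        assert row.log2fc == pytest.approx((-2.0 + -1.8) / 2)


class TestDifferentiationStats:
    def test_ratio_definition(self):
        df = pd.DataFrame(
            {
                "group": ["a", "a"],
                "neurite_length": [50.0, 50.0],
                "cell_width": [10.0, 10.0],
            }
        )
        summary, _ = differentiation_stats(df)
        assert summary.loc[0, "mean_ratio"] == pytest.approx(5.0)

    def test_identical_groups_null(self):
        ratios = [1.0, 2.0, 3.0]
        df = pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3,
                "neurite_length": ratios * 2,
                "cell_width": [1.0] * 6,
            }
        )
        summary, tests = differentiation_stats(df)
        assert tests.loc[0, "t"] == pytest.approx(0.0)
        assert tests.loc[0, "p"] == pytest.approx(1.0)

    def test_sem_matches_definition(self, rng):
        x = rng.uniform(1, 10, 30)
        df = pd.DataFrame(
            {"group": "a", "neurite_length": x, "cell_width": 1.0}
        )
        df2 = pd.DataFrame(
            {"group": "b", "neurite_length": rng.uniform(1, 10, 30), "cell_width": 1.0}
        )
        summary, _ = differentiation_stats(pd.concat([df, df2], ignore_index=True))
        row = summary[summary.group == "a"].iloc[0]
        assert row["sem"] == pytest.approx(x.std(ddof=1) / np.sqrt(30))

    def test_nonpositive_width_rejected(self):
        df = pd.DataFrame(
            {"group": ["a", "a"], "neurite_length": [1, 2], "cell_width": [1, 0]}
        )
        with pytest.raises(ValidationError):
            differentiation_stats(df)

    def test_small_group_rejected(self):
        df = pd.DataFrame(
            {"group": ["a", "b", "b"], "neurite_length": [1, 2, 3],
             "cell_width": [1, 1, 1]}
        )
        with pytest.raises(ValidationError):
            differentiation_stats(df)
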