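"""RBG scoring, threshold calibration, classification, cross-resistance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from phage_evo.resistance_scoring import (
    ClusterResult,
    InteractionMeasurement,
    ThresholdCalibration,
    UndefinedRBGError,
    UnimodalityError,
    build_rbg_matrix,
    calibrate_thresholds,
    classify_resistance,
    cluster_rbg_matrix,
    compute_rbg,
    cross_resistance_summary,
    kde_valley,
)
from phage_evo.synthetic_data import (
    RBGMixtureParams,
    SimulationConfig,
    gen_interaction_rbg,
)

PUBLISHED = ThresholdCalibration(
    peak_low=0.034, peak_high=0.977, valley=0.511,
    ci_low=0.49, ci_high=0.53, class_bounds=(0.49, 0.53),
    n_boot=1000, bandwidth=0.1,
)


def measurement(a0p, a8p, a0c, a8c, strain="s", phage="p"):
    return InteractionMeasurement(
        strain_id=strain, selecting_phage=phage, focal_phage=phage,
        replicate=1, abs_start_phage=a0p, abs_end_phage=a8p,
        abs_start_ctrl=a0c, abs_end_ctrl=a8c,
    )


def beta_mixture(rng, n, lo=0.034, hi=0.977, conc=60.0, w_hi=0.5):
    hi_mask = rng.random(n) < w_hi
    means = np.where(hi_mask, hi, lo)
    return rng.beta(means * conc, (1 - means) * conc)


class TestComputeRBG:
    @pytest.mark.parametrize(
        "m, expected",
        [
            (measurement(0.05, 0.85, 0.05, 0.85), 1.0),   # equal growth
            (measurement(0.05, 0.05, 0.05, 0.85), 0.0),   # no growth under phage
            (measurement(0.10, 0.45, 0.10, 0.80), 0.5),
        ],
    )
    def test_endpoint_ratio(self, m, expected):
        assert compute_rbg(m) == pytest.approx(expected, abs=1e-12)

    def test_negative_growth_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_rbg(measurement(0.10, 0.05, 0.05, 0.85)) == 0.0

    def test_nonpositive_control_growth_rejected(self):
        with pytest.raises(UndefinedRBGError):
            compute_rbg(measurement(0.05, 0.45, 0.85, 0.85))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.01, 100.0), st.floats(0.01, 0.95), st.floats(0.05, 1.0))
    def test_scale_invariance_of_growth_deltas(self, c, frac, ctrl_growth):
        base = measurement(0.05, 0.05 + frac * ctrl_growth, 0.05, 0.05 + ctrl_growth)
        scaled = measurement(
            0.05, 0.05 + c * frac * ctrl_growth, 0.05, 0.05 + c * ctrl_growth
        )
        assert compute_rbg(scaled) == pytest.approx(compute_rbg(base), rel=1e-9)


class TestBuildMatrix:
    def _measurements(self, skip_cell=None):
        out = []
        for s in ("s1", "s2"):
            for p in ("p1", "p2"):
                if (s, p) == skip_cell:
                    continue
                for rep in (1, 2, 3):
                    out.append(InteractionMeasurement(
                        strain_id=s, selecting_phage="p1", focal_phage=p,
                        replicate=rep, abs_start_phage=0.05,
                        abs_end_phage=0.05 + 0.2 * rep,
                        abs_start_ctrl=0.05, abs_end_ctrl=0.85,
                    ))
        return out

    def test_replicates_averaged(self):
        matrix = build_rbg_matrix(self._measurements(), {"p1": "core", "p2": "core"})
        assert matrix.values.shape == (2, 2)
        assert matrix.values.at["s1", "p1"] == pytest.approx((0.2 + 0.4 + 0.6) / 0.8 / 3)

    def test_missing_cell_is_nan_not_zero(self):
        matrix = build_rbg_matrix(
            self._measurements(skip_cell=("s2", "p2")), {"p1": "c", "p2": "c"}
        )
        assert np.isnan(matrix.values.at["s2", "p2"])

    def test_duplicate_replicate_rejected(self):
        ms = self._measurements()
        with pytest.raises(ValueError, match="duplicate"):
            build_rbg_matrix(ms + [ms[0]], {})


class TestCalibration:
    def test_bimodal_mixture_valley_between_peaks_matches_dense_grid(self):
        rng = np.random.default_rng(11)
        values = beta_mixture(rng, 1440)
        cal = calibrate_thresholds(values, n_boot=100, seed=11)
        assert cal.peak_low < cal.valley < cal.peak_high
        # dense-grid argmin oracle over the same KDE between the two peaks
        kde = sps.gaussian_kde(values, bw_method="silverman")
        dense = np.linspace(cal.peak_low, cal.peak_high, 20001)
        oracle = dense[np.argmin(kde(dense))]
        coarse_spacing = (values.max() - values.min() + 6 * cal.bandwidth) / 511
        assert abs(cal.valley - oracle) <= coarse_spacing
        assert cal.ci_low <= cal.valley <= cal.ci_high
        assert cal.class_bounds[0] <= cal.class_bounds[1]

    def test_unimodal_sample_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(UnimodalityError):
            calibrate_thresholds(0.9 + 0.01 * rng.standard_normal(200), n_boot=10)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            calibrate_thresholds(np.linspace(0, 1, 20))

    def test_valley_strictly_between_generating_modes_20_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            valley = kde_valley(beta_mixture(rng, 1440))
            assert 0.034 < valley < 0.977

    def test_bootstrap_ci_width_shrinks_with_n(self):
        widths = {200: [], 2000: []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            for n in widths:
                cal = calibrate_thresholds(
                    beta_mixture(rng, n), n_boot=60, seed=seed
                )
                widths[n].append(cal.ci_high - cal.ci_low)
        assert np.median(widths[2000]) < np.median(widths[200])


class TestClassification:
    @pytest.mark.parametrize(
        "rbg, expected",
        [(0.49, "sensitive"), (0.51, "intermediate"), (0.53, "resistant"),
         (0.0, "sensitive"), (1.2, "resistant")],
    )
    def test_published_boundaries_inclusive(self, rbg, expected):
        assert classify_resistance(rbg, PUBLISHED) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 1.5), st.floats(0, 1.5))
    def test_monotone_in_rbg(self, a, b):
        order = {"sensitive": 0, "intermediate": 1, "resistant": 2}
        lo, hi = sorted((a, b))
        assert (order[classify_resistance(lo, PUBLISHED)]
                <= order[classify_resistance(hi, PUBLISHED)])


class TestCrossResistance:
    def _uniform_matrix(self, rbg_value):
        ms = []
        phages = {"p_core": "core", "p_O": "O-antigen"}
        for i, sel in enumerate(["p_core", "p_core", "p_O"]):
            for p in phages:
                ms.append(InteractionMeasurement(
                    strain_id=f"s{i}", selecting_phage=sel, focal_phage=p,
                    replicate=1, abs_start_phage=0.05,
                    abs_end_phage=0.05 + rbg_value * 0.8,
                    abs_start_ctrl=0.05, abs_end_ctrl=0.85,
                ))
        return build_rbg_matrix(ms, phages)

    def test_all_resistant_matrix_yields_100_percent(self):
        table = cross_resistance_summary(self._uniform_matrix(0.95), PUBLISHED)
        assert (table["percent"] == 100.0).all()

    def test_focal_resistant_but_no_cross_yields_0_percent(self):
        ms = []
        phages = {"p_core": "core", "p_O": "O-antigen"}
        for i in range(3):
            for p, rbg in (("p_core", 0.95), ("p_O", 0.02)):
                ms.append(InteractionMeasurement(
                    strain_id=f"s{i}", selecting_phage="p_core", focal_phage=p,
                    replicate=1, abs_start_phage=0.05,
                    abs_end_phage=0.05 + rbg * 0.8,
                    abs_start_ctrl=0.05, abs_end_ctrl=0.85,
                ))
        table = cross_resistance_summary(build_rbg_matrix(ms, phages), PUBLISHED)
        core_to_o = table[(table.source_group == "core")
                          & (table.target_group == "O-antigen")].iloc[0]
        assert core_to_o.percent == 0.0 and core_to_o.denominator == 3

    def test_empty_denominator_flagged_not_zero(self):
        table = cross_resistance_summary(self._uniform_matrix(0.02), PUBLISHED)
        assert table["undefined"].all()
        assert table["percent"].isna().all()

    def test_numerator_bounded_by_denominator_under_both_rules(self):
        cfg = SimulationConfig(seed=5, rbg=RBGMixtureParams(n_strains=24))
        ms, _ = gen_interaction_rbg(cfg)
        receptor = {f"phage_{j}": g for j, g in enumerate(
            ["core"] * 4 + ["O-antigen"] + ["BtuB"] * 3)}
        matrix = build_rbg_matrix(ms, receptor)
        for rule in ("all", "any"):
            table = cross_resistance_summary(matrix, PUBLISHED, group_rule=rule)
            defined = table[~table.undefined]
            assert (defined.numerator <= defined.denominator).all()
            assert defined.percent.between(0, 100).all()


class TestClustering:
    def _matrix(self, rows, strains=None):
        strains = strains or [f"s{i}" for i in range(len(rows))]
        phages = [f"p{j}" for j in range(len(rows[0]))]
        values = pd.DataFrame(rows, index=strains, columns=phages, dtype=float)
        from phage_evo.resistance_scoring import RBGMatrix

        return RBGMatrix(
            strains=strains, phages=phages, values=values,
            replicate_values=pd.DataFrame(),
            receptor_of_phage={p: "core" for p in phages},
            selecting_phage_of_strain={s: phages[0] for s in strains},
        )

    def test_identical_rows_end_up_adjacent(self):
        result = cluster_rbg_matrix(
            self._matrix([[1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        )
        pos = {s: i for i, s in enumerate(result.order)}
        assert abs(pos["s0"] - pos["s2"]) == 1

    def test_permuting_rows_permutes_labels_not_topology(self):
        rows = [[1.0, 0.9, 0.1], [0.95, 1.0, 0.0], [0.0, 0.1, 1.0], [0.1, 0.0, 0.9]]
        base = cluster_rbg_matrix(self._matrix(rows))
        perm = [2, 0, 3, 1]
        permuted = cluster_rbg_matrix(
            self._matrix([rows[i] for i in perm],
                         strains=[f"s{i}" for i in perm])
        )
        # same merge heights = same topology on this non-degenerate input
        assert np.allclose(sorted(base.linkage[:, 2]), sorted(permuted.linkage[:, 2]))

    def test_planted_blocks_ordered_contiguously(self):
        rng = np.random.default_rng(0)
        archetypes = [np.array([1, 1, 0, 0, 0.0]), np.array([0, 0, 1, 1, 0.0]),
                      np.array([0.5, 0.5, 0.5, 0.5, 1.0])]
        rows, labels = [], []
        for b, arch in enumerate(archetypes):
            for _ in range(4):
                rows.append(np.clip(arch + rng.normal(0, 0.02, 5), 0, 1.2))
                labels.append(b)
        result = cluster_rbg_matrix(self._matrix(rows))
        ordered_blocks = [labels[int(s[1:])] for s in result.order]
        # each planted block occupies one contiguous run
        runs = 1 + sum(ordered_blocks[i] != ordered_blocks[i + 1]
                       for i in range(len(ordered_blocks) - 1))
        assert runs == 3

    def test_single_row_returns_trivial_ordering(self):
        result = cluster_rbg_matrix(self._matrix([[0.5, 0.5]]))
        assert result.order == ["s0"] and result.linkage is None
        assert result.note is not None

    def test_missing_cells_imputed_with_flag(self):
        m = self._matrix([[1.0, 1.0], [0.0, 0.0], [1.0, np.nan]])
        with pytest.warns(UserWarning, match="imputed"):
            result = cluster_rbg_matrix(m)
        assert result.imputed
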