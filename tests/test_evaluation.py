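"""Agreement statistics, inter-observer variability, stratified splits."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelvimetry import (
    CohortTable,
    ConfigError,
    DataError,
    LandmarkSet,
    PatientRecord,
    cohort_flow,
    crossvalidate,
    dimension_agreement,
    interobserver_mae,
    localization_errors,
    mae_summary,
    stratified_kfold,
    stratified_kfold_ids,
)
from pelvimetry.evaluation import StubTrainer
from pelvimetry.geometry import LANDMARK_LABELS


def simple_cohort(n=12, institutes=("a", "b", "c"), observer_shift=None):
    records = []
    rng = np.random.default_rng(0)
    for i in range(n):
        pts = rng.uniform(0, 150, size=(5, 3))
        ref = LandmarkSet.from_points(*pts)
        obs2 = None
        if observer_shift is not None:
            obs2 = LandmarkSet.from_points(*(pts + np.asarray(observer_shift)))
        records.append(
            PatientRecord(
                volume_id=f"v{i}",
                institute_id=institutes[i % len(institutes)],
                reference=ref,
                observer2=obs2,
            )
        )
    return CohortTable(records=records)


class TestLocalizationError:
    def test_identical_sets_zero(self, landmarks):
        errs = localization_errors(landmarks, landmarks)
        assert list(errs.values()) == pytest.approx([0.0] * 5)

    def test_uniform_shift_is_345(self, landmarks):
        shifted = landmarks.transformed(np.eye(3), (3.0, 4.0, 0.0))
        errs = localization_errors(shifted, landmarks)
        assert list(errs.values()) == pytest.approx([5.0] * 5)

    def test_no_common_landmarks_raises(self):
        a = LandmarkSet.from_points(A=(0, 0, 0))
        b = LandmarkSet.from_points(B=(0, 0, 0))
        with pytest.raises(DataError):
            localization_errors(a, b)


class TestMaeSummary:
    @pytest.mark.parametrize(
        "values,mean,sd",
        [([3, 4, 5], 4.0, 1.0), ([-2, 2], 2.0, 0.0), ([7], 7.0, 0.0)],
    )
    def test_hand_cases(self, values, mean, sd):
        m, s = mae_summary(values)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sd)

    def test_matches_two_pass_oracle(self, rng):
        v = rng.normal(0, 5, size=1000)
        m, s = mae_summary(v)
        a = np.abs(v)
        mean = sum(a) / len(a)
        var = sum((x - mean) ** 2 for x in a) / (len(a) - 1)
        assert m == pytest.approx(mean, abs=1e-9)
        assert s == pytest.approx(var**0.5, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(DataError):
            mae_summary([])


class TestDimensionAgreement:
    def test_perfect_prediction(self, rng):
        ref = rng.uniform(80, 140, size=20)
        rep = dimension_agreement(ref, ref)
        assert rep.mae == pytest.approx(0.0)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.bias == pytest.approx(0.0)
        assert rep.outlier_indices == ()

    def test_hand_computed_loa(self):
        # differences (1, -1, 1, -1): bias 0, sample SD = sqrt(4/3)
        ref = np.array([10.0, 10.0, 10.0, 10.0])
        pred = ref - np.array([1.0, -1.0, 1.0, -1.0])
        rep = dimension_agreement(pred, ref)
        assert rep.bias == pytest.approx(0.0)
        assert rep.loa_halfwidth == pytest.approx(1.96 * np.sqrt(4.0 / 3.0), abs=1e-9)
        assert rep.loa_halfwidth == pytest.approx(2.2632, abs=1e-3)

    def test_monotone_distortion_keeps_rho_not_r2(self, rng):
        ref = np.sort(rng.uniform(50, 150, size=30))
        pred = ref + 0.002 * ref**2  # strictly monotone, nonlinear
        rep = dimension_agreement(pred, ref)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.r2 < 1.0

    def test_outlier_excluded_r2_recomputation(self, rng):
        ref = rng.uniform(80, 140, size=200)
        pred = ref + rng.normal(0, 2, size=200)
        pred[:5] += 40.0  # heavy contamination
        rep = dimension_agreement(pred, ref)
        assert len(rep.outlier_indices) >= 1
        keep = np.setdiff1d(np.arange(200), rep.outlier_indices)
        ss_res = np.sum((ref[keep] - pred[keep]) ** 2)
        ss_tot = np.sum((ref[keep] - ref[keep].mean()) ** 2)
        assert rep.r2_without_outliers == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert rep.r2_without_outliers >= rep.r2

    def test_sign_convention_symmetry(self, rng):
        ref = rng.uniform(80, 140, size=50)
        pred = ref + rng.normal(1.0, 3.0, size=50)
        a = dimension_agreement(pred, ref)
        b = dimension_agreement(2 * ref - pred, ref)  # negates all differences
        assert b.bias == pytest.approx(-a.bias)
        assert b.loa_halfwidth == pytest.approx(a.loa_halfwidth)
        assert len(b.outlier_indices) == len(a.outlier_indices)

    def test_gaussian_coverage_converges_to_95(self):
        rng = np.random.default_rng(2024)
        diffs = rng.normal(0.5, 3.0, size=100_000)
        ref = rng.uniform(80, 140, size=100_000)
        rep = dimension_agreement(ref - diffs, ref)
        inside = 1.0 - len(rep.outlier_indices) / rep.n
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_constant_reference_flagged(self):
        rep = dimension_agreement([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert rep.constant_reference
        assert np.isnan(rep.r2)

    def test_too_few_pairs_raises(self):
        with pytest.raises(DataError):
            dimension_agreement([1, 2], [1, 2])


class TestInterObserver:
    def test_identical_observers_zero(self):
        cohort = simple_cohort(observer_shift=(0, 0, 0))
        assert interobserver_mae(cohort) == pytest.approx((0.0, 0.0))

    def test_uniform_5mm_shift(self):
        cohort = simple_cohort(observer_shift=(0, 0, 5.0))
        m, s = interobserver_mae(cohort)
        assert m == pytest.approx(5.0)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_matches_composition_oracle(self, rng):
        records = []
        expected = []
        for i in range(30):
            pts = rng.uniform(0, 150, size=(5, 3))
            noise = rng.normal(0, 2, size=(5, 3))
            records.append(
                PatientRecord(
                    volume_id=f"v{i}",
                    institute_id="x",
                    reference=LandmarkSet.from_points(*pts),
                    observer2=LandmarkSet.from_points(*(pts + noise)),
                )
            )
            expected.extend(np.linalg.norm(noise, axis=1))
        m, s = interobserver_mae(CohortTable(records=records))
        assert m == pytest.approx(np.mean(expected), abs=1e-9)
        assert s == pytest.approx(np.std(expected, ddof=1), abs=1e-9)

    def test_no_dual_annotation_raises(self):
        with pytest.raises(DataError):
            interobserver_mae(simple_cohort())


class TestStratifiedKFold:
    def test_single_institute_even_folds(self):
        ids = {"x": [f"p{i}" for i in range(10)]}
        plan = stratified_kfold_ids(ids, k=5, seed=0)
        assert plan.test_sizes == (2, 2, 2, 2, 2)

    def test_clinical_institute_profile_sizes(self):
        counts = (306, 489, 65, 111, 421, 80, 87, 148)
        ids = {f"inst{j}": [f"i{j}p{i}" for i in range(c)] for j, c in enumerate(counts)}
        plan = stratified_kfold_ids(ids, k=5, seed=3)
        assert sum(plan.test_sizes) == 1707
        assert set(plan.test_sizes) == {341, 342}
        all_test = [i for f in plan.folds for i in f.test_ids]
        assert len(all_test) == len(set(all_test)) == 1707
        for fold in plan.folds:
            assert len(fold.train_ids) + len(fold.test_ids) == 1707
            assert not set(fold.train_ids) & set(fold.test_ids)

    def test_deterministic_under_seed(self):
        ids = {"a": [f"a{i}" for i in range(17)], "b": [f"b{i}" for i in range(9)]}
        p1 = stratified_kfold_ids(ids, k=4, seed=11)
        p2 = stratified_kfold_ids(ids, k=4, seed=11)
        assert p1 == p2
        p3 = stratified_kfold_ids(ids, k=4, seed=12)
        assert p1 != p3

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigError):
            stratified_kfold_ids({"a": ["1", "2"]}, k=1, seed=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        profile=st.lists(st.integers(min_value=1, max_value=60), min_size=1, max_size=8),
        k=st.integers(min_value=2, max_value=6),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_partition_property_random_profiles(self, profile, k, seed):
        ids = {f"I{j}": [f"I{j}p{i}" for i in range(c)] for j, c in enumerate(profile)}
        plan = stratified_kfold_ids(ids, k=k, seed=seed)
        everyone = [i for lst in ids.values() for i in lst]
        tested = [i for f in plan.folds for i in f.test_ids]
        assert sorted(tested) == sorted(everyone)  # each patient tested once
        for inst, lst in ids.items():
            per_fold = [len(set(f.test_ids) & set(lst)) for f in plan.folds]
            assert max(per_fold) - min(per_fold) <= 1
        assert max(plan.test_sizes) - min(plan.test_sizes) <= 1


class TestCohortFlow:
    def test_staged_exclusions(self):
        flow = cohort_flow(2292, {"no sagittal T2": 248, "artifacts/incomplete": 337})
        assert flow["eligible"] == 1707


class TestCrossValidate:
    def test_ground_truth_stub_gives_zero_error(self):
        cohort = simple_cohort(n=15)
        result = crossvalidate(cohort, StubTrainer(), k=5, seed=0)
        assert result.errors["error_mm"].max() == pytest.approx(0.0)
        for rep in result.agreement.values():
            assert rep.mae == pytest.approx(0.0)
            assert rep.r2 == pytest.approx(1.0)

    def test_fixed_offset_on_landmark_a(self):
        cohort = simple_cohort(n=15)
        result = crossvalidate(cohort, StubTrainer(offsets={"A": (3, 4, 0)}), k=5, seed=0)
        a_errors = result.errors.loc[result.errors["landmark"] == "A", "error_mm"]
        assert a_errors.to_numpy() == pytest.approx(np.full(15, 5.0))
        assert result.localization_mean.loc["All", "A"] == pytest.approx(5.0)
        assert result.localization_sd.loc["All", "A"] == pytest.approx(0.0, abs=1e-9)

    def test_every_patient_tested_once(self):
        cohort = simple_cohort(n=20, institutes=("a", "b", "c", "d"))
        result = crossvalidate(cohort, StubTrainer(), k=5, seed=1)
        assert sorted(result.errors["volume_id"].unique()) == sorted(cohort.ids)
        counts = result.errors.groupby("volume_id")["fold"].nunique()
        assert (counts == 1).all()

    def test_duplicate_ids_rejected(self):
        rec = simple_cohort(n=2).records
        rec[1].volume_id = rec[0].volume_id
        with pytest.raises(DataError):
            CohortTable(records=rec)
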