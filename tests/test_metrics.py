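"""Perfusion metric arithmetic, longitudinal tables, and ICC(2,1) agreement."""

import numpy as np
import pandas as pd
import pytest

from octanpa import (
    BinaryMask,
    ContractError,
    DegenerateInputError,
    ManifestError,
    PerfusionMetrics,
    VisitManifest,
    VisitRecord,
    icc_two_raters,
    ischemic_percent,
    longitudinal_table,
    vessel_density,
)

from conftest import make_mask


def icc21_anova_oracle(data):
    """ICC(2,1) via an explicit long-form two-way ANOVA decomposition."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append((i, j, data[i, j]))
    df = pd.DataFrame(rows, columns=["subject", "rater", "y"])
    grand = df.y.mean()
    ss_subj = sum(k * (df[df.subject == i].y.mean() - grand) ** 2 for i in range(n))
    ss_rater = sum(n * (df[df.rater == j].y.mean() - grand) ** 2 for j in range(k))
    ss_tot = ((df.y - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestVesselDensity:
    def test_all_vessel_is_100(self):
        assert vessel_density(make_mask(np.ones((10, 10)))) == 100.0

    def test_empty_mask_is_0(self):
        assert vessel_density(make_mask(np.zeros((10, 10)))) == 0.0

    def test_direct_count(self):
        """353 vessel pixels of 1000 → 35.3% (the scale of a typical scan)."""
        arr = np.zeros(1000, dtype=np.uint8)
        arr[:353] = 1
        assert vessel_density(make_mask(arr.reshape(25, 40))) == pytest.approx(35.3)

    def test_requires_vessel_role(self):
        with pytest.raises(ContractError):
            vessel_density(make_mask(np.ones((4, 4)), role="large_vessel"))


class TestIschemicPercent:
    @pytest.mark.parametrize(
        "area,expected,ndigits",
        [
            (15.40, 11.4, 1),
            (8.50, 6.3, 1),
            (10.92, 8.1, 1),
            (13.71, 10.2, 1),
            (8.63, 6.39, 2),
            (7.03, 5.2, 1),
            (0.0, 0.0, 1),
        ],
    )
    def test_widefield_scan_percentages(self, area, expected, ndigits):
        """mm² → % arithmetic on the 15 × 9 mm widefield scan field."""
        assert round(ischemic_percent(area, (9.0, 15.0)), ndigits) == expected

    def test_area_exceeding_scan_rejected(self):
        with pytest.raises(ContractError):
            ischemic_percent(200.0, (9.0, 15.0))

    def test_negative_area_rejected(self):
        with pytest.raises(ContractError):
            ischemic_percent(-1.0, (9.0, 15.0))


def _metrics(pid, tp, area, plexus="SCP", vd=35.0, eye="OD"):
    return PerfusionMetrics(
        patient_id=pid,
        eye=eye,
        plexus=plexus,
        timepoint=tp,
        ischemic_area_mm2=area,
        ischemic_percent=100 * area / 135.0,
        vessel_density_percent=vd,
        n_clusters=1,
    )


def _manifest(keys):
    return VisitManifest(
        records=tuple(
            VisitRecord(pid, eye, plexus, tp, image_path=f"{pid}_{tp}.tif")
            for (pid, eye, plexus, tp) in keys
        )
    )


class TestLongitudinalTable:
    def test_two_patients_two_timepoints_hand_arithmetic(self):
        """Areas {10, 20} at T0 and {5, 15} at T1: means 15/10, SD 7.07, Δ −5."""
        keys = [("P1", "OD", "SCP", "T0"), ("P2", "OD", "SCP", "T0"),
                ("P1", "OD", "SCP", "T1"), ("P2", "OD", "SCP", "T1")]
        results = {
            ("P1", "OD", "SCP", "T0"): _metrics("P1", "T0", 10.0),
            ("P2", "OD", "SCP", "T0"): _metrics("P2", "T0", 20.0),
            ("P1", "OD", "SCP", "T1"): _metrics("P1", "T1", 5.0),
            ("P2", "OD", "SCP", "T1"): _metrics("P2", "T1", 15.0),
        }
        out = longitudinal_table(_manifest(keys), results)
        s = out["summary"].set_index("timepoint")
        assert s.loc["T0", "ischemic_area_mm2_mean"] == pytest.approx(15.0)
        assert s.loc["T1", "ischemic_area_mm2_mean"] == pytest.approx(10.0)
        assert s.loc["T0", "ischemic_area_mm2_sd"] == pytest.approx(7.0710678, rel=1e-6)
        assert s.loc["T1", "ischemic_area_mm2_sd"] == pytest.approx(7.0710678, rel=1e-6)
        assert s.loc["T1", "ischemic_area_mm2_change_mean"] == pytest.approx(-5.0)
        assert np.isnan(s.loc["T0", "ischemic_area_mm2_change_mean"])

    def test_single_record_sd_missing(self):
        keys = [("P1", "OD", "SCP", "T0")]
        out = longitudinal_table(
            _manifest(keys), {keys[0]: _metrics("P1", "T0", 12.0)}
        )
        assert len(out["rows"]) == 1
        assert np.isnan(out["summary"]["ischemic_area_mm2_sd"].iloc[0])

    def test_empty_results_rejected(self):
        with pytest.raises(ManifestError):
            longitudinal_table(_manifest([("P1", "OD", "SCP", "T0")]), {})

    def test_group_means_recompute_from_rows(self):
        """Conservation: summary means equal the mean of the matching rows."""
        rng = np.random.default_rng(0)
        keys, results = [], {}
        for pid in ("P1", "P2", "P3"):
            for tp in ("T0", "T1", "T2"):
                k = (pid, "OD", "DCP", tp)
                keys.append(k)
                results[k] = _metrics(pid, tp, float(rng.uniform(5, 20)), plexus="DCP")
        out = longitudinal_table(_manifest(keys), results)
        for _, srow in out["summary"].iterrows():
            sel = out["rows"][
                (out["rows"].plexus == srow.plexus) & (out["rows"].timepoint == srow.timepoint)
            ]
            assert srow["ischemic_area_mm2_mean"] == pytest.approx(sel.ischemic_area_mm2.mean())


class TestICC:
    def test_identical_raters_give_one(self):
        data = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc_two_raters(data).icc == pytest.approx(1.0)

    def test_small_matrix_matches_anova_oracle(self):
        data = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc_two_raters(data).icc == pytest.approx(icc21_anova_oracle(data), rel=1e-12)

    def test_random_matrices_match_anova_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            data = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
            assert icc_two_raters(data).icc == pytest.approx(icc21_anova_oracle(data), rel=1e-10)

    def test_cross_check_against_pingouin(self):
        """Independent route: pingouin's ICC2 on long-form data."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        data = rng.normal(size=(12, 2)) + 2.0 * rng.normal(size=(12, 1))
        long = pd.DataFrame(
            [(i, j, data[i, j]) for i in range(12) for j in range(2)],
            columns=["subject", "rater", "y"],
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="y")
        # two-way random, absolute agreement, single measures: labelled
        # "ICC2" or "ICC(A,1)" depending on the pingouin version
        sel = ref[ref.Type.isin(["ICC2", "ICC(A,1)"])]
        icc2 = float(sel["ICC"].iloc[0])
        assert icc_two_raters(data).icc == pytest.approx(icc2, rel=1e-6)

    def test_antithetic_rater_negative(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        data = np.column_stack([x, -x])
        assert icc_two_raters(data).icc < 0

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1))
        a = icc_two_raters(data).icc
        b = icc_two_raters(3.0 * data - 7.0).icc
        assert a == pytest.approx(b, rel=1e-10)

    def test_zscore_pooling_of_two_metrics(self):
        """Pooled multi-metric ICC z-scores each metric before stacking."""
        rng = np.random.default_rng(5)
        m1 = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1))
        m2 = 1000.0 * (rng.normal(size=(6, 2)) + rng.normal(size=(6, 1)))
        rep = icc_two_raters({"area": m1, "density": m2}, normalize=True)
        z = lambda m: (m - m.mean()) / m.std(ddof=1)
        expected = icc_two_raters(np.vstack([z(m1), z(m2)])).icc
        assert rep.icc == pytest.approx(expected, rel=1e-12)
        assert rep.metric_names == ("area", "density")
        assert rep.n_subjects == 12

    def test_zero_subject_variance_degenerate(self):
        data = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DegenerateInputError):
            icc_two_raters(data)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ContractError):
            icc_two_raters(np.array([[1.0, 2.0], [3.0, 4.0]]))
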