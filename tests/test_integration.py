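"""Antigen classification, antibody uid assignment, centring, integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from crossrppa.exceptions import AlignmentError, AnnotationError
from crossrppa.integration import (
    annotate_panels,
    assign_antibody_uids,
    classify_antigens,
    integrate,
    median_centre,
)
from crossrppa.processing import ProcessedIntensityMatrix

from .conftest import integrate_study


class TestClassify:
    def test_isoform_pair_merged_by_synonym_rule(self):
        out = classify_antigens({"ab": ["Erk1", "Erk1/2"]}, {"Erk1": "Erk1/2"})
        assert out["ab"] == "Erk1/2"

    def test_single_target_is_identity(self):
        out = classify_antigens({"ab": ["Akt_pSer473"]})
        assert out["ab"] == "Akt_pSer473"

    def test_distinct_phospho_sites_stay_distinct(self):
        out = classify_antigens({"a1": ["mTOR_pS2448"], "a2": ["mTOR_pS2481"]})
        assert out["a1"] != out["a2"]

    def test_unresolved_multi_target_rejected(self):
        with pytest.raises(AnnotationError, match="synonym"):
            classify_antigens({"ab": ["Akt", "Erk1", "Src"]})

    def test_empty_target_list_rejected(self):
        with pytest.raises(AnnotationError):
            classify_antigens({"ab": []})


class TestUids:
    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["platform_id", "antibody_id", "antigen_class",
                           "supplier_ref", "phospho_site"]
        )

    def test_three_distinct_antibodies_enumerated_a_b_c(self):
        ann = self._ann(
            [("p1", "x", "Her2", "r2", ""), ("p2", "y", "Her2", "r1", ""),
             ("p3", "z", "Her2", "r3", "")]
        )
        out = assign_antibody_uids(ann)
        by_ref = dict(zip(out["supplier_ref"], out["antibody_uid"]))
        assert by_ref == {"r1": "Her2_a", "r2": "Her2_b", "r3": "Her2_c"}

    def test_shared_catalogue_antibody_shares_uid_across_platforms(self):
        ann = self._ann(
            [("p1", "x", "Erk1/2", "cat-1", ""), ("p2", "y", "Erk1/2", "cat-1", "")]
        )
        out = assign_antibody_uids(ann)
        assert out["antibody_uid"].nunique() == 1
        assert len(out) == 2

    def test_shuffled_input_gives_identical_uids(self, rng):
        ann = self._ann(
            [(f"p{i%3}", f"ab{i}", "Akt", f"ref{i}", "") for i in range(8)]
        )
        out1 = assign_antibody_uids(ann)
        shuffled = ann.sample(frac=1, random_state=3).reset_index(drop=True)
        out2 = assign_antibody_uids(shuffled)
        m1 = dict(zip(out1["supplier_ref"], out1["antibody_uid"]))
        m2 = dict(zip(out2["supplier_ref"], out2["antibody_uid"]))
        assert m1 == m2

    def test_conflicting_phospho_site_rejected(self):
        ann = self._ann(
            [("p1", "x", "Akt", "r1", "S473"), ("p2", "y", "Akt", "r1", "T308")]
        )
        with pytest.raises(AnnotationError, match="phospho"):
            assign_antibody_uids(ann)


class TestMedianCentre:
    def test_odd_length_column(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert median_centre(m)["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_column(self):
        m = pd.DataFrame({"a": [5.0, 5.0, 5.0]})
        assert median_centre(m)["a"].tolist() == [0.0, 0.0, 0.0]

    def test_missing_values_carried(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        out = median_centre(m)
        assert out["a"].tolist()[0] == -1.0
        assert np.isnan(out["a"].tolist()[1])
        assert out["a"].tolist()[2] == 1.0

    def test_all_missing_column_dropped_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="all-missing"):
            out = median_centre(m)
        assert list(out.columns) == ["a"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(float, (5, 3), elements=st.floats(-100, 100)))
    def test_centring_is_idempotent(self, x):
        m = pd.DataFrame(x)
        once = median_centre(m)
        twice = median_centre(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def _matrix(platform, samples, columns, values):
    df = pd.DataFrame(values, index=samples, columns=columns, dtype=float)
    return ProcessedIntensityMatrix(
        values=df, platform_id=platform, method="dilution_fit",
        qc=pd.DataFrame("", index=df.index, columns=df.columns),
    )


def _annotations(rows):
    ann = pd.DataFrame(
        rows, columns=["platform_id", "antibody_id", "antigen_class", "supplier_ref"]
    )
    ann["phospho_site"] = ""
    return assign_antibody_uids(ann)


class TestIntegrate:
    def test_default_study_has_87_columns_and_full_reading_counts(self, integrated_all):
        assert integrated_all.values.shape == (108, 87)
        assert integrated_all.manifest["n_readings"] == 9396
        per = integrated_all.manifest["platforms"]
        assert {k: v["n_columns"] for k, v in per.items()} == {
            "paris": 29, "heidelberg": 31, "edinburgh": 27,
        }

    def test_control_reading_counts(self, integrated_control):
        per = integrated_control.manifest["platforms"]
        assert {k: v["n_readings"] for k, v in per.items()} == {
            "paris": 522, "heidelberg": 558, "edinburgh": 486,
        }
        assert integrated_control.manifest["n_readings"] == 1566

    def test_class_missing_from_one_platform_is_dropped_entirely(self):
        samples = ["s1", "s2", "s3"]
        m1 = _matrix("p1", samples, ["a1", "a2"], [[1, 2], [3, 4], [5, 6]])
        m2 = _matrix("p2", samples, ["b1"], [[1], [2], [3]])
        ann = _annotations(
            [("p1", "a1", "Akt", "r1"), ("p1", "a2", "Her2", "r2"),
             ("p2", "b1", "Akt", "r3")]
        )
        out = integrate([m1, m2], ann)
        assert out.manifest["dropped_antigen_classes"] == ["Her2"]
        assert set(out.column_annotations["antigen_class"]) == {"Akt"}

    def test_post_integration_column_medians_are_zero(self, integrated_control):
        med = integrated_control.values.median(axis=0)
        assert np.allclose(med.to_numpy(), 0.0, atol=1e-9)

    def test_sample_mismatch_raises_alignment_error(self):
        m1 = _matrix("p1", ["s1", "s2"], ["a1"], [[1], [2]])
        m2 = _matrix("p2", ["s1", "s3"], ["b1"], [[1], [2]])
        ann = _annotations([("p1", "a1", "Akt", "r1"), ("p2", "b1", "Akt", "r2")])
        with pytest.raises(AlignmentError, match="s3"):
            integrate([m1, m2], ann)

    def test_platform_order_does_not_change_column_set(self, study_moderate):
        a = integrate_study(study_moderate)
        import dataclasses

        from crossrppa.integration import annotate_panels, integrate as _integrate
        from crossrppa.synthetic import DEFAULT_SYNONYMS

        from .conftest import process_study

        mats = process_study(study_moderate)
        ann = annotate_panels(study_moderate.raw_annotations, DEFAULT_SYNONYMS)
        b = _integrate(list(reversed(mats)), ann)
        assert set(a.values.columns) == set(b.values.columns)
        pd.testing.assert_frame_equal(
            a.values[sorted(a.values.columns)], b.values[sorted(b.values.columns)]
        )

    def test_control_median_centring_switch(self, study_moderate):
        ctrl = study_moderate.sample_table.query(
            "treatment == 'DMSO' and timepoint_min == 20"
        ).index
        from crossrppa.integration import annotate_panels, integrate as _integrate
        from crossrppa.synthetic import DEFAULT_SYNONYMS

        from .conftest import process_study

        mats = process_study(study_moderate)
        ann = annotate_panels(study_moderate.raw_annotations, DEFAULT_SYNONYMS)
        out = _integrate(mats, ann, centring_samples=list(ctrl))
        med = out.values.loc[ctrl].median(axis=0)
        assert np.allclose(med.to_numpy(), 0.0, atol=1e-9)
        assert out.manifest["centring_samples"] == 18
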