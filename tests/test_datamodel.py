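"""Factor catalogue structure and raw-to-axis encoding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brcarisk import (
    CLASS_LABELS,
    CLASS_VALUES,
    FACTOR_NAMES,
    FactorValueError,
    PatientRecord,
    encode_record,
)
from brcarisk.datamodel import decode_value

EXPECTED_MF_COUNTS = (5, 2, 2, 2, 3, 3, 2, 3, 4, 2, 2, 2, 2, 2, 2, 5)


class TestCatalogue:
    def test_sixteen_factors_and_43_membership_functions(self, catalogue):
        assert len(catalogue) == 16
        assert tuple(len(f.mfs) for f in catalogue) == EXPECTED_MF_COUNTS
        assert sum(len(f.mfs) for f in catalogue) == 43

    def test_age_partition(self, catalogue):
        age = catalogue[0]
        assert age.name == "age"
        assert tuple(mf.center for mf in age.mfs) == (0, 0.25, 0.5, 0.75, 1)

    def test_position_starts_above_zero(self, catalogue):
        position = next(f for f in catalogue if f.name == "position")
        assert tuple(mf.center for mf in position.mfs) == (0.25, 0.5, 0.75, 1)

    def test_centers_strictly_increasing_and_edges_are_shoulders(self, catalogue):
        for factor in catalogue:
            centers = [mf.center for mf in factor.mfs]
            assert centers == sorted(set(centers))
            for mf in factor.mfs:
                assert mf.shoulder == (mf.center in (0.0, 1.0))

    def test_class_scale_values(self):
        assert [CLASS_VALUES[c] for c in CLASS_LABELS] == [0, 0.25, 0.5, 0.75, 1]


class TestEncoding:
    @pytest.mark.parametrize(
        "factor, raw, expected",
        [
            ("age", 43, 0.75),
            ("age", 14.9, 0.0),
            ("age", 60, 1.0),
            ("sex", "Female", 1.0),
            ("tumour_size_cm", 17.5, 0.0),
            ("tumour_size_cm", 30, 0.5),
            ("n_affected_family", 1, 0.5),
            ("position", "Both Breast", 1.0),
            ("grade", "Grade 2", 0.5),
            ("classification", "Likely Pathogenic", 0.75),
        ],
    )
    def test_raw_values_map_to_their_category_center(
        self, catalogue, factor, raw, expected
    ):
        record = PatientRecord.from_values(**{factor: raw})
        enc = encode_record(record, catalogue)
        i = FACTOR_NAMES.index(factor)
        assert enc.mask[i]
        assert enc.values[i] == pytest.approx(expected)

    def test_missing_entries_are_masked(self, catalogue):
        record = PatientRecord.from_values(age=43)
        enc = encode_record(record, catalogue)
        assert enc.mask.sum() == 1
        assert not enc.mask[FACTOR_NAMES.index("tumour_size_cm")]

    def test_unknown_category_names_the_factor(self, catalogue):
        record = PatientRecord.from_values(position="Elbow")
        with pytest.raises(FactorValueError, match="position"):
            encode_record(record, catalogue)

    def test_negative_age_rejected(self, catalogue):
        record = PatientRecord.from_values(age=-3)
        with pytest.raises(FactorValueError, match="age"):
            encode_record(record, catalogue)

    def test_class_label_maps_to_class_value(self, catalogue):
        record = PatientRecord.from_values(class_label="Pathogenic")
        assert encode_record(record, catalogue).class_value == 1.0

    def test_synonymous_labels_accepted(self, catalogue):
        # the published subject table writes "Yes"/"No" for gene status
        record = PatientRecord.from_values(brca2="Yes", lymph_node="No")
        enc = encode_record(record, catalogue)
        assert enc.values[FACTOR_NAMES.index("brca2")] == 1.0
        assert enc.values[FACTOR_NAMES.index("lymph_node")] == 0.0


def test_catalogue_config_round_trip_and_geometry_override(catalogue, tmp_path):
    """The catalogue serializes to a config file, reloads identically,
    and edited half-widths take effect on reload."""
    from brcarisk.datamodel import load_catalogue, save_catalogue

    path = tmp_path / "catalogue.yaml"
    save_catalogue(path, catalogue)
    loaded = load_catalogue(path)
    assert [f.name for f in loaded] == list(FACTOR_NAMES)
    assert all(
        [m.center for m in a.mfs] == [m.center for m in b.mfs]
        and [m.half_width for m in a.mfs] == [m.half_width for m in b.mfs]
        for a, b in zip(catalogue, loaded)
    )
    text = path.read_text().replace("half_width: 0.25", "half_width: 0.4")
    path.write_text(text)
    widened = load_catalogue(path)
    assert widened[0].mfs[1].half_width == 0.4


@given(data=st.data())
def test_categorical_encoding_round_trips_and_is_idempotent(data):
    """Every category of every categorical factor encodes onto exactly
    one MF center and decodes back to its canonical label."""
    from brcarisk import build_catalogue

    catalogue = build_catalogue()
    factor = data.draw(
        st.sampled_from([f for f in catalogue if f.kind == "categorical"])
    )
    mf = data.draw(st.sampled_from(list(factor.mfs)))
    record = PatientRecord.from_values(**{factor.name: mf.label})
    enc1 = encode_record(record, catalogue)
    enc2 = encode_record(record, catalogue)
    i = [f.name for f in catalogue].index(factor.name)
    assert enc1.values[i] == mf.center
    assert np.array_equal(enc1.values, enc2.values)
    assert decode_value(factor, enc1.values[i]) == mf.label
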