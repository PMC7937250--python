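"""Parsing, filtering and replicate merging of activity exports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casel.curation import (
    ActivityRecord,
    curate,
    filter_primary_sulfonamide,
    filter_records,
    merge_replicates,
    parse_activity_export,
)

HEADER = ("molecule_chembl_id,canonical_smiles,standard_type,"
          "standard_relation,standard_value,standard_units,target_chembl_id\n")


def _record(value=10.0, relation="=", units="nM", endpoint="Ki",
            target="CHEMBL205", smiles="NS(=O)(=O)c1ccccc1", cid="C1"):
    return ActivityRecord(
        compound_id=cid, smiles=smiles, target_id=target,
        endpoint_type=endpoint, relation=relation, value=value, units=units,
    )


class TestParse:
    def test_direct_field_mapping(self, tmp_path):
        path = tmp_path / "export.csv"
        path.write_text(
            HEADER + 'CHEMBLX,NS(=O)(=O)c1ccccc1,Ki,=,12,nM,CHEMBL205\n'
        )
        records, warnings = parse_activity_export(path)
        assert warnings == []
        (r,) = records
        assert r.compound_id == "CHEMBLX"
        assert r.endpoint_type == "Ki"
        assert r.relation == "=" and r.value == 12.0 and r.units == "nM"
        assert not r.censored

    def test_unparseable_value_excluded_with_line_number(self, tmp_path):
        path = tmp_path / "export.csv"
        path.write_text(
            HEADER
            + 'A,C,Ki,=,n/a,nM,CHEMBL205\n'
            + 'B,C,Ki,=,5,nM,CHEMBL205\n'
        )
        records, warnings = parse_activity_export(path)
        assert [r.compound_id for r in records] == ["B"]
        assert len(warnings) == 1 and "line 2" in warnings[0]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        records, warnings = parse_activity_export(path)
        assert records == [] and warnings == []

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "export.csv"
        path.write_text("molecule_chembl_id,canonical_smiles\nA,C\n")
        with pytest.raises(ValueError, match="standard_type"):
            parse_activity_export(path)


class TestFilterRecords:
    def test_unit_endpoint_relation_target_rules(self):
        records = [
            _record(units="uM"),            # wrong unit
            _record(endpoint="Kd"),         # wrong endpoint
            _record(relation="<"),          # wrong relation
            _record(target="CHEMBL1"),      # wrong target
            _record(relation=">"),          # censored but kept
            _record(endpoint="IC50"),       # kept
        ]
        kept = filter_records(records)
        assert len(kept) == 2
        assert kept[0].censored and not kept[1].censored

    def test_idempotence(self, small_study):
        once = filter_records(small_study.records)
        assert filter_records(once) == once


class TestSulfonamideFilter:
    @pytest.mark.parametrize("smiles,kept", [
        ("NS(=O)(=O)c1ccccc1", True),            # benzenesulfonamide
        ("CNS(=O)(=O)c1ccccc1", False),          # N-methyl: secondary
        ("CC(=O)Nc1nnc(s1)S(N)(=O)=O", True),    # acetazolamide
        ("NS(=O)(=O)O", False),                  # S not bound to carbon
    ])
    def test_substructure_rule(self, smiles, kept):
        out, _ = filter_primary_sulfonamide([_record(smiles=smiles)])
        assert (len(out) == 1) == kept

    def test_idempotence_and_canonicalisation(self):
        records = [_record(smiles="NS(=O)(=O)c1ccccc1"),
                   _record(smiles="O=S(=O)(N)c1ccccc1", cid="C2")]
        once, _ = filter_primary_sulfonamide(records)
        twice, _ = filter_primary_sulfonamide(once)
        assert twice == once
        assert once[0].smiles == once[1].smiles  # same canonical form

    def test_unparseable_smiles_warned_and_all_bad_is_error(self):
        out, warnings = filter_primary_sulfonamide(
            [_record(), _record(smiles="not_a_smiles", cid="C2")]
        )
        assert len(out) == 1 and len(warnings) == 1
        with pytest.raises(ValueError, match="column mapping"):
            filter_primary_sulfonamide([_record(smiles="garbage")])


class TestMergeReplicates:
    def _merge_values(self, values, censored_flags=None):
        censored_flags = censored_flags or [False] * len(values)
        records = [
            _record(value=v, relation=">" if c else "=")
            for v, c in zip(values, censored_flags)
        ]
        return merge_replicates(records)

    def test_consistent_group_keeps_mean(self):
        kept, discarded = self._merge_values([10.0, 10.5, 9.5])
        assert discarded == []
        (a,) = kept
        assert a.activity_nM == pytest.approx(10.0)
        assert a.merge_rule == "mean_kept" and a.n_records == 3

    def test_large_conflicting_group_uses_mode(self):
        kept, discarded = self._merge_values([1, 1, 1, 1, 100, 1])
        (a,) = kept
        assert a.activity_nM == 1.0 and a.merge_rule == "mode_replaced"

    def test_small_conflicting_group_discarded(self):
        kept, discarded = self._merge_values([1.0, 100.0])
        assert kept == [] and discarded == [("C1", "hCA_II")]

    def test_single_record_passthrough(self):
        kept, _ = self._merge_values([42.0])
        assert kept[0].activity_nM == 42.0 and kept[0].merge_rule == "single"

    def test_censored_flag_semantics(self):
        all_cens, _ = self._merge_values([2000.0, 2100.0], [True, True])
        assert all_cens[0].censored and all_cens[0].any_censored
        mixed, _ = self._merge_values([2000.0, 2100.0], [True, False])
        assert not mixed[0].censored and mixed[0].any_censored

    @given(st.lists(st.floats(0.1, 1e6), min_size=1, max_size=4))
    def test_small_groups_agree_with_brute_force_rule(self, values):
        """On groups of <= 4 values the decision matches the direct SD/mean rule."""
        kept, discarded = self._merge_values(values)
        arr = np.asarray(values)
        if len(values) == 1:
            expect_kept, expect_value = True, values[0]
        else:
            sd, mean = arr.std(), arr.mean()
            expect_kept = sd < 0.20 * mean  # n <= 5: no mode rescue
            expect_value = mean
        assert (len(kept) == 1) == expect_kept
        assert len(kept) + len(discarded) == 1  # totality
        if expect_kept:
            assert kept[0].activity_nM == pytest.approx(expect_value)

    def test_no_value_invention(self, small_study):
        from casel.curation import _round_sig
        kept, _ = merge_replicates(filter_records(small_study.records))
        by_group = {}
        for r in filter_records(small_study.records):
            by_group.setdefault((r.compound_id, r.target_id), []).append(r.value)
        from casel.curation import DEFAULT_TARGET_MAP
        for a in kept:
            target = next(k for k, v in DEFAULT_TARGET_MAP.items() if v == a.isoform)
            values = by_group[(a.compound_id, target)]
            allowed = set(values) | {np.mean(values)} | {_round_sig(v) for v in values}
            assert any(a.activity_nM == pytest.approx(v) for v in allowed)


def test_curate_end_to_end_unique_groups(small_export):
    frame, report = curate(small_export)
    assert report.n_compound_activities == len(frame)
    # exactly one curated activity per compound x isoform
    assert not frame.duplicated(["compound_id", "isoform"]).any()
    assert (frame.activity_nM > 0).all()
    assert report.n_groups == report.n_compound_activities + report.n_groups_discarded
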