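import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtquant.errors import DataError
from vtquant.formats_io import Contig, ContigSet, MappingProfile, write_quant_table
from vtquant.quantify import (
    compare_datasets,
    compute_contig_rpkm,
    compute_erpkm,
    compute_etpm,
    compute_rc,
    quantify_dataset,
)
from vtquant.virtual_reference import VirtualReference, VirtualTranscript


def _make_vref(spec: dict[str, list[tuple[str, int]]]) -> tuple[VirtualReference, ContigSet]:
    """spec: vt_id -> [(contig_id, length), ...]"""
    contigs = ContigSet(
        Contig(id=cid, length=ln) for members in spec.values() for cid, ln in members
    )
    transcripts = {
        vt_id: VirtualTranscript(
            vt_id=vt_id,
            subject_id=vt_id,
            member_contigs=[cid for cid, _ in members],
            total_length=sum(ln for _, ln in members),
        )
        for vt_id, members in spec.items()
    }
    return VirtualReference(transcripts=transcripts), contigs


def brute_force_quant(
    spec: dict[str, list[tuple[str, int]]], counts: dict[str, int]
) -> tuple[dict[str, float], dict[str, float]]:
    """Literal nested-sum evaluation of the eRPKM/eTPM formulas, written
    independently of the quantify module."""
    grand_reads = 0
    for members in spec.values():
        for cid, _ in members:
            grand_reads += counts.get(cid, 0)
    erpkm = {}
    rates = {}
    for vt_id, members in spec.items():
        n_sum = 0
        l_sum = 0
        for cid, ln in members:
            n_sum += counts.get(cid, 0)
            l_sum += ln
        erpkm[vt_id] = 1e9 * n_sum / (l_sum * grand_reads)
        rates[vt_id] = n_sum / l_sum
    total_rate = sum(rates.values())
    etpm = {vt_id: 1e6 * r / total_rate for vt_id, r in rates.items()}
    return erpkm, etpm


TOY_SPEC = {"A": [("c1", 1000), ("c2", 500)], "B": [("c3", 2000)]}
TOY_COUNTS = {"c1": 100, "c2": 50, "c3": 300}


class TestComputeRc:
    def test_identity_on_counts(self, toy_contigs, toy_profile):
        quants = compute_rc(toy_profile, toy_contigs)
        assert {q.contig_id: q.rc for q in quants} == {"c1": 100, "c2": 50, "c3": 300}

    def test_absent_contigs_zero(self, toy_contigs):
        profile = MappingProfile(dataset_label="d", counts={"c1": 7})
        quants = compute_rc(profile, toy_contigs)
        assert {q.contig_id: q.rc for q in quants} == {"c1": 7, "c2": 0, "c3": 0}

    def test_empty_profile_all_zero(self, toy_contigs):
        profile = MappingProfile(dataset_label="d", counts={})
        assert all(q.rc == 0 for q in compute_rc(profile, toy_contigs))


class TestContigRpkm:
    def test_hand_value(self):
        contigs = ContigSet([Contig(id="c1", length=1000)])
        profile = MappingProfile(
            dataset_label="d", counts={"c1": 100, "other": 999_900}
        )
        contigs.add(Contig(id="other", length=10))
        quants = compute_contig_rpkm(compute_rc(profile, contigs), contigs, profile)
        by_id = {q.contig_id: q.rpkm for q in quants}
        # 1e9 * 100 / (1000 * 1e6) = 100
        assert by_id["c1"] == pytest.approx(100.0)

    def test_zero_reads_zero_rpkm(self, toy_contigs):
        profile = MappingProfile(dataset_label="d", counts={"c1": 10})
        quants = compute_contig_rpkm(compute_rc(profile, toy_contigs), toy_contigs, profile)
        assert {q.contig_id: q.rpkm for q in quants}["c2"] == 0.0

    def test_scale_invariance(self, toy_contigs, toy_profile):
        a = compute_contig_rpkm(
            compute_rc(toy_profile, toy_contigs), toy_contigs, toy_profile
        )
        doubled = MappingProfile(
            dataset_label="d", counts={k: 2 * v for k, v in toy_profile.counts.items()}
        )
        b = compute_contig_rpkm(compute_rc(doubled, toy_contigs), toy_contigs, doubled)
        for qa, qb in zip(a, b):
            assert qa.rpkm == pytest.approx(qb.rpkm)

    def test_no_mapped_reads_errors(self, toy_contigs):
        profile = MappingProfile(dataset_label="d", counts={})
        with pytest.raises(DataError, match="no mapped reads"):
            compute_contig_rpkm(compute_rc(profile, toy_contigs), toy_contigs, profile)


class TestWorkedExample:
    """VT A: 1000 bp/100 reads + 500 bp/50 reads; VT B: 2000 bp/300 reads."""

    def test_erpkm_hand_values(self, toy_vref, toy_contigs, toy_profile):
        erpkm = compute_erpkm(toy_vref, toy_profile, toy_contigs)
        assert erpkm["A"] == pytest.approx(1e9 * 150 / (1500 * 450), rel=1e-12)
        assert erpkm["B"] == pytest.approx(1e9 * 300 / (2000 * 450), rel=1e-12)
        assert erpkm["A"] == pytest.approx(222222.222, rel=1e-6)
        assert erpkm["B"] == pytest.approx(333333.333, rel=1e-6)

    def test_etpm_hand_values(self, toy_vref, toy_contigs, toy_profile):
        etpm = compute_etpm(toy_vref, toy_profile, toy_contigs)
        assert etpm["A"] == pytest.approx(400000.0, rel=1e-12)
        assert etpm["B"] == pytest.approx(600000.0, rel=1e-12)

    def test_matches_brute_force_oracle(self, toy_vref, toy_contigs, toy_profile):
        erpkm_o, etpm_o = brute_force_quant(TOY_SPEC, TOY_COUNTS)
        erpkm = compute_erpkm(toy_vref, toy_profile, toy_contigs)
        etpm = compute_etpm(toy_vref, toy_profile, toy_contigs)
        for vt_id in erpkm_o:
            assert erpkm[vt_id] == pytest.approx(erpkm_o[vt_id], rel=1e-9)
            assert etpm[vt_id] == pytest.approx(etpm_o[vt_id], rel=1e-9)

    def test_rc_sums(self, toy_vref, toy_contigs, toy_profile):
        bundle = quantify_dataset(toy_vref, toy_profile, toy_contigs)
        assert bundle.rc_sum == {"A": 150, "B": 300}


class TestErpkmEtpmProperties:
    def test_single_vt_erpkm_is_1e9_over_length(self):
        vref, contigs = _make_vref({"A": [("c1", 1234)]})
        profile = MappingProfile(dataset_label="d", counts={"c1": 77})
        erpkm = compute_erpkm(vref, profile, contigs)
        assert erpkm["A"] == pytest.approx(1e9 / 1234, rel=1e-12)

    def test_single_vt_etpm_is_1e6(self):
        vref, contigs = _make_vref({"A": [("c1", 1234)]})
        profile = MappingProfile(dataset_label="d", counts={"c1": 3})
        assert compute_etpm(vref, profile, contigs)["A"] == pytest.approx(1e6)

    def test_zero_read_vt_gets_zero_but_stays(self):
        vref, contigs = _make_vref(TOY_SPEC)
        profile = MappingProfile(dataset_label="d", counts={"c3": 10})
        etpm = compute_etpm(vref, profile, contigs)
        assert etpm["A"] == 0.0
        assert etpm["B"] == pytest.approx(1e6)

    def test_zero_denominator_errors(self):
        vref, contigs = _make_vref(TOY_SPEC)
        profile = MappingProfile(dataset_label="dx", counts={})
        with pytest.raises(DataError, match="dx"):
            compute_erpkm(vref, profile, contigs)
        with pytest.raises(DataError, match="dx"):
            compute_etpm(vref, profile, contigs)

    def test_denominator_excludes_orphan_reads_by_default(self):
        vref, contigs = _make_vref({"A": [("c1", 1000)]})
        contigs.add(Contig(id="orph", length=500))
        profile = MappingProfile(dataset_label="d", counts={"c1": 100, "orph": 900})
        erpkm = compute_erpkm(vref, profile, contigs)
        assert erpkm["A"] == pytest.approx(1e9 * 100 / (1000 * 100), rel=1e-12)
        all_mapped = compute_erpkm(vref, profile, contigs, denominator_mode="all-mapped")
        assert all_mapped["A"] == pytest.approx(1e9 * 100 / (1000 * 1000), rel=1e-12)

    def test_split_invariance(self):
        whole, contigs_w = _make_vref({"A": [("c1", 1000)], "B": [("c3", 2000)]})
        split, contigs_s = _make_vref(
            {"A": [("c1a", 400), ("c1b", 600)], "B": [("c3", 2000)]}
        )
        p_whole = MappingProfile(dataset_label="d", counts={"c1": 100, "c3": 300})
        p_split = MappingProfile(
            dataset_label="d", counts={"c1a": 30, "c1b": 70, "c3": 300}
        )
        for fn in (compute_erpkm, compute_etpm):
            a = fn(whole, p_whole, contigs_w)
            b = fn(split, p_split, contigs_s)
            assert a["A"] == pytest.approx(b["A"], rel=1e-12)
            assert a["B"] == pytest.approx(b["B"], rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(201, 5000), st.integers(0, 10_000)),
            min_size=1,
            max_size=10,
        ),
        scale=st.integers(2, 9),
    )
    def test_scale_invariance_and_normalization(self, data, scale):
        spec = {f"V{i}": [(f"c{i}", ln)] for i, (ln, _) in enumerate(data)}
        counts = {f"c{i}": n for i, (_, n) in enumerate(data)}
        if sum(counts.values()) == 0:
            counts["c0"] = 1
        vref, contigs = _make_vref(spec)
        p1 = MappingProfile(dataset_label="d", counts=counts)
        p2 = MappingProfile(
            dataset_label="d", counts={k: scale * v for k, v in counts.items()}
        )
        etpm1 = compute_etpm(vref, p1, contigs)
        etpm2 = compute_etpm(vref, p2, contigs)
        erpkm1 = compute_erpkm(vref, p1, contigs)
        erpkm2 = compute_erpkm(vref, p2, contigs)
        assert math.isclose(sum(etpm1.values()), 1e6, rel_tol=1e-6)
        for vt_id in etpm1:
            assert math.isclose(etpm1[vt_id], etpm2[vt_id], rel_tol=1e-9)
            assert math.isclose(erpkm1[vt_id], erpkm2[vt_id], rel_tol=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_brute_force_oracle_small_m(self, data):
        """m <= 5 random references vs literal nested-sum evaluation."""
        m = data.draw(st.integers(1, 5))
        spec = {}
        counts = {}
        cid = 0
        for i in range(m):
            k = data.draw(st.integers(1, 4))
            members = []
            for _ in range(k):
                ln = data.draw(st.integers(201, 4000))
                n = data.draw(st.integers(0, 500))
                members.append((f"c{cid}", ln))
                counts[f"c{cid}"] = n
                cid += 1
            spec[f"V{i}"] = members
        if sum(counts.values()) == 0:
            counts["c0"] = 1
        vref, contigs = _make_vref(spec)
        profile = MappingProfile(dataset_label="d", counts=counts)
        erpkm_o, etpm_o = brute_force_quant(spec, counts)
        erpkm = compute_erpkm(vref, profile, contigs)
        etpm = compute_etpm(vref, profile, contigs)
        for vt_id in spec:
            assert math.isclose(erpkm[vt_id], erpkm_o[vt_id], rel_tol=1e-9)
            assert math.isclose(etpm[vt_id], etpm_o[vt_id], rel_tol=1e-9)

    def test_etpm_erpkm_consistency(self):
        vref, contigs = _make_vref(TOY_SPEC)
        profile = MappingProfile(dataset_label="d", counts=TOY_COUNTS)
        erpkm = compute_erpkm(vref, profile, contigs)
        etpm = compute_etpm(vref, profile, contigs)
        total = sum(erpkm.values())
        for vt_id in erpkm:
            assert etpm[vt_id] == pytest.approx(1e6 * erpkm[vt_id] / total, rel=1e-9)


class TestQuantifyDataset:
    def test_conservation(self):
        all_contigs = ContigSet(
            [
                Contig(id="c1", length=1000),
                Contig(id="c2", length=500),
                Contig(id="orph", length=400),
                Contig(id="tiny", length=100),
            ]
        )
        vref = VirtualReference(
            transcripts={
                "A": VirtualTranscript(
                    vt_id="A", subject_id="A", member_contigs=["c1", "c2"],
                    total_length=1500,
                )
            },
            orphan_contigs={"orph"},
            short_contigs={"tiny"},
        )
        profile = MappingProfile(
            dataset_label="d", counts={"c1": 10, "c2": 5, "orph": 3, "tiny": 2}
        )
        bundle = quantify_dataset(vref, profile, all_contigs)
        vt_reads = sum(bundle.rc_sum.values())
        other = sum(
            profile.count(c) for c in vref.orphan_contigs | vref.short_contigs
        )
        assert vt_reads + other == profile.total_mapped
        by_id = {q.contig_id: q.rc for q in bundle.contig_quants}
        assert by_id["orph"] == 3  # orphan RC still reported per contig

    def test_reads_only_on_orphans_errors(self):
        vref, contigs = _make_vref({"A": [("c1", 1000)]})
        contigs.add(Contig(id="orph", length=400))
        vref.orphan_contigs.add("orph")
        profile = MappingProfile(dataset_label="d", counts={"orph": 5})
        with pytest.raises(DataError):
            quantify_dataset(vref, profile, contigs)


class TestCompareDatasets:
    def test_depth_scaling_changes_rc_only(self):
        vref, contigs = _make_vref(TOY_SPEC)
        p1 = MappingProfile(dataset_label="d1", counts=dict(TOY_COUNTS))
        p2 = MappingProfile(
            dataset_label="d2", counts={k: 10 * v for k, v in TOY_COUNTS.items()}
        )
        table = compare_datasets(vref, [p1, p2], contigs)
        for rec in table.records:
            assert rec.rc_sum["d2"] == 10 * rec.rc_sum["d1"]
            assert rec.erpkm["d2"] == pytest.approx(rec.erpkm["d1"], rel=1e-12)
            assert rec.etpm["d2"] == pytest.approx(rec.etpm["d1"], rel=1e-12)

    def test_second_dataset_zero_on_b(self):
        vref, contigs = _make_vref(TOY_SPEC)
        p1 = MappingProfile(dataset_label="d1", counts=dict(TOY_COUNTS))
        p2 = MappingProfile(dataset_label="d2", counts={"c1": 40, "c2": 20})
        table = compare_datasets(vref, [p1, p2], contigs)
        rec_a = table.record("A")
        rec_b = table.record("B")
        assert rec_a.etpm["d2"] == pytest.approx(1e6)
        assert rec_b.etpm["d2"] == 0.0

    def test_three_profiles_accepted(self):
        vref, contigs = _make_vref(TOY_SPEC)
        profiles = [
            MappingProfile(dataset_label=f"d{i}", counts=dict(TOY_COUNTS))
            for i in range(3)
        ]
        table = compare_datasets(vref, profiles, contigs)
        assert table.dataset_labels == ["d0", "d1", "d2"]

    def test_duplicate_labels_rejected(self):
        vref, contigs = _make_vref(TOY_SPEC)
        profiles = [
            MappingProfile(dataset_label="d", counts=dict(TOY_COUNTS)),
            MappingProfile(dataset_label="d", counts=dict(TOY_COUNTS)),
        ]
        with pytest.raises(DataError, match="duplicate"):
            compare_datasets(vref, profiles, contigs)

    def test_fewer_than_two_rejected(self):
        vref, contigs = _make_vref(TOY_SPEC)
        with pytest.raises(DataError):
            compare_datasets(
                vref, [MappingProfile(dataset_label="d", counts=dict(TOY_COUNTS))], contigs
            )


class TestWriteQuantTable:
    def test_written_shape_and_round_trip(self, tmp_path):
        vref, contigs = _make_vref(TOY_SPEC)
        p1 = MappingProfile(dataset_label="d1", counts=dict(TOY_COUNTS))
        p2 = MappingProfile(dataset_label="d2", counts=dict(TOY_COUNTS))
        table = compare_datasets(vref, [p1, p2], contigs)
        path = tmp_path / "quant.tsv"
        write_quant_table(table, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        header = lines[0].split("\t")
        assert len(header) == 4 + 2 * 3
        # round-trip within printed precision (6 significant digits)
        from vtquant.cli import _read_quant_table

        back = _read_quant_table(str(path))
        for rec in table.records:
            rb = back.record(rec.vt_id)
            for label in table.dataset_labels:
                assert rb.rc_sum[label] == rec.rc_sum[label]
                assert rb.etpm[label] == pytest.approx(rec.etpm[label], rel=1e-5)

    def test_empty_table_refused(self, tmp_path):
        from vtquant.quantify import QuantTable

        with pytest.raises(DataError):
            write_quant_table(
                QuantTable(records=[], dataset_labels=["d"]), tmp_path / "q.tsv"
            )
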