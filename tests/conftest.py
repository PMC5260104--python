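import pytest

from vtquant.formats_io import Contig, ContigSet, MappingProfile
from vtquant.virtual_reference import VirtualReference, VirtualTranscript


@pytest.fixture
def toy_contigs() -> ContigSet:
    """Contigs of the worked two-VT example: 1000+500 bp in A, 2000 bp in B."""
    return ContigSet(
        [
            Contig(id="c1", length=1000),
            Contig(id="c2", length=500),
            Contig(id="c3", length=2000),
        ]
    )


@pytest.fixture
def toy_vref() -> VirtualReference:
    """VT A = {c1, c2} (total 1500 bp), VT B = {c3} (2000 bp)."""
    return VirtualReference(
        transcripts={
            "A": VirtualTranscript(
                vt_id="A", subject_id="A", member_contigs=["c1", "c2"],
                total_length=1500,
            ),
            "B": VirtualTranscript(
                vt_id="B", subject_id="B", member_contigs=["c3"], total_length=2000,
            ),
        }
    )


@pytest.fixture
def toy_profile() -> MappingProfile:
    """100 + 50 reads on VT A's members, 300 on VT B's single member."""
    return MappingProfile(
        dataset_label="d1", counts={"c1": 100, "c2": 50, "c3": 300}
    )


@pytest.fixture
def small_obo(tmp_path):
    """Diamond DAG: T0 root; T1, T2 is_a T0; T3 is_a T1 and part_of T2."""
    path = tmp_path / "small.obo"
    path.write_text(
        "format-version: 1.2\n"
        "\n"
        "[Term]\n"
        "id: GO:0000000\n"
        "name: root\n"
        "namespace: biological_process\n"
        "\n"
        "[Term]\n"
        "id: GO:0000001\n"
        "name: t1\n"
        "namespace: biological_process\n"
        "is_a: GO:0000000 ! root\n"
        "\n"
        "[Term]\n"
        "id: GO:0000002\n"
        "name: t2\n"
        "namespace: biological_process\n"
        "is_a: GO:0000000\n"
        "\n"
        "[Term]\n"
        "id: GO:0000003\n"
        "name: t3\n"
        "namespace: biological_process\n"
        "is_a: GO:0000001\n"
        "relationship: part_of GO:0000002\n"
        "\n"
    )
    return path
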