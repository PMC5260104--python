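"""RC, eRPKM and eTPM over a shared virtual reference, per dataset.

For virtual transcript x with member contigs i = 1..k_x carrying n_{x,i}
mapped reads over l_{x,i} bp:

    eRPKM_x = 1e9 * (sum_i n_{x,i}) / ((sum_i l_{x,i}) * N)
    eTPM_x  = 1e6 * rate_x / sum_t rate_t,   rate_x = sum_i n_{x,i} / sum_i l_{x,i}

where N defaults to the total reads mapped to virtual-transcript members
only ("vt-only"); pass denominator_mode="all-mapped" to use the profile's
full mapped total instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from vtquant.errors import DataError
from vtquant.formats_io import ContigSet, MappingProfile
from vtquant.virtual_reference import VirtualReference

DENOMINATOR_MODES = ("vt-only", "all-mapped")


@dataclass
class ContigQuant:
    contig_id: str
    rc: int
    rpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.rc < 0 or self.rpkm < 0:
            raise DataError(f"negative quant value for contig {self.contig_id!r}")


@dataclass
class QuantRecord:
    """Per-virtual-transcript values across datasets (keyed by dataset label)."""

    vt_id: str
    subject_id: str
    n_contigs: int
    total_length: int
    rc_sum: dict[str, int] = field(default_factory=dict)
    erpkm: dict[str, float] = field(default_factory=dict)
    etpm: dict[str, float] = field(default_factory=dict)


@dataclass
class QuantTable:
    records: list[QuantRecord]
    dataset_labels: list[str]

    def record(self, vt_id: str) -> QuantRecord:
        for rec in self.records:
            if rec.vt_id == vt_id:
                return rec
        raise KeyError(vt_id)


@dataclass
class DatasetQuant:
    """One dataset's bundle: per-contig RC/RPKM plus per-VT sums."""

    dataset_label: str
    contig_quants: list[ContigQuant]
    rc_sum: dict[str, int]
    erpkm: dict[str, float]
    etpm: dict[str, float]


def compute_rc(profile: MappingProfile, contigs: ContigSet) -> list[ContigQuant]:
    """Read count per contig; contigs absent from the profile get 0."""
    return [ContigQuant(contig_id=c.id, rc=profile.count(c.id)) for c in contigs]


def compute_contig_rpkm(
    quants: list[ContigQuant], contigs: ContigSet, profile: MappingProfile
) -> list[ContigQuant]:
    """Per-contig RPKM = 1e9 * n_j / (l_j * N), N = total mapped reads in the
    profile (all contigs, not just VT members)."""
    total = profile.total_mapped
    if total == 0:
        raise DataError(f"no mapped reads (dataset {profile.dataset_label!r})")
    return [
        ContigQuant(
            contig_id=q.contig_id,
            rc=q.rc,
            rpkm=1e9 * q.rc / (contigs.length_of(q.contig_id) * total),
        )
        for q in quants
    ]


def _vt_reads_and_lengths(
    vref: VirtualReference, profile: MappingProfile
) -> tuple[dict[str, int], dict[str, int]]:
    reads = {
        vt.vt_id: sum(profile.count(c) for c in vt.member_contigs)
        for vt in vref.transcripts.values()
    }
    lengths = {vt.vt_id: vt.total_length for vt in vref.transcripts.values()}
    return reads, lengths


def _mapped_total(
    vref: VirtualReference, profile: MappingProfile, denominator_mode: str
) -> int:
    if denominator_mode == "vt-only":
        reads, _ = _vt_reads_and_lengths(vref, profile)
        return sum(reads.values())
    if denominator_mode == "all-mapped":
        return profile.total_mapped
    raise ValueError(f"unknown denominator mode {denominator_mode!r}")


def compute_erpkm(
    vref: VirtualReference,
    profile: MappingProfile,
    contigs: ContigSet,
    denominator_mode: str = "vt-only",
) -> dict[str, float]:
    if vref.m < 1:
        raise DataError("empty virtual reference")
    reads, lengths = _vt_reads_and_lengths(vref, profile)
    total = _mapped_total(vref, profile, denominator_mode)
    if total == 0:
        raise DataError(
            f"no reads mapped to virtual reference (dataset {profile.dataset_label!r})"
        )
    return {
        vt_id: 1e9 * reads[vt_id] / (lengths[vt_id] * total) for vt_id in reads
    }


def compute_etpm(
    vref: VirtualReference, profile: MappingProfile, contigs: ContigSet
) -> dict[str, float]:
    if vref.m < 1:
        raise DataError("empty virtual reference")
    reads, lengths = _vt_reads_and_lengths(vref, profile)
    rates = {vt_id: reads[vt_id] / lengths[vt_id] for vt_id in reads}
    # sum in sorted key order so the result is invariant to input ordering
    total_rate = sum(rates[k] for k in sorted(rates))
    if total_rate == 0:
        raise DataError(
            f"no reads mapped to virtual reference (dataset {profile.dataset_label!r})"
        )
    return {vt_id: 1e6 * rate / total_rate for vt_id, rate in rates.items()}


def quantify_dataset(
    vref: VirtualReference,
    profile: MappingProfile,
    contigs: ContigSet,
    denominator_mode: str = "vt-only",
) -> DatasetQuant:
    """RC per contig plus rc_sum/eRPKM/eTPM per virtual transcript, from one
    mapping profile. Zero-read VTs keep eRPKM = eTPM = 0 and stay in the
    table; only a dataset with zero reads on the whole reference errors."""
    quants = compute_rc(profile, contigs)
    if profile.total_mapped > 0:
        quants = compute_contig_rpkm(quants, contigs, profile)
    reads, _ = _vt_reads_and_lengths(vref, profile)
    return DatasetQuant(
        dataset_label=profile.dataset_label,
        contig_quants=quants,
        rc_sum=reads,
        erpkm=compute_erpkm(vref, profile, contigs, denominator_mode),
        etpm=compute_etpm(vref, profile, contigs),
    )


def compare_datasets(
    vref: VirtualReference,
    profiles: list[MappingProfile],
    contigs: ContigSet,
    denominator_mode: str = "vt-only",
) -> QuantTable:
    """Quantify two or more datasets against the shared reference.

    The virtual-transcript universe is identical across datasets; RC columns
    reflect sequencing depth while eRPKM/eTPM are depth-normalized.
    """
    if len(profiles) < 2:
        raise DataError("need at least two mapping profiles to compare")
    labels = [p.dataset_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate dataset labels: {labels}")

    records = [
        QuantRecord(
            vt_id=vt.vt_id,
            subject_id=vt.subject_id,
            n_contigs=vt.k,
            total_length=vt.total_length,
        )
        for vt in sorted(vref.transcripts.values(), key=lambda v: v.vt_id)
    ]
    by_id = {rec.vt_id: rec for rec in records}
    for profile in profiles:
        bundle = quantify_dataset(vref, profile, contigs, denominator_mode)
        for vt_id, rec in by_id.items():
            rec.rc_sum[profile.dataset_label] = bundle.rc_sum[vt_id]
            rec.erpkm[profile.dataset_label] = bundle.erpkm[vt_id]
            rec.etpm[profile.dataset_label] = bundle.etpm[vt_id]
    return QuantTable(records=records, dataset_labels=labels)
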