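"""Best-hit selection and clustering of contigs into virtual transcripts.

Every annotatable contig (longer than the length cutoff) gets at most one
best homology hit; all contigs sharing a best-hit subject form one virtual
transcript. The resulting reference partitions the contig universe into
VT members, orphans (no qualifying hit) and short contigs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from vtquant.errors import DataError, FormatError
from vtquant.formats_io import ContigSet, HomologyHit

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG_LENGTH = 200

ORPHAN_PREFIX = "orphan:"

REF_MAP_COLUMNS = ["contig_id", "length", "status", "vt_id", "subject_id"]


def max_encodable_protein_length(contig_length: int) -> int:
    """Largest protein (in amino acids) a fully coding sequence of this
    length could encode, assuming no untranslated region."""
    if contig_length < 3:
        return 0
    return math.floor(contig_length / 3)


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    e_value: float
    bit_score: float


# map contig_id -> BestHit
BestHitMap = dict[str, BestHit]


@dataclass
class VirtualTranscript:
    """Cluster of contigs sharing one best-hit subject (vt_id == subject)."""

    vt_id: str
    subject_id: str
    member_contigs: list[str]
    total_length: int

    @property
    def k(self) -> int:
        return len(self.member_contigs)

    def __post_init__(self) -> None:
        if not self.member_contigs:
            raise DataError(f"virtual transcript {self.vt_id!r} has no members")
        if len(set(self.member_contigs)) != len(self.member_contigs):
            raise DataError(f"virtual transcript {self.vt_id!r} has duplicate members")


@dataclass
class VirtualReference:
    """Partition of the contig universe used as shared quantification reference."""

    transcripts: dict[str, VirtualTranscript]
    orphan_contigs: set[str] = field(default_factory=set)
    short_contigs: set[str] = field(default_factory=set)

    @property
    def m(self) -> int:
        return len(self.transcripts)

    def member_contig_ids(self) -> set[str]:
        out: set[str] = set()
        for vt in self.transcripts.values():
            out.update(vt.member_contigs)
        return out


def filter_annotatable(
    contigs: ContigSet, min_length: int = DEFAULT_MIN_CONTIG_LENGTH
) -> ContigSet:
    """Keep contigs strictly longer than min_length bp.

    A 200 bp contig is excluded at the default cutoff: it can encode at most
    a 66-residue protein even with no UTR, too short to annotate reliably.
    """
    if len(contigs) == 0:
        logger.warning("filter_annotatable called on an empty contig set")
    kept = ContigSet(c for c in contigs if c.length > min_length)
    if len(contigs) and len(kept) == 0:
        logger.warning("no contigs longer than %d bp", min_length)
    return kept


def short_contig_ids(
    contigs: ContigSet, min_length: int = DEFAULT_MIN_CONTIG_LENGTH
) -> set[str]:
    """Ids excluded by filter_annotatable at the same cutoff (for reporting)."""
    return {c.id for c in contigs if c.length <= min_length}


def select_best_hit(
    hits: list[HomologyHit],
    eligible: ContigSet,
    max_evalue: float | None = None,
) -> BestHitMap:
    """Pick each eligible contig's best hit.

    Ranking: maximal bit score, then minimal e-value, then lexicographically
    smallest subject id (fully deterministic). Hits for contigs outside
    `eligible` are ignored; contigs with no hit are simply absent. No
    e-value ceiling is applied unless max_evalue is given.
    """
    best: BestHitMap = {}
    for hit in hits:
        if hit.query_id not in eligible:
            continue
        if max_evalue is not None and hit.e_value > max_evalue:
            continue
        current = best.get(hit.query_id)
        candidate = BestHit(hit.subject_id, hit.e_value, hit.bit_score)
        if current is None or _hit_rank(candidate) < _hit_rank(current):
            best[hit.query_id] = candidate
    return best


def _hit_rank(h: BestHit) -> tuple[float, float, str]:
    return (-h.bit_score, h.e_value, h.subject_id)


def build_virtual_transcripts(
    best: BestHitMap,
    eligible: ContigSet,
    all_contigs: ContigSet,
    include_orphans: bool = False,
) -> VirtualReference:
    """Cluster contigs sharing a best-hit subject into virtual transcripts.

    Eligible contigs absent from `best` become orphans; with
    include_orphans=True each orphan instead becomes a singleton VT with
    vt_id "orphan:<contig_id>". Contigs below the length cutoff (in
    all_contigs but not eligible) are recorded as short.
    """
    for contig_id in best:
        if contig_id not in eligible:
            raise DataError(f"best-hit contig {contig_id!r} not in eligible set")

    by_subject: dict[str, list[str]] = {}
    for contig_id in sorted(best):
        by_subject.setdefault(best[contig_id].subject_id, []).append(contig_id)

    transcripts: dict[str, VirtualTranscript] = {}
    for subject_id in sorted(by_subject):
        members = by_subject[subject_id]
        transcripts[subject_id] = VirtualTranscript(
            vt_id=subject_id,
            subject_id=subject_id,
            member_contigs=members,
            total_length=sum(eligible.length_of(c) for c in members),
        )

    orphans = {c.id for c in eligible if c.id not in best}
    short = {c.id for c in all_contigs if c.id not in eligible}

    if include_orphans:
        for contig_id in sorted(orphans):
            vt_id = ORPHAN_PREFIX + contig_id
            transcripts[vt_id] = VirtualTranscript(
                vt_id=vt_id,
                subject_id="",
                member_contigs=[contig_id],
                total_length=eligible.length_of(contig_id),
            )
        orphans = set()

    if not transcripts:
        raise DataError("no virtual transcripts")

    return VirtualReference(
        transcripts=transcripts, orphan_contigs=orphans, short_contigs=short
    )


def write_reference_map(
    vref: VirtualReference, all_contigs: ContigSet, path: str | Path
) -> None:
    """TSV: contig_id, length, status {member|orphan|short}, vt_id, subject_id."""
    contig_to_vt = {
        c: vt.vt_id for vt in vref.transcripts.values() for c in vt.member_contigs
    }
    with open(path, "w") as fh:
        fh.write("\t".join(REF_MAP_COLUMNS) + "\n")
        for contig_id in sorted(all_contigs.ids()):
            if contig_id in contig_to_vt:
                vt_id = contig_to_vt[contig_id]
                status = "member"
                subject = vref.transcripts[vt_id].subject_id
            elif contig_id in vref.orphan_contigs:
                vt_id, status, subject = "", "orphan", ""
            else:
                vt_id, status, subject = "", "short", ""
            fh.write(
                "\t".join(
                    [
                        contig_id,
                        str(all_contigs.length_of(contig_id)),
                        status,
                        vt_id,
                        subject,
                    ]
                )
                + "\n"
            )


def read_reference_map(path: str | Path) -> tuple[VirtualReference, ContigSet]:
    """Rebuild (VirtualReference, ContigSet-of-lengths) from a reference map TSV."""
    from vtquant.formats_io import Contig

    members: dict[str, list[tuple[str, int, str]]] = {}
    orphans: set[str] = set()
    short: set[str] = set()
    contigs = ContigSet()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != REF_MAP_COLUMNS:
            raise FormatError(f"{path}: unexpected reference-map header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            contig_id, length_s, status, vt_id, subject = fields
            contigs.add(Contig(id=contig_id, length=int(length_s)))
            if status == "member":
                members.setdefault(vt_id, []).append((contig_id, int(length_s), subject))
            elif status == "orphan":
                orphans.add(contig_id)
            elif status == "short":
                short.add(contig_id)
            else:
                raise FormatError(f"{path}:{lineno}: unknown status {status!r}")
    transcripts = {
        vt_id: VirtualTranscript(
            vt_id=vt_id,
            subject_id=rows[0][2],
            member_contigs=sorted(r[0] for r in rows),
            total_length=sum(r[1] for r in rows),
        )
        for vt_id, rows in members.items()
    }
    if not transcripts:
        raise DataError(f"{path}: no virtual transcripts in reference map")
    return (
        VirtualReference(
            transcripts=transcripts, orphan_contigs=orphans, short_contigs=short
        ),
        contigs,
    )
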