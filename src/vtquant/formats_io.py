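"""Readers and writers for every standard format the pipeline touches.

FASTA contigs (Biopython), BLAST outfmt-6 hit tables, SAM/BAM or 2-column
TSV read mappings (pysam), OBO ontologies (small stanza parser over a
networkx DAG) and subject->GO association TSVs. All domain types used
downstream are defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pysam
from Bio import SeqIO

from vtquant.errors import DataError, FormatError

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """An assembled sequence: id (FASTA header token), length in bp, optional sequence."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise DataError(f"contig {self.id!r} has non-positive length {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise DataError(
                f"contig {self.id!r}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


class ContigSet:
    """Collection of contigs keyed by unique id; preserves insertion order."""

    def __init__(self, contigs: Iterable[Contig] = ()) -> None:
        self._contigs: dict[str, Contig] = {}
        for contig in contigs:
            self.add(contig)

    def add(self, contig: Contig) -> None:
        if contig.id in self._contigs:
            raise FormatError(f"duplicate contig id {contig.id!r}")
        self._contigs[contig.id] = contig

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[contig_id]

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    def ids(self) -> list[str]:
        return list(self._contigs)

    def length_of(self, contig_id: str) -> int:
        return self._contigs[contig_id].length


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    # 1-based inclusive BLAST coordinates; parsed but unused by the method
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise DataError("hit with empty query or subject id")
        if self.e_value < 0:
            raise DataError(f"negative e-value {self.e_value} for {self.query_id}")


@dataclass
class MappingProfile:
    """Per-dataset mapped-read counts per contig."""

    dataset_label: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig_id, n in self.counts.items():
            if n < 0:
                raise DataError(
                    f"negative count {n} for contig {contig_id!r} "
                    f"(dataset {self.dataset_label!r})"
                )

    @property
    def total_mapped(self) -> int:
        return sum(self.counts.values())

    def count(self, contig_id: str) -> int:
        return self.counts.get(contig_id, 0)


class GoDag:
    """GO terms with child->parent is_a/part_of edges; one root per namespace.

    Backed by a networkx DiGraph whose edges point child -> parent, so
    ancestors of a term are its graph descendants.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_term(self, term_id: str, name: str = "", namespace: str = "") -> None:
        self.graph.add_node(term_id, name=name, namespace=namespace)

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        self.graph.add_edge(child, parent, relation=relation)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def name(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("name", "")

    def namespace(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("namespace", "")

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self.graph.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from term_id along child->parent edges."""
        return nx.descendants(self.graph, term_id)

    def roots(self) -> dict[str, str]:
        """Map namespace -> root term id (term with no parents)."""
        out: dict[str, str] = {}
        for node in self.graph.nodes:
            if self.graph.out_degree(node) == 0:
                ns = self.namespace(node)
                if ns in out:
                    raise DataError(
                        f"namespace {ns!r} has multiple roots: {out[ns]}, {node}"
                    )
                out[ns] = node
        return out

    def validate(self) -> None:
        try:
            cycle = nx.find_cycle(self.graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise FormatError(f"ontology contains a cycle through {cycle[0][0]!r}")
        roots = set(self.roots().values())
        for node in self.graph.nodes:
            if node in roots:
                continue
            if not (self.ancestors(node) & roots):
                raise DataError(f"term {node!r} cannot reach a namespace root")


class GoAssociation:
    """Multimap subject_id -> set of GO term ids."""

    def __init__(self, mapping: Mapping[str, set[str]] | None = None) -> None:
        self._map: dict[str, set[str]] = {
            k: set(v) for k, v in (mapping or {}).items()
        }

    def add(self, subject_id: str, term_id: str) -> None:
        self._map.setdefault(subject_id, set()).add(term_id)

    def terms_for(self, subject_id: str) -> set[str]:
        return set(self._map.get(subject_id, set()))

    def subjects(self) -> list[str]:
        return sorted(self._map)

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_contigs(path: str | Path) -> ContigSet:
    """Read a contig FASTA into a ContigSet.

    The contig id is the header token before the first whitespace; length is
    computed from the (possibly line-wrapped) sequence. Duplicate ids and
    empty files are hard errors.
    """
    contigs = ContigSet()
    for record in SeqIO.parse(str(path), "fasta"):
        contigs.add(Contig(id=record.id, length=len(record.seq), sequence=str(record.seq)))
    if len(contigs) == 0:
        raise FormatError(f"no FASTA records in {path}")
    return contigs


def write_contigs(contigs: ContigSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            if contig.sequence is None:
                raise DataError(f"contig {contig.id!r} has no sequence to write")
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig.sequence), width):
                fh.write(contig.sequence[i : i + width] + "\n")


def read_hits(path: str | Path, dialect: str = "blast6") -> list[HomologyHit]:
    """Parse a 12-column BLAST outfmt-6 tabular hit file.

    LAST's blast-tab output uses the same 12 columns, so one parser covers
    both upstream tools. Lines starting with '#' are skipped.
    """
    if dialect != "blast6":
        raise ValueError(f"unsupported hit dialect {dialect!r}")
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable field ({exc})") from exc
    return hits


def _read_mapping_tsv(path: str | Path, dataset_label: str) -> MappingProfile:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns (contig_id<TAB>count), "
                    f"got {len(fields)}"
                )
            contig_id, raw = fields
            try:
                n = int(raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad count {raw!r}") from exc
            if n < 0:
                raise FormatError(f"{path}:{lineno}: negative count {n}")
            counts[contig_id] = counts.get(contig_id, 0) + n
    return MappingProfile(dataset_label=dataset_label, counts=counts)


def _read_mapping_sam(path: str | Path, dataset_label: str) -> MappingProfile:
    # Each mapped primary, non-supplementary record counts 1 toward its
    # reference; paired-end mates count individually.
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as samfile:
        for rec in samfile:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            ref = rec.reference_name
            counts[ref] = counts.get(ref, 0) + 1
    return MappingProfile(dataset_label=dataset_label, counts=counts)


def read_mapping(
    path: str | Path, dataset_label: str, fmt: str | None = None
) -> MappingProfile:
    """Read per-contig read counts from a SAM/BAM alignment or a 2-column TSV.

    fmt is 'sam', 'bam', 'tsv' or None to sniff from the file extension.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = {"sam": "sam", "bam": "bam"}.get(suffix.lstrip("."), "tsv")
    if fmt in ("sam", "bam"):
        return _read_mapping_sam(path, dataset_label)
    if fmt == "tsv":
        return _read_mapping_tsv(path, dataset_label)
    raise ValueError(f"unsupported mapping format {fmt!r}")


def read_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2/1.4 file into a GoDag.

    [Term] stanzas become terms; 'is_a' and 'relationship: part_of' lines
    become child->parent edges; obsolete terms are excluded. Cycles are a
    hard error.
    """
    dag = GoDag()
    edges: list[tuple[str, str, str]] = []
    stanza: dict[str, list[str]] | None = None

    def flush(current: dict[str, list[str]] | None) -> None:
        if current is None:
            return
        if current.get("is_obsolete", ["false"])[0].lower() == "true":
            return
        term_id = current.get("id", [""])[0]
        if not term_id:
            return
        dag.add_term(
            term_id,
            name=current.get("name", [""])[0],
            namespace=current.get("namespace", [""])[0],
        )
        for parent in current.get("is_a", []):
            edges.append((term_id, parent, "is_a"))
        for rel in current.get("relationship", []):
            parts = rel.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                edges.append((term_id, parts[1], "part_of"))

    with open(path) as fh:
        in_term = False
        for raw in fh:
            line = raw.split("!")[0].strip()
            if line.startswith("["):
                flush(stanza if in_term else None)
                in_term = line == "[Term]"
                stanza = {} if in_term else None
                continue
            if not in_term or not line or stanza is None:
                continue
            if ":" not in line:
                continue
            key, value = line.split(":", 1)
            stanza.setdefault(key.strip(), []).append(value.strip())
        flush(stanza if in_term else None)

    for child, parent, relation in edges:
        if parent not in dag:
            logger.warning("dropping edge to unknown/obsolete parent %s", parent)
            continue
        dag.add_edge(child, parent, relation)
    dag.validate()
    return dag


def read_associations(path: str | Path, dag: GoDag | None = None) -> GoAssociation:
    """Read subject_id<TAB>GO-term rows; duplicates collapse to a set.

    If a dag is supplied, associations to terms absent from it are dropped
    with a warning.
    """
    assoc = GoAssociation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns "
                    f"(subject_id<TAB>term_id), got {len(fields)}"
                )
            subject_id, term_id = fields
            if dag is not None and term_id not in dag:
                logger.warning(
                    "%s:%d: term %s not in ontology; association dropped",
                    path, lineno, term_id,
                )
                continue
            assoc.add(subject_id, term_id)
    return assoc


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_quant_table(table, path: str | Path) -> None:
    """Write a QuantTable as tab-delimited text (6 significant digits).

    Columns: vtranscript_id, subject_id, n_contigs, total_length, then per
    dataset <label>_rc, <label>_erpkm, <label>_etpm. Rows sorted by
    vtranscript_id.
    """
    if not table.records:
        raise DataError("refusing to write an empty quantification table")
    header = ["vtranscript_id", "subject_id", "n_contigs", "total_length"]
    for label in table.dataset_labels:
        header += [f"{label}_rc", f"{label}_erpkm", f"{label}_etpm"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in sorted(table.records, key=lambda r: r.vt_id):
            row = [rec.vt_id, rec.subject_id, str(rec.n_contigs), str(rec.total_length)]
            for label in table.dataset_labels:
                row.append(str(rec.rc_sum[label]))
                row.append(_fmt_float(rec.erpkm[label]))
                row.append(_fmt_float(rec.etpm[label]))
            fh.write("\t".join(row) + "\n")
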