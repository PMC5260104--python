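"""GO-level cumulative views over a quantified virtual reference.

Terms get a level (minimum edge distance to their namespace root along
is_a/part_of edges, or maximum with level_mode="max"); each virtual
transcript inherits its best-hit subject's GO terms, optionally closed
under the ancestor relation; per-term rows then sum RC/eRPKM/eTPM over the
virtual transcripts reaching that term.

A VT annotated to several terms at one level contributes its full value to
each of their rows, so level sums are not a partition of the total.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from vtquant.errors import DataError
from vtquant.formats_io import GoAssociation, GoDag
from vtquant.quantify import QuantTable
from vtquant.virtual_reference import ORPHAN_PREFIX, VirtualReference

logger = logging.getLogger(__name__)

# term_id -> level (namespace root = 0)
GoLevelIndex = dict[str, int]


@dataclass
class GoSummaryRow:
    term_id: str
    term_name: str
    namespace: str
    level: int
    n_vtranscripts: dict[str, int] = field(default_factory=dict)
    rc_sum: dict[str, int] = field(default_factory=dict)
    erpkm_sum: dict[str, float] = field(default_factory=dict)
    etpm_sum: dict[str, float] = field(default_factory=dict)


def assign_levels(dag: GoDag, mode: str = "min") -> GoLevelIndex:
    """Level of each term: min (default) or max number of edges on a path to
    its namespace root. BFS from each root over parent->child direction."""
    if mode not in ("min", "max"):
        raise ValueError(f"unknown level mode {mode!r}")
    levels: GoLevelIndex = {}
    for root in dag.roots().values():
        levels[root] = 0
        queue = deque([root])
        while queue:
            node = queue.popleft()
            for child in dag.children(node):
                candidate = levels[node] + 1
                if child not in levels:
                    levels[child] = candidate
                    queue.append(child)
                elif mode == "min" and candidate < levels[child]:
                    levels[child] = candidate
                    queue.append(child)
                elif mode == "max" and candidate > levels[child]:
                    levels[child] = candidate
                    queue.append(child)
    for term in dag.terms():
        if term not in levels:
            raise DataError(f"term {term!r} unreachable from any namespace root")
    return levels


def annotate_vtranscripts(
    vref: VirtualReference, assoc: GoAssociation
) -> dict[str, set[str]]:
    """Each VT inherits the GO terms of its best-hit subject; orphan
    singletons get the empty set."""
    out: dict[str, set[str]] = {}
    for vt in vref.transcripts.values():
        if vt.vt_id.startswith(ORPHAN_PREFIX) or not vt.subject_id:
            out[vt.vt_id] = set()
        else:
            out[vt.vt_id] = assoc.terms_for(vt.subject_id)
    return out


def propagate(dag: GoDag, vt_terms: dict[str, set[str]]) -> dict[str, set[str]]:
    """Close each VT's term set under the ancestor relation up to the root."""
    cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in cache:
            cache[term] = {term} | dag.ancestors(term) if term in dag else {term}
        return cache[term]

    return {
        vt_id: set().union(*(closure(t) for t in terms)) if terms else set()
        for vt_id, terms in vt_terms.items()
    }


def summarize_at_level(
    quant: QuantTable,
    vt_terms_closed: dict[str, set[str]],
    levels: GoLevelIndex,
    level: int,
    dag: GoDag,
    namespace: str | None = None,
) -> list[GoSummaryRow]:
    """One row per term at the requested level (optionally restricted to one
    namespace): how many VTs reach the term and their summed RC/eRPKM/eTPM
    per dataset. Each VT counts once per term regardless of how many of its
    annotations descend from it. Rows sorted by term_id."""
    if level < 0:
        raise ValueError("level must be >= 0")
    terms_at_level = [
        t
        for t, lv in levels.items()
        if lv == level and (namespace is None or dag.namespace(t) == namespace)
    ]
    if not terms_at_level:
        logger.warning("no GO terms at level %d", level)
        return []

    by_vt = {rec.vt_id: rec for rec in quant.records}
    rows: list[GoSummaryRow] = []
    for term in sorted(terms_at_level):
        vt_ids = sorted(
            vt_id
            for vt_id, terms in vt_terms_closed.items()
            if term in terms and vt_id in by_vt
        )
        row = GoSummaryRow(
            term_id=term,
            term_name=dag.name(term),
            namespace=dag.namespace(term),
            level=level,
        )
        for label in quant.dataset_labels:
            row.n_vtranscripts[label] = len(vt_ids)
            row.rc_sum[label] = sum(by_vt[v].rc_sum[label] for v in vt_ids)
            row.erpkm_sum[label] = sum(by_vt[v].erpkm[label] for v in vt_ids)
            row.etpm_sum[label] = sum(by_vt[v].etpm[label] for v in vt_ids)
        rows.append(row)
    return rows


def write_go_summary(
    rows: list[GoSummaryRow], dataset_labels: list[str], path: str | Path
) -> None:
    """TSV: term_id, name, namespace, level, then per dataset
    n_vtranscripts, rc_sum, erpkm_sum, etpm_sum."""
    header = ["term_id", "name", "namespace", "level"]
    for label in dataset_labels:
        header += [
            f"{label}_n_vtranscripts",
            f"{label}_rc_sum",
            f"{label}_erpkm_sum",
            f"{label}_etpm_sum",
        ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            cells = [row.term_id, row.term_name, row.namespace, str(row.level)]
            for label in dataset_labels:
                cells += [
                    str(row.n_vtranscripts[label]),
                    str(row.rc_sum[label]),
                    f"{row.erpkm_sum[label]:.6g}",
                    f"{row.etpm_sum[label]:.6g}",
                ]
            fh.write("\t".join(cells) + "\n")
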