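"""Self-contained synthetic test worlds in the exact formats the pipeline reads.

A world is a set of ground-truth transcripts with known per-condition
abundance rates, fragmented into contigs; hit rows link contigs to their
parent subject; a random is_a DAG plays the ontology; counts are emitted
either exactly (deterministic rounding of rate*length shares) or with
Poisson noise. Everything is fully determined by (params, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from vtquant.errors import DataError
from vtquant.formats_io import MappingProfile

NUCLEOTIDES = np.array(list("ACGT"))

# default condition labels used when the caller does not supply any
DEFAULT_CONDITIONS = ("cond1", "cond2")


@dataclass(frozen=True)
class ContigPlan:
    contig_id: str
    transcript_index: int
    length: int
    offset: int
    has_hit: bool
    is_short: bool


@dataclass
class FixtureTruth:
    """Ground truth for one synthetic world; fully determined by (params, seed)."""

    seed: int
    condition_labels: tuple[str, ...]
    # per transcript: (subject_id, length, {condition: rate})
    transcripts: list[tuple[str, int, dict[str, float]]]
    contigs: list[ContigPlan] = field(default_factory=list)
    # subject_id -> set of GO term ids
    go_assignments: dict[str, set[str]] = field(default_factory=dict)
    # ontology: term -> (name, namespace), child->parent is_a edges
    go_terms: dict[str, tuple[str, str]] = field(default_factory=dict)
    go_edges: list[tuple[str, str]] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)

    def rate_of(self, contig: ContigPlan, condition: str) -> float:
        return self.transcripts[contig.transcript_index][2][condition]

    def subject_of(self, contig: ContigPlan) -> str:
        return self.transcripts[contig.transcript_index][0]

    def expected_subjects(self) -> set[str]:
        """Subjects expected to become virtual transcripts at default settings."""
        return {
            self.subject_of(c)
            for c in self.contigs
            if c.has_hit and not c.is_short
        }

    def analytic_quant(
        self, counts: dict[str, dict[str, int]], min_length: int = 200
    ) -> dict[str, dict[str, dict[str, float]]]:
        """Literal nested-sum evaluation of eRPKM/eTPM per condition from
        given per-contig counts, restricted to annotatable hit-bearing
        contigs. Independent of the quantify module (plain loops)."""
        members: dict[str, list[ContigPlan]] = {}
        for c in self.contigs:
            if c.has_hit and c.length > min_length:
                members.setdefault(self.subject_of(c), []).append(c)
        out: dict[str, dict[str, dict[str, float]]] = {}
        for condition in counts:
            n_sum = {}
            l_sum = {}
            for subject, contig_list in members.items():
                n_sum[subject] = sum(
                    counts[condition].get(c.contig_id, 0) for c in contig_list
                )
                l_sum[subject] = sum(c.length for c in contig_list)
            grand_n = sum(n_sum.values())
            rates = {s: n_sum[s] / l_sum[s] for s in members}
            grand_rate = sum(rates.values())
            erpkm = {}
            etpm = {}
            for s in members:
                erpkm[s] = (
                    1e9 * n_sum[s] / (l_sum[s] * grand_n) if grand_n else 0.0
                )
                etpm[s] = 1e6 * rates[s] / grand_rate if grand_rate else 0.0
            out[condition] = {"erpkm": erpkm, "etpm": etpm, "rc": dict(n_sum)}
        return out


def simulate_world(
    n_transcripts: int = 20,
    mean_contigs_per_transcript: float = 2.0,
    length_range: tuple[int, int] = (300, 3000),
    orphan_fraction: float = 0.1,
    short_fraction: float = 0.1,
    n_go_terms: int = 20,
    seed: int = 0,
    condition_labels: tuple[str, ...] = DEFAULT_CONDITIONS,
) -> FixtureTruth:
    """Build a deterministic ground-truth world.

    Each transcript is fragmented into >=1 non-overlapping contigs; a
    fraction of contigs get no hit row (orphans-to-be) and a fraction are
    shrunk to <=200 bp so the annotation length filter has work to do.
    """
    if n_transcripts < 1 or n_go_terms < 2:
        raise DataError("need at least 1 transcript and 2 GO terms")
    if mean_contigs_per_transcript < 1:
        raise DataError("mean_contigs_per_transcript must be >= 1")
    if not (0 <= orphan_fraction <= 1 and 0 <= short_fraction <= 1):
        raise DataError("fractions must lie in [0, 1]")
    lo, hi = length_range
    if lo < 250 or hi < lo:
        raise DataError(
            f"length_range {length_range} too small to fragment into "
            "annotatable contigs (need lo >= 250)"
        )

    rng = np.random.default_rng(seed)
    transcripts: list[tuple[str, int, dict[str, float]]] = []
    contigs: list[ContigPlan] = []
    sequences: dict[str, str] = {}

    for t_idx in range(n_transcripts):
        subject = f"P{t_idx + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        rates = {
            label: float(rng.uniform(0.5, 20.0)) for label in condition_labels
        }
        transcripts.append((subject, length, rates))

        max_frags = max(1, length // 250)
        n_frags = min(max_frags, 1 + rng.poisson(mean_contigs_per_transcript - 1.0))
        # non-overlapping fragments: split [0, length) at sorted cut points,
        # each piece at least 250 bp before optional shrinking
        if n_frags == 1:
            bounds = [0, length]
        else:
            cuts = sorted(
                int(c) for c in rng.choice(
                    np.arange(250, length - 249, 1), size=n_frags - 1, replace=False
                )
            )
            # enforce minimum piece size by rejecting too-close cuts
            pieces_ok = all(
                b - a >= 250 for a, b in zip([0] + cuts, cuts + [length])
            )
            if not pieces_ok:
                step = length // n_frags
                cuts = [step * i for i in range(1, n_frags)]
            bounds = [0] + cuts + [length]

        for f_idx in range(len(bounds) - 1):
            start, end = bounds[f_idx], bounds[f_idx + 1]
            contig_id = f"c{t_idx + 1:04d}_{f_idx + 1}"
            frag_len = end - start
            is_short = bool(rng.random() < short_fraction)
            if is_short:
                frag_len = int(rng.integers(50, 201))
            has_hit = not bool(rng.random() < orphan_fraction)
            contigs.append(
                ContigPlan(
                    contig_id=contig_id,
                    transcript_index=t_idx,
                    length=frag_len,
                    offset=start,
                    has_hit=has_hit,
                    is_short=is_short,
                )
            )
            sequences[contig_id] = "".join(
                rng.choice(NUCLEOTIDES, size=frag_len)
            )

    terms, edges = _random_ontology(n_go_terms, rng)
    go_assignments: dict[str, set[str]] = {}
    term_pool = sorted(terms)[1:]  # anything but the root
    for subject, _, _ in transcripts:
        n_terms = int(rng.integers(1, 4))
        picked = rng.choice(term_pool, size=min(n_terms, len(term_pool)), replace=False)
        go_assignments[subject] = {str(t) for t in picked}

    return FixtureTruth(
        seed=seed,
        condition_labels=tuple(condition_labels),
        transcripts=transcripts,
        contigs=contigs,
        go_assignments=go_assignments,
        go_terms=terms,
        go_edges=edges,
        sequences=sequences,
    )


def _random_ontology(
    n_terms: int, rng: np.random.Generator
) -> tuple[dict[str, tuple[str, str]], list[tuple[str, str]]]:
    """Random rooted DAG: term i > 0 gets 1-2 is_a parents among terms < i."""
    namespace = "biological_process"
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str]] = []
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    terms[ids[0]] = ("root process", namespace)
    for i in range(1, n_terms):
        terms[ids[i]] = (f"process {i}", namespace)
        n_parents = 1 if i == 1 else int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((ids[i], ids[int(p)]))
    return terms, edges


def simulate_counts(
    truth: FixtureTruth,
    condition_labels: tuple[str, ...] | None = None,
    depth_per_condition: int | dict[str, int] = 100_000,
    noise: str = "exact",
    seed: int = 0,
) -> dict[str, MappingProfile]:
    """Per-condition counts over ALL contigs (short and orphan included).

    exact mode: count_j = round(depth * rate_j*l_j / sum(rate*l)), rounding
    half away from zero deterministically. poisson mode: Poisson draws with
    those means, seeded.
    """
    if noise not in ("exact", "poisson"):
        raise ValueError(f"unknown noise mode {noise!r}")
    labels = tuple(condition_labels) if condition_labels else truth.condition_labels
    rng = np.random.default_rng(seed)
    profiles: dict[str, MappingProfile] = {}
    for label in labels:
        if isinstance(depth_per_condition, dict):
            depth = depth_per_condition[label]
        else:
            depth = depth_per_condition
        if depth <= 0:
            raise DataError(f"depth for condition {label!r} must be positive")
        weights = np.array(
            [truth.rate_of(c, label) * c.length for c in truth.contigs], dtype=float
        )
        means = depth * weights / weights.sum()
        if noise == "exact":
            values = np.floor(means + 0.5).astype(int)
        else:
            values = rng.poisson(means)
        counts = {
            c.contig_id: int(v) for c, v in zip(truth.contigs, values)
        }
        profiles[label] = MappingProfile(dataset_label=label, counts=counts)
    return profiles


def write_counts_tsv(profile: MappingProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig_id in sorted(profile.counts):
            fh.write(f"{contig_id}\t{profile.counts[contig_id]}\n")


def write_counts_sam(
    truth: FixtureTruth, profile: MappingProfile, path: str | Path
) -> None:
    """Minimal SAM: one primary single-end record per counted read, fixed
    position and CIGAR (the method consumes only per-contig totals)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in truth.contigs:
            fh.write(f"@SQ\tSN:{c.contig_id}\tLN:{c.length}\n")
        read_no = 0
        for c in truth.contigs:
            for _ in range(profile.counts.get(c.contig_id, 0)):
                read_no += 1
                fh.write(
                    f"r{read_no:08d}\t0\t{c.contig_id}\t1\t60\t50M\t*\t0\t0\t*\t*\n"
                )


def emit_fixture_bundle(
    truth: FixtureTruth,
    out_dir: str | Path,
    depth_per_condition: int | dict[str, int] = 100_000,
    noise: str = "exact",
    seed: int = 0,
    sam: bool = False,
) -> dict[str, Path]:
    """Write contigs.fasta, hits.tsv, counts_<label>.tsv (or .sam),
    ontology.obo, associations.tsv and truth.json into out_dir.

    truth.json records the analytic eRPKM/eTPM per condition computed by
    literal nested sums from the emitted counts; see FixtureTruth.analytic_quant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "contigs.fasta"
    with open(fasta, "w") as fh:
        for c in truth.contigs:
            fh.write(f">{c.contig_id}\n")
            seq = truth.sequences[c.contig_id]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["contigs"] = fasta

    hits = out / "hits.tsv"
    with open(hits, "w") as fh:
        fh.write("# qseqid sseqid pident length mismatch gapopen qstart qend "
                 "sstart send evalue bitscore\n")
        for c in truth.contigs:
            if not c.has_hit:
                continue
            subject = truth.subject_of(c)
            aln = min(c.length, 300)
            fh.write(
                f"{c.contig_id}\t{subject}\t95.0\t{aln}\t5\t0\t1\t{aln}\t1\t{aln}"
                f"\t1e-50\t{200.0 + c.length / 100.0:.1f}\n"
            )
    paths["hits"] = hits

    profiles = simulate_counts(
        truth, None, depth_per_condition, noise=noise, seed=seed
    )
    counts_by_condition: dict[str, dict[str, int]] = {}
    for label, profile in profiles.items():
        if sam:
            p = out / f"counts_{label}.sam"
            write_counts_sam(truth, profile, p)
        else:
            p = out / f"counts_{label}.tsv"
            write_counts_tsv(profile, p)
        paths[f"counts_{label}"] = p
        counts_by_condition[label] = dict(profile.counts)

    obo = out / "ontology.obo"
    with open(obo, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term_id in sorted(truth.go_terms):
            name, namespace = truth.go_terms[term_id]
            fh.write("[Term]\n")
            fh.write(f"id: {term_id}\n")
            fh.write(f"name: {name}\n")
            fh.write(f"namespace: {namespace}\n")
            for child, parent in truth.go_edges:
                if child == term_id:
                    fh.write(f"is_a: {parent}\n")
            fh.write("\n")
    paths["ontology"] = obo

    assoc = out / "associations.tsv"
    with open(assoc, "w") as fh:
        for subject in sorted(truth.go_assignments):
            for term in sorted(truth.go_assignments[subject]):
                fh.write(f"{subject}\t{term}\n")
    paths["associations"] = assoc

    truth_json = out / "truth.json"
    analytic = truth.analytic_quant(counts_by_condition)
    with open(truth_json, "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "condition_labels": list(truth.condition_labels),
                "transcripts": [
                    {"subject_id": s, "length": l, "rates": r}
                    for s, l, r in truth.transcripts
                ],
                "contigs": [
                    {
                        "contig_id": c.contig_id,
                        "subject_id": truth.subject_of(c),
                        "length": c.length,
                        "offset": c.offset,
                        "has_hit": c.has_hit,
                        "is_short": c.is_short,
                    }
                    for c in truth.contigs
                ],
                "expected_subjects": sorted(truth.expected_subjects()),
                "analytic": analytic,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    paths["truth"] = truth_json
    return paths
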