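# vtquant

Compare bulk RNA-seq datasets from organisms **without a reference genome**.

Given de novo assembled contigs and a tabular homology search (BLAST
outfmt-6 / LAST blast-tab), `vtquant` clusters contigs that share a best-hit
subject into **virtual transcripts**, then computes comparable expression
measures per dataset against that shared reference:

- **RC** — raw read count per contig / summed per virtual transcript;
- **eRPKM** — reads per kilobase per million, using the VT's summed member
  lengths and (by default) the read total over VT members only;
- **eTPM** — length-normalized rates rescaled to sum to 10^6 per dataset.

It also produces Gene Ontology level summaries: per-term virtual-transcript
counts and cumulative RC/eRPKM/eTPM after rolling annotations up the
is_a/part_of hierarchy.

## CLI

Four subcommands mirror the pipeline stages. A fully synthetic, deterministic
fixture bundle lets you try the whole thing without any external data:

```sh
# 1. generate a synthetic world (contigs, hits, counts, ontology, truth)
vtquant simulate demo/ --seed 7

# 2. cluster contigs into a virtual reference (contigs >200 bp, best hit per contig)
vtquant build-ref demo/contigs.fasta demo/hits.tsv -o demo/ref.tsv

# 3. quantify two (or more) datasets against the shared reference
vtquant quantify demo/ref.tsv \
    -m cond1=demo/counts_cond1.tsv -m cond2=demo/counts_cond2.tsv \
    -o demo/quant.tsv --per-contig demo/per_contig.tsv

# 4. GO-level cumulative summary at a chosen depth
vtquant go-summarize demo/quant.tsv demo/ref.tsv \
    demo/ontology.obo demo/associations.tsv --level 2 -o demo/go_level2.tsv
```

Mapping inputs may be SAM/BAM (primary, mapped records are counted; mates
count individually) or two-column `contig<TAB>count` TSVs. All outputs are
tab-delimited with a single header row. Exit codes: 0 success, 1 usage
error, 2 data error.

Useful flags: `--min-length` (annotation cutoff, default 200 bp, strict),
`--include-orphans` (promote hit-less contigs to singleton VTs),
`--max-evalue`, `--denominator {vt-only,all-mapped}`,
`--level-mode {min,max}`, `--direct-only` (no ancestor propagation).

## Library layout

| module | contents |
|---|---|
| `vtquant.formats_io` | FASTA/BLAST-6/SAM/OBO/TSV readers & writers, domain types |
| `vtquant.virtual_reference` | length filter, best-hit selection, VT clustering |
| `vtquant.quantify` | RC / eRPKM / eTPM, multi-dataset tables |
| `vtquant.go_summary` | term levels, ancestor propagation, per-level rollups |
| `vtquant.synthetic_fixtures` | deterministic ground-truth worlds & emitters |
| `vtquant.cli` | the subcommands above |

## Notes

- eTPM values for one dataset always sum to 10^6; eRPKM/eTPM are invariant
  to sequencing depth while RC scales with it.
- The eRPKM denominator counts reads on virtual-transcript members only
  (orphan/short contigs excluded); pass `--denominator all-mapped` to use the
  profile's full mapped total.
- Per-contig RPKM (the optional `--per-contig` table) uses the full mapped
  total of the profile.
- GO "level" is the minimum edge distance from the namespace root; a VT
  annotated to several terms at one level contributes fully to each row, so
  level sums are not a partition of the total.
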