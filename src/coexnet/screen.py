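"""Target-module extraction and transcription-factor candidate screening.

Given a module partition, a target-gene list (silk protein genes and
known regulators, each possibly with several isoforms) and a transcript
annotation table, this module answers: which modules contain the targets,
what else is in those modules, and which members carry a TF-diagnostic
domain.  The TF-domain list is explicit configuration — what counts as a
"major TF motif" is a curation decision — and the packaged default can
be replaced wholesale.

All outputs are pure functions of their inputs and deterministically
ordered, so re-running with identical inputs yields byte-identical
report files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import ModulePartition
from .io import AnnotationTable, TargetSet

__all__ = [
    "TFCandidate",
    "ScreenRow",
    "ScreenReport",
    "extract_target_modules",
    "screen_tfs",
    "build_report",
    "write_report_tsv",
    "write_tf_candidates_tsv",
]


@dataclass(frozen=True)
class TFCandidate:
    transcript_id: str
    module_id: int
    matched_domains: tuple[str, ...]
    description: str = ""
    is_known_target: bool = False  # candidate is itself a target isoform


@dataclass
class ScreenRow:
    """Per-target summary: modules hit, members, TF candidates."""

    gene: str
    module_ids: tuple[int, ...]
    total_transcripts: int  # unique transcripts over the gene's modules
    per_module_sum: int  # sum of per-module member counts
    tf_candidates: tuple[TFCandidate, ...]
    missing_isoforms: tuple[str, ...] = ()

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_candidates)


@dataclass
class ScreenReport:
    rows: list[ScreenRow]
    n_modules_total: int  # all modules of the partition (incl. singletons)
    n_multi_member_modules: int  # modules with >= 2 members
    target_module_ids: tuple[int, ...]  # union over all targets
    tf_candidate_ids: tuple[str, ...]  # union over all target modules
    unresolved_genes: tuple[str, ...] = ()  # targets with no isoform in partition

    @property
    def n_target_modules(self) -> int:
        return len(self.target_module_ids)

    @property
    def n_tf_candidates(self) -> int:
        return len(self.tf_candidate_ids)


def extract_target_modules(
    partition: ModulePartition, targets: TargetSet
) -> dict[str, tuple[int, ...]]:
    """Module IDs containing at least one isoform of each target gene.

    Genes with multiple isoforms may hit multiple modules.  Isoforms
    absent from the partition are ignored here (they are warned about at
    load time); a gene with no resolvable isoform maps to an empty tuple.
    """
    assignment = partition.assignment
    out: dict[str, tuple[int, ...]] = {}
    for gene, isoforms in targets.targets.items():
        mods = sorted({assignment[t] for t in isoforms if t in assignment})
        out[gene] = tuple(mods)
    return out


def screen_tfs(
    module_ids,
    partition: ModulePartition,
    annotation: AnnotationTable,
    tf_domains,
    known_target_ids=frozenset(),
) -> list[TFCandidate]:
    """Transcripts in the given modules annotated with a TF domain.

    Candidates that are themselves target isoforms (e.g. a known
    regulator inside a silk-gene module) are flagged, not removed.
    Output is sorted by transcript ID.
    """
    tf_domains = frozenset(tf_domains)
    if not tf_domains:
        raise ValueError("tf_domains must be non-empty")
    wanted = set(int(m) for m in module_ids)
    known = frozenset(known_target_ids)
    hits = []
    for tid, lab in zip(partition.transcript_ids, partition.labels):
        if int(lab) not in wanted:
            continue
        matched = annotation.domains_of(tid) & tf_domains
        if matched:
            hits.append(
                TFCandidate(
                    transcript_id=tid,
                    module_id=int(lab),
                    matched_domains=tuple(sorted(matched)),
                    description=annotation.description_of(tid),
                    is_known_target=tid in known,
                )
            )
    hits.sort(key=lambda c: c.transcript_id)
    return hits


def build_report(
    targets: TargetSet,
    partition: ModulePartition,
    annotation: AnnotationTable,
    tf_domains,
) -> ScreenReport:
    """One row per target gene plus global totals.

    ``total_transcripts`` counts unique transcripts over a gene's modules
    (``per_module_sum`` gives the other convention; the two are equal
    because a partition's modules are disjoint).
    """
    tf_domains = frozenset(tf_domains)
    if not tf_domains:
        raise ValueError("tf_domains must be non-empty")
    gene_modules = extract_target_modules(partition, targets)
    sizes = partition.module_sizes()
    all_target_ids = frozenset(t for iso in targets.targets.values() for t in iso)

    rows = []
    unresolved = []
    for gene, isoforms in targets.targets.items():
        mods = gene_modules[gene]
        if not mods:
            unresolved.append(gene)
        members = np.isin(partition.labels, list(mods)) if mods else np.zeros(0)
        total = int(members.sum()) if mods else 0
        per_module_sum = int(sum(sizes[m] for m in mods))
        cands = (
            screen_tfs(mods, partition, annotation, tf_domains, all_target_ids)
            if mods
            else []
        )
        rows.append(
            ScreenRow(
                gene=gene,
                module_ids=mods,
                total_transcripts=total,
                per_module_sum=per_module_sum,
                tf_candidates=tuple(cands),
                missing_isoforms=tuple(targets.missing.get(gene, ())),
            )
        )

    union_modules = tuple(sorted({m for r in rows for m in r.module_ids}))
    union_tfs = tuple(
        sorted({c.transcript_id for r in rows for c in r.tf_candidates})
    )
    return ScreenReport(
        rows=rows,
        n_modules_total=partition.n_modules,
        n_multi_member_modules=partition.n_multi_member_modules,
        target_module_ids=union_modules,
        tf_candidate_ids=union_tfs,
        unresolved_genes=tuple(unresolved),
    )


def write_report_tsv(report: ScreenReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tn_modules\tmodule_ids\ttotal_transcripts\tper_module_sum"
            "\tn_tfs\ttf_transcript_ids\n"
        )
        for r in report.rows:
            fh.write(
                f"{r.gene}\t{r.n_modules}\t"
                f"{','.join(str(m) for m in r.module_ids)}\t"
                f"{r.total_transcripts}\t{r.per_module_sum}\t{r.n_tfs}\t"
                f"{','.join(c.transcript_id for c in r.tf_candidates)}\n"
            )
        fh.write(
            f"TOTAL\t{report.n_target_modules}\t"
            f"{','.join(str(m) for m in report.target_module_ids)}\t"
            f"\t\t{report.n_tf_candidates}\t\n"
        )


def write_tf_candidates_tsv(report: ScreenReport, path) -> None:
    """One row per (gene, TF candidate) pair, fully deterministic."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene\tmodule_id\tdomains\tdescription\tknown_target\n")
        for r in report.rows:
            for c in r.tf_candidates:
                fh.write(
                    f"{c.transcript_id}\t{r.gene}\t{c.module_id}\t"
                    f"{';'.join(c.matched_domains)}\t{c.description}\t"
                    f"{'yes' if c.is_known_target else 'no'}\n"
                )
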