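"""Readers and writers for the plain tab-separated pipeline formats.

All pipeline inputs and outputs are TSV: an expression table (transcripts
as rows, samples as columns, TPM values), optional sample metadata
(sample -> tissue/series), a two-column target list (gene, transcript),
a transcript annotation table (domain accessions and free-text
description), and a one-accession-per-line transcription-factor domain
list.  Tab is the only dialect; loaders never reorder rows, so output
order always equals file order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "AnnotationRecord",
    "AnnotationTable",
    "TargetSet",
    "load_expression",
    "write_expression",
    "load_targets",
    "load_annotation",
    "load_tf_domains",
    "average_replicates",
]

_PFAM_RE = re.compile(r"PF\d{5}")


@dataclass
class ExpressionMatrix:
    """A transcripts x samples matrix of non-negative expression values.

    Attributes
    ----------
    transcript_ids : list of str
        Row identifiers, unique, in file order.  IDs are opaque strings
        (both reference-gene-set and assembly-derived forms occur).
    sample_ids : list of str
        Column identifiers, unique, in file order.
    values : ndarray of shape (n_transcripts, n_samples)
        Finite, non-negative expression values (TPM).
    sample_meta : dict or None
        Optional ``sample_id -> {"tissue": ..., "series": ...}`` map.
        Tissue labels are cosmetic (reports only), never used in any
        computation.
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_meta: dict[str, dict[str, str]] | None = None

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.sample_ids)} samples"
            )
        _check_unique(self.transcript_ids, "transcript")
        _check_unique(self.sample_ids, "sample")
        bad = np.argwhere(~np.isfinite(self.values) | (self.values < 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-finite or negative expression value at row "
                f"'{self.transcript_ids[i]}', column '{self.sample_ids[j]}'"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    transcript_id: str
    domains: frozenset[str]
    description: str = ""


@dataclass
class AnnotationTable:
    """Transcript -> domain annotation; absent transcripts have no domains."""

    records: dict[str, AnnotationRecord] = field(default_factory=dict)

    def domains_of(self, transcript_id: str) -> frozenset[str]:
        rec = self.records.get(transcript_id)
        return rec.domains if rec is not None else frozenset()

    def description_of(self, transcript_id: str) -> str:
        rec = self.records.get(transcript_id)
        return rec.description if rec is not None else ""


@dataclass
class TargetSet:
    """Target genes and their isoform transcript IDs.

    ``targets`` preserves every listed isoform in file order; isoforms not
    found in the expression matrix are additionally collected in
    ``missing`` (warned about, never silently dropped).
    """

    targets: dict[str, list[str]]
    missing: dict[str, list[str]] = field(default_factory=dict)

    def present(self, gene: str, universe: set[str] | None = None) -> list[str]:
        ids = self.targets[gene]
        if universe is None:
            miss = set(self.missing.get(gene, ()))
            return [t for t in ids if t not in miss]
        return [t for t in ids if t in universe]


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} ID: '{x}'")
        seen.add(x)


def load_expression(path, meta_path=None) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    The first column holds transcript IDs, the header row sample IDs.
    Duplicate IDs, negative or non-finite values, non-numeric cells and
    fewer than 3 sample columns are all hard errors with coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(
            f"expression table has {df.shape[1]} sample columns; "
            "at least 3 are required for correlation"
        )
    transcript_ids = [str(x) for x in df.index]
    sample_ids = [str(x) for x in df.columns]
    _check_unique(transcript_ids, "transcript")
    _check_unique(sample_ids, "sample")
    raw = df.to_numpy(dtype=object)
    try:
        # numpy's parser is correctly rounded, so written tables
        # round-trip bit-identically
        numeric = raw.astype(float)
    except (ValueError, TypeError):
        numeric = np.full(raw.shape, np.nan)
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    numeric[i, j] = float(raw[i, j])
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric expression value at row "
                        f"'{transcript_ids[i]}', column '{sample_ids[j]}': "
                        f"{raw[i, j]!r}"
                    ) from None
    bad = np.argwhere(~np.isfinite(numeric))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric or non-finite expression value at row "
            f"'{transcript_ids[i]}', column '{sample_ids[j]}': "
            f"{df.iat[i, j]!r}"
        )
    meta = _load_sample_meta(meta_path) if meta_path is not None else None
    return ExpressionMatrix(transcript_ids, sample_ids, numeric, meta)


def _load_sample_meta(path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"sample metadata must have columns {sorted(required)}; got {list(df.columns)}"
        )
    meta = {}
    for _, row in df.iterrows():
        meta[str(row["sample_id"])] = {
            "tissue": str(row["tissue"]),
            "series": str(row.get("series", "")) if "series" in df.columns else "",
        }
    return meta


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write an expression table; round-trips values bit-identically.

    Values are printed with Python's shortest round-trip float repr, so
    ``load_expression(write_expression(m)) == m`` exactly.
    """
    with open(path, "w") as fh:
        fh.write("transcript_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for tid, row in zip(matrix.transcript_ids, matrix.values):
            fh.write(tid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_sample_meta(meta: dict[str, dict[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\tseries\n")
        for sid, rec in meta.items():
            fh.write(f"{sid}\t{rec.get('tissue', '')}\t{rec.get('series', '')}\n")


def load_targets(path, matrix) -> TargetSet:
    """Read a two-column (gene, transcript_id) target list.

    ``matrix`` is an :class:`ExpressionMatrix` or any iterable of
    transcript IDs defining the universe.  Isoforms absent from it are
    kept but collected into the ``missing`` map and reported with a
    warning.  An empty file is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"target list '{path}' is empty")
    if df.shape[1] < 2:
        raise ValueError("target list must have two columns: gene<TAB>transcript_id")
    if isinstance(matrix, ExpressionMatrix):
        universe = set(matrix.transcript_ids)
    else:
        universe = set(matrix)
    targets: dict[str, list[str]] = {}
    missing: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        gene, tid = str(row[0]), str(row[1])
        targets.setdefault(gene, []).append(tid)
        if tid not in universe:
            missing.setdefault(gene, []).append(tid)
    if missing:
        n_miss = sum(len(v) for v in missing.values())
        warnings.warn(
            f"{n_miss} target transcript(s) not present in the expression matrix: "
            + "; ".join(f"{g}: {', '.join(v)}" for g, v in missing.items()),
            stacklevel=2,
        )
    return TargetSet(targets, missing)


def _parse_domain_field(raw: str, transcript_id: str) -> frozenset[str]:
    # Accepts "PF00250", "Forkhead (PF00250)", and semicolon-joined mixes.
    # Tokens with no parseable accession are warned about and dropped;
    # the row itself is kept.
    domains: set[str] = set()
    for token in str(raw).split(";"):
        token = token.strip()
        if not token:
            continue
        accs = _PFAM_RE.findall(token)
        if accs:
            domains.update(accs)
        elif re.fullmatch(r"[\w.\-]+", token):
            domains.add(token)  # bare non-Pfam accession, kept opaque
        else:
            warnings.warn(
                f"unparseable domain token {token!r} for transcript "
                f"'{transcript_id}'; keeping parseable subset",
                stacklevel=3,
            )
    return frozenset(domains)


def load_annotation(path) -> AnnotationTable:
    """Read a transcript annotation table (id, domains, description).

    The domain field is semicolon-delimited; each token may be a bare
    accession or a ``Name (PFxxxxx)`` form.  Malformed tokens produce a
    warning and the row is kept with its parseable subset.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, dtype=str, comment="#", keep_default_na=False
    )
    records: dict[str, AnnotationRecord] = {}
    for _, row in df.iterrows():
        tid = str(row[0])
        if tid == "transcript_id":  # tolerate a header line
            continue
        raw_domains = str(row[1]) if df.shape[1] > 1 else ""
        description = str(row[2]) if df.shape[1] > 2 else ""
        if tid in records:
            raise ValueError(f"duplicate transcript ID in annotation: '{tid}'")
        records[tid] = AnnotationRecord(
            tid, _parse_domain_field(raw_domains, tid), description
        )
    return AnnotationTable(records)


def load_tf_domains(path=None) -> frozenset[str]:
    """Read a TF-domain list (one accession per line, ``#`` comments).

    With no path, the packaged default list of DNA-binding / TF-diagnostic
    Pfam domains is returned.  The list is a required, swappable piece of
    configuration: what counts as a "TF motif" is a curation decision.
    """
    if path is None:
        text = (
            resources.files("coexnet").joinpath("data/tf_domains.txt").read_text()
        )
    else:
        text = Path(path).read_text()
    domains = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            domains.add(line)
    if not domains:
        raise ValueError("TF-domain list is empty")
    return frozenset(domains)


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns per (tissue, series) group.

    Requires sample metadata.  Group order follows first appearance of
    each group in the sample order.
    """
    if matrix.sample_meta is None:
        raise ValueError("replicate averaging requires sample metadata")
    groups: dict[tuple[str, str], list[int]] = {}
    for j, sid in enumerate(matrix.sample_ids):
        rec = matrix.sample_meta.get(sid)
        if rec is None:
            raise ValueError(f"sample '{sid}' missing from metadata")
        groups.setdefault((rec.get("tissue", ""), rec.get("series", "")), []).append(j)
    new_ids = []
    cols = []
    meta = {}
    for (tissue, series), idx in groups.items():
        name = f"{series}:{tissue}" if series else tissue
        new_ids.append(name)
        cols.append(matrix.values[:, idx].mean(axis=1))
        meta[name] = {"tissue": tissue, "series": series}
    if len(new_ids) < 3:
        raise ValueError("fewer than 3 tissue groups after replicate averaging")
    return ExpressionMatrix(
        list(matrix.transcript_ids), new_ids, np.column_stack(cols), meta
    )
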