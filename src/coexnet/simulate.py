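"""Synthetic tissue-panel expression data with planted modules.

The generator emulates the structure of a bulk multi-tissue TPM table:
samples are tissues x biological replicates, and each planted module has
a tissue signature — high expression in a small tissue subset, near-zero
baseline elsewhere — shared by its member transcripts up to a
per-transcript gain and multiplicative log-normal noise.  TPM-like data
is non-negative and heteroscedastic, which multiplicative noise captures
and additive Gaussian noise would not.

Module signatures use disjoint-ish tissue subsets (each module owns a
distinct primary tissue when modules <= tissues, optionally plus one
shared extra), so planted modules are separable at high |corr| while
between-module correlation stays moderate.  Background transcripts are
independent log-normal noise; they exercise the excluded/singleton path
and stress the threshold.

All randomness flows from the single spec seed through one generator
stream, so identical specs give byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .community import ModulePartition
from .io import (
    AnnotationRecord,
    AnnotationTable,
    ExpressionMatrix,
    TargetSet,
    write_expression,
    write_sample_meta,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SimulationResult",
    "simulate",
    "adjusted_rand_index",
    "write_fixtures",
]

# domains handed to the ~10% of members flagged as TFs, cycled per module
_TF_DOMAIN_CYCLE = ("PF00250", "PF05920", "PF00170", "PF00412", "PF00447")
_NON_TF_DOMAIN = "PF07690"  # a transporter domain: annotated but never screened


@dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic dataset.

    Defaults describe a planted-module benchmark of 10 modules of 50
    transcripts over a 10-tissue x 3-replicate panel with multiplicative
    log-normal noise (sigma 0.2 on the log scale) and no background.
    """

    n_modules: int = 10
    transcripts_per_module: int | list[int] = 50
    n_tissues: int = 10
    replicates_per_tissue: int = 3
    expression_scale: float = 100.0
    noise_sd: float = 0.2
    background_fraction: float = 0.0
    seed: int = 42

    def module_sizes(self) -> list[int]:
        if isinstance(self.transcripts_per_module, int):
            return [self.transcripts_per_module] * self.n_modules
        sizes = list(self.transcripts_per_module)
        if len(sizes) != self.n_modules:
            raise ValueError("transcripts_per_module list length != n_modules")
        return sizes

    def validate(self) -> None:
        if self.n_modules < 1 or any(s < 1 for s in self.module_sizes()):
            raise ValueError("module counts and sizes must be >= 1")
        if self.n_tissues < 1 or self.replicates_per_tissue < 1:
            raise ValueError("tissue and replicate counts must be >= 1")
        if self.expression_scale <= 0:
            raise ValueError("expression_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must be in [0, 1)")

    @property
    def n_background(self) -> int:
        planted = sum(self.module_sizes())
        # background_fraction is the fraction of ALL transcripts
        return int(round(planted * self.background_fraction / (1.0 - self.background_fraction)))


@dataclass
class GroundTruth:
    """Planted module label per transcript; background labeled -1."""

    labels: dict[str, int] = field(default_factory=dict)

    def planted_ids(self) -> list[str]:
        return [t for t, lab in self.labels.items() if lab != -1]


@dataclass
class SimulationResult:
    matrix: ExpressionMatrix
    truth: GroundTruth
    annotation: AnnotationTable
    targets: TargetSet


def simulate(spec: SyntheticSpec) -> SimulationResult:
    """Generate a matrix, ground truth, annotation and target fixture.

    One member per module is flagged as that module's target gene, and a
    random ~10% of members per module receive a TF-diagnostic domain in
    the annotation (one member per module also gets a non-TF domain, so
    screens have true negatives).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sizes = spec.module_sizes()
    m = spec.n_tissues * spec.replicates_per_tissue

    sample_ids = [
        f"tissue{t:02d}_rep{r + 1}"
        for t in range(spec.n_tissues)
        for r in range(spec.replicates_per_tissue)
    ]
    sample_meta = {
        sid: {"tissue": sid.split("_")[0], "series": "sim"} for sid in sample_ids
    }

    transcript_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: dict[str, int] = {}
    ann: dict[str, AnnotationRecord] = {}
    targets: dict[str, list[str]] = {}

    baseline = 0.01 * spec.expression_scale
    for k, size in enumerate(sizes):
        active = {k % spec.n_tissues}
        if rng.random() < 0.5:
            active.add(int(rng.integers(spec.n_tissues)))
        signature = np.full(spec.n_tissues, baseline)
        signature[sorted(active)] = spec.expression_scale
        sig_samples = np.repeat(signature, spec.replicates_per_tissue)

        member_ids = [f"mod{k:02d}_t{j:03d}" for j in range(size)]
        for tid in member_ids:
            gain = float(np.exp(rng.normal(0.0, 0.3)))
            noise = np.exp(rng.normal(0.0, spec.noise_sd, m)) if spec.noise_sd else 1.0
            rows.append(sig_samples * gain * noise)
            transcript_ids.append(tid)
            truth[tid] = k
        targets[f"gene{k:02d}"] = [member_ids[0]]

        n_tf = max(1, int(round(0.1 * size)))
        tf_members = rng.choice(size, size=min(n_tf, size), replace=False)
        for idx in sorted(int(i) for i in tf_members):
            tid = member_ids[idx]
            dom = _TF_DOMAIN_CYCLE[k % len(_TF_DOMAIN_CYCLE)]
            ann[tid] = AnnotationRecord(
                tid, frozenset({dom}), "synthetic transcription factor"
            )
        non_tf = member_ids[-1]
        if non_tf not in ann:
            ann[non_tf] = AnnotationRecord(
                non_tf, frozenset({_NON_TF_DOMAIN}), "synthetic transporter"
            )

    for j in range(spec.n_background):
        tid = f"bg_t{j:04d}"
        # independent heavy-tailed noise around a low baseline
        rows.append(np.exp(rng.normal(np.log(baseline + 1.0), 1.0, m)))
        transcript_ids.append(tid)
        truth[tid] = -1

    matrix = ExpressionMatrix(transcript_ids, sample_ids, np.array(rows), sample_meta)
    return SimulationResult(
        matrix=matrix,
        truth=GroundTruth(truth),
        annotation=AnnotationTable(ann),
        targets=TargetSet(targets),
    )


def adjusted_rand_index(truth: GroundTruth, partition: ModulePartition) -> float:
    """Chance-corrected agreement between planted and detected modules.

    Background transcripts (label -1) are excluded from scoring.  The two
    inputs must cover the same transcript universe.
    """
    if set(truth.labels) != set(partition.transcript_ids):
        raise ValueError("truth and partition cover different transcript sets")
    assignment = partition.assignment
    ids = truth.planted_ids()
    if not ids:
        raise ValueError("no planted (non-background) transcripts to score")
    a = [truth.labels[t] for t in ids]
    b = [assignment[t] for t in ids]
    return float(adjusted_rand_score(a, b))


def write_fixtures(result: SimulationResult, out_dir) -> dict[str, Path]:
    """Write the four fixture files (plus sample metadata and truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
        "targets": out / "targets.tsv",
        "annotation": out / "annotation.tsv",
    }
    write_expression(result.matrix, paths["expression"])
    write_sample_meta(result.matrix.sample_meta, paths["samples"])
    with open(paths["truth"], "w") as fh:
        fh.write("transcript_id\tplanted_module\n")
        for tid in result.matrix.transcript_ids:
            fh.write(f"{tid}\t{result.truth.labels[tid]}\n")
    with open(paths["targets"], "w") as fh:
        for gene, isoforms in result.targets.targets.items():
            for tid in isoforms:
                fh.write(f"{gene}\t{tid}\n")
    with open(paths["annotation"], "w") as fh:
        for tid in result.matrix.transcript_ids:
            rec = result.annotation.records.get(tid)
            if rec is not None:
                fh.write(f"{tid}\t{';'.join(sorted(rec.domains))}\t{rec.description}\n")
    return paths
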