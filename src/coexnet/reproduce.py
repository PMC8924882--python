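"""Side-by-side comparison of pipeline counts with published reference counts.

For the deposited *Bombyx mori* multi-tissue transcript TPM table
(doi:10.18908/lsdba.nbdc02443-002.V001; 51,926 transcripts across tissue
panels including the five silk-gland regions), published module counts
exist for the silk-protein target screen: 1022 network modules in total,
20 modules containing target-gene isoforms, and 91 TF candidates across
those modules, with per-target breakdowns.  Exact reproduction is not
guaranteed — the original tool's Louvain seed, node order and edge
weighting convention are unpublished — so this module reports the
pipeline's own counts alongside the reference for *both* edge-weighting
modes and *both* module-counting conventions (all modules vs. modules
with >= 2 members), letting the user judge agreement under each reading.
"""

from __future__ import annotations

import pandas as pd

from .estimator import detect_modules
from .io import AnnotationTable, ExpressionMatrix, TargetSet
from .screen import build_report

__all__ = ["PUBLISHED_SILK_STUDY_COUNTS", "reproduction_report", "write_reproduction_tsv"]

# Reference counts published for the deposited B. mori silk-gland screen.
# Per-target tuples are (modules, total transcripts, TF candidates).
PUBLISHED_SILK_STUDY_COUNTS = {
    "modules_total": 1022,
    "target_modules": 20,
    "tf_candidates": 91,
    "per_target": {
        "sericin1": (7, 565, 39),
        "sericin2": (6, 289, 11),
        "sericin3": (1, 36, 2),
        "fibroin-H": (1, 42, 5),
        "fibroin-L": (1, 80, 4),
        "SGF1": (1, 119, 11),
        "SGF3": (1, 120, 6),
        "sage": (1, 114, 8),
        "Antennapedia": (1, 126, 5),
    },
}


def reproduction_report(
    matrix: ExpressionMatrix,
    targets: TargetSet,
    annotation: AnnotationTable,
    tf_domains,
    *,
    threshold: float = 0.1,
    resolution: float = 1.0,
    block_size: int = 2048,
    log_transform: bool = False,
    seed: int = 1,
    reference: dict | None = None,
) -> pd.DataFrame:
    """Run both weighting modes and tabulate counts against a reference.

    Returns a long-format frame with columns ``metric``, ``weighting``,
    ``value`` and ``reference``.  Module totals appear under both
    counting conventions (``modules_total`` includes singleton modules,
    ``modules_multi_member`` does not); the reference value is attached
    to both since the published convention is not stated.
    """
    if reference is None:
        reference = PUBLISHED_SILK_STUDY_COUNTS
    per_target_ref = reference.get("per_target", {})
    rows = []
    for weighting in ("similarity", "unweighted"):
        result = detect_modules(
            matrix,
            threshold=threshold,
            weighting=weighting,
            resolution=resolution,
            block_size=block_size,
            log_transform=log_transform,
            seed=seed,
        )
        report = build_report(targets, result.partition, annotation, tf_domains)
        rows.append(
            ("modules_total", weighting, report.n_modules_total,
             reference.get("modules_total"))
        )
        rows.append(
            ("modules_multi_member", weighting, report.n_multi_member_modules,
             reference.get("modules_total"))
        )
        rows.append(
            ("target_modules", weighting, report.n_target_modules,
             reference.get("target_modules"))
        )
        rows.append(
            ("tf_candidates", weighting, report.n_tf_candidates,
             reference.get("tf_candidates"))
        )
        for r in report.rows:
            ref = per_target_ref.get(r.gene, (None, None, None))
            rows.append((f"{r.gene}/modules", weighting, r.n_modules, ref[0]))
            rows.append(
                (f"{r.gene}/total_transcripts", weighting, r.total_transcripts, ref[1])
            )
            rows.append((f"{r.gene}/tf_candidates", weighting, r.n_tfs, ref[2]))
    return pd.DataFrame(rows, columns=["metric", "weighting", "value", "reference"])


def write_reproduction_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
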