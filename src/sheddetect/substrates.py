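"""Filter classified targets down to cell-surface substrate candidates.

A sheddase cleaves ectodomains at the cell surface, so its direct
substrates must (a) change post-transcriptionally (protein moves, mRNA does
not follow), (b) move opposite to the bait (accumulate when the protease is
knocked down), and (c) reside on the cell surface.  Candidates are ranked
by membrane-topology class (single-pass ectodomains are the archetypal
shedding substrates) and then by effect size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import FeatureAnnotation, TOPOLOGY_CLASSES

logger = logging.getLogger(__name__)

__all__ = ["filter_candidates", "topology_summary", "DEFAULT_TOPOLOGY_PRIORITY"]

#: Ranking order: type I single-pass first, then type II, remaining
#: single-pass classes, GPI-anchored, multi-pass, untyped.
DEFAULT_TOPOLOGY_PRIORITY = (
    "single_pass_I",
    "single_pass_II",
    "single_pass_III",
    "single_pass_IV",
    "single_pass_unknown",
    "gpi_anchor",
    "multi_pass",
    "none",
)


def filter_candidates(
    targets: pd.DataFrame,
    annotation: FeatureAnnotation,
    topology_priority=DEFAULT_TOPOLOGY_PRIORITY,
) -> pd.DataFrame:
    """Apply the three-way substrate gate and rank the survivors.

    Gate: regulation_class == post_transcriptional AND bait_direction ==
    negative AND is_surface per annotation.  Proteins missing from the
    annotation are logged and excluded.  Order: topology priority, then
    descending |protein_log2fc|; ``priority_rank`` is 1-based.
    """
    prio = {cls: i for i, cls in enumerate(topology_priority)}
    unknown = set(TOPOLOGY_CLASSES) - set(topology_priority)
    if unknown:
        raise ValueError(f"topology priority does not cover classes {sorted(unknown)}")

    ann = annotation.table.set_index("protein_id")
    rows = []
    for _, t in targets.iterrows():
        pid = t["protein_id"]
        if pid not in ann.index:
            logger.info("protein %s lacks annotation coverage; excluded from candidates", pid)
            continue
        if t["regulation_class"] != "post_transcriptional":
            continue
        if t["bait_direction"] != "negative":
            continue
        a = ann.loc[pid]
        if not bool(a["is_surface"]):
            continue
        rows.append(
            {
                "protein_id": pid,
                "topology": a["topology"],
                "subcellular_location": a["subcellular_location"],
                "protein_log2fc": float(t["protein_log2fc"]),
                "bait_cor": float(t["bait_cor"]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "topology", "subcellular_location", "protein_log2fc", "bait_cor"],
    )
    if not out.empty:
        out["_prio"] = out["topology"].map(prio)
        out["_mag"] = -np.abs(out["protein_log2fc"])
        out = out.sort_values(["_prio", "_mag", "protein_id"], kind="stable")
        out = out.drop(columns=["_prio", "_mag"]).reset_index(drop=True)
    out["priority_rank"] = np.arange(1, len(out) + 1)
    return out


def topology_summary(candidates: pd.DataFrame) -> dict[str, int]:
    """Candidate counts per membrane-topology class (zeros included)."""
    counts = {cls: 0 for cls in TOPOLOGY_CLASSES}
    if not candidates.empty:
        for cls, n in candidates["topology"].value_counts().items():
            counts[cls] = int(n)
    counts["total"] = int(len(candidates))
    return counts
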