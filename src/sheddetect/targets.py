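"""Classify differential proteins as transcriptional vs post-transcriptional
targets of the bait protease, and by sign of their bait correlation.

A differential protein is a *transcriptional* target when the systematic
(joint + orthogonal) variation of its protein column positively and
significantly correlates across samples with the systematic variation of
its mRNA; otherwise it is a *post-transcriptional* target.  Each target is
additionally tested for positive or negative correlation with the bait's
systematic protein profile; substrate candidates are expected to rise when
the bait is knocked down, i.e. to correlate negatively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionMatrix, FeatureAnnotation
from .o2pls import O2PLS

logger = logging.getLogger(__name__)

__all__ = ["pair_features", "classify_targets"]

REGULATION_CLASSES = ("transcriptional", "post_transcriptional", "unclassified")
BAIT_DIRECTIONS = ("positive", "negative", "none")


def pair_features(
    mrna: ExpressionMatrix,
    protein: ExpressionMatrix,
    annotation: FeatureAnnotation,
) -> pd.DataFrame:
    """Map each protein to its mRNA column via the gene annotation.

    Proteins without a detected mRNA are retained unpaired (they remain
    eligible post-transcriptional candidates).  If several annotation rows
    map one protein to different genes, the gene whose mRNA has the highest
    mean expression wins (logged).  Several proteins mapping to one gene
    (fan-in) is allowed.
    """
    mrna_pos = {g: i for i, g in enumerate(mrna.feature_ids)}
    mean_expr = mrna.values.mean(axis=0)
    gene_map: dict[str, list[str]] = {}
    for _, row in annotation.table.iterrows():
        gene_map.setdefault(row["protein_id"], []).append(row["gene_id"])

    rows = []
    for pid in protein.feature_ids:
        genes = [g for g in gene_map.get(pid, []) if g in mrna_pos]
        if not genes:
            declared = gene_map.get(pid, [None])[0]
            rows.append({"protein_id": pid, "gene_id": declared, "mrna_feature": None,
                         "note": "no mRNA detected"})
            continue
        if len(set(genes)) > 1:
            genes = sorted(set(genes), key=lambda g: -mean_expr[mrna_pos[g]])
            logger.info("protein %s maps to multiple detected mRNAs; keeping "
                        "highest-expressed %s", pid, genes[0])
        gene = genes[0]
        rows.append({"protein_id": pid, "gene_id": gene, "mrna_feature": gene, "note": ""})
    return pd.DataFrame(rows)


def _correlation_test(a: np.ndarray, b: np.ndarray, alternative: str):
    """Pearson r and p across samples; degenerate columns give (nan, 1)."""
    if np.std(a) == 0 or np.std(b) == 0 or len(a) < 3:
        return np.nan, 1.0
    res = stats.pearsonr(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def classify_targets(
    model: O2PLS,
    mrna: ExpressionMatrix,
    protein: ExpressionMatrix,
    dep_results: pd.DataFrame,
    pairs: pd.DataFrame,
    bait: str,
    alpha: float = 0.05,
    fc_gate: float = 1.2,
    use_systematic: bool = True,
) -> pd.DataFrame:
    """Build the target table for differential proteins passing the FC gate.

    Parameters
    ----------
    model : O2PLS
        Fitted on the sample-paired ``mrna`` (X) and ``protein`` (Y)
        matrices, in that orientation.
    dep_results : DataFrame
        Output of the protein differential test (feature_id, log2fc, fdr).
    pairs : DataFrame
        Output of :func:`pair_features`.
    bait : str
        Protein id of the perturbed protease; excluded from the table.
    use_systematic : bool
        Correlate systematic parts (default) or the raw preprocessed
        matrices (sensitivity analysis).
    """
    if bait not in protein.feature_ids:
        raise ValueError(f"bait {bait!r} is not a detected protein")
    if model.n_features_x_ != mrna.n_features or model.n_features_y_ != protein.n_features:
        raise ValueError("model dimensions do not match the supplied matrices")

    if use_systematic:
        Sx = model.systematic_part("X")
        Sy = model.systematic_part("Y")
    else:
        Sx = mrna.values - mrna.values.mean(axis=0)
        Sy = protein.values - protein.values.mean(axis=0)

    dep = dep_results.set_index("feature_id")
    x_pos = {g: i for i, g in enumerate(mrna.feature_ids)}
    y_pos = {p: i for i, p in enumerate(protein.feature_ids)}
    pair_lut = pairs.set_index("protein_id")
    bait_col = Sy[:, y_pos[bait]]

    gate = np.log2(fc_gate)
    tabled = [
        pid for pid in protein.feature_ids
        if pid != bait
        and pid in dep.index
        and not bool(dep.loc[pid].get("untestable", False))
        and abs(dep.loc[pid, "log2fc"]) > gate
        and dep.loc[pid, "fdr"] < alpha
    ]

    records = []
    for pid in tabled:
        y = Sy[:, y_pos[pid]]
        gene = None
        mrna_feature = None
        if pid in pair_lut.index:
            gene = pair_lut.loc[pid, "gene_id"]
            mrna_feature = pair_lut.loc[pid, "mrna_feature"]
        if mrna_feature is not None and mrna_feature in x_pos:
            r, p = _correlation_test(y, Sx[:, x_pos[mrna_feature]], "greater")
        else:
            r, p = np.nan, np.nan  # no mRNA: positive correlation cannot be established
        rb, pb = _correlation_test(y, bait_col, "two-sided")
        records.append(
            {
                "protein_id": pid,
                "gene_id": gene,
                "mrna_protein_cor": r,
                "mrna_protein_p": p,
                "bait_cor": rb,
                "bait_p": pb,
                "protein_log2fc": dep.loc[pid, "log2fc"],
                "protein_fdr": dep.loc[pid, "fdr"],
            }
        )

    table = pd.DataFrame(
        records,
        columns=[
            "protein_id", "gene_id", "mrna_protein_cor", "mrna_protein_p",
            "bait_cor", "bait_p", "protein_log2fc", "protein_fdr",
        ],
    )
    if table.empty:
        table["mrna_protein_q"] = []
        table["bait_q"] = []
        table["regulation_class"] = []
        table["bait_direction"] = []
        return table

    table["mrna_protein_q"] = bh_adjust(table["mrna_protein_p"].to_numpy())
    table["bait_q"] = bh_adjust(table["bait_p"].to_numpy())

    transcriptional = (
        table["mrna_protein_q"].notna()
        & (table["mrna_protein_q"] < alpha)
        & (table["mrna_protein_cor"] > 0)
    )
    table["regulation_class"] = np.where(transcriptional, "transcriptional", "post_transcriptional")

    sig_bait = table["bait_q"].notna() & (table["bait_q"] < alpha)
    table["bait_direction"] = np.where(
        sig_bait, np.where(table["bait_cor"] > 0, "positive", "negative"), "none"
    )
    n_unpaired = int(table["mrna_protein_cor"].isna().sum())
    if n_unpaired:
        logger.info("%d differential proteins without detected mRNA kept as "
                    "post-transcriptional-eligible", n_unpaired)
    return table
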