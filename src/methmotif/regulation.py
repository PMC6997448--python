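"""Methylation-affinity concordance and target-gene expression analysis.

A motif/TF association is *concordant* when the TF's in-vitro methylation
preference matches the motif's methylation direction (MethylPlus with a
hyper-methylated motif, or MethylMinus with a hypo-methylated one) and
*discordant* otherwise; pairs with an undefined motif label or an unknown
TF class are excluded.  Target genes are tested for tumor-vs-normal
differential expression with an unpaired two-sided Wilcoxon rank-sum test
(p < 0.05 on the raw p-value, direction from the sign of the median
difference), and each pair is labeled up- / down- / mixed-regulated by a
strict >50% majority among its differentially expressed targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .motif import Motif


@dataclass
class DEResult:
    gene: str
    median_tumor: float
    median_normal: float
    p: float
    direction: str  # up | down | none


@dataclass
class RegulationCall:
    motif: Motif | None
    tf_name: str
    motif_label: str  # hyper | hypo
    methyl_class: str  # MethylPlus | MethylMinus
    concordance: str  # concordant | discordant
    regulation: str  # up | down | mixed
    n_de_targets: int
    de_results: list[DEResult] = field(default_factory=list)


def classify_concordance(motif_label: str, methyl_class: str) -> str:
    """Concordant / discordant / excluded per the affinity-direction rule."""
    if motif_label not in ("hyper", "hypo") or methyl_class not in (
        "MethylPlus",
        "MethylMinus",
    ):
        return "excluded"
    concordant = (methyl_class == "MethylPlus" and motif_label == "hyper") or (
        methyl_class == "MethylMinus" and motif_label == "hypo"
    )
    return "concordant" if concordant else "discordant"


def wilcoxon_de(
    tumor_values,
    normal_values,
    gene: str = "",
    alpha: float = 0.05,
) -> DEResult:
    """Two-sided rank-sum differential-expression call for one gene.

    Exact enumeration for tie-free groups of size <= 20, otherwise the
    normal approximation with tie correction.  A gene is called up (down)
    when the tumor-minus-normal median difference is positive (negative)
    and p < alpha; an exactly zero median difference is never called.
    """
    t = np.asarray(tumor_values, dtype=float)
    c = np.asarray(normal_values, dtype=float)
    if t.size < 3 or c.size < 3:
        raise ValueError("need >= 3 values per group")
    med_t, med_c = float(np.median(t)), float(np.median(c))
    pooled = np.concatenate([t, c])
    if np.all(pooled == pooled[0]):
        return DEResult(gene, med_t, med_c, 1.0, "none")
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(t.size, c.size) <= 20 and not has_ties) else "asymptotic"
    p = float(mannwhitneyu(t, c, alternative="two-sided", method=method).pvalue)
    diff = med_t - med_c
    if p < alpha and diff > 0:
        direction = "up"
    elif p < alpha and diff < 0:
        direction = "down"
    else:
        direction = "none"
    return DEResult(gene, med_t, med_c, p, direction)


def classify_regulation(de_results: list[DEResult]) -> tuple[str, int]:
    """Strict-majority regulation label over differentially expressed targets.

    Returns (label, number of DE targets).  With no DE target the label is
    mixed by the fallback rule.
    """
    de = [r for r in de_results if r.direction != "none"]
    n = len(de)
    if n == 0:
        return "mixed", 0
    n_up = sum(1 for r in de if r.direction == "up")
    if n_up / n > 0.5:
        return "up", n
    if (n - n_up) / n > 0.5:
        return "down", n
    return "mixed", n


def regulation_calls(
    pairs: list[tuple[Motif | None, str, str]],
    methyl_classes: dict[str, str],
    targets: pd.DataFrame,
    expression: pd.DataFrame,
    sample_labels: pd.Series,
    alpha: float = 0.05,
) -> list[RegulationCall]:
    """Concordance + regulation labels for motif/TF pairs.

    ``pairs`` holds (motif, tf_name, motif_label) triples; ``targets`` maps
    tf_name -> gene rows; ``expression`` is genes x samples with
    ``sample_labels`` in {tumor, normal}.  Pairs whose concordance is
    excluded are dropped.  Per-gene DE tests are cached across TFs.
    """
    tumor_cols = sample_labels.index[sample_labels == "tumor"]
    normal_cols = sample_labels.index[sample_labels == "normal"]
    de_cache: dict[str, DEResult] = {}

    def de_for(gene: str) -> DEResult | None:
        if gene not in expression.index:
            return None
        if gene not in de_cache:
            row = expression.loc[gene]
            de_cache[gene] = wilcoxon_de(
                row[tumor_cols], row[normal_cols], gene=gene, alpha=alpha
            )
        return de_cache[gene]

    calls: list[RegulationCall] = []
    by_tf = targets.groupby("tf_name")["gene"]
    for motif, tf_name, motif_label in pairs:
        methyl_class = methyl_classes.get(tf_name, "unknown")
        concordance = classify_concordance(motif_label, methyl_class)
        if concordance == "excluded":
            continue
        genes = by_tf.get_group(tf_name).tolist() if tf_name in by_tf.groups else []
        de_results = [r for r in (de_for(g) for g in genes) if r is not None]
        regulation, n_de = classify_regulation(de_results)
        calls.append(
            RegulationCall(
                motif=motif,
                tf_name=tf_name,
                motif_label=motif_label,
                methyl_class=methyl_class,
                concordance=concordance,
                regulation=regulation,
                n_de_targets=n_de,
                de_results=de_results,
            )
        )
    return calls


def summarize_contingency(calls: list[RegulationCall], by: str = "pairs") -> pd.DataFrame:
    """2x3 contingency of concordance vs regulation direction.

    ``by='pairs'`` counts motif/TF pairs per cell; ``by='genes'`` counts
    unique differentially expressed target genes (a gene contributes to the
    cell of every pair it is a DE target of, but once per cell).
    """
    table = pd.DataFrame(
        0,
        index=["concordant", "discordant"],
        columns=["down", "mixed", "up"],
        dtype=int,
    )
    if by == "pairs":
        for call in calls:
            table.loc[call.concordance, call.regulation] += 1
    elif by == "genes":
        seen: dict[tuple[str, str], set[str]] = {}
        for call in calls:
            cell = seen.setdefault((call.concordance, call.regulation), set())
            cell.update(r.gene for r in call.de_results if r.direction != "none")
        for (conc, reg), genes in seen.items():
            table.loc[conc, reg] = len(genes)
    else:
        raise ValueError("by must be 'pairs' or 'genes'")
    return table
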