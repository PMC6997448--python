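"""Methylation-direction labeling and genomic-context annotation of motifs.

A motif is labeled hyper- (hypo-) methylated when strictly more than 70% of
the CpGs carrying it are hyper- (hypo-) methylated; otherwise its status is
undefined.  Direction enrichment against a background set uses the
over-representation tail of the hypergeometric distribution, significant at
p < 0.05 per direction (no cross-motif correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .motif import Motif, match_positions
from .records import CGI_REGIONS, CpGRecord, GENE_REGIONS


@dataclass
class MotifMethylLabel:
    motif: Motif
    n_cpgs: int
    frac_hyper: float
    label: str  # hyper | hypo | undefined
    p_hyper: float | None = None
    p_hypo: float | None = None
    significant_hyper: bool = False
    significant_hypo: bool = False


@dataclass
class GenomicDistribution:
    gene_region_counts: dict[str, int]
    cgi_region_counts: dict[str, int]


def motif_cpg_set(motif: Motif, records: list[CpGRecord]) -> frozenset[str]:
    """IDs of records whose flanking sequence contains >= 1 motif match."""
    return frozenset(
        r.cpg_id for r in records if match_positions(motif, r.sequence)
    )


def label_direction(
    members: set[str],
    hyper: set[str],
    hypo: set[str],
    threshold: float = 0.70,
) -> MotifMethylLabel:
    """Dominant methylation direction of a motif's CpG set.

    ``members`` must all carry a direction (subset of hyper ∪ hypo).  The
    rule is strict: a label is assigned only when the direction fraction
    exceeds ``threshold``.
    """
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    if not members <= (set(hyper) | set(hypo)):
        raise ValueError("members must all be labeled hyper or hypo")
    n = len(members)
    frac_hyper = len(members & set(hyper)) / n
    if frac_hyper > threshold:
        label = "hyper"
    elif (1 - frac_hyper) > threshold:
        label = "hypo"
    else:
        label = "undefined"
    return MotifMethylLabel(motif=None, n_cpgs=n, frac_hyper=frac_hyper, label=label)


def hypergeom_direction_test(k: int, n: int, K: int, N: int) -> float:
    """Over-representation tail P(X >= k), X ~ Hypergeometric(N, K, n).

    k = motif CpGs in the direction, n = motif CpGs, K = background CpGs in
    the direction, N = background size.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError("inconsistent hypergeometric counts")
    return float(hypergeom.sf(k - 1, N, K, n))


def direction_enrichment(
    motif: Motif,
    members: set[str],
    hyper: set[str],
    hypo: set[str],
    background: set[str],
    threshold: float = 0.70,
    alpha: float = 0.05,
) -> MotifMethylLabel:
    """Full direction annotation: 70% label plus both hypergeometric tails.

    The background is the CpG universe with known directions (for cancer
    analyses, the input iDMC set).
    """
    members = set(members) & set(background)
    lab = label_direction(members, hyper, hypo, threshold)
    bg_hyper = len(set(hyper) & set(background))
    bg_hypo = len(set(hypo) & set(background))
    k_hyper = len(members & set(hyper))
    lab.motif = motif
    lab.p_hyper = hypergeom_direction_test(
        k_hyper, len(members), bg_hyper, len(background)
    )
    lab.p_hypo = hypergeom_direction_test(
        len(members) - k_hyper, len(members), bg_hypo, len(background)
    )
    lab.significant_hyper = lab.p_hyper < alpha
    lab.significant_hypo = lab.p_hypo < alpha
    return lab


def genomic_distribution(
    members: set[str], annotation: pd.DataFrame
) -> GenomicDistribution:
    """Region tallies for a motif's CpG set.

    ``annotation`` is indexed by cpg_id with columns ``gene_regions`` (tuple
    or semicolon-joined tokens; a CpG in several regions increments each
    counter once) and ``cgi_region`` (exactly one class per CpG).
    """
    gene_counts = {r: 0 for r in GENE_REGIONS}
    cgi_counts = {r: 0 for r in CGI_REGIONS}
    missing = set(members) - set(annotation.index)
    if missing:
        raise ValueError(f"unannotated CpGs: {sorted(missing)[:3]}...")
    for cpg in members:
        regions = annotation.at[cpg, "gene_regions"]
        if isinstance(regions, str):
            regions = tuple(t for t in regions.split(";") if t)
        for r in set(regions):
            if r not in gene_counts:
                raise ValueError(f"unknown gene region {r!r} for {cpg}")
            gene_counts[r] += 1
        cgi = annotation.at[cpg, "cgi_region"]
        if cgi not in cgi_counts:
            raise ValueError(f"unknown CGI region {cgi!r} for {cpg}")
        cgi_counts[cgi] += 1
    return GenomicDistribution(gene_region_counts=gene_counts, cgi_region_counts=cgi_counts)
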