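"""Variance-based CpG selection and iDMC direction splitting.

Stable CpGs (sCpGs) are those whose methylation variance across samples
falls strictly below a low percentile of the per-CpG variance distribution
(default 1st); unstable CpGs (uCpGs) fall strictly above a high percentile
(default 99th).  Tables of informative differentially methylated CpGs
(iDMCs) are split by their hyper/hypo direction of change in tumor.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .records import BetaMatrix, CpGSetSelection

logger = logging.getLogger(__name__)


def compute_variance(matrix: BetaMatrix) -> pd.Series:
    """Per-CpG sample variance (unbiased, divisor n - 1)."""
    if len(matrix.sample_ids) < 2:
        raise ValueError("variance needs at least 2 samples")
    return matrix.values.var(axis=1, ddof=1)


def select_by_percentile(
    variances: pd.Series,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    tissue: str = "",
) -> tuple[CpGSetSelection, CpGSetSelection]:
    """Stable/unstable CpG sets at the given variance percentiles.

    Percentiles are computed with linear interpolation between order
    statistics; membership uses strict inequalities (below the low
    percentile / above the high one).
    """
    if not 0 < low_pct < high_pct < 100:
        raise ValueError("need 0 < low_pct < high_pct < 100")
    if len(variances) < 100:
        warnings.warn(
            f"only {len(variances)} CpGs: percentile estimates are unstable",
            stacklevel=2,
        )
    v = variances.to_numpy(dtype=float)
    lo = np.percentile(v, low_pct)
    hi = np.percentile(v, high_pct)
    background = frozenset(variances.index)
    stable = frozenset(variances.index[v < lo])
    unstable = frozenset(variances.index[v > hi])
    if not stable or not unstable:
        raise ValueError(
            "empty stable or unstable selection (degenerate variance distribution)"
        )
    logger.info(
        "selected %d stable / %d unstable of %d CpGs", len(stable), len(unstable), len(v)
    )
    return (
        CpGSetSelection(kind="stable", members=stable, background=background, tissue=tissue),
        CpGSetSelection(kind="unstable", members=unstable, background=background, tissue=tissue),
    )


def split_idmc(
    idmc_table: pd.DataFrame,
    background: set[str] | None = None,
    tissue: str = "",
) -> tuple[CpGSetSelection, CpGSetSelection, CpGSetSelection]:
    """Partition an iDMC table into (hyper, hypo, all) selections.

    The table must have columns ``cpg_id`` and ``direction`` with direction
    in {hyper, hypo}.  The background defaults to the full iDMC set; for
    motif discovery it is normally the whole platform CpG set.
    """
    if idmc_table.empty:
        raise ValueError("empty iDMC table")
    for col in ("cpg_id", "direction"):
        if col not in idmc_table.columns:
            raise ValueError(f"iDMC table lacks required column {col!r}")
    bad = ~idmc_table["direction"].isin(["hyper", "hypo"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown direction {idmc_table['direction'].iloc[row]!r} at row {row}"
        )
    dup = idmc_table.groupby("cpg_id")["direction"].nunique()
    if (dup > 1).any():
        culprit = dup[dup > 1].index[0]
        raise ValueError(f"CpG {culprit!r} labeled with conflicting directions")
    hyper = frozenset(idmc_table.loc[idmc_table.direction == "hyper", "cpg_id"])
    hypo = frozenset(idmc_table.loc[idmc_table.direction == "hypo", "cpg_id"])
    union = hyper | hypo
    bg = frozenset(background) if background is not None else union
    if not union <= bg:
        raise ValueError("iDMC CpGs missing from the supplied background")
    return (
        CpGSetSelection(kind="hyper_idmc", members=hyper, background=bg, tissue=tissue),
        CpGSetSelection(kind="hypo_idmc", members=hypo, background=bg, tissue=tissue),
        CpGSetSelection(kind="idmc_all", members=union, background=bg, tissue=tissue),
    )
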