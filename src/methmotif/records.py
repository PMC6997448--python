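"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_REGIONS = ("1stExon", "3'UTR", "5'UTR", "Body", "TSS1500", "TSS200")
CGI_REGIONS = ("Island", "N_Shelf", "N_Shore", "OpenSea", "S_Shelf", "S_Shore")


@dataclass
class CpGRecord:
    """One methylation-array probe: ID, flanking sequence and annotation.

    ``sequence`` is the probed CpG dinucleotide plus its flanks (the CG sits
    at the center).  ``gene_regions`` may be empty (intergenic CpG) or hold
    several region classes; ``cgi_region`` is exactly one CpG-density class.
    ``direction`` is set only for differentially methylated CpGs.
    """

    cpg_id: str
    sequence: str
    gene_regions: tuple[str, ...] = ()
    cgi_region: str = "OpenSea"
    direction: str | None = None  # "hyper" | "hypo" | None


@dataclass
class BetaMatrix:
    """CpG x sample methylation fractions with sample condition labels."""

    values: pd.DataFrame  # index = cpg_ids, columns = sample_ids, values in [0,1]
    sample_labels: pd.Series | None = None  # sample -> condition/tissue

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("beta matrix contains missing values; filter at load time")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("CpG and sample IDs must be unique")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CpGSetSelection:
    """A named CpG set (stable/unstable/iDMC split) with its background."""

    kind: str  # stable | unstable | idmc_all | hyper_idmc | hypo_idmc
    members: frozenset[str]
    background: frozenset[str]
    tissue: str = ""

    def __post_init__(self) -> None:
        if not self.members <= self.background:
            raise ValueError("selection members must be a subset of the background")
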