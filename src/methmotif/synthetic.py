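"""Synthetic pipeline inputs with known ground truth.

Generates every input the pipeline consumes — CpG flanking sequences with
motifs planted at elevated frequency in a designated subset, beta-value
matrices with per-CpG variance heterogeneity, hyper/hypo direction labels,
a toy TF motif database with methylation-affinity classes, TF target maps
and tumor/normal expression matrices with planted shifts — so that every
downstream stage can be tested against a known answer without external
downloads.

All generators are pure functions of their arguments including the seed:
child seeds for each stage are derived deterministically from the single
config seed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif import Motif
from .records import BetaMatrix, CGI_REGIONS, CpGRecord, GENE_REGIONS
from .tfbs import TFMotif

# fixed per-stage offsets so each generator draws from an independent stream
_STAGE_IDS = {
    "flanks": 1,
    "annotation": 2,
    "plant": 3,
    "beta": 4,
    "idmc": 5,
    "regulation": 6,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE_IDS[stage]])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``planted_motifs`` entries are (iupac_word, subset_fraction,
    fraction_in, fraction_out): the word is planted in ``fraction_in`` of a
    designated subset of CpGs and ``fraction_out`` of the rest.
    ``variance_groups`` entries are (fraction_of_cpgs, beta_mean,
    concentration): low concentration yields high per-CpG variance.
    """

    n_cpgs: int = 2000
    n_samples: int = 50
    flank_len: int = 20
    gc_fraction: float = 0.5
    planted_motifs: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: [("TGACTCA", 0.1, 0.30, 0.01)]
    )
    variance_groups: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.99, 0.5, 100.0), (0.01, 0.5, 2.0)]
    )
    n_hyper: int = 150
    n_hypo: int = 150
    tf_db_size: int = 20
    n_targets_per_tf: int = 10
    de_fraction: float = 0.8
    expression_effect: float = 2.0
    n_tumor: int = 50
    n_normal: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in [self.gc_fraction, self.de_fraction]:
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for word, sub, fin, fout in self.planted_motifs:
            if len(word) > 2 * self.flank_len + 2:
                raise ValueError("planted motif longer than the sequence window")
            for f in (sub, fin, fout):
                if not 0 <= f <= 1:
                    raise ValueError("fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    planted_occurrences: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    true_stable: frozenset[str] = frozenset()
    true_unstable: frozenset[str] = frozenset()
    true_de_genes: dict[str, str] = field(default_factory=dict)
    tf_classes: dict[str, str] = field(default_factory=dict)


def gen_flank_sequences(
    n: int,
    flank_len: int = 20,
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> list[CpGRecord]:
    """Random CpG records: 2*flank_len + 2 nt with a fixed central CG.

    Non-central bases are i.i.d. with P(G) = P(C) = gc_fraction / 2.  Each
    record also receives a random genomic annotation (0-3 gene-region
    classes, one CGI class).
    """
    if n < 1 or flank_len < 1:
        raise ValueError("n and flank_len must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie in (0, 1)")
    rng = _stage_rng(seed, "flanks")
    arng = _stage_rng(seed, "annotation")
    L = 2 * flank_len + 2
    probs = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    bases = np.array(list("ACGT"))
    records = []
    for i in range(n):
        seq = rng.choice(bases, size=L, p=probs)
        seq[flank_len] = "C"
        seq[flank_len + 1] = "G"
        n_gene = arng.integers(0, 4)
        gene_regions = tuple(
            sorted(arng.choice(GENE_REGIONS, size=n_gene, replace=False))
        )
        cgi = str(arng.choice(CGI_REGIONS))
        records.append(
            CpGRecord(
                cpg_id=f"cg{i + 1:08d}",
                sequence="".join(seq),
                gene_regions=gene_regions,
                cgi_region=cgi,
            )
        )
    return records


def plant_motif(
    records: list[CpGRecord],
    motif_word: str,
    subset: set[str],
    fraction_in: float,
    fraction_out: float = 0.0,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[list[CpGRecord], GroundTruth]:
    """Overwrite a concrete instance of ``motif_word`` into flank sequences.

    A fraction ``fraction_in`` of the subset sequences (and ``fraction_out``
    of the rest) receive one instantiation of the IUPAC word (each ambiguous
    position sampled uniformly) at a uniformly chosen offset that does not
    touch the central CG dinucleotide.  Occurrences are recorded in the
    returned :class:`GroundTruth`.  Input records are not mutated.
    """
    motif = Motif.from_consensus(motif_word)
    ids = {r.cpg_id for r in records}
    if not set(subset) <= ids:
        raise ValueError("subset contains unknown CpG IDs")
    if records and len(motif) > len(records[0].sequence):
        raise ValueError("motif longer than the flank window")
    if fraction_in < fraction_out:
        warnings.warn(
            "fraction_in < fraction_out: planted motif carries no discoverable signal",
            stacklevel=2,
        )
    rng = _stage_rng(seed, "plant")
    truth = truth if truth is not None else GroundTruth()
    occ = truth.planted_occurrences.setdefault(motif_word, set())
    out = []
    m = len(motif)
    for rec in records:
        L = len(rec.sequence)
        flank_len = (L - 2) // 2
        frac = fraction_in if rec.cpg_id in subset else fraction_out
        rec = copy.copy(rec)
        if frac > 0 and rng.random() < frac:
            # offsets whose window avoids the central CG at [flank_len, flank_len+1]
            valid = [
                off
                for off in range(L - m + 1)
                if off + m <= flank_len or off >= flank_len + 2
            ]
            if not valid:
                raise ValueError("no valid planting offset avoids the central CG")
            off = int(valid[rng.integers(len(valid))])
            word = "".join(
                str(rng.choice(sorted(s))) for s in motif.position_sets
            )
            seq = rec.sequence
            rec.sequence = seq[:off] + word + seq[off + m :]
            occ.add((rec.cpg_id, off))
        out.append(rec)
    return out, truth


def gen_beta_matrix(config: SimulationConfig) -> tuple[BetaMatrix, GroundTruth]:
    """Beta-value matrix with planted variance heterogeneity.

    Each CpG belongs to a variance group (fraction, mean, concentration c);
    its sample values are i.i.d. Beta(mean*c, (1-mean)*c), so variance
    mean*(1-mean)/(1+c) decreases with c.  The extreme-concentration groups
    define ``true_stable`` (highest c) and ``true_unstable`` (lowest c).
    """
    fracs = [g[0] for g in config.variance_groups]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("variance_groups fractions must sum to 1")
    rng = _stage_rng(config.seed, "beta")
    n = config.n_cpgs
    cpg_ids = [f"cg{i + 1:08d}" for i in range(n)]
    # contiguous group blocks, then a deterministic shuffle of CpG order
    sizes = [int(round(f * n)) for f in fracs]
    sizes[-1] = n - sum(sizes[:-1])
    group_of = np.repeat(np.arange(len(sizes)), sizes)
    perm = rng.permutation(n)
    group_of = group_of[perm]
    values = np.empty((n, config.n_samples))
    for gi, (_, mean, conc) in enumerate(config.variance_groups):
        mask = group_of == gi
        a = mean * conc
        b = (1 - mean) * conc
        values[mask] = rng.beta(a, b, size=(int(mask.sum()), config.n_samples))
    df = pd.DataFrame(
        values, index=cpg_ids, columns=[f"S{j + 1:04d}" for j in range(config.n_samples)]
    )
    concs = [g[2] for g in config.variance_groups]
    truth = GroundTruth(
        true_stable=frozenset(
            np.array(cpg_ids)[group_of == int(np.argmax(concs))].tolist()
        ),
        true_unstable=frozenset(
            np.array(cpg_ids)[group_of == int(np.argmin(concs))].tolist()
        ),
    )
    labels = pd.Series("normal", index=df.columns, name="condition")
    return BetaMatrix(values=df, sample_labels=labels), truth


def gen_idmc_table(config: SimulationConfig) -> pd.DataFrame:
    """Hyper/hypo direction labels for a disjoint random pair of CpG subsets."""
    rng = _stage_rng(config.seed, "idmc")
    n_idmc = config.n_hyper + config.n_hypo
    if n_idmc > config.n_cpgs:
        raise ValueError("n_hyper + n_hypo exceeds n_cpgs")
    ids = [f"cg{i + 1:08d}" for i in range(config.n_cpgs)]
    chosen = rng.choice(ids, size=n_idmc, replace=False)
    rows = [(c, "hyper") for c in chosen[: config.n_hyper]] + [
        (c, "hypo") for c in chosen[config.n_hyper :]
    ]
    return pd.DataFrame(rows, columns=["cpg_id", "direction"])


def gen_regulation_fixture(
    config: SimulationConfig,
    consensi: list[str] | None = None,
    tf_directions: dict[str, str] | None = None,
) -> tuple[list[TFMotif], pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Toy TF database, target map and tumor/normal expression matrices.

    PWMs are built from (optionally supplied) consensus words with
    multinomial count noise.  Each TF is labeled MethylPlus / MethylMinus /
    unknown.  A ``de_fraction`` of each TF's target genes receives a median
    expression shift of ``expression_effect`` (log2 scale) between tumor and
    normal; the shift direction per TF comes from ``tf_directions`` or is
    drawn at random.  Returns (tf_db, target map, expression genes x
    samples, sample condition labels, truth).
    """
    if config.tf_db_size < 1:
        raise ValueError("tf_db_size must be >= 1")
    if config.n_tumor < 3 or config.n_normal < 3:
        raise ValueError("need >= 3 tumor and >= 3 normal samples (Wilcoxon degenerate)")
    # independent sub-streams: the TF database (words, PWMs, classes) must
    # not change when direction overrides alter how many draws are consumed
    rng_db = np.random.default_rng([int(config.seed), _STAGE_IDS["regulation"], 0])
    rng = np.random.default_rng([int(config.seed), _STAGE_IDS["regulation"], 1])
    bases = np.array(list("ACGT"))
    tf_db: list[TFMotif] = []
    truth = GroundTruth()
    target_rows = []
    gene_idx = 0
    gene_effects: dict[str, float] = {}
    nsites = 50
    for t in range(config.tf_db_size):
        name = f"TF{t + 1:03d}"
        if consensi is not None and t < len(consensi):
            word = consensi[t]
        else:
            word = "".join(rng_db.choice(bases, size=8))
        motif = Motif.from_consensus(word)
        pwm = np.empty((len(motif), 4))
        for i, s in enumerate(motif.position_sets):
            probs = np.full(4, 0.05)
            for b in s:
                probs["ACGT".index(b)] = 0.0
            probs[probs == 0.0] = (1 - 0.05 * (4 - len(s))) / len(s)
            counts = rng_db.multinomial(nsites, probs)
            pwm[i] = counts / nsites
        methyl_class = str(
            rng_db.choice(["MethylPlus", "MethylMinus", "unknown"], p=[0.4, 0.4, 0.2])
        )
        tf_db.append(TFMotif(tf_name=name, pwm=pwm, methyl_class=methyl_class))
        truth.tf_classes[name] = methyl_class
        direction = None
        if tf_directions is not None:
            direction = tf_directions.get(name)
        elif config.expression_effect > 0:
            direction = str(rng.choice(["up", "down"]))
        for _ in range(config.n_targets_per_tf):
            gene = f"G{gene_idx + 1:05d}"
            gene_idx += 1
            target_rows.append((name, gene))
            if (
                direction is not None
                and config.expression_effect > 0
                and rng.random() < config.de_fraction
            ):
                # "mixed" TFs shift each target in an independent direction
                gene_dir = (
                    str(rng.choice(["up", "down"])) if direction == "mixed" else direction
                )
                effect = config.expression_effect
                gene_effects[gene] = effect if gene_dir == "up" else -effect
                truth.true_de_genes[gene] = gene_dir
    targets = pd.DataFrame(target_rows, columns=["tf_name", "gene"])
    genes = targets["gene"].tolist()
    n_t, n_n = config.n_tumor, config.n_normal
    samples = [f"T{j + 1:04d}" for j in range(n_t)] + [
        f"N{j + 1:04d}" for j in range(n_n)
    ]
    base = rng.uniform(4, 10, size=len(genes))
    expr = rng.normal(0.0, 1.0, size=(len(genes), n_t + n_n)) + base[:, None]
    for gi, gene in enumerate(genes):
        expr[gi, :n_t] += gene_effects.get(gene, 0.0)
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    labels = pd.Series(
        ["tumor"] * n_t + ["normal"] * n_n, index=samples, name="condition"
    )
    return tf_db, targets, expr_df, labels, truth


def gen_fixture(config: SimulationConfig) -> dict:
    """Generate the complete linked fixture used by the full pipeline.

    Planted motifs target the iDMC CpG set (hyper CpGs for the first planted
    word, hypo for the second, alternating), so discovery on the iDMC set
    against the platform background can recover them with a defined
    methylation direction.
    """
    records = gen_flank_sequences(
        config.n_cpgs, config.flank_len, config.gc_fraction, seed=config.seed
    )
    beta, truth = gen_beta_matrix(config)
    idmc = gen_idmc_table(config)
    hyper = set(idmc.loc[idmc.direction == "hyper", "cpg_id"])
    hypo = set(idmc.loc[idmc.direction == "hypo", "cpg_id"])
    for rec in records:
        if rec.cpg_id in hyper:
            rec.direction = "hyper"
        elif rec.cpg_id in hypo:
            rec.direction = "hypo"
    consensi = []
    for k, (word, _sub, fin, fout) in enumerate(config.planted_motifs):
        subset = hyper if k % 2 == 0 else hypo
        records, truth = plant_motif(
            records, word, subset, fin, fout, seed=config.seed + 7 * k + 1, truth=truth
        )
        consensi.append(word)
    tf_db, targets, expr, expr_labels, reg_truth = gen_regulation_fixture(
        config, consensi=consensi
    )
    truth.tf_classes = reg_truth.tf_classes
    truth.true_de_genes = reg_truth.true_de_genes
    return {
        "records": records,
        "beta": beta,
        "idmc": idmc,
        "tf_db": tf_db,
        "targets": targets,
        "expression": expr,
        "expression_labels": expr_labels,
        "truth": truth,
        "config": config,
    }
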