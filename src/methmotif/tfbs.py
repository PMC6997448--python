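"""Matching discovered motifs against a TF motif (PWM) database.

The comparison is Tomtom-like: ungapped alignment of frequency columns over
all offsets, scored by mean per-column similarity, with significance from a
seeded column-shuffle empirical null.  Reported matches must overlap the
query by at least ``min_overlap`` columns and reach an E-value below
``e_max`` (E = empirical p x database size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif import Motif, motif_to_pfm

SQRT2 = np.sqrt(2.0)

METHYL_CLASSES = ("MethylPlus", "MethylMinus", "unknown")


@dataclass
class TFMotif:
    """A TF position frequency matrix with a methylation-affinity class.

    ``methyl_class`` encodes in-vitro binding preference: MethylPlus TFs
    prefer methylated sites, MethylMinus TFs unmethylated ones.
    """

    tf_name: str
    pwm: np.ndarray  # (length, 4) rows sum to 1
    methyl_class: str = "unknown"

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4 or self.pwm.shape[0] < 1:
            raise ValueError("PWM must be a (length >= 1, 4) matrix")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if self.methyl_class not in METHYL_CLASSES:
            raise ValueError(f"unknown methyl class {self.methyl_class!r}")

    def __len__(self) -> int:
        return self.pwm.shape[0]

    def reverse_complement_pwm(self) -> np.ndarray:
        # complement swaps A<->T and C<->G, i.e. reverses the base axis
        return self.pwm[::-1, ::-1]


@dataclass
class MotifTFMatch:
    motif: Motif
    tf: TFMotif
    offset: int
    overlap: int
    score: float
    p: float
    e: float
    strand: str = "+"


def _column_similarity_matrix(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """(m, n) matrix of 1 - ||q_i - t_j|| / sqrt(2) column similarities."""
    diff = query[:, None, :] - target[None, :, :]
    return 1.0 - np.sqrt((diff**2).sum(axis=2)) / SQRT2


def _best_alignment(sim: np.ndarray, min_overlap: int):
    """Best (offset, overlap, score) over all ungapped offsets.

    ``sim[i, j]`` is the similarity between query column i and target column
    j; the alignment at offset d pairs query i with target i + d.  The score
    normalizes the summed similarity by the overlap length (mean column
    similarity).  Returns None if no offset reaches ``min_overlap``.
    """
    m, n = sim.shape
    best = None
    for d in range(-(m - min_overlap), n - min_overlap + 1):
        qi0 = max(0, -d)
        ti0 = max(0, d)
        ov = min(m - qi0, n - ti0)
        if ov < min_overlap:
            continue
        idx = np.arange(ov)
        score = sim[qi0 + idx, ti0 + idx].mean()
        if best is None or score > best[2] + 1e-15:
            best = (d, ov, float(score))
    return best


def compare_motif_pwm(
    query: np.ndarray,
    target: TFMotif,
    min_overlap: int = 5,
    revcomp: bool = True,
):
    """Best ungapped alignment of a query PFM against a TF PWM.

    Returns ``(offset, overlap, score, strand)`` or ``None`` when no offset
    achieves ``min_overlap`` aligned columns.  With ``revcomp`` (default,
    since TF databases are strand-symmetric) the better of the two target
    orientations is reported.
    """
    query = np.asarray(query, dtype=float)
    if query.shape[0] < 1 or len(target) < 1:
        raise ValueError("empty query or target")
    results = []
    best_fwd = _best_alignment(_column_similarity_matrix(query, target.pwm), min_overlap)
    if best_fwd is not None:
        results.append((*best_fwd, "+"))
    if revcomp:
        best_rev = _best_alignment(
            _column_similarity_matrix(query, target.reverse_complement_pwm()), min_overlap
        )
        if best_rev is not None:
            results.append((*best_rev, "-"))
    if not results:
        return None
    return max(results, key=lambda r: (r[2], r[3] == "+"))


def match_significance(
    score: float,
    query: np.ndarray,
    target: TFMotif,
    db_size: int,
    n_shuffles: int = 1000,
    min_overlap: int = 5,
    seed: int = 0,
    revcomp: bool = True,
) -> tuple[float, float]:
    """Empirical (p, E) for an observed alignment score.

    The null preserves the target's column multiset: columns are permuted
    ``n_shuffles`` times and the best alignment score recomputed each time.
    p uses add-one smoothing: (1 + #{null >= observed}) / (n_shuffles + 1);
    E = p x database size.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    query = np.asarray(query, dtype=float)
    n = len(target)
    if n < 2:
        return 1.0, float(db_size)
    rng = np.random.default_rng(seed)
    sims = [_column_similarity_matrix(query, target.pwm)]
    if revcomp:
        sims.append(_column_similarity_matrix(query, target.reverse_complement_pwm()))
    m = query.shape[0]
    exceed = 0
    perms = np.vstack([rng.permutation(n) for _ in range(n_shuffles)])
    null_best = np.full(n_shuffles, -np.inf)
    for sim in sims:
        for d in range(-(m - min_overlap), n - min_overlap + 1):
            qi0 = max(0, -d)
            ti0 = max(0, d)
            ov = min(m - qi0, n - ti0)
            if ov < min_overlap:
                continue
            qidx = qi0 + np.arange(ov)
            tidx = perms[:, ti0 : ti0 + ov]
            scores = sim[qidx[None, :], tidx].mean(axis=1)
            np.maximum(null_best, scores, out=null_best)
    exceed = int((null_best >= score - 1e-12).sum())
    p = (1 + exceed) / (n_shuffles + 1)
    return p, p * db_size


def scan_database(
    motif: Motif,
    db: list[TFMotif],
    min_overlap: int = 5,
    e_max: float = 10.0,
    n_shuffles: int = 1000,
    seed: int = 0,
    revcomp: bool = True,
) -> list[MotifTFMatch]:
    """All database TFs matching ``motif`` under the overlap and E-value filters.

    Matches are sorted by E-value (ties: higher score, then TF name).
    """
    if not db:
        raise ValueError("TF database is empty")
    query = motif_to_pfm(motif)
    out: list[MotifTFMatch] = []
    for i, tf in enumerate(db):
        aln = compare_motif_pwm(query, tf, min_overlap=min_overlap, revcomp=revcomp)
        if aln is None:
            continue
        offset, overlap, score, strand = aln
        p, e = match_significance(
            score,
            query,
            tf,
            db_size=len(db),
            n_shuffles=n_shuffles,
            min_overlap=min_overlap,
            seed=seed + i,
            revcomp=revcomp,
        )
        if e < e_max and overlap >= min_overlap:
            out.append(
                MotifTFMatch(
                    motif=motif,
                    tf=tf,
                    offset=offset,
                    overlap=overlap,
                    score=score,
                    p=p,
                    e=e,
                    strand=strand,
                )
            )
    out.sort(key=lambda r: (r.e, -r.score, r.tf.tf_name))
    return out
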