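"""Discriminative elicitation of short IUPAC motifs.

Given a positive and a background set of DNA sequences, the procedure finds
IUPAC words (length 3-8 by default) over-represented in the positive set:

1. every exact A/C/G/T word of each length occurring in the positive set is
   scored by a one-sided Fisher exact test on zero-or-one per-sequence
   counts (a sequence counts once no matter how many windows match);
2. the best-scoring seed words are refined by best-improvement hill
   climbing, generalizing one position at a time to a strictly larger IUPAC
   base set and accepting only strict p-value improvements;
3. the round's best motif receives an E-value = Fisher p x number of exact
   candidate words tested in the round; if it passes the threshold it is
   emitted and all of its match windows are masked (replaced by N) in both
   sequence sets, and the procedure repeats.

The search is deterministic: ties are broken toward shorter motifs, then
lexicographically smaller consensus strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .motif import (
    IUPAC_SETS,
    Motif,
    SET_TO_IUPAC,
    encode_sequences,
    match_positions,
    matches_encoded,
)

# strict IUPAC supersets of each allowed-base set, used as hill-climb moves
_SUPERSETS: dict[frozenset[str], list[frozenset[str]]] = {
    s: sorted(
        (t for t in IUPAC_SETS.values() if s < t),
        key=lambda t: (len(t), SET_TO_IUPAC[t]),
    )
    for s in IUPAC_SETS.values()
}

# beyond this many concrete expansions, fall back to the vectorized scanner
_MAX_INDEX_EXPANSIONS = 2048


@dataclass
class MotifDiscoveryResult:
    motif: Motif
    pos_with: int
    pos_total: int
    neg_with: int
    neg_total: int
    fisher_p: float
    e_value: float
    n_candidates: int
    iteration: int
    matched_pos_ids: frozenset[str] = frozenset()

    @property
    def consensus(self) -> str:
        return self.motif.consensus


def fisher_enrichment(
    pos_with: int, pos_total: int, neg_with: int, neg_total: int
) -> float:
    """One-sided Fisher exact p for positive-set over-representation.

    Probability of observing >= ``pos_with`` positive-set successes under
    the hypergeometric null of the pooled 2x2 table with fixed margins.
    """
    for c in (pos_with, pos_total, neg_with, neg_total):
        if c < 0:
            raise ValueError("counts must be non-negative")
    if pos_with > pos_total or neg_with > neg_total:
        raise ValueError("with-counts cannot exceed totals")
    N = pos_total + neg_total
    K = pos_with + neg_with
    return float(hypergeom.sf(pos_with - 1, N, K, pos_total))


def _as_id_seq_lists(sequences) -> tuple[list[str], list[str]]:
    """Normalize a dict id->seq or an iterable of sequences."""
    if isinstance(sequences, dict):
        ids = list(sequences)
        return ids, [sequences[i].upper() for i in ids]
    seqs = [s.upper() for s in sequences]
    return [str(i) for i in range(len(seqs))], seqs


def _build_index(
    seqs: list[str], lengths: range, revcomp: bool
) -> dict[int, dict[str, set[int]]]:
    """Per-length inverted index: exact word -> set of sequence indices.

    Windows containing a masked base (N) are skipped, matching the motif
    semantics where N matches nothing.
    """
    comp = str.maketrans("ACGT", "TGCA")
    index: dict[int, dict[str, set[int]]] = {k: {} for k in lengths}
    for i, seq in enumerate(seqs):
        views = [seq]
        if revcomp:
            views.append(seq.translate(comp)[::-1])
        for view in views:
            L = len(view)
            for k in lengths:
                idx_k = index[k]
                for off in range(L - k + 1):
                    w = view[off : off + k]
                    if "N" in w:
                        continue
                    s = idx_k.get(w)
                    if s is None:
                        idx_k[w] = {i}
                    else:
                        s.add(i)
    return index


class _RoundScorer:
    """Zero-or-one motif counting against one round's (masked) sequences."""

    def __init__(self, seqs: list[str], lengths: range, revcomp: bool):
        self.seqs = seqs
        self.revcomp = revcomp
        self.index = _build_index(seqs, lengths, revcomp)
        self._encoded = encode_sequences(seqs) if seqs else None

    def count_word_sets(self, k: int) -> dict[str, set[int]]:
        return self.index[k]

    def matching_indices(self, motif: Motif) -> set[int]:
        k = len(motif)
        if motif.n_expansions() <= _MAX_INDEX_EXPANSIONS and k in self.index:
            idx = self.index[k]
            out: set[int] = set()
            for w in motif.expansions():
                s = idx.get(w)
                if s:
                    out |= s
            return out
        hit = matches_encoded(motif, self._encoded)
        if self.revcomp:
            hit = hit | matches_encoded(motif.reverse_complement(), self._encoded)
        return set(np.flatnonzero(hit).tolist())

    def count(self, motif: Motif) -> int:
        return len(self.matching_indices(motif))


def _hill_climb(
    seed_word: str,
    pos: _RoundScorer,
    neg: _RoundScorer,
    pos_total: int,
    neg_total: int,
) -> tuple[Motif, float, int, int]:
    """Best-improvement generalization of a seed word.

    Moves replace one position's base set with a strict IUPAC superset; the
    first and last columns are never widened to the full wildcard N (keeps
    motif boundaries informative).  Only strict p improvements are accepted.
    """
    motif = Motif.from_consensus(seed_word)
    cur_pw = len(pos.matching_indices(motif))
    cur_nw = len(neg.matching_indices(motif))
    cur_p = fisher_enrichment(cur_pw, pos_total, cur_nw, neg_total)
    m = len(motif)
    while True:
        best_move = None
        for i in range(m):
            for sup in _SUPERSETS[motif.position_sets[i]]:
                if i in (0, m - 1) and sup == IUPAC_SETS["N"]:
                    continue
                cand = Motif(
                    motif.position_sets[:i] + (sup,) + motif.position_sets[i + 1 :]
                )
                pw = len(pos.matching_indices(cand))
                nw = len(neg.matching_indices(cand))
                p = fisher_enrichment(pw, pos_total, nw, neg_total)
                key = (p, cand.consensus)
                if p < cur_p and (best_move is None or key < best_move[0]):
                    best_move = (key, cand, pw, nw)
        if best_move is None:
            return motif, cur_p, cur_pw, cur_nw
        _, motif, cur_pw, cur_nw = best_move
        cur_p = best_move[0][0]


def mask_matches(motif: Motif, sequences: list[str], revcomp: bool = False) -> list[str]:
    """Replace every match window of ``motif`` with N in each sequence."""
    m = len(motif)
    out = []
    rc = motif.reverse_complement() if revcomp else None
    for seq in sequences:
        offsets = match_positions(motif, seq)
        if rc is not None:
            offsets = sorted(set(offsets) | set(match_positions(rc, seq)))
        if offsets:
            chars = list(seq)
            for off in offsets:
                chars[off : off + m] = "N" * m
            seq = "".join(chars)
        out.append(seq)
    return out


def discover_motifs(
    positives,
    background,
    min_len: int = 3,
    max_len: int = 8,
    e_threshold: float = 0.05,
    max_rounds: int = 20,
    n_seeds: int = 100,
    revcomp: bool = False,
) -> list[MotifDiscoveryResult]:
    """Iterative discriminative motif discovery.

    ``positives`` and ``background`` are dicts mapping sequence ID to DNA
    string (plain iterables of strings also work; IDs then default to list
    indices).  Returns one result per emitted motif, in discovery order
    (which is also increasing E-value order within a round structure).
    """
    pos_ids, pos_seqs = _as_id_seq_lists(positives)
    neg_ids, neg_seqs = _as_id_seq_lists(background)
    if not pos_seqs:
        raise ValueError("positive set is empty")
    if not neg_seqs:
        raise ValueError("background set is empty")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    lengths = range(min_len, max_len + 1)
    pos_total, neg_total = len(pos_seqs), len(neg_seqs)

    results: list[MotifDiscoveryResult] = []
    for rnd in range(max_rounds):
        pos_scorer = _RoundScorer(pos_seqs, lengths, revcomp)
        neg_scorer = _RoundScorer(neg_seqs, lengths, revcomp)

        # score every exact candidate word occurring in the positive set
        seed_pool: list[tuple[float, int, str]] = []
        n_candidates = 0
        for k in lengths:
            idx = pos_scorer.index[k]
            if not idx:
                continue
            words = sorted(idx)
            n_candidates += len(words)
            pw = np.array([len(idx[w]) for w in words])
            neg_idx = neg_scorer.index[k]
            nw = np.array([len(neg_idx.get(w, ())) for w in words])
            p = hypergeom.sf(pw - 1, pos_total + neg_total, pw + nw, pos_total)
            for w, pv in zip(words, p):
                seed_pool.append((float(pv), k, w))
        if n_candidates == 0:
            break
        seed_pool.sort()
        seeds = seed_pool[:n_seeds]

        best = None  # (p, len, consensus, motif, pw, nw)
        for _seed_p, _k, word in seeds:
            motif, p, pw, nw = _hill_climb(
                word, pos_scorer, neg_scorer, pos_total, neg_total
            )
            key = (p, len(motif), motif.consensus)
            if best is None or key < best[:3]:
                best = (p, len(motif), motif.consensus, motif, pw, nw)
        if best is None:
            break
        p, _, _, motif, pw, nw = best
        e_value = max(p * n_candidates, p)
        if e_value >= e_threshold:
            break
        matched = pos_scorer.matching_indices(motif)
        results.append(
            MotifDiscoveryResult(
                motif=motif,
                pos_with=pw,
                pos_total=pos_total,
                neg_with=nw,
                neg_total=neg_total,
                fisher_p=p,
                e_value=e_value,
                n_candidates=n_candidates,
                iteration=rnd + 1,
                matched_pos_ids=frozenset(pos_ids[i] for i in matched),
            )
        )
        pos_seqs = mask_matches(motif, pos_seqs, revcomp=revcomp)
        neg_seqs = mask_matches(motif, neg_seqs, revcomp=revcomp)
    results.sort(key=lambda r: r.e_value)  # stable: preserves round order on ties
    return results
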