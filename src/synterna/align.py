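"""Seeded local nucleotide alignment with BLASTN-like scoring.

The engine is a k-mer-seeded, two-hit triggered local aligner: seed words are
located on shared diagonals, clustered into candidate regions, and each region
is resolved by an exact affine-gap Smith-Waterman pass (numba kernel) on the
padded sub-rectangle.  Small problems skip the heuristics and run the full
dynamic program, so the heuristic layer only ever engages where it matters
(transcript-vs-genome searches).  E-values use Karlin-Altschul statistics with
lambda solved exactly for the scoring scheme.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ._kernels import sw_fill, sw_traceback

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


@dataclass(frozen=True)
class Scoring:
    """BLASTN-like scoring: a gap of length L costs gap_open + L*gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    ka_k: float = 0.30  # documented approximation; exact K is immaterial at 1e-10


@lru_cache(maxsize=16)
def karlin_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


def evalue(score: int, query_len: int, search_space: int, scoring: Scoring) -> float:
    lam = karlin_lambda(scoring.match, scoring.mismatch)
    return scoring.ka_k * query_len * search_space * math.exp(-lam * score)


def bitscore(score: int, scoring: Scoring) -> float:
    lam = karlin_lambda(scoring.match, scoring.mismatch)
    return (lam * score - math.log(scoring.ka_k)) / math.log(2.0)


@dataclass
class LocalAlignment:
    """One local alignment (HSP) in forward coordinates of both sequences."""

    score: int
    qstart: int
    qend: int  # half-open
    sstart: int
    send: int
    n_ident: int
    aln_len: int
    mismatches: int
    gap_opens: int


@dataclass
class PairwiseHit:
    """A scored hit of a query transcript against a subject sequence."""

    query_id: str
    subject_id: str
    identity_pct: float  # 100 * identical positions / query length
    aln_span_query: int
    score: int
    evalue: float
    bitscore: float = 0.0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    strand: str = "+"
    aln_len: int = 0
    mismatches: int = 0
    gap_opens: int = 0


def smith_waterman(qseq: str, sseq: str, scoring: Scoring = Scoring()) -> LocalAlignment:
    """Exact full-matrix affine-gap local alignment (also the extension engine)."""
    q = encode(qseq)
    s = encode(sseq)
    H, E, F, best, bi, bj = sw_fill(
        q, s, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, 0, 0)
    qs, ss, n_ident, aln_len, n_mm, n_go = sw_traceback(
        q, s, H, E, F, bi, bj,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    return LocalAlignment(int(best), int(qs), int(bi), int(ss), int(bj),
                          int(n_ident), int(aln_len), int(n_mm), int(n_go))


def _word_codes(codes: np.ndarray, word: int) -> np.ndarray:
    """Rolling 2-bit word codes; positions containing N get code -1."""
    n = codes.shape[0]
    if n < word:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    c = codes.astype(np.int64)
    out = np.zeros(n - word + 1, dtype=np.int64)
    ok = np.ones(n - word + 1, dtype=bool)
    for k in range(word):
        out = out * 4 + c[k: n - word + 1 + k]
        ok &= valid[k: n - word + 1 + k]
    out[~ok] = -1
    return out


def _multi_arange(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(s, s+c) for every (s, c) pair, vectorized."""
    keep = counts > 0
    starts, counts = starts[keep], counts[keep]
    if starts.size == 0:
        return np.empty(0, dtype=np.int64)
    total = int(counts.sum())
    steps = np.ones(total, dtype=np.int64)
    ends = np.cumsum(counts)
    steps[0] = starts[0]
    steps[ends[:-1]] = starts[1:] - (starts[:-1] + counts[:-1] - 1)
    return np.cumsum(steps)


class _WordIndex:
    """Sorted word-code index over one subject sequence."""

    def __init__(self, codes: np.ndarray, word: int):
        self.word = word
        wc = _word_codes(codes, word)
        keep = np.flatnonzero(wc >= 0)
        order = np.argsort(wc[keep], kind="stable")
        self.sorted_codes = wc[keep][order]
        self.positions = keep[order].astype(np.int64)

    def match(self, qwc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, subject_pos) word matches, as two arrays."""
        valid_q = np.flatnonzero(qwc >= 0)
        codes = qwc[valid_q]
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        counts = hi - lo
        qpos = np.repeat(valid_q, counts)
        spos = self.positions[_multi_arange(lo, counts)]
        return qpos.astype(np.int64), spos


def _seed_regions(qcodes: np.ndarray, index: _WordIndex, word: int,
                  band: int, max_seed_gap: int, two_hit: bool) -> list[tuple[int, int, int, int]]:
    """Cluster seed matches into candidate rectangles (q0,q1,s0,s1), padded later."""
    qwc = _word_codes(qcodes, word)
    qa, sa = index.match(qwc)
    return _regions_from_seeds(qa, sa, word, band, max_seed_gap, two_hit)


def _regions_from_seeds(qa: np.ndarray, sa: np.ndarray, word: int, band: int,
                        max_seed_gap: int, two_hit: bool
                        ) -> list[tuple[int, int, int, int]]:
    if qa.size == 0:
        return []
    diag = sa - qa
    order = np.lexsort((qa, diag))
    qa, sa, diag = qa[order], sa[order], diag[order]
    regions = []
    start = 0
    for k in range(1, len(qa) + 1):
        if k == len(qa) or diag[k] - diag[k - 1] > band:
            # same diagonal bundle; split on large query gaps
            sub = np.argsort(qa[start:k], kind="stable") + start
            run = [sub[0]]
            for idx in sub[1:]:
                if qa[idx] - qa[run[-1]] > max_seed_gap:
                    regions.append(run)
                    run = [idx]
                else:
                    run.append(idx)
            regions.append(run)
            start = k
    out = []
    for run in regions:
        if two_hit and len(run) < 2:
            continue
        qs = int(min(qa[i] for i in run))
        qe = int(max(qa[i] for i in run)) + word
        ss = int(min(sa[i] for i in run))
        se = int(max(sa[i] for i in run)) + word
        out.append((qs, qe, ss, se))
    return out


def _merge_rects(rects: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    rects = sorted(rects)
    merged: list[list[int]] = []
    for r in rects:
        for m in merged:
            if r[0] < m[1] and r[1] > m[0] and r[2] < m[3] and r[3] > m[2]:
                m[0] = min(m[0], r[0])
                m[1] = max(m[1], r[1])
                m[2] = min(m[2], r[2])
                m[3] = max(m[3], r[3])
                break
        else:
            merged.append(list(r))
    return [tuple(m) for m in merged]  # type: ignore[misc]


@dataclass
class SeedParams:
    word: int = 11
    band: int = 64
    max_seed_gap: int = 1000
    two_hit: bool = True
    full_dp_max_area: int = 250_000
    pad: int = 64


def local_alignments(qseq: str, sseq: str, scoring: Scoring = Scoring(),
                     seed: SeedParams = SeedParams(),
                     index: _WordIndex | None = None) -> list[LocalAlignment]:
    """All candidate local alignments of query vs one subject strand.

    Small problems (or queries shorter than the seed word) run one exact DP on
    the whole matrix; otherwise each seeded region is resolved independently.
    """
    nq, ns = len(qseq), len(sseq)
    if nq == 0 or ns == 0:
        return []
    if nq * ns <= seed.full_dp_max_area or nq < seed.word or ns < seed.word:
        aln = smith_waterman(qseq, sseq, scoring)
        return [aln] if aln.score > 0 else []
    qcodes = encode(qseq)
    if index is None:
        index = _WordIndex(encode(sseq), seed.word)
    rects = _seed_regions(qcodes, index, seed.word, seed.band, seed.max_seed_gap,
                          seed.two_hit)
    rects = [(max(0, q0 - seed.pad), min(nq, q1 + seed.pad),
              max(0, s0 - seed.pad), min(ns, s1 + seed.pad))
             for q0, q1, s0, s1 in rects]
    alignments = []
    for q0, q1, s0, s1 in _merge_rects(rects):
        aln = smith_waterman(qseq[q0:q1], sseq[s0:s1], scoring)
        if aln.score > 0:
            aln.qstart += q0
            aln.qend += q0
            aln.sstart += s0
            aln.send += s0
            alignments.append(aln)
    return alignments


def _dedupe(alns: list[LocalAlignment]) -> list[LocalAlignment]:
    """Drop HSPs whose subject interval overlaps a better-scoring one."""
    out: list[LocalAlignment] = []
    for a in sorted(alns, key=lambda x: (-x.score, x.sstart, x.qstart)):
        if all(a.send <= b.sstart or a.sstart >= b.send for b in out):
            out.append(a)
    return sorted(out, key=lambda x: (-x.score, x.sstart, x.qstart))


def _to_hit(query_id: str, subject_id: str, aln: LocalAlignment, qlen: int,
            strand: str, search_space: int, scoring: Scoring) -> PairwiseHit:
    if strand == "-":
        qstart, qend = qlen - aln.qend, qlen - aln.qstart
    else:
        qstart, qend = aln.qstart, aln.qend
    return PairwiseHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=100.0 * aln.n_ident / qlen,
        aln_span_query=aln.qend - aln.qstart,
        score=aln.score,
        evalue=evalue(aln.score, qlen, search_space, scoring),
        bitscore=bitscore(aln.score, scoring),
        qstart=qstart,
        qend=qend,
        sstart=aln.sstart,
        send=aln.send,
        strand=strand,
        aln_len=aln.aln_len,
        mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
    )


def pairwise_similarity(qseq: str, sseq: str, scoring: Scoring = Scoring(),
                        query_id: str = "query", subject_id: str = "subject",
                        evalue_threshold: float = 1e-10,
                        search_space: int | None = None,
                        both_strands: bool = False,
                        seed: SeedParams = SeedParams()) -> PairwiseHit | None:
    """Best local hit of query against subject, or None when no hit passes
    the e-value threshold."""
    if not qseq or not sseq:
        raise ValueError("pairwise_similarity requires non-empty sequences")
    space = search_space if search_space is not None else len(sseq)
    candidates = [(a, "+") for a in local_alignments(qseq, sseq, scoring, seed)]
    if both_strands:
        candidates += [(a, "-") for a in
                       local_alignments(revcomp(qseq), sseq, scoring, seed)]
    best: PairwiseHit | None = None
    for aln, strand in candidates:
        hit = _to_hit(query_id, subject_id, aln, len(qseq), strand, space, scoring)
        if hit.evalue > evalue_threshold:
            continue
        if best is None or hit.score > best.score:
            best = hit
    return best


class SequenceDatabase:
    """A searchable set of subject sequences behind one concatenated word
    index (sequences joined with N runs so no word spans a boundary)."""

    def __init__(self, sequences: dict[str, str], scoring: Scoring = Scoring(),
                 seed: SeedParams = SeedParams()):
        self.scoring = scoring
        self.seed = seed
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.total_length = sum(len(v) for v in self.sequences.values())
        self._ids = sorted(self.sequences)
        gap = "N" * seed.word
        concat = gap.join(self.sequences[k] for k in self._ids)
        starts = []
        pos = 0
        for k in self._ids:
            starts.append(pos)
            pos += len(self.sequences[k]) + seed.word
        self._starts = np.array(starts, dtype=np.int64)
        self._index = _WordIndex(encode(concat), seed.word) if concat else None

    def search(self, qseq: str, query_id: str = "query",
               evalue_threshold: float = 1e-10,
               both_strands: bool = True) -> list[PairwiseHit]:
        """All HSPs of the query against the database passing the e-value cut,
        best first (deterministic tie-break on subject id / coordinates)."""
        hits: list[PairwiseHit] = []
        qlen = len(qseq)
        if qlen == 0 or self._index is None:
            return hits
        strands = [("+", qseq)] + ([("-", revcomp(qseq))] if both_strands else [])
        per_subject: dict[str, list[tuple[LocalAlignment, str]]] = {}
        for strand, q in strands:
            qcodes = encode(q)
            qwc = _word_codes(qcodes, self.seed.word)
            qa, sa = self._index.match(qwc)
            if qa.size == 0:
                continue
            sub_idx = np.searchsorted(self._starts, sa, side="right") - 1
            local = sa - self._starts[sub_idx]
            order = np.argsort(sub_idx, kind="stable")
            sub_idx, qa, local = sub_idx[order], qa[order], local[order]
            bounds = np.flatnonzero(np.diff(sub_idx)) + 1
            for chunk_q, chunk_s, si in zip(np.split(qa, bounds),
                                            np.split(local, bounds),
                                            sub_idx[np.r_[0, bounds]]):
                sid = self._ids[int(si)]
                sseq = self.sequences[sid]
                rects = _regions_from_seeds(chunk_q, chunk_s, self.seed.word,
                                            self.seed.band,
                                            self.seed.max_seed_gap,
                                            self.seed.two_hit)
                pad = self.seed.pad
                rects = [(max(0, q0 - pad), min(len(q), q1 + pad),
                          max(0, s0 - pad), min(len(sseq), s1 + pad))
                         for q0, q1, s0, s1 in rects]
                for q0, q1, s0, s1 in _merge_rects(rects):
                    aln = smith_waterman(q[q0:q1], sseq[s0:s1], self.scoring)
                    if aln.score <= 0:
                        continue
                    aln.qstart += q0
                    aln.qend += q0
                    aln.sstart += s0
                    aln.send += s0
                    per_subject.setdefault(sid, []).append((aln, strand))
        for sid in sorted(per_subject):
            alns = per_subject[sid]
            kept = {id(a) for a in _dedupe([a for a, _ in alns])}
            for aln, strand in alns:
                if id(aln) not in kept:
                    continue
                hit = _to_hit(query_id, sid, aln, qlen, strand,
                              self.total_length, self.scoring)
                if hit.evalue <= evalue_threshold:
                    hits.append(hit)
        hits.sort(key=lambda h: (-h.score, h.subject_id, h.sstart))
        return hits
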