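"""Local alignment engine.

A desk-scale substitute for the BLAST / Bowtie2 steps of a virome pipeline:
seed-and-extend local alignment of contigs and reads against a phage genome
or marker-gene database, with raw Smith-Waterman scores, percent identity
computed from the traceback, and Karlin-Altschul e-values.

The dynamic programming kernels implement the affine-gap (Gotoh) recursion
exactly; a gap of length L costs ``gap_open + L * gap_extend``.  For small
problems every subject is aligned exhaustively, so the best reported score
equals the full Smith-Waterman optimum; for larger databases k-mer seeding
restricts the DP to diagonal windows around seed matches (a documented
heuristic, exact whenever the optimal alignment passes near a seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .seqs import encode, kmer_codes, revcomp, revcomp_rows

__all__ = [
    "Scoring",
    "AlignmentHit",
    "EvalueParams",
    "LocalAlignment",
    "smith_waterman",
    "seed_and_extend_align",
    "karlin_lambda",
    "estimate_evalue",
    "ReadMapper",
    "ReadHit",
]


@dataclass(frozen=True)
class Scoring:
    """BLASTN-like nucleotide scoring; N never scores as a match."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -3.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass(frozen=True)
class EvalueParams:
    """Karlin-Altschul parameters: E = K * m * n * exp(-lambda * S)."""

    K: float
    lam: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be positive")
        if self.m < 1 or self.n < 1:
            raise ValueError("sequence/database lengths must be >= 1")


@dataclass
class LocalAlignment:
    """Result of aligning one query/subject pair."""

    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns


@dataclass
class AlignmentHit:
    """One local hit of a query against a database subject.

    Spans are 0-based half-open on the forward strand of each sequence;
    ``aligned_length`` counts alignment columns including gap columns, and
    ``percent_identity`` = 100 * matches / columns.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int
    score: float
    e_value: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    strand: str


# ---------------------------------------------------------------------------
# DP kernels


@njit(cache=True, nogil=True)
def _sw_score(q, s, match, mismatch, go, ge):  # pragma: no cover - numba
    """Score-only Gotoh local alignment; returns (best, end_i, end_j)
    with 1-based DP end coordinates."""
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros(n + 1, np.float64)
    F = np.full(n + 1, -1.0e30, np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        diag = 0.0
        E = -1.0e30
        for j in range(1, n + 1):
            up = H[j]
            f = F[j] + ge
            fo = up + go + ge
            if fo > f:
                f = fo
            F[j] = f
            e = E + ge
            eo = H[j - 1] + go + ge
            if eo > e:
                e = eo
            E = e
            sj = s[j - 1]
            if qi == sj and qi < 4:
                h = diag + match
            else:
                h = diag + mismatch
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[j] = h
            diag = up
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True, nogil=True)
def _sw_traceback(q, s, match, mismatch, go, ge, ei, ej):  # pragma: no cover
    """Full DP with packed pointers; traceback from DP cell (ei, ej) in the
    H state.  Pointer byte: bits 0-1 = H choice (0 stop, 1 diag, 2 E, 3 F),
    bit 2 = E opened from H, bit 3 = F opened from H.

    Returns (score, q_start, s_start, matches, columns, qgaps, sgaps).
    """
    m = q.shape[0]
    n = s.shape[0]
    ptr = np.zeros((m + 1, n + 1), np.uint8)
    H = np.zeros(n + 1, np.float64)
    F = np.full(n + 1, -1.0e30, np.float64)
    h_end = 0.0
    for i in range(1, m + 1):
        qi = q[i - 1]
        diag = 0.0
        E = -1.0e30
        for j in range(1, n + 1):
            up = H[j]
            fo = up + go + ge
            fe = F[j] + ge
            if fo >= fe:
                F[j] = fo
                pf = 1
            else:
                F[j] = fe
                pf = 0
            eo = H[j - 1] + go + ge
            ee = E + ge
            if eo >= ee:
                E = eo
                pe = 1
            else:
                E = ee
                pe = 0
            if qi == s[j - 1] and qi < 4:
                h = diag + match
            else:
                h = diag + mismatch
            ph = 1
            if E > h:
                h = E
                ph = 2
            if F[j] > h:
                h = F[j]
                ph = 3
            if h <= 0.0:
                h = 0.0
                ph = 0
            H[j] = h
            diag = up
            ptr[i, j] = ph | (pe << 2) | (pf << 3)
            if i == ei and j == ej:
                h_end = h

    i = ei
    j = ej
    state = 0  # 0=H, 1=E, 2=F
    matches = 0
    columns = 0
    qgaps = 0
    sgaps = 0
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            ph = p & 3
            if ph == 0:
                break
            if ph == 1:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif ph == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            qgaps += 1
            opened = (p >> 2) & 1
            j -= 1
            if opened == 1:
                state = 0
        else:
            columns += 1
            sgaps += 1
            opened = (p >> 3) & 1
            i -= 1
            if opened == 1:
                state = 0
    return h_end, i, j, matches, columns, qgaps, sgaps


@njit(cache=True, nogil=True)
def _diag_align(read, s, d, match, mismatch):  # pragma: no cover - numba
    """Best gapless local alignment of ``read`` against subject ``s`` on
    diagonal ``d`` (read[i] paired with s[i+d]): maximum-scoring segment of
    the per-position match/mismatch score vector.

    Returns (score, q_start, q_end, matches, columns).
    """
    L = read.shape[0]
    n = s.shape[0]
    q0 = -d if d < 0 else 0
    q1 = n - d if n - d < L else L
    best = 0.0
    cur = 0.0
    cur_start = q0
    cur_matches = 0
    b_s = q0
    b_e = q0
    b_matches = 0
    for i in range(q0, q1):
        qi = read[i]
        if qi == s[i + d] and qi < 4:
            v = match
            mt = 1
        else:
            v = mismatch
            mt = 0
        if cur < 0.0:
            cur = v
            cur_start = i
            cur_matches = mt
        else:
            cur += v
            cur_matches += mt
        if cur > best:
            best = cur
            b_s = cur_start
            b_e = i + 1
            b_matches = cur_matches
    return best, b_s, b_e, b_matches, b_e - b_s


def _traceback_window(q: np.ndarray, s: np.ndarray, sc: Scoring,
                      best: float, bi: int, bj: int) -> LocalAlignment:
    """Recompute the DP with pointers on a subject window guaranteed to
    contain the optimal alignment ending at (bi, bj), then trace back."""
    width = min(bj, 2 * bi + 16)
    j0 = bj - width
    score, qs, ss, matches, columns, _qg, _sg = _sw_traceback(
        q[:bi], s[j0:bj], sc.match, sc.mismatch, sc.gap_open, sc.gap_extend,
        bi, width)
    return LocalAlignment(score=float(score), query_span=(qs, bi),
                          subject_span=(j0 + ss, bj), matches=int(matches),
                          columns=int(columns))


def smith_waterman(query, subject, scoring: Scoring = Scoring()) -> LocalAlignment | None:
    """Exact affine-gap local alignment of a single pair.

    Returns the best-scoring local alignment, or None when the optimal
    score is 0 (no positive-scoring alignment exists).
    """
    q = encode(query)
    s = encode(subject)
    if q.size == 0 or s.size == 0:
        return None
    best, bi, bj = _sw_score(q, s, scoring.match, scoring.mismatch,
                             scoring.gap_open, scoring.gap_extend)
    if best <= 0:
        return None
    return _traceback_window(q, s, scoring, best, bi, bj)


# ---------------------------------------------------------------------------
# E-values


def karlin_lambda(scoring: Scoring = Scoring(),
                  freqs: Sequence[float] | None = None) -> float:
    """Ungapped Karlin-Altschul lambda for a match/mismatch matrix.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 over the four bases with
    background frequencies ``freqs`` (uniform by default).  Gap penalties do
    not enter; the gapped statistic is approximated by the ungapped scale.
    """
    p = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("base frequencies must be a distribution over ACGT")
    pm = float((p ** 2).sum())  # probability of an identity pair
    pmm = 1.0 - pm

    def f(lam: float) -> float:
        return (pm * math.exp(lam * scoring.match)
                + pmm * math.exp(lam * scoring.mismatch) - 1.0)

    return float(brentq(f, 1e-3, 20.0))


def estimate_evalue(score: float, params: EvalueParams) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return params.K * params.m * params.n * math.exp(-params.lam * score)


# ---------------------------------------------------------------------------
# Seeded search


def _seed_windows(codes: np.ndarray, index: dict, n_subjects: int,
                  qlen: int, band: int) -> dict[int, list[tuple[int, int]]]:
    """Collect, per subject, subject-coordinate windows around seed matches."""
    per_subject: dict[int, list[int]] = {}
    for qpos in range(codes.shape[0]):
        entry = index.get(int(codes[qpos]))
        if entry is None:
            continue
        for sidx, spos in entry:
            per_subject.setdefault(sidx, []).append(spos - qpos)
    windows: dict[int, list[tuple[int, int]]] = {}
    for sidx, diags in per_subject.items():
        diags.sort()
        clusters: list[tuple[int, int]] = []
        lo = hi = diags[0]
        for d in diags[1:]:
            if d - hi > qlen:
                clusters.append((lo, hi))
                lo = d
            hi = d
        clusters.append((lo, hi))
        windows[sidx] = [(max(0, lo - band), hi + qlen + band)
                         for lo, hi in clusters]
    return windows


def seed_and_extend_align(
    query,
    subjects: Mapping[str, object],
    *,
    query_id: str = "query",
    k: int = 13,
    scoring: Scoring = Scoring(),
    min_score: float = 25.0,
    evalue_K: float = 0.1,
    lam: float | None = None,
    db_length: int | None = None,
    max_exhaustive_cells: int = 500_000,
    band: int = 48,
) -> list[AlignmentHit]:
    """Search a query against a subject database on both strands.

    Every reported hit meets ``min_score``; identity and aligned length come
    from the DP traceback.  When the total DP size is small the search is
    exhaustive (exact Smith-Waterman per subject); otherwise subjects and
    regions are selected by shared k-mers.  Hits are sorted by score, then
    e-value, then subject id.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    q = encode(query)
    if q.size == 0 or not subjects:
        return []
    seqs = {sid: encode(s) for sid, s in subjects.items()}
    ids = sorted(seqs)
    total = sum(len(s) for s in seqs.values())
    n_db = db_length if db_length is not None else total
    lam = karlin_lambda(scoring) if lam is None else lam
    params = EvalueParams(K=evalue_K, lam=lam, m=int(q.size), n=int(n_db))
    exhaustive = q.size * total <= max_exhaustive_cells

    index: dict | None = None
    if not exhaustive:
        index = {}
        for sidx, sid in enumerate(ids):
            codes = kmer_codes(seqs[sid], k) if len(seqs[sid]) >= k else np.empty(0, np.int64)
            for pos in range(codes.shape[0]):
                c = int(codes[pos])
                if c >= 0:
                    index.setdefault(c, []).append((sidx, pos))

    hits: list[AlignmentHit] = []
    for strand in "+-":
        qa = q if strand == "+" else revcomp(q)
        if exhaustive:
            windows = {sidx: [(0, len(seqs[ids[sidx]]))]
                       for sidx in range(len(ids))}
        else:
            if qa.size < k:
                continue
            qcodes = kmer_codes(qa, k)
            windows = _seed_windows(qcodes, index, len(ids), int(qa.size), band)
        for sidx, wins in windows.items():
            sid = ids[sidx]
            s = seqs[sid]
            best = (0.0, 0, 0, 0)  # score, bi, bj, w0
            for w0, w1 in wins:
                w1 = min(w1, len(s))
                if w1 - w0 <= 0:
                    continue
                sc, bi, bj = _sw_score(qa, s[w0:w1], scoring.match,
                                       scoring.mismatch, scoring.gap_open,
                                       scoring.gap_extend)
                if sc > best[0]:
                    best = (sc, bi, bj, w0)
            if best[0] < min_score:
                continue
            sc, bi, bj, w0 = best
            aln = _traceback_window(qa, s[w0:], scoring, sc, bi, bj)
            qs, qe = aln.query_span
            if strand == "-":
                qs, qe = q.size - qe, q.size - qs
            hits.append(AlignmentHit(
                query_id=query_id,
                subject_id=sid,
                percent_identity=aln.identity,
                aligned_length=aln.columns,
                score=aln.score,
                e_value=estimate_evalue(aln.score, params),
                query_span=(qs, qe),
                subject_span=(w0 + aln.subject_span[0], w0 + aln.subject_span[1]),
                strand=strand,
            ))
    hits.sort(key=lambda h: (-h.score, h.e_value, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# Batch read mapping


@dataclass
class ReadHit:
    subject_id: str
    strand: str
    score: float
    percent_identity: float
    aligned_length: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    detailed: bool = True


class ReadMapper:
    """Map batches of reads against a fixed subject set (contigs or marker
    genes) by k-mer seeding and windowed local DP.

    Seeding is strictly a speed device: a read is aligned only to subjects
    with which it shares at least one exact k-mer on either strand, then the
    DP runs in a diagonal window around the seeds.
    """

    def __init__(self, subjects: Mapping[str, object], *, k: int = 13,
                 scoring: Scoring = Scoring(), min_score: float = 40.0,
                 band: int = 24, probe_stride: int = 4):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.scoring = scoring
        self.min_score = min_score
        self.band = band
        self.probe_stride = max(1, probe_stride)
        self.ids = sorted(subjects)
        self.seqs = [encode(subjects[sid]) for sid in self.ids]
        index: dict[int, list[tuple[int, int]]] = {}
        for sidx, s in enumerate(self.seqs):
            if len(s) < k:
                continue
            codes = kmer_codes(s, k)
            for pos in range(codes.shape[0]):
                c = int(codes[pos])
                if c >= 0:
                    index.setdefault(c, []).append((sidx, pos))
        self._index = index
        self._code_arr = np.fromiter(index.keys(), dtype=np.int64,
                                     count=len(index))
        self._code_arr.sort()
        # concatenated subject bytes (0xFF separators) for the exact-match
        # fast path: an error-free read is an exact substring of its source
        self._blob = b"\xff".join(s.tobytes() for s in self.seqs)
        starts = [0]
        for s in self.seqs[:-1]:
            starts.append(starts[-1] + len(s) + 1)
        self._starts = np.asarray(starts, np.int64)

    def _exact_occurrences(self, rb: bytes) -> list[tuple[int, int]]:
        """All (subject_idx, offset) exact occurrences of a read."""
        out = []
        pos = self._blob.find(rb)
        while pos != -1:
            sidx = int(np.searchsorted(self._starts, pos, side="right")) - 1
            out.append((sidx, pos - int(self._starts[sidx])))
            pos = self._blob.find(rb, pos + 1)
        return out

    def map_reads(self, reads: np.ndarray | list) -> list[list[ReadHit]]:
        """Return, per read, the hits (best alignment per subject) with
        score >= min_score, sorted by (-score, subject_id).

        Every hit carries the subject and the DP (or exact-match) score;
        full traceback detail (identity, aligned length, spans) is computed
        for all hits tied at the read's best score — the only ones the
        downstream counting rules consult.  Lower-scoring hits keep
        ``detailed=False`` with NaN identity.
        """
        if isinstance(reads, list):
            if not reads:
                return []
            lengths = {len(r) for r in reads}
            if len(lengths) == 1:
                mat = np.vstack([encode(r) for r in reads])
            else:
                return [self.map_reads(encode(r)[None, :])[0] for r in reads]
        else:
            mat = np.asarray(reads, dtype=np.uint8)
        n_reads, qlen = mat.shape
        if qlen < self.k:
            return [[] for _ in range(n_reads)]
        rc = revcomp_rows(mat)
        match = self.scoring.match
        exact_score = qlen * match

        # candidate detection on strided k-mer probes, both strands
        probe_idx = np.arange(0, qlen - self.k + 1, self.probe_stride)
        cand: dict[int, list[tuple[str, np.ndarray, np.ndarray]]] = {}
        for strand, m in (("+", mat), ("-", rc)):
            codes = kmer_codes(m, self.k, stride=self.probe_stride)
            memb = np.isin(codes, self._code_arr)
            for r in np.nonzero(memb.any(axis=1))[0]:
                cand.setdefault(int(r), []).append((strand, codes[r], memb[r]))

        out: list[list[ReadHit]] = [[] for _ in range(n_reads)]
        for r, oriented in cand.items():
            # exact-substring fast path (reads without N only)
            exact: list[ReadHit] = []
            if mat[r].max() < 4:
                for strand, m in (("+", mat), ("-", rc)):
                    for sidx, off in self._exact_occurrences(m[r].tobytes()):
                        exact.append(ReadHit(
                            subject_id=self.ids[sidx], strand=strand,
                            score=exact_score, percent_identity=100.0,
                            aligned_length=qlen, query_span=(0, qlen),
                            subject_span=(off, off + qlen)))
            if exact:
                if exact_score >= self.min_score:
                    seen: dict[str, ReadHit] = {}
                    for h in exact:
                        seen.setdefault(h.subject_id, h)
                    out[r] = sorted(seen.values(),
                                    key=lambda h: h.subject_id)
                continue
            # seeded path: gapless diagonal alignment when all seeds of a
            # subject agree on one diagonal (substitution-only match),
            # windowed affine DP otherwise
            sc = self.scoring
            per_subj: dict[int, tuple] = {}  # sidx -> ("aln"|"dp", score, ...)
            for strand, codes, memb in oriented:
                read = mat[r] if strand == "+" else rc[r]
                per_subject: dict[int, list[int]] = {}
                for pi in np.nonzero(memb)[0]:
                    qpos = int(probe_idx[pi])
                    for sidx, spos in self._index[int(codes[pi])]:
                        per_subject.setdefault(sidx, []).append(spos - qpos)
                for sidx, diags in per_subject.items():
                    s = self.seqs[sidx]
                    if min(diags) == max(diags):
                        d = diags[0]
                        score, qs0, qe0, matches, columns = _diag_align(
                            read, s, d, sc.match, sc.mismatch)
                        if score < self.min_score:
                            continue
                        rec = ("aln", score, strand, qs0, qe0,
                               qs0 + d, qe0 + d, matches, columns)
                    else:
                        lo = max(0, min(diags) - self.band)
                        hi = min(len(s), max(diags) + qlen + self.band)
                        score, bi, bj = _sw_score(read, s[lo:hi], sc.match,
                                                  sc.mismatch, sc.gap_open,
                                                  sc.gap_extend)
                        if score < self.min_score:
                            continue
                        rec = ("dp", score, strand, lo, bi, bj)
                    prev = per_subj.get(sidx)
                    if prev is None or rec[1] > prev[1]:
                        per_subj[sidx] = rec
            if not per_subj:
                continue
            top = max(rec[1] for rec in per_subj.values())
            hits: list[ReadHit] = []
            for sidx, rec in per_subj.items():
                kind, score, strand = rec[0], rec[1], rec[2]
                if score < top:
                    hits.append(ReadHit(
                        subject_id=self.ids[sidx], strand=strand, score=score,
                        percent_identity=float("nan"), aligned_length=0,
                        query_span=(0, 0), subject_span=(0, 0),
                        detailed=False))
                    continue
                if kind == "aln":
                    _, _, _, qs, qe, ss, se, matches, columns = rec
                    identity = 100.0 * matches / columns
                else:
                    _, _, _, lo, bi, bj = rec
                    read = mat[r] if strand == "+" else rc[r]
                    aln = _traceback_window(read, self.seqs[sidx][lo:],
                                            sc, score, bi, bj)
                    qs, qe = aln.query_span
                    ss = lo + aln.subject_span[0]
                    se = lo + aln.subject_span[1]
                    identity = aln.identity
                    columns = aln.columns
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                hits.append(ReadHit(
                    subject_id=self.ids[sidx], strand=strand, score=score,
                    percent_identity=identity, aligned_length=int(columns),
                    query_span=(int(qs), int(qe)),
                    subject_span=(int(ss), int(se))))
            out[r] = sorted(hits, key=lambda h: (-h.score, h.subject_id))
        return out
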