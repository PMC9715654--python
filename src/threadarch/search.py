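"""Class-aware local alignment and E-value calibrated proteome search.

The degenerate residue-class query is aligned directly against every
proteome entry with affine-gap Smith–Waterman over a 9-class × 20-letter
scoring scheme, instead of first collapsing the query to one concrete
sequence.  Scores are in bits: a class C matched to letter a scores
log2(P(a|C)/p_a) with P(a|C) uniform over the class members, a fixed
mismatch floor otherwise, and zero for UNK columns (no evidence).

Statistical significance follows the Karlin–Altschul form
E(S) = K·m·n·exp(−λS), with (K, λ) fitted empirically: maximum local
scores against within-sequence shuffles of the database are fitted to a
Gumbel distribution by maximum likelihood.  Reported E-values use the
total database length, i.e. the per-subject expectations summed over the
database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from .fingerprint import CLASS_LABELS, CLASS_MEMBERS, DegenerateQuery
from .io import ProteomeRecord, logger
from .synth import AA_LETTERS

CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}
UNK_IDX = CLASS_INDEX["UNK"]


@dataclass
class ScoringScheme:
    """Class-vs-letter score matrix (bits) plus affine gap penalties."""

    matrix: np.ndarray  # (n_classes, 20)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape != (len(CLASS_LABELS), 20):
            raise ValueError(f"score matrix must be {(len(CLASS_LABELS), 20)}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("score matrix must be finite")
        if np.any(self.matrix[UNK_IDX] != 0.0):
            raise ValueError("UNK row must be all zeros")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")

    def score(self, label: str, letter: str) -> float:
        return float(self.matrix[CLASS_INDEX[label], AA_INDEX[letter]])


def build_scoring(
    background: dict[str, float] | np.ndarray | None = None,
    scale: float = 1.0,
    mismatch: float = -4.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> ScoringScheme:
    """Log-odds scoring for class columns against a background composition.

    score(C, a) = scale·log2((1/|C|)/p_a) for a ∈ members(C), scale·mismatch
    otherwise; the UNK row is identically zero.
    """
    if background is None:
        bg = np.full(20, 0.05)
    elif isinstance(background, dict):
        bg = np.array([background.get(a, 0.0) for a in AA_LETTERS], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    if bg.shape != (20,):
        raise ValueError("background must have 20 entries")
    if np.any(bg <= 0):
        zero = [AA_LETTERS[i] for i in np.flatnonzero(bg <= 0)]
        raise ValueError(f"background probability must be > 0 for every letter (bad: {zero})")
    matrix = np.full((len(CLASS_LABELS), 20), scale * mismatch, dtype=float)
    for label, members in CLASS_MEMBERS.items():
        ci = CLASS_INDEX[label]
        if label == "UNK":
            matrix[ci, :] = 0.0
            continue
        p_match = 1.0 / len(members)
        for a in members:
            matrix[ci, AA_INDEX[a]] = scale * math.log2(p_match / bg[AA_INDEX[a]])
    return ScoringScheme(matrix, gap_open, gap_extend, bg)


# ---------------------------------------------------------------------------
# Affine-gap local DP (Gotoh); a gap of length n costs open + n·extend


@njit(cache=True)
def _sw_matrices(q, s, S, open_ext, ext):
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), -1e30)
    F = np.full((m + 1, n + 1), -1e30)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - open_ext, E[i, j - 1] - ext)
            F[i, j] = max(H[i - 1, j] - open_ext, F[i - 1, j] - ext)
            h = H[i - 1, j - 1] + S[q[i - 1], s[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@dataclass
class LocalAlignment:
    """Optimal local alignment of a degenerate query to one subject."""

    score: float
    query_span: tuple[int, int]  # 1-based inclusive; (0, 0) if empty
    subject_span: tuple[int, int]
    pairs: list[tuple[int, int]]  # matched (query_pos, subject_pos), 1-based

    @property
    def is_empty(self) -> bool:
        return not self.pairs


def encode_query(query: DegenerateQuery | list[str]) -> np.ndarray:
    labels = query.labels if isinstance(query, DegenerateQuery) else list(query)
    return np.array([CLASS_INDEX[lab] for lab in labels], dtype=np.int64)


def encode_subject(sequence: str) -> np.ndarray:
    # X (unknown residue) is scored as the background-average letter: map to A
    return np.array([AA_INDEX.get(ch, AA_INDEX["A"]) for ch in sequence.upper()], dtype=np.int64)


def align_local(
    query: DegenerateQuery | list[str],
    subject: str,
    scheme: ScoringScheme,
) -> LocalAlignment:
    """Optimal affine-gap local alignment of the class query to a sequence.

    Ties are broken deterministically: the endpoint is the first maximum in
    row-major order and the traceback prefers match over deletion over
    insertion, which yields the shortest of the tied alignments.
    """
    q = encode_query(query)
    s = encode_subject(subject)
    if len(q) == 0 or len(s) == 0:
        raise ValueError("empty query or subject")
    open_ext = scheme.gap_open + scheme.gap_extend
    H, E, F, best, bi, bj = _sw_matrices(q, s, scheme.matrix, open_ext, scheme.gap_extend)
    if best <= 0.0:
        return LocalAlignment(0.0, (0, 0), (0, 0), [])
    pairs = []
    i, j = bi, bj
    tol = 1e-9
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] <= tol:
                break
            diag = H[i - 1, j - 1] + scheme.matrix[q[i - 1], s[j - 1]]
            if abs(H[i, j] - diag) <= tol:
                pairs.append((i, j))
                i, j = i - 1, j - 1
            elif abs(H[i, j] - F[i, j]) <= tol:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            if abs(F[i, j] - (H[i - 1, j] - open_ext)) <= tol:
                state = "H"
            i -= 1
        else:
            if abs(E[i, j] - (H[i, j - 1] - open_ext)) <= tol:
                state = "H"
            j -= 1
    q_start, s_start = i + 1, j + 1
    return LocalAlignment(float(best), (q_start, bi), (s_start, bj), pairs[::-1])


# ---------------------------------------------------------------------------
# E-value calibration


@dataclass
class EvalueCalibration:
    """Empirical Karlin–Altschul parameters: E(S) = K·m·n·exp(−λS)."""

    K: float
    lam: float
    n_shuffles: int
    sample_size: int

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be > 0")

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * score)


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (location, scale) fit."""
    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0:
        raise ValueError("degenerate fit: all scores identical")
    loc, scale = gumbel_r.fit(scores)
    return float(loc), float(scale)


def calibrate_evalue(
    query: DegenerateQuery | list[str],
    proteome: list[ProteomeRecord],
    scheme: ScoringScheme,
    n_shuffles: int = 100,
    seed: int = 0,
) -> EvalueCalibration:
    """Fit (K, λ) from max local scores against within-sequence shuffles.

    Shuffling within each sequence preserves composition and length while
    destroying any real signal, so the resulting maxima sample the null.
    """
    if n_shuffles < 30:
        raise ValueError(f"n_shuffles={n_shuffles} < 30: too few for a stable Gumbel fit")
    if not proteome:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(seed)
    q = encode_query(query)
    m = len(q)
    scores = np.empty(n_shuffles)
    lengths = np.empty(n_shuffles)
    open_ext = scheme.gap_open + scheme.gap_extend
    for t in range(n_shuffles):
        rec = proteome[t % len(proteome)]
        s = encode_subject(rec.sequence)
        rng.shuffle(s)
        *_, best, _, _ = _sw_matrices(q, s, scheme.matrix, open_ext, scheme.gap_extend)
        scores[t] = best
        lengths[t] = len(s)
    loc, scale = fit_gumbel(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (m * lengths.mean())
    return EvalueCalibration(K=K, lam=lam, n_shuffles=n_shuffles, sample_size=n_shuffles)


# ---------------------------------------------------------------------------
# Ranked search


@dataclass
class AlignmentHit:
    """Scored match of the degenerate query to one proteome entry.

    identity is the fraction of aligned non-UNK query columns whose subject
    letter is a member of the query class; coverage is aligned query
    positions over query length.
    """

    subject_id: str
    score: float  # bits
    evalue: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage outside [0, 1]")
        if self.evalue <= 0.0:
            raise ValueError("E-value must be > 0")


def _identity_coverage(
    query: DegenerateQuery | list[str], subject: str, aln: LocalAlignment
) -> tuple[float, float]:
    labels = query.labels if isinstance(query, DegenerateQuery) else list(query)
    informative = matched = 0
    for qi, sj in aln.pairs:
        lab = labels[qi - 1]
        if lab == "UNK":
            continue
        informative += 1
        if subject[sj - 1].upper() in CLASS_MEMBERS[lab]:
            matched += 1
    identity = matched / informative if informative else 0.0
    coverage = len({qi for qi, _ in aln.pairs}) / len(labels)
    return identity, coverage


def search_proteome(
    query: DegenerateQuery | list[str],
    proteome: list[ProteomeRecord],
    scheme: ScoringScheme,
    calibration: EvalueCalibration | None = None,
    evalue_max: float = 0.01,
    n_shuffles: int = 100,
    seed: int = 0,
) -> list[AlignmentHit]:
    """Align the query to every proteome entry and rank hits by E-value.

    E-values are database-wide (n = total database length).  Only hits with
    E ≤ ``evalue_max`` are reported, ascending in E.
    """
    if not proteome:
        logger.warning("empty proteome: no hits")
        return []
    if calibration is None:
        calibration = calibrate_evalue(query, proteome, scheme, n_shuffles=n_shuffles, seed=seed)
    m = len(query.labels) if isinstance(query, DegenerateQuery) else len(query)
    db_len = sum(len(rec.sequence) for rec in proteome)
    hits = []
    for rec in proteome:
        aln = align_local(query, rec.sequence, scheme)
        if aln.is_empty:
            continue
        ev = calibration.evalue(aln.score, m, db_len)
        if ev > evalue_max:
            continue
        identity, coverage = _identity_coverage(query, rec.sequence, aln)
        hits.append(
            AlignmentHit(
                subject_id=rec.id,
                score=aln.score,
                evalue=ev,
                query_span=aln.query_span,
                subject_span=aln.subject_span,
                identity=identity,
                coverage=coverage,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id))
    return hits
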