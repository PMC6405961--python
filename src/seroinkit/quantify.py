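"""Class-specific read counting by translated local alignment.

Reads are compared against each class's 80 C-terminal query residues by
Smith-Waterman over all six reading frames (the TBLASTN idea), and hits
are thresholded on Karlin-Altschul E-values E = K * m * n * exp(-lambda*S)
with ungapped lambda and K applied to the (affine-gapped) scores - the
classic approximation, which overstates E slightly and is therefore
conservative at a fixed threshold.  n is the translated read length, i.e.
E-values are per read, not per library.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from math import exp, gcd, log
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SeqRecordLite, translate

DEFAULT_EVALUE = 1e-20
QUERY_LEN = 80
LOCAL_GAP_OPEN = 11.0
LOCAL_GAP_EXTEND = 1.0

#: Robinson & Robinson amino-acid background frequencies
ROBINSON_FREQS: dict[str, float] = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


@dataclass(frozen=True)
class KarlinAltschulParams:
    """lambda and K for an ungapped scoring system."""

    lam: float
    K: float
    matrix: str
    H: float  # relative entropy (nats per aligned pair)

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * exp(-self.lam * score)


def _score_probabilities(matrix, background: Mapping[str, float]
                         ) -> dict[int, float]:
    total = sum(background.values())
    freqs = {aa: f / total for aa, f in background.items()}
    probs: dict[int, float] = {}
    for a, pa in freqs.items():
        for b, pb in freqs.items():
            s = int(matrix[a][b])
            probs[s] = probs.get(s, 0.0) + pa * pb
    return probs


def karlin_altschul_params(matrix_name: str = "BLOSUM62",
                           background: Optional[Mapping[str, float]] = None,
                           score_probs: Optional[Mapping[int, float]] = None,
                           tol: float = 1e-9) -> KarlinAltschulParams:
    """Solve for lambda and K of an ungapped scoring system.

    lambda is the positive root of sum_ij p_i p_j exp(lambda s_ij) = 1
    (bisection to ``tol``); K follows the classic lattice-case series
    approximation, with the closed form for {+1, -1}-type score supports.
    Requires negative expected score and at least one positive score.
    """
    if score_probs is None:
        matrix = substitution_matrices.load(matrix_name)
        score_probs = _score_probabilities(matrix, background or ROBINSON_FREQS)
    probs = {int(s): float(p) for s, p in score_probs.items() if p > 0}
    expected = sum(s * p for s, p in probs.items())
    if expected >= 0 or max(probs) <= 0:
        raise ValueError(
            "invalid scoring system: expected score must be negative and "
            "some score positive"
        )

    def f(lam: float) -> float:
        return sum(p * exp(lam * s) for s, p in probs.items()) - 1.0

    lo, hi = tol, 0.5
    while f(hi) < 0:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (lo, mid) if f(mid) > 0 else (mid, hi)
    lam = 0.5 * (lo + hi)

    av = sum(p * s * exp(lam * s) for s, p in probs.items())  # E[S e^{lam S}]
    H = lam * av
    K = _karlin_K(probs, lam, av)
    return KarlinAltschulParams(lam, K, matrix_name, H)


def _karlin_K(probs: dict[int, float], lam: float, av: float,
              iters: int = 100) -> float:
    """Lattice-case K via the Karlin-Altschul series.

    sigma = sum_k (1/k) [ E(e^{lam S_k}; S_k < 0) + P(S_k >= 0) ],
    K = d * exp(-2 sigma) / (av * (1 - e^{-lam d})) with d the score-span
    lattice unit.  For the minimal support {-1, +1} the closed form
    (p(+1) - p(-1))^2 / p(-1) is exact and used directly.
    """
    scores = sorted(probs)
    low, high = scores[0], scores[-1]
    d = reduce(gcd, (abs(s) for s in scores if s != 0))
    if set(scores) == {-1, 1}:
        return (probs[1] - probs[-1]) ** 2 / probs[-1]
    span = high - low
    step = np.zeros(span + 1)
    for s, p in probs.items():
        step[s - low] += p
    sigma = 0.0
    pk = step.copy()
    for k in range(1, iters + 1):
        if k > 1:
            pk = np.convolve(pk, step)
        vals = np.arange(k * low, k * high + 1)
        neg = vals < 0
        bracket = float(np.sum(pk[neg] * np.exp(lam * vals[neg])) + np.sum(pk[~neg]))
        sigma += bracket / k
    return d * exp(-2.0 * sigma) / (av * (1.0 - exp(-lam * d)))


@dataclass
class ReadHit:
    """Best translated-frame local alignment of a read against one query."""

    read_id: str
    seroin_class: str
    frame: int
    score: float
    evalue: float


def _local_aligner(matrix_name: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -LOCAL_GAP_OPEN
    aligner.extend_gap_score = -LOCAL_GAP_EXTEND
    return aligner


def local_align_translated(read: SeqRecordLite | str, query_protein: str,
                           params: KarlinAltschulParams,
                           seroin_class: str = "?",
                           aligner: Optional[Align.PairwiseAligner] = None
                           ) -> Optional[ReadHit]:
    """Best Smith-Waterman hit of the query over all six frame translations.

    Returns None for reads shorter than one codon.  The E-value uses
    m = query length and n = translated frame length.
    """
    seq = read.sequence if isinstance(read, SeqRecordLite) else read
    rid = read.id if isinstance(read, SeqRecordLite) else "read"
    if len(seq) < 3:
        return None
    aligner = aligner or _local_aligner(params.matrix)
    best: Optional[ReadHit] = None
    for frame in range(6):
        prot = translate(seq, frame)
        if not prot:
            continue
        score = float(aligner.score(query_protein, prot))
        if score <= 0:
            continue
        ev = params.evalue(score, len(query_protein), len(prot))
        if best is None or score > best.score:
            best = ReadHit(rid, seroin_class, frame, score, ev)
    return best


@dataclass
class ClassCounts:
    """Per-class read counts at an E-value threshold."""

    counts: dict[str, int]
    unassigned: int
    total: int
    skipped: int
    evalue_max: float


def count_class_reads(reads: Sequence[SeqRecordLite],
                      class_queries: Mapping[str, str],
                      evalue_max: float = DEFAULT_EVALUE,
                      params: Optional[KarlinAltschulParams] = None
                      ) -> ClassCounts:
    """Assign each read to the class of its single best hit under threshold.

    Queries should be the 80 C-terminal residues of each class reference
    (shorter references simply use their full length).  Ties between
    classes on the best score leave the read unassigned; every read lands
    in exactly one of counts/unassigned/skipped.
    """
    params = params or karlin_altschul_params()
    aligner = _local_aligner(params.matrix)
    counts = {cls: 0 for cls in class_queries}
    unassigned = 0
    skipped = 0
    for read in reads:
        if len(read.sequence) < 3:
            skipped += 1
            continue
        hits = []
        for cls, query in class_queries.items():
            hit = local_align_translated(read, query, params, cls, aligner)
            if hit is not None and hit.evalue <= evalue_max:
                hits.append(hit)
        if not hits:
            unassigned += 1
            continue
        hits.sort(key=lambda h: (-h.score, h.seroin_class))
        if len(hits) > 1 and hits[0].score == hits[1].score:
            unassigned += 1
            continue
        counts[hits[0].seroin_class] += 1
    return ClassCounts(counts, unassigned, len(reads), skipped, evalue_max)


def cterm_query(protein: str, query_len: int = QUERY_LEN) -> str:
    """The C-terminal ``query_len`` residues (full protein when shorter)."""
    return protein[-query_len:]
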