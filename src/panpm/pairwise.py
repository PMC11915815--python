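"""Shared local-alignment helpers (BLOSUM62, affine gaps) and e-values.

E-values use the Karlin–Altschul approximation with the standard gapped
BLOSUM62 (open 11 / extend 1) parameters lambda = 0.267, K = 0.041; the
search-space size is query length x database residues.  This is a
thresholding device, not a re-implementation of BLAST statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

_LAMBDA = 0.267
_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_LOCAL = make_aligner("local")
_GLOBAL = make_aligner("global")


def _sanitize(seq: str) -> str:
    # BLOSUM62 in Biopython has no column for every ambiguity code; X is
    # present, so only map other unknowns onto X.
    alpha = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in alpha else "X" for c in seq.upper())


@dataclass(frozen=True)
class LocalHit:
    score: float
    identities: int
    aligned_query: int
    aligned_target: int

    @property
    def identity_short(self) -> float:
        """Identity normalized by the shorter aligned span (0 if empty)."""
        span = min(self.aligned_query, self.aligned_target)
        return self.identities / span if span else 0.0


def best_local_hit(query: str, target: str) -> LocalHit | None:
    """Best-scoring local alignment of query vs target, or None if <= 0."""
    q, t = _sanitize(query), _sanitize(target)
    if not q or not t:
        return None
    score = _LOCAL.score(q, t)
    if score <= 0:
        return None
    aln = next(iter(_LOCAL.align(q, t)))
    counts = aln.counts()
    qspan = sum(b - a for a, b in aln.aligned[0])
    tspan = sum(b - a for a, b in aln.aligned[1])
    return LocalHit(score, counts.identities, qspan, tspan)


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity normalized by the shorter sequence."""
    a, b = _sanitize(a), _sanitize(b)
    if not a or not b:
        return 0.0
    aln = next(iter(_GLOBAL.align(a, b)))
    return aln.counts().identities / min(len(a), len(b))


def evalue(score: float, query_len: int, db_residues: int) -> float:
    """Karlin-Altschul e-value for a raw local-alignment score."""
    if query_len <= 0 or db_residues <= 0:
        return math.inf
    return _K * query_len * db_residues * math.exp(-_LAMBDA * score)
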