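"""Local protein alignment, bit scores, and the bit score ratio (BSR).

The BSR of a sequence pair is its local-alignment bit score normalised by
the smaller of the two self-alignment bit scores, giving a symmetric
similarity in [0, 1].  It is the pairwise quantity behind homolog fishing,
inter-cluster distances and the minimum spanning forest.

Alignment is exact Smith–Waterman with affine gaps (no heuristic seeding);
the default scoring is BLOSUM62 with gap open -11 / extend -1 and the
standard gapped Karlin–Altschul parameters lambda = 0.267, K = 0.041.
Gap convention: the first residue of a gap costs ``gap_open`` and every
further residue ``gap_extend`` (a gap of length g costs 11 + (g-1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_model import PROTEIN_ALPHABET, SequenceError


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin–Altschul constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267
    k_: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise ValueError("lambda_ and k_ must be positive")

    @property
    def substitution(self):
        return _load_matrix(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        """Substitution score for one residue pair."""
        return float(self.substitution[a, b])


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=_load_matrix(scheme.matrix_name),
        open_gap_score=scheme.gap_open,
        extend_gap_score=scheme.gap_extend,
    )
    return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentResult:
    """Optimal local alignment with identity and coverage bookkeeping.

    ``path`` lists the aligned blocks as ``((a_start, a_end), (b_start,
    b_end))`` pairs of 0-based half-open coordinates; an empty path means no
    positive-scoring local alignment exists.
    """

    raw_score: float
    bit_score: float
    path: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    identity: float = 0.0
    query_cov: float = 0.0
    subject_cov: float = 0.0


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise SequenceError(f"{name}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise SequenceError(f"{name}: illegal residue(s) {sorted(bad)}")


def bit_score(raw: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin–Altschul normalised score: (lambda*raw - ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be non-negative for local alignment")
    return (scheme.lambda_ * raw - math.log(scheme.k_)) / math.log(2.0)


def align_local(a: str, b: str,
                scheme: ScoringScheme = DEFAULT_SCHEME) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment of two protein sequences.

    Returns the optimal raw and bit score together with the deterministic
    first traceback's aligned blocks, identity over aligned columns, and
    coverage of each sequence by the aligned span.  A pair with no
    positive-scoring alignment yields raw_score 0 and an empty path.
    """
    _check_protein(a, "first sequence")
    _check_protein(b, "second sequence")
    aligner = _aligner(scheme)
    score = float(aligner.score(a, b))
    if score <= 0:
        return AlignmentResult(raw_score=0.0, bit_score=bit_score(0.0, scheme))
    aln = aligner.align(a, b)[0]
    blocks = [
        ((int(sa), int(ea)), (int(sb), int(eb)))
        for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1])
    ]
    matches = 0
    cols = 0
    for (sa, ea), (sb, eb) in blocks:
        cols += ea - sa
        for i, j in zip(range(sa, ea), range(sb, eb)):
            if a[i] == b[j]:
                matches += 1
    # gap columns inside the local alignment also count as aligned columns
    span_a = blocks[-1][0][1] - blocks[0][0][0]
    span_b = blocks[-1][1][1] - blocks[0][1][0]
    gap_cols = (span_a - cols) + (span_b - cols)
    total_cols = cols + gap_cols
    identity = matches / total_cols if total_cols else 0.0
    return AlignmentResult(
        raw_score=score,
        bit_score=bit_score(score, scheme),
        path=blocks,
        identity=identity,
        query_cov=span_a / len(a),
        subject_cov=span_b / len(b),
    )


def self_bit_score(a: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Bit score of a sequence aligned to itself (the BSR denominator)."""
    aligner = _aligner(scheme)
    return bit_score(max(float(aligner.score(a, a)), 0.0), scheme)


def bsr(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Bit score ratio: bits(a,b) / min(bits(a,a), bits(b,b)), clipped to [0,1].

    Symmetric by construction.  Raises on a degenerate sequence whose self
    bit score is non-positive.
    """
    denom = min(self_bit_score(a, scheme), self_bit_score(b, scheme))
    if denom <= 0:
        raise ValueError("degenerate sequence: self bit score <= 0")
    aligner = _aligner(scheme)
    raw = max(float(aligner.score(a, b)), 0.0)
    if raw <= 0:
        return 0.0
    return float(min(max(bit_score(raw, scheme) / denom, 0.0), 1.0))


def bsr_matrix(seqs: dict[str, str],
               scheme: ScoringScheme = DEFAULT_SCHEME) -> "tuple[list[str], np.ndarray]":
    """All-vs-all BSR matrix; returns (ordered ids, symmetric array).

    Self bit scores are computed once per sequence.
    """
    ids = sorted(seqs)
    aligner = _aligner(scheme)
    selfbits = {i: self_bit_score(seqs[i], scheme) for i in ids}
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[ids[i]], seqs[ids[j]]
            denom = min(selfbits[ids[i]], selfbits[ids[j]])
            if denom <= 0:
                raise ValueError(f"degenerate sequence {ids[i]} or {ids[j]}")
            raw = max(float(aligner.score(a, b)), 0.0)
            val = 0.0 if raw <= 0 else min(max(bit_score(raw, scheme) / denom, 0.0), 1.0)
            mat[i, j] = mat[j, i] = val
    return ids, mat


def write_bsr_matrix(ids: list[str], mat: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, rid in enumerate(ids):
            fh.write(rid + "\t" + "\t".join(f"{v:.4f}" for v in mat[i]) + "\n")
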