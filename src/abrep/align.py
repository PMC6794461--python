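"""Pairwise alignment primitives.

Two engines, chosen by purpose:

* germline assignment and signature search use local (Smith-Waterman style)
  alignment through :class:`Bio.Align.PairwiseAligner` with nucleotide
  BLAST-like scores (+2 match, -3 mismatch, -5 open, -2 extend), plus a
  Karlin-Altschul style significance score ``evalue_like = K*m*n*exp(-lambda*S)``
  with K = 0.41 and lambda = 0.625 as documented, configurable constants;
* clustering identity uses the Levenshtein identity ``1 - d / max(|a|, |b|)``
  (edlib backend), the deterministic definition used by the USEARCH/vsearch
  family of greedy clusterers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import edlib
from Bio import Align

DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -3
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXTEND = -2
KARLIN_K = 0.41
KARLIN_LAMBDA = 0.625


@dataclass
class AlignmentResult:
    """A local alignment of a query against a reference sequence."""

    query_span: tuple[int, int]
    reference_span: tuple[int, int]
    score: float
    identity: float
    #: (reference position, query base) for every aligned mismatching column
    mismatch_positions: list[tuple[int, str]]
    evalue_like: float
    #: aligned blocks [((ref_start, ref_end), (q_start, q_end)), ...]
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    n_matches: int = 0
    n_columns: int = 0

    def ref_to_query(self) -> dict[int, int]:
        """Reference position -> query position over aligned (paired) columns."""
        out: dict[int, int] = {}
        for (r0, r1), (q0, q1) in self.blocks:
            for k in range(r1 - r0):
                out[r0 + k] = q0 + k
        return out

    def longest_match_run(self, reference: str, query: str) -> int:
        best = run = 0
        for (r0, r1), (q0, q1) in self.blocks:
            for k in range(r1 - r0):
                if reference[r0 + k] == query[q0 + k]:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
            run = 0  # gap between blocks breaks the run
        return best


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
             mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def evalue_like(score: float, m: int, n: int,
                k: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    """Karlin-Altschul style expectation for a local alignment score.

    Monotone decreasing in ``score`` at fixed search-space size ``m * n``.
    """
    return k * m * n * math.exp(-lam * score)


def local_align(
    reference: str,
    query: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult | None:
    """Best local alignment of ``query`` against ``reference``.

    Returns None when no positive-scoring alignment exists. Identity is
    matching columns / aligned columns (paired plus internal gap columns;
    local alignments carry no terminal gaps by construction).
    """
    if not reference or not query:
        return None
    al = _aligner(match, mismatch, gap_open, gap_extend, "local")
    try:
        alignment = al.align(reference, query)[0]
    except (IndexError, ValueError):
        return None
    ref_blocks, q_blocks = alignment.aligned
    blocks = [
        ((int(r0), int(r1)), (int(q0), int(q1)))
        for (r0, r1), (q0, q1) in zip(ref_blocks, q_blocks)
    ]
    if not blocks:
        return None
    matches = 0
    paired = 0
    mismatches: list[tuple[int, str]] = []
    for (r0, r1), (q0, q1) in blocks:
        paired += r1 - r0
        for k in range(r1 - r0):
            if reference[r0 + k] == query[q0 + k]:
                matches += 1
            else:
                mismatches.append((r0 + k, query[q0 + k]))
    r_span = (blocks[0][0][0], blocks[-1][0][1])
    q_span = (blocks[0][1][0], blocks[-1][1][1])
    columns = (r_span[1] - r_span[0]) + (q_span[1] - q_span[0]) - paired
    return AlignmentResult(
        query_span=q_span,
        reference_span=r_span,
        score=float(alignment.score),
        identity=matches / columns if columns else 0.0,
        mismatch_positions=mismatches,
        evalue_like=evalue_like(float(alignment.score), len(reference), len(query)),
        blocks=blocks,
        n_matches=matches,
        n_columns=columns,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Levenshtein identity ``1 - d / max(|a|, |b|)``; symmetric in a, b.

    Identical strings score 1.0; "ACGT" vs "ACGA" scores 0.75.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))
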