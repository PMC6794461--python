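"""Signature search, prevalence estimation, and rarefaction.

A signature query describes an antibody class by any of three modes:

* ``cdr3`` — an anchored amino-acid motif over the CDR3, in the
  dash-separated grammar used in the repertoire literature
  (``X-X-[AFILMYWV]-[EQ]-X``: ``X`` any residue, ``[...]`` a residue
  class, plain letters literal), optionally with gene / isotype / length
  constraints;
* ``position`` — residue classes required at numbered positions
  (any supported numbering scheme), e.g. Trp at heavy-chain position 52;
* ``sequence`` — similarity search of a full V(D)J sequence, keeping hits
  with an expectation value below a cutoff.

Per-repertoire signature frequency divides matched transcripts by the
unique transcripts of the same germline gene (or the whole repertoire —
the convention is explicit). Rarefaction resamples repertoire subsets to
show how the coefficient of variation (sample SD of per-repeat mean
frequencies over their mean) shrinks as more repertoires are sampled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import evalue_like, local_align
from .model import AnnotatedTranscript

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class QueryError(ValueError):
    """Malformed signature query; the message localizes the fault."""


@dataclass
class SignatureQuery:
    mode: str  # cdr3 | position | sequence
    gene_constraint: Optional[str] = None  # gene- or allele-level name
    isotype_constraint: Optional[str] = None
    cdr3_length: Optional[int] = None
    motif: Optional[str] = None
    #: (scheme, position label, residue class text) requirements
    positions: list[tuple[str, str, str]] = field(default_factory=list)
    query_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("cdr3", "position", "sequence"):
            raise QueryError(f"unknown query mode {self.mode!r}")
        if self.mode == "cdr3" and self.motif is None and self.cdr3_length is None:
            raise QueryError("cdr3 mode requires a motif and/or a CDR3 length")
        if self.mode == "position" and not self.positions:
            raise QueryError("position mode requires position constraints")
        if self.mode == "sequence" and not self.query_seq:
            raise QueryError("sequence mode requires a query sequence")


def _compile_slot(slot: str, index: int) -> str:
    if slot == "X":
        return "."
    if slot.startswith("[") and slot.endswith("]"):
        inner = slot[1:-1]
        if not inner or any(c not in AA20 + "X" for c in inner):
            raise QueryError(f"slot {index + 1}: bad residue class {slot!r}")
        return "." if "X" in inner else f"[{inner}]"
    if all(c in AA20 for c in slot):
        return slot
    raise QueryError(f"slot {index + 1}: unrecognized token {slot!r}")


def compile_motif(motif: str) -> re.Pattern:
    """Compile a dash-separated motif to an anchored regular expression."""
    if not motif:
        raise QueryError("empty motif")
    parts = [_compile_slot(s, i) for i, s in enumerate(motif.split("-"))]
    return re.compile("".join(parts) + r"\Z")


def _residue_class_match(cls: str, residue: str) -> bool:
    if cls == "X":
        return True
    if cls.startswith("[") and cls.endswith("]"):
        return residue in cls[1:-1] or "X" in cls[1:-1]
    return residue == cls


def _gene_matches(constraint: Optional[str], t: AnnotatedTranscript) -> bool:
    if constraint is None:
        return True
    if t.v_call is None:
        return False
    if "*" in constraint:  # allele-level
        return t.v_call == constraint
    return t.v_gene == constraint


def _common_constraints(q: SignatureQuery, t: AnnotatedTranscript) -> bool:
    if not _gene_matches(q.gene_constraint, t):
        return False
    if q.isotype_constraint is not None and t.isotype != q.isotype_constraint:
        return False
    return True


def match_cdr3(query: SignatureQuery, t: AnnotatedTranscript) -> bool:
    """True iff gene/isotype/length constraints hold and the CDR3 matches
    the motif anchored over its full length."""
    if query.mode != "cdr3":
        raise QueryError("match_cdr3 requires a cdr3-mode query")
    if not _common_constraints(query, t) or t.cdr3_aa is None:
        return False
    if query.cdr3_length is not None and len(t.cdr3_aa) != query.cdr3_length:
        return False
    if query.motif is not None:
        return compile_motif(query.motif).fullmatch(t.cdr3_aa) is not None
    return True


def match_position(query: SignatureQuery, t: AnnotatedTranscript) -> bool:
    """True iff every (scheme, position, residue class) constraint holds.

    Unnumbered or unobserved positions fail their constraint.
    """
    if query.mode != "position":
        raise QueryError("match_position requires a position-mode query")
    if not _common_constraints(query, t):
        return False
    for scheme, label, cls in query.positions:
        numbering = t.numbering.get(scheme)
        if numbering is None:
            raise QueryError(
                f"transcript {t.record.read_id!r} carries no {scheme} numbering"
            )
        residue = numbering.get(label)
        if residue is None or not _residue_class_match(cls, residue):
            return False
    return True


def match_sequence(
    query: SignatureQuery,
    transcripts: Sequence[AnnotatedTranscript],
    evalue_max: float = 1e-6,
) -> list[AnnotatedTranscript]:
    """Similarity search; hits with evalue below the cutoff, best first."""
    if query.mode != "sequence":
        raise QueryError("match_sequence requires a sequence-mode query")
    if not query.query_seq:
        raise QueryError("empty query sequence")
    hits: list[tuple[float, AnnotatedTranscript]] = []
    for t in transcripts:
        if not _common_constraints(query, t):
            continue
        aln = local_align(query.query_seq, t.record.nt)
        if aln is None:
            continue
        e = evalue_like(aln.score, len(query.query_seq), len(t.record.nt))
        if e < evalue_max:
            hits.append((aln.score, t))
    hits.sort(key=lambda h: -h[0])
    return [t for _, t in hits]


def matches(query: SignatureQuery, t: AnnotatedTranscript) -> bool:
    if query.mode == "cdr3":
        return match_cdr3(query, t)
    if query.mode == "position":
        return match_position(query, t)
    raise QueryError("per-transcript matching supports cdr3/position modes")


@dataclass
class PrevalenceRow:
    repertoire_id: str
    matched: int
    denominator: int
    frequency: Optional[float]  # None (absent) on a zero denominator


@dataclass
class PrevalenceResult:
    rows: list[PrevalenceRow]

    @property
    def mean_frequency(self) -> Optional[float]:
        fs = [r.frequency for r in self.rows if r.frequency is not None]
        return float(np.mean(fs)) if fs else None

    @property
    def sd_frequency(self) -> Optional[float]:
        fs = [r.frequency for r in self.rows if r.frequency is not None]
        return float(np.std(fs, ddof=1)) if len(fs) > 1 else None

    @property
    def fraction_with_match(self) -> Optional[float]:
        rows = [r for r in self.rows if r.frequency is not None]
        if not rows:
            return None
        return sum(1 for r in rows if r.matched > 0) / len(rows)


def signature_frequency(
    query: SignatureQuery,
    transcripts: Sequence[AnnotatedTranscript],
    repertoire_id: str = "",
    denominator: str = "gene",
) -> PrevalenceRow:
    """Signature frequency in one curated repertoire.

    ``denominator="gene"`` counts unique transcripts assigned to the
    query's gene constraint (falls back to the whole repertoire when the
    query has none); ``denominator="all"`` always uses the whole
    repertoire. A zero denominator reports the frequency as absent (None),
    never as 0.
    """
    if denominator not in ("gene", "all"):
        raise ValueError("denominator must be 'gene' or 'all'")
    if denominator == "gene" and query.gene_constraint is not None:
        pool = [t for t in transcripts if _gene_matches(query.gene_constraint, t)]
    else:
        pool = list(transcripts)
    matched = sum(1 for t in pool if matches(query, t))
    denom = len(pool)
    return PrevalenceRow(
        repertoire_id=repertoire_id, matched=matched, denominator=denom,
        frequency=(matched / denom) if denom else None,
    )


def pairing_frequency(heavy_freq: float, light_freq: float) -> float:
    """Paired-chain prevalence per million B cells under random pairing.

    The product of the two whole-repertoire chain frequencies, scaled to
    per-million and reported to two significant figures.
    """
    for name, v in (("heavy_freq", heavy_freq), ("light_freq", light_freq)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    per_million = heavy_freq * light_freq * 1e6
    if per_million == 0.0:
        return 0.0
    return float(f"{per_million:.2g}")


@dataclass
class RarefactionCurve:
    sample_sizes: list[int]
    n_repeats: int
    mean_freq: list[float]
    cv: list[float]
    seed: int


def rarefaction_from_frequencies(
    freqs: Sequence[float],
    sizes: Sequence[int],
    n_repeats: int = 20,
    seed: int = 0,
    exhaustive: bool = False,
) -> RarefactionCurve:
    """Rarefaction of a per-repertoire frequency vector.

    For each size i, ``n_repeats`` subsets of i repertoires are drawn
    without replacement (independently across repeats, one seeded
    generator); CV_i is the sample (n-1) standard deviation of the repeat
    mean frequencies divided by their mean (0 when the mean is 0).
    With ``exhaustive=True`` every possible subset is used exactly once
    instead of random repeats (feasible only for small panels).
    """
    from itertools import combinations

    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    mean_out: list[float] = []
    cv_out: list[float] = []
    for size in sizes:
        if not 1 <= size <= len(freqs):
            raise ValueError(
                f"sample size {size} exceeds the {len(freqs)} available repertoires"
            )
        if exhaustive:
            repeat_means = np.array([
                freqs[list(idx)].mean()
                for idx in combinations(range(len(freqs)), size)
            ])
            n_repeats = len(repeat_means)
        else:
            repeat_means = np.array([
                # sorted indices make the mean independent of draw order,
                # so identical subsets give bit-identical means
                freqs[np.sort(rng.choice(len(freqs), size=size, replace=False))].mean()
                for _ in range(n_repeats)
            ])
        grand = repeat_means.mean()
        if n_repeats <= 1 or np.ptp(repeat_means) == 0.0:
            sd = 0.0  # identical repeats: exactly zero spread
        else:
            sd = repeat_means.std(ddof=1)
        mean_out.append(float(grand))
        cv_out.append(float(sd / grand) if grand > 0 else 0.0)
    return RarefactionCurve(sample_sizes=list(sizes), n_repeats=n_repeats,
                            mean_freq=mean_out, cv=cv_out, seed=seed)


def rarefaction_cv(
    query: SignatureQuery,
    repertoires: dict[str, Sequence[AnnotatedTranscript]],
    sizes: Sequence[int],
    n_repeats: int = 20,
    seed: int = 0,
    denominator: str = "gene",
) -> RarefactionCurve:
    """Rarefaction of a signature's frequency across curated repertoires."""
    freqs = []
    for rep_id in sorted(repertoires):
        row = signature_frequency(query, repertoires[rep_id],
                                  repertoire_id=rep_id, denominator=denominator)
        freqs.append(row.frequency if row.frequency is not None else 0.0)
    return rarefaction_from_frequencies(freqs, sizes, n_repeats=n_repeats,
                                        seed=seed)
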