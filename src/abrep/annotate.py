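"""Raw reads to annotated transcripts.

Stages, in the order a pipeline applies them: pair merging, quality
filtering (expected miscalls from Phred scores, minimum merged length),
germline V/(D)/J assignment by local alignment, CDR3 extraction from the
conserved 2nd-Cys / J-Trp(Phe) anchors, isotype assignment against a CH1
database, frameshift/stop-codon screening, somatic-hypermutation (SHM)
computation against the assigned germline V, and position numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import AlignmentResult, evalue_like, local_align
from .model import (
    AnnotatedTranscript,
    GermlineGene,
    SequenceRecord,
    j_anchor_offset,
    revcomp,
    translate,
)
from .numbering import SCHEMES, cdr3_labels, scheme_table


@dataclass
class QCThresholds:
    """Read-level quality-control thresholds.

    ``max_expected_miscalls``: maximum summed per-base error probability
    (expected miscalls) tolerated in a merged read; ``min_merged_length``:
    minimum merged-transcript length in nt; ``isotype_evalue_max``:
    significance cutoff for CH1 isotype assignment.
    """

    max_expected_miscalls: float = 20.0
    min_merged_length: int = 300
    isotype_evalue_max: float = 1e-6

    def __post_init__(self) -> None:
        if (self.max_expected_miscalls <= 0 or self.min_merged_length <= 0
                or self.isotype_evalue_max <= 0):
            raise ValueError("QC thresholds must be positive")


# ---------------------------------------------------------------------------
# read merging and quality filtering
# ---------------------------------------------------------------------------

def merge_read_pair(
    r1: SequenceRecord, r2: SequenceRecord, min_overlap: int = 10
) -> tuple[Optional[SequenceRecord], str]:
    """Merge a read pair by its best ungapped 3' overlap.

    ``r2`` is reverse-complemented; the overlap maximizing matches minus
    mismatches wins (so spurious long overlaps with many disagreements
    cannot outrank a clean shorter one; ties go to the longer overlap).
    Disagreeing overlap bases are
    resolved in favor of the higher Phred score with merged quality
    ``|q1 - q2|``; agreeing bases keep ``max(q1, q2)``. Rejected (None plus
    a reason code) when no overlap reaches ``min_overlap`` bases or the
    best overlap's identity is below 0.8.
    """
    if len(r1.nt) < min_overlap or len(r2.nt) < min_overlap:
        return None, "too_short_for_overlap"
    s2 = revcomp(r2.nt)
    q2 = list(reversed(r2.quals)) if r2.quals is not None else [40] * len(s2)
    q1 = r1.quals if r1.quals is not None else [40] * len(r1.nt)
    best_o, best_score, best_matches = 0, None, 0
    for o in range(min_overlap, min(len(r1.nt), len(s2)) + 1):
        matches = sum(1 for x, y in zip(r1.nt[-o:], s2[:o]) if x == y)
        score = 2 * matches - o  # matches - mismatches
        if best_score is None or score >= best_score:
            best_o, best_score, best_matches = o, score, matches
    if best_matches / best_o < 0.8:
        return None, "overlap_identity_below_0.8"
    o = best_o
    merged_nt: list[str] = list(r1.nt[:-o] if o else r1.nt)
    merged_q: list[int] = list(q1[:-o] if o else q1)
    for k in range(o):
        b1, b2 = r1.nt[len(r1.nt) - o + k], s2[k]
        p1, p2 = q1[len(r1.nt) - o + k], q2[k]
        if b1 == b2:
            merged_nt.append(b1)
            merged_q.append(max(p1, p2))
        else:
            merged_nt.append(b1 if p1 >= p2 else b2)
            merged_q.append(abs(p1 - p2))
    merged_nt += list(s2[o:])
    merged_q += list(q2[o:])
    return (
        SequenceRecord(read_id=r1.read_id, nt="".join(merged_nt), quals=merged_q,
                       umi=r1.umi),
        "merged",
    )


def expected_errors(quals: Sequence[int]) -> float:
    """Expected number of miscalls, sum of ``10^(-Q/10)`` over the read."""
    if any(q < 0 for q in quals):
        raise ValueError("negative Phred score")
    return sum(10.0 ** (-q / 10.0) for q in quals)


def qc_filter(
    records: Iterable[SequenceRecord], thresholds: QCThresholds | None = None
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Drop reads that are too short or carry too many expected miscalls."""
    thresholds = thresholds or QCThresholds()
    kept: list[SequenceRecord] = []
    rejected: list[tuple[SequenceRecord, str]] = []
    for r in records:
        if len(r.nt) < thresholds.min_merged_length:
            rejected.append((r, "length_below_minimum"))
        elif (r.quals is not None
              and expected_errors(r.quals) > thresholds.max_expected_miscalls):
            rejected.append((r, "expected_errors_above_maximum"))
        else:
            kept.append(r)
    return kept, rejected


# ---------------------------------------------------------------------------
# germline assignment
# ---------------------------------------------------------------------------

@dataclass
class VDJAssignment:
    v_call: Optional[str] = None
    d_call: Optional[str] = None
    j_call: Optional[str] = None
    v_alignment: Optional[AlignmentResult] = None
    d_alignment: Optional[AlignmentResult] = None
    j_alignment: Optional[AlignmentResult] = None
    unassignable_reason: Optional[str] = None

    @property
    def assignable(self) -> bool:
        return self.v_call is not None and self.j_call is not None


MIN_V_SCORE = 100.0
MIN_J_SCORE = 30.0
MIN_D_MATCH_RUN = 5  # contiguous matching nt required to call a D gene


def _best_hit(
    query: str, candidates: list[GermlineGene], min_score: float
) -> tuple[Optional[GermlineGene], Optional[AlignmentResult]]:
    """Highest-scoring candidate; ties broken by identity, then allele name."""
    best: tuple[float, float, str] | None = None
    best_gene, best_aln = None, None
    for g in candidates:
        aln = local_align(g.ungapped_nt, query)
        if aln is None or aln.score < min_score:
            continue
        # higher score wins; ties: higher identity, then smaller allele name
        key = (aln.score, aln.identity, g.allele_name)
        if (best is None or key[0] > best[0]
                or (key[0] == best[0] and key[1] > best[1])
                or (key[0] == best[0] and key[1] == best[1] and key[2] < best[2])):
            best, best_gene, best_aln = key, g, aln
    return best_gene, best_aln


def assign_vdj(
    record: SequenceRecord,
    germline: list[GermlineGene],
    chain: Optional[str] = None,
    min_v_score: float = MIN_V_SCORE,
    min_j_score: float = MIN_J_SCORE,
) -> VDJAssignment:
    """Assign germline V, (D,) and J by best local alignment.

    The J segment is searched strictly 3' of the V span; D (heavy chain
    only) between V and J, and the D call is withheld unless the best D
    alignment contains >= 5 contiguous matching nt.
    """
    vs = [g for g in germline if g.segment_kind == "V"
          and (chain is None or g.chain == chain)]
    v_gene, v_aln = _best_hit(record.nt, vs, min_v_score)
    if v_gene is None:
        return VDJAssignment(unassignable_reason="no_v_above_threshold")
    v_end = v_aln.query_span[1]

    js = [g for g in germline if g.segment_kind == "J" and g.chain == v_gene.chain]
    tail = record.nt[v_end:]
    j_gene, j_aln = _best_hit(tail, js, min_j_score) if tail else (None, None)
    if j_gene is None:
        return VDJAssignment(v_call=v_gene.allele_name, v_alignment=v_aln,
                             unassignable_reason="no_j_above_threshold")
    j_aln = _shift_query(j_aln, v_end)

    d_call, d_aln = None, None
    if v_gene.chain == "heavy":
        ds = [g for g in germline if g.segment_kind == "D" and g.chain == "heavy"]
        mid = record.nt[v_end:j_aln.query_span[0]]
        if mid and ds:
            d_gene, d_hit = _best_hit(mid, ds, min_score=2.0 * MIN_D_MATCH_RUN)
            if d_hit is not None and d_hit.longest_match_run(
                d_gene.ungapped_nt, mid
            ) >= MIN_D_MATCH_RUN:
                d_call = d_gene.allele_name
                d_aln = _shift_query(d_hit, v_end)
    return VDJAssignment(
        v_call=v_gene.allele_name, d_call=d_call, j_call=j_gene.allele_name,
        v_alignment=v_aln, d_alignment=d_aln, j_alignment=j_aln,
    )


def _shift_query(aln: AlignmentResult, offset: int) -> AlignmentResult:
    aln.query_span = (aln.query_span[0] + offset, aln.query_span[1] + offset)
    aln.blocks = [((r0, r1), (q0 + offset, q1 + offset))
                  for (r0, r1), (q0, q1) in aln.blocks]
    return aln


# ---------------------------------------------------------------------------
# CDR3, isotype, productiveness, SHM, numbering
# ---------------------------------------------------------------------------

def _germline_by_name(germline: list[GermlineGene], allele: str) -> GermlineGene:
    for g in germline:
        if g.allele_name == allele:
            return g
    raise KeyError(allele)


def extract_cdr3(
    nt: str,
    v_gene: GermlineGene,
    v_aln: AlignmentResult,
    j_gene: GermlineGene,
    j_aln: AlignmentResult,
) -> tuple[Optional[str], Optional[str]]:
    """CDR3 between the 2nd conserved Cys (IMGT 104) and the J Trp/Phe (118).

    Returns (cdr3_nt, cdr3_aa), or (None, None) when either anchor cannot
    be located, an anchor residue is mutated away, or the interval is not a
    multiple of three (out-of-frame junction).
    """
    span = v_gene.ungapped_index_of_imgt(104)
    if span is None:
        return None, None
    r2q_v = v_aln.ref_to_query()
    if span[1] - 1 not in r2q_v or span[0] not in r2q_v:
        return None, None
    cys_start = r2q_v[span[0]]
    cys_end = r2q_v[span[1] - 1] + 1
    try:
        w_off = j_anchor_offset(j_gene)
    except Exception:
        return None, None
    r2q_j = j_aln.ref_to_query()
    if w_off not in r2q_j:
        return None, None
    w_start = r2q_j[w_off]
    if w_start <= cys_end or (w_start - cys_end) % 3 != 0:
        return None, None
    if translate(nt[cys_start : cys_start + 3]) != "C":
        return None, None
    expected = "W" if j_gene.chain == "heavy" else "F"
    if translate(nt[w_start : w_start + 3]) not in (expected,):
        return None, None
    cdr3_nt = nt[cys_end:w_start]
    return cdr3_nt, translate(cdr3_nt)


_ISOTYPE_OF_GENE = {"IGHM": "IgM", "IGHG": "IgG", "IGHA": "IgA",
                    "IGHE": "IgE", "IGHD": "IgD"}


def assign_isotype(
    nt_tail: str,
    ch1_db: list[GermlineGene],
    evalue_max: float = 1e-6,
) -> str:
    """Isotype from the best CH1 hit at the transcript's 3' terminus."""
    if not nt_tail:
        return "unknown"
    best_e, best_iso = None, "unknown"
    for g in ch1_db:
        if g.segment_kind != "C":
            continue
        aln = local_align(g.ungapped_nt, nt_tail)
        if aln is None:
            continue
        e = evalue_like(aln.score, len(g.ungapped_nt), len(nt_tail))
        if e <= evalue_max and (best_e is None or e < best_e):
            best_e = e
            best_iso = _ISOTYPE_OF_GENE.get(g.gene_name[:4], "unknown")
    return best_iso


def detect_frameshift_stop(
    nt: str, v_aln: AlignmentResult, j_aln: AlignmentResult,
    cdr3_nt: Optional[str],
) -> bool:
    """Productive iff the V(D)J region is stop-free in the germline V frame
    and the junction kept V and J frames compatible (CDR3 extractable)."""
    if cdr3_nt is None:
        return False
    r0, _ = v_aln.reference_span
    q0, _ = v_aln.query_span
    start = q0 - (r0 % 3)
    while start < 0:
        start += 3
    region = nt[start : j_aln.query_span[1]]
    return "*" not in translate(region)


def compute_shm(
    v_aln: AlignmentResult, v_gene: GermlineGene, nt: str
) -> tuple[float, list[tuple[str, str, str]]]:
    """SHM level and amino-acid substitutions against the assigned V.

    ``shm_nt_pct`` is 100 x mismatched / aligned V columns, with N bases
    excluded from both numerator and denominator. Substitutions are
    reported per IMGT position as (label, germline aa, observed aa).
    """
    ref = v_gene.ungapped_nt
    cols = 0
    mism = 0
    for (r0, r1), (q0, q1) in v_aln.blocks:
        for k in range(r1 - r0):
            rb, qb = ref[r0 + k], nt[q0 + k]
            if rb == "N" or qb == "N":
                continue
            cols += 1
            if rb != qb:
                mism += 1
    pct = 100.0 * mism / cols if cols else 0.0

    subs: list[tuple[str, str, str]] = []
    imgt_map = number_positions(nt, v_gene, v_aln, scheme="IMGT",
                                cdr3_aa=None)
    germ_res = _germline_residues(v_gene)
    for label, res in imgt_map.items():
        germ = germ_res.get(label)
        if germ is not None and res != germ and res != "X":
            subs.append((label, germ, res))
    subs.sort(key=lambda s: float(s[0]))
    return pct, subs


def _germline_residues(v: GermlineGene) -> dict[str, str]:
    aa = translate(v.ungapped_nt)
    out = {}
    for i, res in enumerate(aa):
        out[str(v.imgt_position_of_ungapped(3 * i))] = res
    return out


def number_positions(
    nt: str,
    v_gene: GermlineGene,
    v_aln: AlignmentResult,
    scheme: str = "IMGT",
    cdr3_aa: Optional[str] = None,
) -> dict[str, str]:
    """Map scheme position labels to observed residues.

    IMGT comes from composing the V alignment with the germline's gapped
    coordinates; CDR3 residues (when provided) are numbered 105-117 by the
    symmetric-fill rule. Kabat/Chothia compose the IMGT map with the
    registered per-gene translation table; positions without a table row
    are left out (unmapped).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unsupported numbering scheme {scheme!r}")
    r2q = v_aln.ref_to_query()
    imgt: dict[str, str] = {}
    germ_aa_len = len(v_gene.ungapped_nt) // 3
    for codon_i in range(germ_aa_len):
        s = 3 * codon_i
        if s in r2q and s + 1 in r2q and s + 2 in r2q:
            q = (r2q[s], r2q[s + 1], r2q[s + 2])
            if q[1] == q[0] + 1 and q[2] == q[1] + 1:  # codon intact in query
                res = translate(nt[q[0] : q[0] + 3])
                imgt[str(v_gene.imgt_position_of_ungapped(s))] = res
    if cdr3_aa:
        for label, res in zip(cdr3_labels(len(cdr3_aa)), cdr3_aa):
            imgt[label] = res
    if scheme == "IMGT":
        return imgt
    table = scheme_table(v_gene.gene_name, scheme)
    if table is None:
        return {}
    return {table[label]: res for label, res in imgt.items() if label in table}


# ---------------------------------------------------------------------------
# one-shot annotation
# ---------------------------------------------------------------------------

def annotate_record(
    record: SequenceRecord,
    germline: list[GermlineGene],
    chain: Optional[str] = None,
    thresholds: QCThresholds | None = None,
    schemes: Sequence[str] = ("IMGT",),
    repertoire_id: str = "",
    donor_id: str = "",
) -> Optional[AnnotatedTranscript]:
    """Full annotation of one merged read; None when V/J are unassignable."""
    thresholds = thresholds or QCThresholds()
    vdj = assign_vdj(record, germline, chain=chain)
    if not vdj.assignable:
        return None
    v = _germline_by_name(germline, vdj.v_call)
    j = _germline_by_name(germline, vdj.j_call)
    cdr3_nt, cdr3_aa = extract_cdr3(record.nt, v, vdj.v_alignment, j,
                                    vdj.j_alignment)
    productive = detect_frameshift_stop(record.nt, vdj.v_alignment,
                                        vdj.j_alignment, cdr3_nt)
    shm_pct, aa_subs = compute_shm(vdj.v_alignment, v, record.nt)
    iso = "unknown"
    if v.chain == "heavy":
        tail = record.nt[vdj.j_alignment.query_span[1]:]
        ch1 = [g for g in germline if g.segment_kind == "C"]
        iso = assign_isotype(tail, ch1, thresholds.isotype_evalue_max)
    numbering = {
        s: number_positions(record.nt, v, vdj.v_alignment, scheme=s,
                            cdr3_aa=cdr3_aa)
        for s in schemes
    }
    return AnnotatedTranscript(
        record=record, v_call=vdj.v_call, d_call=vdj.d_call, j_call=vdj.j_call,
        isotype=iso, cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, shm_nt_pct=shm_pct,
        shm_aa_substitutions=aa_subs, numbering=numbering,
        productive=productive, repertoire_id=repertoire_id, donor_id=donor_id,
    )
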