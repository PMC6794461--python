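"""Readers and writers for the on-disk formats.

Three dialects live here:

* IMGT-gapped germline FASTA (V segments may carry ``.``/``-`` gaps at
  IMGT-deleted positions; ``-`` is normalized to ``.`` on load),
* plain FASTQ (Phred+33) / FASTA reads,
* the annotated-transcript FASTA dialect, which carries curation metadata
  as semicolon-delimited ``key=value`` pairs after the sequence id.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .model import (
    GAP,
    AnnotatedTranscript,
    ConfigurationError,
    GermlineGene,
    ParseError,
    SequenceRecord,
)

log = logging.getLogger(__name__)

HEADER_DELIM = ";"

# Fields encoded in the annotated-FASTA header, in a fixed order so output
# is byte-stable. "absent" fields are simply omitted.
_HEADER_FIELDS = (
    "v_call",
    "d_call",
    "j_call",
    "isotype",
    "cdr3_nt",
    "cdr3_aa",
    "shm_nt_pct",
    "productive",
    "abundance",
    "umi",
    "donor",
    "repertoire",
)


def _infer_segment(allele_name: str) -> tuple[str, str]:
    """Infer (segment_kind, chain) from an IMGT-style allele name.

    ``IGHD`` is ambiguous between the D-segment locus and the IgD constant
    gene: the constant gene is exactly ``IGHD`` before the ``*``, D segments
    carry a family/gene suffix (``IGHD2-2*01``).
    """
    name = allele_name.upper()
    if name.startswith("IGK"):
        chain = "kappa"
    elif name.startswith("IGL"):
        chain = "lambda"
    else:
        chain = "heavy"
    gene = name.split("*")[0]
    kind_char = name[3:4]
    if kind_char == "D":
        kind = "D" if len(gene) > 4 else "C"
    elif kind_char in ("V", "J"):
        kind = kind_char
    else:
        kind = "C"
    return kind, chain


def load_germline_fasta(path: str | os.PathLike) -> list[GermlineGene]:
    """Load an IMGT-gapped germline reference FASTA.

    Headers are expected to contain the allele name (``GENE*NN``) as the
    first whitespace- or ``|``-separated token that contains ``*`` (IMGT
    reference headers put it in field 2 of a ``|``-separated line).

    Raises
    ------
    ParseError
        For malformed FASTA (names the offending line).
    ConfigurationError
        For duplicate allele names.
    """
    genes: list[GermlineGene] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1 is not a FASTA header: {first!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        allele = None
        for token in header.replace("|", " ").split():
            if "*" in token:
                allele = token
                break
        if allele is None:
            raise ParseError(
                f"{path}: header {header!r} contains no GENE*NN allele name"
            )
        if allele in seen:
            raise ConfigurationError(f"{path}: duplicate allele {allele!r}")
        seen.add(allele)
        gapped = str(rec.seq).upper().replace("-", GAP)
        kind, chain = _infer_segment(allele)
        genes.append(
            GermlineGene(
                allele_name=allele, segment_kind=kind, chain=chain, gapped_nt=gapped
            )
        )
    if not genes:
        log.warning("%s: no germline entries found", path)
    return genes


def write_germline_fasta(genes: Iterable[GermlineGene], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.allele_name}\n{g.gapped_nt}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[SequenceRecord]:
    """Stream FASTQ (Phred+33) records in file order."""
    n_read = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            n_read += 1
            yield SequenceRecord(
                read_id=rec.id,
                nt=str(rec.seq).upper(),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # biopython's length-mismatch / truncation errors
        raise ParseError(f"{path}: record {n_read + 1}: {exc}") from exc


def read_fasta(path: str | os.PathLike) -> Iterator[SequenceRecord]:
    """Stream FASTA records; no quality scores."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SequenceRecord(read_id=rec.id, nt=str(rec.seq).upper(), quals=None)


def write_fastq(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            quals = r.quals if r.quals is not None else [40] * len(r.nt)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.nt}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# annotated-transcript FASTA dialect
# ---------------------------------------------------------------------------

def _format_value(value) -> str:
    if isinstance(value, bool):
        return "T" if value else "F"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _header_pairs(t: AnnotatedTranscript) -> list[tuple[str, str]]:
    raw = {
        "v_call": t.v_call,
        "d_call": t.d_call,
        "j_call": t.j_call,
        "isotype": None if t.isotype == "unknown" else t.isotype,
        "cdr3_nt": t.cdr3_nt,
        "cdr3_aa": t.cdr3_aa,
        "shm_nt_pct": t.shm_nt_pct,
        "productive": t.productive,
        "abundance": t.record.abundance,
        "umi": t.record.umi,
        "donor": t.donor_id or None,
        "repertoire": t.repertoire_id or None,
    }
    pairs = []
    for key in _HEADER_FIELDS:
        value = raw[key]
        if value is None:
            continue
        text = _format_value(value)
        if HEADER_DELIM in text or "=" in text:
            raise ValueError(
                f"field {key}={text!r} contains the reserved delimiter"
            )
        pairs.append((key, text))
    return pairs


def write_annotated_fasta(
    transcripts: Iterable[AnnotatedTranscript], path: str | os.PathLike
) -> None:
    """Write transcripts with their annotation encoded in the header line."""
    with open(path, "w") as fh:
        for t in transcripts:
            if HEADER_DELIM in t.record.read_id:
                raise ValueError(
                    f"read id {t.record.read_id!r} contains the reserved delimiter"
                )
            tags = HEADER_DELIM.join(f"{k}={v}" for k, v in _header_pairs(t))
            fh.write(f">{t.record.read_id}{HEADER_DELIM}{tags}\n{t.record.nt}\n")


def parse_annotated_header(header: str, nt: str = "") -> AnnotatedTranscript:
    """Parse one annotated-FASTA header (without the leading ``>``)."""
    parts = header.strip().split(HEADER_DELIM)
    read_id, tags = parts[0], parts[1:]
    fields: dict[str, str] = {}
    for tag in tags:
        if not tag:
            continue
        if "=" not in tag:
            raise ParseError(f"malformed header tag {tag!r} in {header!r}")
        key, _, value = tag.partition("=")
        fields[key] = value
    rec = SequenceRecord(
        read_id=read_id,
        nt=nt,
        umi=fields.get("umi"),
        abundance=int(fields.get("abundance", 1)),
    )
    return AnnotatedTranscript(
        record=rec,
        v_call=fields.get("v_call"),
        d_call=fields.get("d_call"),
        j_call=fields.get("j_call"),
        isotype=fields.get("isotype", "unknown"),
        cdr3_nt=fields.get("cdr3_nt"),
        cdr3_aa=fields.get("cdr3_aa"),
        shm_nt_pct=float(fields["shm_nt_pct"]) if "shm_nt_pct" in fields else None,
        productive=fields.get("productive") == "T",
        donor_id=fields.get("donor", ""),
        repertoire_id=fields.get("repertoire", ""),
    )


def read_annotated_fasta(path: str | os.PathLike) -> Iterator[AnnotatedTranscript]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield parse_annotated_header(rec.description, nt=str(rec.seq).upper())
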