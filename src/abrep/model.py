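"""Core domain types shared across the toolkit.

All coordinates handled internally are 0-based half-open; IMGT position
labels (the numbering a germline gene carries) are 1-based, as the scheme
defines them. Conversion between the two happens in :mod:`abrep.io` and
:mod:`abrep.numbering` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

GAP = "."

#: Heavy-chain constant-region class inferred from the CH1 portion.
ISOTYPES = ("IgM", "IgD", "IgG", "IgA", "IgE", "unknown")

SEGMENT_KINDS = ("V", "D", "J", "C")
CHAINS = ("heavy", "kappa", "lambda")


class ConfigurationError(ValueError):
    """Invalid reference data or parameters (e.g. duplicate allele names)."""


class ParseError(ValueError):
    """Malformed on-disk input; carries file/line context in the message."""


@dataclass(frozen=True)
class GermlineGene:
    """One germline segment (V, D, J or CH1) in IMGT-gapped coordinates.

    ``gapped_nt`` may contain ``.`` at IMGT-deleted positions; for V
    segments the gapped string is codon-aligned so that nucleotide column
    ``c`` belongs to IMGT (amino-acid) position ``c // 3 + 1``.
    """

    allele_name: str
    segment_kind: str
    chain: str
    gapped_nt: str

    def __post_init__(self) -> None:
        if self.segment_kind not in SEGMENT_KINDS:
            raise ConfigurationError(f"unknown segment kind {self.segment_kind!r}")
        if self.chain not in CHAINS:
            raise ConfigurationError(f"unknown chain {self.chain!r}")
        if "*" not in self.allele_name:
            raise ConfigurationError(
                f"allele name {self.allele_name!r} does not match GENE*NN"
            )

    @property
    def gene_name(self) -> str:
        """Gene-level name: allele suffix stripped (``IGHV1-2*02`` -> ``IGHV1-2``)."""
        return self.allele_name.split("*")[0]

    @property
    def ungapped_nt(self) -> str:
        return self.gapped_nt.replace(GAP, "")

    @property
    def imgt_position_of_column(self) -> dict[int, int]:
        """Map gapped nucleotide column -> 1-based IMGT amino-acid position.

        Only non-gap columns appear; gapped (IMGT-deleted) positions are
        simply absent from the map.
        """
        return {
            col: col // 3 + 1
            for col, base in enumerate(self.gapped_nt)
            if base != GAP
        }

    def imgt_position_of_ungapped(self, i: int) -> int:
        """IMGT position of the ``i``-th (0-based) ungapped nucleotide."""
        count = -1
        for col, base in enumerate(self.gapped_nt):
            if base != GAP:
                count += 1
                if count == i:
                    return col // 3 + 1
        raise IndexError(i)

    def ungapped_index_of_imgt(self, position: int) -> Optional[tuple[int, int]]:
        """Half-open ungapped nt span of an IMGT codon, or None if deleted."""
        start = None
        count = 0
        span = []
        for col, base in enumerate(self.gapped_nt):
            if base != GAP:
                if col // 3 + 1 == position:
                    span.append(count)
                count += 1
        if not span:
            return None
        return span[0], span[-1] + 1


@dataclass
class SequenceRecord:
    """A read or collapsed transcript, with optional qualities and UMI."""

    read_id: str
    nt: str
    quals: Optional[list[int]] = None
    umi: Optional[str] = None
    abundance: int = 1

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.nt):
            raise ParseError(
                f"record {self.read_id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.nt)}"
            )
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


@dataclass
class AnnotatedTranscript:
    """A curated transcript with germline calls and derived annotation."""

    record: SequenceRecord
    v_call: Optional[str] = None
    d_call: Optional[str] = None
    j_call: Optional[str] = None
    isotype: str = "unknown"
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    shm_nt_pct: Optional[float] = None
    # (IMGT position label, germline aa, observed aa)
    shm_aa_substitutions: list[tuple[str, str, str]] = field(default_factory=list)
    # scheme -> {position label -> residue}
    numbering: dict[str, dict[str, str]] = field(default_factory=dict)
    productive: bool = False
    repertoire_id: str = ""
    donor_id: str = ""

    @property
    def v_gene(self) -> Optional[str]:
        return self.v_call.split("*")[0] if self.v_call else None

    @property
    def j_gene(self) -> Optional[str]:
        return self.j_call.split("*")[0] if self.j_call else None


@dataclass(frozen=True)
class RepertoireMetadata:
    repertoire_id: str
    donor_id: str
    donor_state: str = "healthy"
    tissue: str = "PBMC"
    cell_subset: str = "B cell"
    uses_umi: bool = False


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def translate(nt: str) -> str:
    """Translate in frame 0; incomplete/ambiguous codons become ``X``."""
    table = _codon_table()
    return "".join(
        table.get(nt[i : i + 3].upper(), "X") for i in range(0, len(nt) - 2, 3)
    )


def j_anchor_offset(j: GermlineGene) -> int:
    """Ungapped nt offset of a J segment's W/F anchor codon.

    The anchor is the first W (heavy) or F (light) of the conserved
    WGXG / FGXG motif, searched across all three frames.
    """
    nt = j.ungapped_nt
    for frame in range(3):
        aa = translate(nt[frame:])
        for i in range(len(aa) - 3):
            if aa[i] in "WF" and aa[i + 1] == "G" and aa[i + 3] == "G":
                return frame + 3 * i
    raise ConfigurationError(f"J segment {j.allele_name} lacks a WGXG/FGXG motif")
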