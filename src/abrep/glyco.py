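"""Gene-specific N-glycosylation profiles (GSNPs).

N-linked glycosylation requires the sequon Asn-X-Ser/Thr with X != Pro.
A GSNP records, per IMGT position of the sequon's Asn, the fraction of
somatically mutated transcripts (SHM above a threshold) that carry a
sequon there which is *not* encoded by the germline V gene — i.e. sites
introduced by somatic hypermutation.

The sequon rule is the canonical sequence-level criterion; frequencies it
yields are an upper bound relative to profiles additionally filtered by a
structure-aware predictor, since not every sequon is occupied in vivo.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .annotate import _germline_residues
from .model import AnnotatedTranscript, GermlineGene


def scan_sequons(aa: str) -> list[int]:
    """0-based positions i with aa[i] = N, aa[i+1] != P, aa[i+2] in {S, T}."""
    return [
        i
        for i in range(len(aa) - 2)
        if aa[i] == "N" and aa[i + 1] != "P" and aa[i + 2] in ("S", "T")
    ]


@dataclass
class GSNP:
    v_gene: str
    #: IMGT position label (the sequon's Asn) -> fraction of eligible transcripts
    freq: dict[str, float] = field(default_factory=dict)
    n_eligible: int = 0


def _label_order(label: str) -> float:
    return float(label)


def _sequon_labels(numbering: dict[str, str]) -> set[str]:
    """IMGT labels of sequon Asn positions in a numbered residue map.

    Residues are laid out in IMGT label order; a sequon counts only when
    all three of its residues are numbered (consecutively observed), so
    motifs running into unnumbered territory are ignored.
    """
    items = []
    for label, res in numbering.items():
        try:
            items.append((_label_order(label), label, res))
        except ValueError:
            continue
    items.sort()
    seq = "".join(res for _, _, res in items)
    return {items[i][1] for i in scan_sequons(seq)}


def build_gsnp(
    transcripts: list[AnnotatedTranscript],
    germline: list[GermlineGene],
    min_shm_pct: float = 1.0,
) -> dict[str, GSNP]:
    """GSNPs for every V gene observed among eligible transcripts.

    Eligible transcripts have SHM strictly above ``min_shm_pct`` (percent
    mismatched nucleotides in the V region). Sequons present at the
    homologous numbered position of the transcript's assigned germline V
    are excluded; denominators count eligible transcripts per gene.
    """
    germ_sequons: dict[str, set[str]] = {}
    for g in germline:
        if g.segment_kind == "V":
            residues = _germline_residues(g)
            germ_sequons[g.allele_name] = _sequon_labels(residues)

    eligible: dict[str, list[AnnotatedTranscript]] = defaultdict(list)
    for t in transcripts:
        if (t.v_call and t.shm_nt_pct is not None
                and t.shm_nt_pct > min_shm_pct and "IMGT" in t.numbering):
            eligible[t.v_gene].append(t)

    profiles: dict[str, GSNP] = {}
    for gene, ts in sorted(eligible.items()):
        counts: dict[str, int] = defaultdict(int)
        for t in ts:
            baseline = germ_sequons.get(t.v_call, set())
            for label in _sequon_labels(t.numbering["IMGT"]):
                if label not in baseline:
                    counts[label] += 1
        profiles[gene] = GSNP(
            v_gene=gene,
            freq={p: n / len(ts) for p, n in sorted(counts.items())},
            n_eligible=len(ts),
        )
    return profiles


def write_gsnp_tsv(profiles: dict[str, GSNP], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tposition\tfrequency\tn_eligible\n")
        for gene in sorted(profiles):
            p = profiles[gene]
            for label, f in sorted(p.freq.items(), key=lambda kv: float(kv[0])):
                fh.write(f"{gene}\t{label}\t{f:.6g}\t{p.n_eligible}\n")
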