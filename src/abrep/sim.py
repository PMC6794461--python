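"""Synthetic repertoire generator with exact ground truth.

Emulates the processes a repertoire-curation pipeline has to undo:
V(D)J recombination from a small germline set, hotspot-biased point
somatic hypermutation (SHM), several mRNA molecules per cell, PCR
duplication with per-base error, Phred-quality strings with
quality-consistent miscalls, and optional UMIs with collisions.

A single :class:`numpy.random.Generator` seeded from the config drives
every draw, in a fixed documented order (cells, then molecules, then
copies, then per-read noise, then the final shuffle), so identical
configs give byte-identical output.

Indel SHM is not simulated: the curation pipeline discards frameshifted
transcripts, so substitutions alone exercise every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ConfigurationError,
    GermlineGene,
    SequenceRecord,
    j_anchor_offset,
    translate,
)

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate(a + b + c) != "*"
]

# IMGT positions deleted (gap codons) in the toy V genes; chosen inside
# CDR1/CDR2 where real short alleles carry their IMGT gaps.
_TOY_V_GAPS = {
    "heavy": (31, 32, 33, 60, 61),
    "kappa": (30, 31, 32, 33, 61),
}

_HEAVY_J_STEM = "TGGGGCCAAGGAACCCTGGTCACCGTCTCCTCA"  # WGQGTLVTVSS
_KAPPA_J_STEM = "TTCGGCCAAGGGACCAAGGTGGAAATCAAA"  # FGQGTKVEIK


def _random_codon(rng: np.random.Generator, exclude: tuple[str, ...] = ()) -> str:
    choices = [c for c in _SENSE_CODONS if c not in exclude]
    return choices[int(rng.integers(len(choices)))]


def _toy_v(rng: np.random.Generator, name: str, chain: str) -> GermlineGene:
    """A 104-codon IMGT-gapped V with conserved Cys23/Trp41/Cys104."""
    gaps = _TOY_V_GAPS[chain]
    codons = []
    for pos in range(1, 105):
        if pos in gaps:
            codons.append("...")
        elif pos == 23:
            codons.append("TGC")
        elif pos == 41:
            codons.append("TGG")
        elif pos == 104:
            codons.append("TGT")
        else:
            # avoid extra Cys/Trp so the CDR3 anchors stay unambiguous
            codons.append(_random_codon(rng, exclude=("TGT", "TGC", "TGG")))
    return GermlineGene(name, "V", chain, "".join(codons))


def _toy_j(rng: np.random.Generator, name: str, chain: str) -> GermlineGene:
    stem = _HEAVY_J_STEM if chain == "heavy" else _KAPPA_J_STEM
    n_prefix_codons = 2 + int(rng.integers(2))  # 2-3 codons feeding CDR3
    prefix = "".join(
        _random_codon(rng, exclude=("TGT", "TGC", "TGG")) for _ in range(n_prefix_codons)
    )
    return GermlineGene(name, "J", chain, prefix + stem)




def make_toy_germline(seed: int = 1) -> list[GermlineGene]:
    """Deterministic toy germline set: 4+2 V, 2 D, 2+2 J, 2 CH1 segments.

    Every V ends with the conserved 2nd-Cys codon (IMGT 104); every J
    contains WGXG (heavy) or FGXG (kappa) so CDR3 extraction is well-posed.
    """
    rng = np.random.default_rng(seed)
    genes: list[GermlineGene] = []
    for i in range(1, 5):
        genes.append(_toy_v(rng, f"IGHV-T{i}*01", "heavy"))
    for i in range(1, 3):
        genes.append(_toy_v(rng, f"IGKV-T{i}*01", "kappa"))
    for i in range(1, 3):
        d_nt = "".join(_BASES[rng.integers(4, size=14 + 3 * i)])
        genes.append(GermlineGene(f"IGHD-T{i}*01", "D", "heavy", d_nt))
    for i in range(1, 3):
        genes.append(_toy_j(rng, f"IGHJ-T{i}*01", "heavy"))
    for i in range(1, 3):
        genes.append(_toy_j(rng, f"IGKJ-T{i}*01", "kappa"))
    for name in ("IGHM*01", "IGHG1*01"):
        ch1 = "".join(_BASES[rng.integers(4, size=60)])
        genes.append(GermlineGene(name, "C", "heavy", ch1))
    return genes


@dataclass
class SimulationConfig:
    seed: int = 1
    n_cells: int = 100
    germline: list[GermlineGene] = field(default_factory=list)
    chain: str = "heavy"
    shm_rate: float = 0.02
    hotspot_multiplier: float = 3.0
    n_region_mean: float = 4.0
    mrna_per_cell_mean: float = 3.0
    pcr_duplicates_mean: float = 3.0
    min_pcr_duplicates: int = 1
    fixed_counts: bool = False  # use the integer means exactly (no Poisson)
    pcr_error_rate: float = 1e-3
    seq_mean_q: float = 35.0
    seq_q_sd: float = 3.0
    seq_miscall_scale: float = 1.0  # 0 turns quality-implied miscalls off
    umi_length: int = 0
    umi_collision_rate: float = 0.0
    attach_constant: bool = True
    repertoire_id: str = "sim"
    donor_id: str = "donor1"

    def __post_init__(self) -> None:
        for name in ("shm_rate", "pcr_error_rate", "umi_collision_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")


@dataclass
class CellTruth:
    cell_id: str
    v_call: str
    d_call: Optional[str]
    j_call: str
    transcript_nt: str  # post-SHM V(D)J (+ CH1 tail when attached)
    vdj_nt: str  # post-SHM V(D)J region only
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    isotype: str
    shm_positions: list[tuple[int, str, str]]  # (0-based nt pos, from, to)
    v_aa_substitutions: list[tuple[int, str, str]]  # (IMGT pos, germ aa, obs aa)


@dataclass
class ReadTruth:
    read_id: str
    cell_id: str
    molecule_id: str
    umi: Optional[str]
    true_nt: str


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    reads: dict[str, ReadTruth]
    #: per V gene: (IMGT position, amino acid) -> substitution count over cells
    substitution_counts: dict[str, dict[tuple[int, str], int]]

    @property
    def unique_transcripts(self) -> set[str]:
        return {c.transcript_nt for c in self.cells}

    def cell(self, cell_id: str) -> CellTruth:
        return next(c for c in self.cells if c.cell_id == cell_id)


def _hotspot_mask(nt: np.ndarray) -> np.ndarray:
    """True at the mutable base of WRC (the C) / GYW (the G) AID hotspots."""
    n = len(nt)
    mask = np.zeros(n, dtype=bool)
    s = "".join(nt)
    for i in range(n):
        if s[i] == "C" and i >= 2 and s[i - 2] in "AT" and s[i - 1] in "AG":
            mask[i] = True
        elif s[i] == "G" and i + 2 < n and s[i + 1] in "CT" and s[i + 2] in "AT":
            mask[i] = True
    return mask


def _apply_shm(
    rng: np.random.Generator, nt: str, rate: float, multiplier: float
) -> tuple[str, list[tuple[int, str, str]]]:
    if rate <= 0.0:
        return nt, []
    arr = np.array(list(nt))
    probs = np.full(len(arr), rate)
    probs[_hotspot_mask(arr)] = min(rate * multiplier, 0.95)
    hits = np.nonzero(rng.random(len(arr)) < probs)[0]
    muts: list[tuple[int, str, str]] = []
    for i in hits:
        old = arr[i]
        new = _BASES[_BASES != old][int(rng.integers(3))]
        arr[i] = new
        muts.append((int(i), old, new))
    return "".join(arr), muts


def _substitute(rng: np.random.Generator, nt: str, rate: float) -> str:
    """Uniform per-base substitution noise (PCR errors)."""
    if rate <= 0.0:
        return nt
    arr = np.array(list(nt))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _BASES[_BASES != arr[i]][int(rng.integers(3))]
    return "".join(arr)


def _count(rng: np.random.Generator, mean: float, minimum: int, fixed: bool) -> int:
    if fixed:
        return max(minimum, int(round(mean)))
    if mean <= minimum:
        return minimum
    return minimum + int(rng.poisson(mean - minimum))


def _make_cell(
    rng: np.random.Generator, cfg: SimulationConfig, cell_id: str,
    vs: list[GermlineGene], ds: list[GermlineGene], js: list[GermlineGene],
    cs: list[GermlineGene],
) -> CellTruth:
    v = vs[int(rng.integers(len(vs)))]
    j = js[int(rng.integers(len(js)))]
    d = ds[int(rng.integers(len(ds)))] if ds and cfg.chain == "heavy" else None
    v_nt = v.ungapped_nt
    j_nt = j.ungapped_nt
    w_off = j_anchor_offset(j)

    # junction: N1 + trimmed D + N2, padded to keep the J anchor in frame;
    # redrawn (bounded) if the rearrangement translates with a stop codon
    for _ in range(25):
        n1 = int(rng.geometric(1.0 / (1.0 + cfg.n_region_mean)) - 1)
        n2 = int(rng.geometric(1.0 / (1.0 + cfg.n_region_mean)) - 1)
        if d is not None:
            lt = int(rng.integers(0, 4))
            rt = int(rng.integers(0, 4))
            d_part = d.ungapped_nt[lt : len(d.ungapped_nt) - rt]
        else:
            d_part = ""
        junction = "".join(_BASES[rng.integers(4, size=n1)]) + d_part + "".join(
            _BASES[rng.integers(4, size=n2)]
        )
        pad = (-(len(junction) + w_off)) % 3
        junction += "".join(_BASES[rng.integers(4, size=pad)])
        vdj = v_nt + junction + j_nt
        if "*" not in translate(vdj):
            break
    vdj_mut, muts = _apply_shm(rng, vdj, cfg.shm_rate, cfg.hotspot_multiplier)

    cys_end = len(v_nt)  # V ends with the 2nd-Cys codon by construction
    w_start = cys_end + len(junction) + w_off
    cdr3_nt = vdj_mut[cys_end:w_start]
    cdr3_aa = translate(cdr3_nt)
    aa_mut = translate(vdj_mut)
    productive = (
        "*" not in aa_mut
        and translate(vdj_mut[cys_end - 3 : cys_end]) == "C"
        and translate(vdj_mut[w_start : w_start + 3]) in ("W", "F")
    )

    if cfg.attach_constant and cs:
        c = cs[int(rng.integers(len(cs)))]
        transcript = vdj_mut + c.ungapped_nt
        isotype = {"IGHM": "IgM", "IGHG": "IgG", "IGHA": "IgA",
                   "IGHE": "IgE", "IGHD": "IgD"}.get(c.gene_name[:4], "unknown")
    else:
        transcript = vdj_mut
        isotype = "unknown"

    v_aa_subs: list[tuple[int, str, str]] = []
    germ_aa = translate(v_nt)
    mut_aa = translate(vdj_mut[: len(v_nt)])
    for codon_i, (ga, ma) in enumerate(zip(germ_aa, mut_aa)):
        if ga != ma:
            imgt_pos = v.imgt_position_of_ungapped(codon_i * 3)
            v_aa_subs.append((imgt_pos, ga, ma))

    return CellTruth(
        cell_id=cell_id, v_call=v.allele_name,
        d_call=d.allele_name if d is not None else None, j_call=j.allele_name,
        transcript_nt=transcript, vdj_nt=vdj_mut, cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa, productive=productive, isotype=isotype,
        shm_positions=muts, v_aa_substitutions=v_aa_subs,
    )


def simulate_repertoire(cfg: SimulationConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Simulate one repertoire; returns shuffled reads plus full ground truth."""
    if not cfg.germline:
        raise ConfigurationError("empty germline set")
    rng = np.random.default_rng(cfg.seed)
    vs = [g for g in cfg.germline if g.segment_kind == "V" and g.chain == cfg.chain]
    js = [g for g in cfg.germline if g.segment_kind == "J" and g.chain == cfg.chain]
    ds = [g for g in cfg.germline if g.segment_kind == "D" and g.chain == cfg.chain]
    cs = [g for g in cfg.germline if g.segment_kind == "C"]
    if not vs or not js:
        raise ConfigurationError(f"germline lacks V or J segments for chain {cfg.chain}")

    cells = [
        _make_cell(rng, cfg, f"cell{i:05d}", vs, ds, js, cs)
        for i in range(cfg.n_cells)
    ]

    reads: list[SequenceRecord] = []
    read_truth: dict[str, ReadTruth] = {}
    used_umis: list[str] = []
    used_set: set[str] = set()
    read_n = 0
    for cell in cells:
        n_mrna = _count(rng, cfg.mrna_per_cell_mean, 1, cfg.fixed_counts)
        for m in range(n_mrna):
            mol_id = f"{cell.cell_id}.m{m}"
            umi: Optional[str] = None
            if cfg.umi_length > 0:
                if used_umis and rng.random() < cfg.umi_collision_rate:
                    umi = used_umis[int(rng.integers(len(used_umis)))]
                else:
                    # rejection-sample so collisions occur only at the
                    # configured rate, never by chance
                    while True:
                        umi = "".join(_BASES[rng.integers(4, size=cfg.umi_length)])
                        if umi not in used_set:
                            break
                used_umis.append(umi)
                used_set.add(umi)
            n_copies = _count(rng, cfg.pcr_duplicates_mean, cfg.min_pcr_duplicates,
                              cfg.fixed_counts)
            for _ in range(n_copies):
                nt = _substitute(rng, cell.transcript_nt, cfg.pcr_error_rate)
                quals = np.clip(
                    np.rint(rng.normal(cfg.seq_mean_q, cfg.seq_q_sd, size=len(nt))),
                    2, 41,
                ).astype(int)
                if cfg.seq_miscall_scale > 0.0:
                    p_err = cfg.seq_miscall_scale * np.power(10.0, -quals / 10.0)
                    hits = np.nonzero(rng.random(len(nt)) < p_err)[0]
                    if len(hits):
                        arr = np.array(list(nt))
                        for i in hits:
                            arr[i] = _BASES[_BASES != arr[i]][int(rng.integers(3))]
                        nt = "".join(arr)
                read_id = f"read{read_n:07d}"
                read_n += 1
                reads.append(SequenceRecord(read_id, nt, quals=list(map(int, quals)),
                                            umi=umi))
                read_truth[read_id] = ReadTruth(read_id, cell.cell_id, mol_id, umi,
                                                cell.transcript_nt)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    sub_counts: dict[str, dict[tuple[int, str], int]] = {}
    for cell in cells:
        gene = cell.v_call.split("*")[0]
        per_gene = sub_counts.setdefault(gene, {})
        for pos, _germ, obs in cell.v_aa_substitutions:
            per_gene[(pos, obs)] = per_gene.get((pos, obs), 0) + 1

    return reads, GroundTruth(cells=cells, reads=read_truth,
                              substitution_counts=sub_counts)


def curation_study_config(seed: int = 1, n_cells: int = 1000) -> SimulationConfig:
    """Reference conditions for curation-recovery analyses.

    1,000 cells, three mRNA molecules per cell and five PCR duplicates per
    molecule (fixed counts), per-base PCR error 1e-3, Phred ~Q40
    sequencing, 12-nt UMIs without collisions. Five duplicates per molecule
    (comfortably above the >= 3 a majority-vote consensus needs) keep the
    vote at every column effectively free of ties at this error rate, and
    three molecules per cell give the cluster path a depth margin; three
    mRNA per cell is a conservative stand-in for the many immunoglobulin
    transcripts a real B cell carries.
    """
    return SimulationConfig(
        seed=seed, n_cells=n_cells, germline=make_toy_germline(1),
        chain="heavy", shm_rate=0.02, hotspot_multiplier=3.0,
        mrna_per_cell_mean=3, pcr_duplicates_mean=5, min_pcr_duplicates=3,
        fixed_counts=True, pcr_error_rate=1e-3, seq_mean_q=40.0, seq_q_sd=2.0,
        umi_length=12, umi_collision_rate=0.0,
    )


def write_truth_tsv(truth: GroundTruth, path: str) -> None:
    """Per-read truth table: read_id, cell, molecule, umi, true sequence."""
    with open(path, "w") as fh:
        fh.write("read_id\tcell_id\tmolecule_id\tumi\ttrue_nt\n")
        for rid in sorted(truth.reads):
            rt = truth.reads[rid]
            fh.write(f"{rt.read_id}\t{rt.cell_id}\t{rt.molecule_id}\t"
                     f"{rt.umi or ''}\t{rt.true_nt}\n")
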