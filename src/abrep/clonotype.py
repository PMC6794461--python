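"""Clonotyping, gene-specific substitution profiles (GSSPs), mutation rarity.

A clone groups transcripts that plausibly descend from one recombination
event: same V gene, same J gene, same CDR3 length, and CDR3 nucleotide
identity >= 90% to the clone seed. One representative per clone feeds GSSP
construction, so clonally expanded lineages contribute one observation.

A GSSP tabulates, per IMGT position and amino acid, how often somatic
hypermutation produced that substitution across clone representatives of
one V gene. The rarity of an observed substitution is
``(1 - GSSP frequency) * 100`` percent; substitutions with frequency below
0.5% are flagged rare.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .curate import greedy_cluster
from .model import AnnotatedTranscript, SequenceRecord

CLONE_CDR3_IDENTITY = 0.90
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class Clone:
    v_gene: str
    j_gene: str
    cdr3_length: int
    members: list[AnnotatedTranscript]
    representative: AnnotatedTranscript


def cluster_clones(
    transcripts: list[AnnotatedTranscript],
    identity_threshold: float = CLONE_CDR3_IDENTITY,
) -> tuple[list[Clone], list[AnnotatedTranscript]]:
    """Partition annotated transcripts into clones.

    Transcripts are grouped by (V gene, J gene, CDR3 length) and greedily
    clustered on CDR3 nucleotide identity within each group. Returns
    (clones, excluded) where excluded are transcripts without V/J calls or
    CDR3.
    """
    excluded: list[AnnotatedTranscript] = []
    groups: dict[tuple[str, str, int], list[AnnotatedTranscript]] = defaultdict(list)
    for t in transcripts:
        if not t.v_gene or not t.j_gene or not t.cdr3_nt or not t.cdr3_aa:
            excluded.append(t)
            continue
        groups[(t.v_gene, t.j_gene, len(t.cdr3_aa))].append(t)

    clones: list[Clone] = []
    for (v_gene, j_gene, cdr3_len) in sorted(groups):
        members = groups[(v_gene, j_gene, cdr3_len)]
        by_id = {t.record.read_id: t for t in members}
        proxies = [
            SequenceRecord(read_id=t.record.read_id, nt=t.cdr3_nt,
                           abundance=t.record.abundance)
            for t in members
        ]
        for cl in greedy_cluster(proxies, identity_threshold):
            clone_members = [by_id[m.read_id] for m in cl.members]
            clones.append(
                Clone(v_gene=v_gene, j_gene=j_gene, cdr3_length=cdr3_len,
                      members=clone_members,
                      representative=by_id[cl.centroid.read_id])
            )
    return clones, excluded


@dataclass
class GSSP:
    v_gene: str
    n_clones: int
    #: (IMGT position label, amino acid) -> substitution frequency in [0, 1]
    freq: dict[tuple[str, str], float] = field(default_factory=dict)
    #: IMGT position label -> number of clone representatives observing it
    coverage: dict[str, int] = field(default_factory=dict)
    normalization_mode: str = "per_observed"


MIN_GSSP_CLONES = 100


def _v_region_labels(numbering: dict[str, str]) -> list[str]:
    """IMGT labels covering the germline V region (positions <= 104)."""
    out = []
    for label in numbering:
        try:
            if float(label) <= 104:
                out.append(label)
        except ValueError:
            continue
    return out


def build_gssp(
    representatives: list[AnnotatedTranscript],
    v_gene: str,
    min_clones: int = MIN_GSSP_CLONES,
    normalization_mode: str = "per_observed",
) -> Optional[GSSP]:
    """Build the substitution profile of one V gene from clone representatives.

    ``per_observed`` (default): freq(p, X) = representatives carrying the
    non-germline residue X at p, divided by all representatives observing p
    (unmutated representatives count in the denominator).
    ``per_mutated``: the denominator is restricted to representatives
    mutated at p, so frequencies at a position sum to 1 when any mutation
    was observed there.

    Returns None (withheld) with fewer than ``min_clones`` representatives.
    """
    if normalization_mode not in ("per_observed", "per_mutated"):
        raise ValueError(f"unknown normalization mode {normalization_mode!r}")
    reps = [r for r in representatives if r.v_gene == v_gene]
    if not reps and representatives:
        raise ValueError(f"no representatives assigned to gene {v_gene!r}")
    if len(reps) < min_clones:
        return None
    coverage: dict[str, int] = defaultdict(int)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    mutated_at: dict[str, int] = defaultdict(int)
    for rep in reps:
        imgt = rep.numbering.get("IMGT", {})
        for label in _v_region_labels(imgt):
            coverage[label] += 1
        for label, _germ, obs in rep.shm_aa_substitutions:
            counts[(label, obs)] += 1
            mutated_at[label] += 1
    freq: dict[tuple[str, str], float] = {}
    for (label, aa), n in counts.items():
        denom = (coverage[label] if normalization_mode == "per_observed"
                 else mutated_at[label])
        if denom:
            freq[(label, aa)] = n / denom
    return GSSP(v_gene=v_gene, n_clones=len(reps), freq=freq,
                coverage=dict(coverage), normalization_mode=normalization_mode)


def compare_gssp(a: GSSP, b: GSSP) -> Optional[float]:
    """Pearson correlation of two profiles over shared covered cells.

    Cells are (position, amino acid) pairs at positions both profiles
    cover; frequencies absent from one profile count as 0. None when the
    profiles share no covered position.
    """
    if a.v_gene != b.v_gene:
        raise ValueError("profiles are for different V genes")
    if a.normalization_mode != b.normalization_mode:
        raise ValueError("profiles use different normalization modes")
    shared = [p for p in a.coverage if a.coverage[p] > 0 and b.coverage.get(p, 0) > 0]
    if not shared:
        return None
    xs, ys = [], []
    for p in shared:
        for aa in AMINO_ACIDS:
            xs.append(a.freq.get((p, aa), 0.0))
            ys.append(b.freq.get((p, aa), 0.0))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


RARE_FREQUENCY_THRESHOLD = 0.005  # substitutions below 0.5% are "rare"


@dataclass(frozen=True)
class MutationRarity:
    position: str
    germline_aa: str
    observed_aa: str
    frequency: float
    rarity: float
    is_rare: bool


def mutation_rarity(
    transcript: AnnotatedTranscript,
    gssp_db: dict[str, GSSP],
    rare_threshold: float = RARE_FREQUENCY_THRESHOLD,
) -> list[MutationRarity]:
    """Rarity of every amino-acid substitution in a transcript.

    Rarity = (1 - frequency of the substitution in the gene's GSSP) * 100%.
    Raises KeyError naming the gene when no GSSP exists for it.
    """
    gene = transcript.v_gene
    if gene not in gssp_db:
        raise KeyError(f"no GSSP available for gene {gene!r}")
    gssp = gssp_db[gene]
    out = []
    for label, germ, obs in transcript.shm_aa_substitutions:
        f = gssp.freq.get((label, obs), 0.0)
        out.append(
            MutationRarity(position=label, germline_aa=germ, observed_aa=obs,
                           frequency=f, rarity=(1.0 - f) * 100.0,
                           is_rare=f < rare_threshold)
        )
    return out


def write_gssp_tsv(gssp: GSSP, path: str) -> None:
    """Serialize a profile as TSV plus a JSON sidecar with the mode."""
    import json

    with open(path, "w") as fh:
        fh.write("gene\tposition\taa\tfrequency\tcoverage\tn_clones\n")
        for (label, aa), f in sorted(gssp.freq.items(),
                                     key=lambda kv: (float(kv[0][0]), kv[0][1])):
            fh.write(f"{gssp.v_gene}\t{label}\t{aa}\t{f:.6g}\t"
                     f"{gssp.coverage.get(label, 0)}\t{gssp.n_clones}\n")
    with open(str(path) + ".json", "w") as fh:
        json.dump({"v_gene": gssp.v_gene, "n_clones": gssp.n_clones,
                   "normalization_mode": gssp.normalization_mode}, fh, indent=1)
        fh.write("\n")


def read_gssp_tsv(path: str) -> GSSP:
    import json

    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    gssp = GSSP(v_gene=meta["v_gene"], n_clones=meta["n_clones"],
                normalization_mode=meta["normalization_mode"])
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gene, label, aa, f, cov, _n = line.rstrip("\n").split("\t")
            gssp.freq[(label, aa)] = float(f)
            gssp.coverage[label] = int(cov)
    return gssp
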