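"""Strain-level analysis: consensus genotypes, GTR distances, clustering.

Three stages, run per MSP and per sample:

1. **Consensus calling.**  A per-site pileup over the MSP's signature
   genes (base quality >= 13 by default) is reduced to an IUPAC consensus:
   sites below depth 3 are masked 'N'; otherwise the allele set is the
   reference base (when read-supported) plus every alternate at frequency
   >= *f* (0.1 in the default "mixed" configuration; *f* = 0.5 keeps only
   dominant alleles).  Multiple alleles are encoded as the IUPAC ambiguity
   code.  Sites are evaluated independently; indels are ignored.
2. **Breadth filter.**  A sample-specific MSP is retained when at least
   80 of its 100 signature genes (scaled proportionally for smaller MSPs)
   have breadth >= 0.5, breadth being the fraction of positions at depth
   >= 3.
3. **Pairwise mutation rate.**  Consensus sequences are inherently
   aligned (substitutions only), so the divergence matrix over sites that
   are informative (non-'N') in both samples feeds a closed-form general
   time-reversible (GTR) distance with empirical equilibrium frequencies:
   d = -sum_i pi_i [log(Pi^-1 F_hat)]_ii.  At least 10 informative sites
   are required.  IUPAC ambiguity is counted fractionally: a site pair
   spreads weight 1/(|A|*|B|) over the Cartesian product of its allele
   sets.

Downstream, complete-linkage clustering at a mutation-rate cutoff
(5e-3 ~ 99% ANI) groups samples carrying the same strain, and the
engraftment rate of a donor/recipient cohort is the fraction of
conspecific strain pairs below the identity cutoff (1e-4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.linalg
from scipy.spatial.distance import squareform

from .catalogue import Catalogue
from .counting import (
    DEFAULT_MIN_IDENTITY,
    FilterStats,
    _group_pairs,
    iter_sam_alignments,
)

DEFAULT_F = 0.1
DOMINANT_F = 0.5
DEFAULT_MIN_DEPTH = 3
DEFAULT_MIN_BASE_QUALITY = 13
DEFAULT_MIN_INFORMATIVE = 10
DEFAULT_MIN_GENES = 80
DEFAULT_OF_GENES = 100
DEFAULT_MIN_BREADTH = 0.5
DEFAULT_CLUSTER_CUTOFF = 5e-3
DEFAULT_IDENTICAL_CUTOFF = 1e-4

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: frozenset of bases -> IUPAC character (4-fold ambiguity collapses to N).
IUPAC_CODE: dict[frozenset, str] = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_SET: dict[str, frozenset] = {c: s for s, c in IUPAC_CODE.items()}
#: characters that carry allele information (everything except N).
INFORMATIVE = frozenset(c for c in IUPAC_SET if c != "N")


class StrainError(Exception):
    pass


@dataclass
class SiteCall:
    gene_id: str
    position: int  # 0-based
    depth: int
    allele_counts: dict[str, int]
    consensus: str


@dataclass
class ConsensusGenotype:
    """Sample-specific consensus over one MSP's signature genes."""

    sample_id: str
    msp_id: str
    sequences: dict[str, str]  # gene_id -> IUPAC/N consensus, gene length
    breadth: dict[str, float]  # gene_id -> fraction of positions at depth >= min_depth
    passed_filter: bool = False

    def concatenated(self, gene_order: Sequence[str] | None = None) -> str:
        order = sorted(self.sequences) if gene_order is None else gene_order
        return "".join(self.sequences[g] for g in order)


@dataclass
class DistanceResult:
    msp_id: str
    sample_a: str
    sample_b: str
    informative_sites: int
    mutation_rate: float | None
    reason: str | None = None  # set when mutation_rate is missing


# ---------------------------------------------------------------------------
# Stage 1: pileup and consensus
# ---------------------------------------------------------------------------

def call_site(
    counts: Mapping[str, int],
    ref_base: str,
    f: float = DEFAULT_F,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> str:
    """IUPAC consensus of one site from its allele counts.

    Depth below ``min_depth`` masks the site as 'N'.  The allele set is
    the reference base when it has read support, plus every non-reference
    base at frequency >= f.  An empty set (reference unsupported, no
    alternate reaching f) falls back to the majority base, ties encoded
    as the IUPAC code of the tied set.
    """
    depth = sum(counts.get(b, 0) for b in _BASES)
    if depth < min_depth:
        return "N"
    alleles = set()
    if ref_base in _BASE_INDEX and counts.get(ref_base, 0) >= 1:
        alleles.add(ref_base)
    for b in _BASES:
        if b != ref_base and counts.get(b, 0) / depth >= f - 1e-12:
            alleles.add(b)
    if not alleles:
        top = max(counts.get(b, 0) for b in _BASES)
        alleles = {b for b in _BASES if counts.get(b, 0) == top}
    return IUPAC_CODE[frozenset(alleles)]


def consensus_from_counts(
    counts: np.ndarray,
    ref_seq: str,
    f: float = DEFAULT_F,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[str, float]:
    """Consensus string and breadth from an (L, 4) allele-count matrix."""
    L = len(ref_seq)
    depth = counts.sum(axis=1)
    chars = []
    for pos in range(L):
        if depth[pos] < min_depth:
            chars.append("N")
        else:
            chars.append(
                call_site(
                    {b: int(counts[pos, i]) for b, i in _BASE_INDEX.items()},
                    ref_seq[pos],
                    f=f,
                    min_depth=min_depth,
                )
            )
    breadth = float((depth >= min_depth).sum() / L) if L else 0.0
    return "".join(chars), breadth


def pileup_counts(
    segments: Iterable,
    gene_length: int,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """(L, 4) allele-count matrix from pysam segments aligned to one gene.

    Only aligned match positions contribute (indels drop out of the
    aligned pairs); bases below the quality floor or outside {A,C,G,T}
    are ignored.  Secondary alignments without a stored sequence cannot
    contribute bases and are skipped.  ``out`` accumulates in place.
    """
    counts = np.zeros((gene_length, 4), dtype=np.int64) if out is None else out
    for seg in segments:
        seq = seg.query_sequence
        if seq is None:
            continue
        quals = seg.query_qualities
        cigar = seg.cigartuples
        if cigar is not None and len(cigar) == 1 and cigar[0][0] == 0:
            # fast path: single-M alignment, contiguous columns
            start = seg.reference_start
            n = cigar[0][1]
            codes = np.frombuffer(seq[:n].encode(), dtype=np.uint8)
            base_idx = np.full(n, -1, dtype=np.int64)
            for b, i in _BASE_INDEX.items():
                base_idx[codes == ord(b)] = i
            ok = base_idx >= 0
            if quals is not None:
                ok &= np.asarray(quals[:n]) >= min_base_quality
            rpos = np.arange(start, start + n)
            inside = (rpos >= 0) & (rpos < gene_length)
            ok &= inside
            np.add.at(counts, (rpos[ok], base_idx[ok]), 1)
            continue
        for qpos, rpos in seg.get_aligned_pairs(matches_only=True):
            if rpos is None or qpos is None or not (0 <= rpos < gene_length):
                continue
            base = seq[qpos]
            if base not in _BASE_INDEX:
                continue
            if quals is not None and quals[qpos] < min_base_quality:
                continue
            counts[rpos, _BASE_INDEX[base]] += 1
    return counts


def pileup_consensus(
    segments: Iterable,
    gene_sequence: str,
    f: float = DEFAULT_F,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    gene_id: str = "",
) -> tuple[list[SiteCall], str]:
    """Per-site calls and consensus string for one gene."""
    counts = pileup_counts(segments, len(gene_sequence), min_base_quality)
    consensus, _ = consensus_from_counts(counts, gene_sequence, f, min_depth)
    calls = [
        SiteCall(
            gene_id=gene_id,
            position=pos,
            depth=int(counts[pos].sum()),
            allele_counts={b: int(counts[pos, i]) for b, i in _BASE_INDEX.items()},
            consensus=consensus[pos],
        )
        for pos in range(len(gene_sequence))
    ]
    return calls, consensus


def consensus_genotypes(
    sam_path: str | Path,
    catalogue: Catalogue,
    sample_id: str | None = None,
    msp_ids: Iterable[str] | None = None,
    f: float = DEFAULT_F,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    n_signature: int = DEFAULT_OF_GENES,
    min_genes: int = DEFAULT_MIN_GENES,
    of_genes: int = DEFAULT_OF_GENES,
    min_breadth: float = DEFAULT_MIN_BREADTH,
) -> dict[str, ConsensusGenotype]:
    """Build consensus genotypes for each MSP from one sample's alignments.

    Alignments pass the same identity filter and per-read grouping as the
    counting stage before entering the pileup, so the strain view and the
    abundance view are built from the same evidence.
    """
    sid = Path(sam_path).stem if sample_id is None else sample_id
    wanted = set(msp_ids) if msp_ids is not None else set(catalogue.msps)
    sig_genes: dict[str, str] = {}  # gene_id -> msp_id, signature genes only
    for msp_id in wanted:
        for g in catalogue.signature_genes(msp_id, n_signature):
            sig_genes[g] = msp_id

    arrays: dict[str, np.ndarray] = {}
    stats = FilterStats()
    pairs = iter_sam_alignments(sam_path, stats)
    for _, kept in _group_pairs(pairs, min_identity, stats):
        for rec, seg in kept:
            msp_id = sig_genes.get(rec.gene_id)
            if msp_id is None:
                continue
            gene = catalogue.genes[rec.gene_id]
            if gene.sequence is None:
                raise StrainError(
                    f"gene {rec.gene_id} has no catalogue sequence; the strain "
                    "stage requires genes.fasta"
                )
            arr = arrays.get(rec.gene_id)
            if arr is None:
                arr = arrays[rec.gene_id] = np.zeros((gene.length, 4), dtype=np.int64)
            pileup_counts([seg], gene.length, min_base_quality, out=arr)

    out: dict[str, ConsensusGenotype] = {}
    for msp_id in sorted(wanted):
        sequences: dict[str, str] = {}
        breadth: dict[str, float] = {}
        for g in catalogue.signature_genes(msp_id, n_signature):
            gene = catalogue.genes[g]
            counts = arrays.get(g)
            if counts is None:
                sequences[g] = "N" * gene.length
                breadth[g] = 0.0
            else:
                seq, br = consensus_from_counts(counts, gene.sequence, f, min_depth)
                sequences[g] = seq
                breadth[g] = br
        geno = ConsensusGenotype(sid, msp_id, sequences, breadth)
        geno.passed_filter = breadth_filter(
            geno, min_genes=min_genes, of_genes=of_genes, min_breadth=min_breadth
        )
        out[msp_id] = geno
    return out


# ---------------------------------------------------------------------------
# Stage 2: breadth filter
# ---------------------------------------------------------------------------

def breadth_filter(
    genotype: ConsensusGenotype,
    min_genes: int = DEFAULT_MIN_GENES,
    of_genes: int = DEFAULT_OF_GENES,
    min_breadth: float = DEFAULT_MIN_BREADTH,
) -> bool:
    """True when enough signature genes are broadly covered.

    Default: >= 80 of 100 signature genes at breadth >= 0.5.  MSPs with
    fewer signature genes scale the requirement proportionally
    (ceil(min_genes/of_genes * n)).
    """
    n_used = len(genotype.breadth)
    if n_used == 0:
        return False
    required = min_genes if n_used >= of_genes else math.ceil(
        min_genes / of_genes * n_used - 1e-9
    )
    n_ok = sum(1 for b in genotype.breadth.values() if b >= min_breadth)
    return n_ok >= required


# ---------------------------------------------------------------------------
# Stage 3: pairwise GTR mutation rate
# ---------------------------------------------------------------------------

def _divergence_matrix(seq_a: str, seq_b: str) -> tuple[np.ndarray, int]:
    """4x4 site-pair weight matrix over informative sites.

    Unambiguous site pairs are tallied vectorized; ambiguous IUPAC pairs
    spread fractional weight over the product of their allele sets.
    """
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    if len(a) != len(b):
        raise StrainError("consensus sequences differ in length")

    lut = np.full(256, -2, dtype=np.int64)  # -2 uninformative, -1 ambiguous
    for c in INFORMATIVE:
        lut[ord(c)] = _BASE_INDEX.get(c, -1)
    ia, ib = lut[a], lut[b]
    informative = (ia >= -1) & (ib >= -1)
    n_inf = int(informative.sum())

    F = np.zeros((4, 4))
    plain = informative & (ia >= 0) & (ib >= 0)
    np.add.at(F, (ia[plain], ib[plain]), 1.0)
    for pos in np.nonzero(informative & ((ia < 0) | (ib < 0)))[0]:
        sa = IUPAC_SET[chr(a[pos])]
        sb = IUPAC_SET[chr(b[pos])]
        w = 1.0 / (len(sa) * len(sb))
        for x in sa:
            for y in sb:
                F[_BASE_INDEX[x], _BASE_INDEX[y]] += w
    return F, n_inf


def gtr_distance(F: np.ndarray) -> float | None:
    """Closed-form GTR distance from a site-pair divergence matrix.

    Symmetrizes and normalizes F, takes empirical equilibrium frequencies
    pi from its marginals and returns d = -sum_i pi_i log(Pi^-1 F_hat)_ii.
    Bases absent from both sequences are dropped.  Returns None when the
    matrix logarithm is not real (saturated divergence).
    """
    total = F.sum()
    if total <= 0:
        return None
    if F.sum() - np.trace(F) == 0:
        return 0.0
    present = (F.sum(axis=0) + F.sum(axis=1)) > 0
    Fs = F[np.ix_(present, present)]
    Fhat = (Fs + Fs.T) / (2.0 * total)
    pi = Fhat.sum(axis=1)
    P = Fhat / pi[:, None]
    try:
        M = scipy.linalg.logm(P)
    except Exception:
        return None
    if not np.all(np.isfinite(M)) or (
        np.iscomplexobj(M) and np.max(np.abs(M.imag)) > 1e-8
    ):
        return None
    d = -float(np.sum(pi * np.diag(M).real))
    return max(d, 0.0)


def pairwise_mutation_rate(
    a: ConsensusGenotype,
    b: ConsensusGenotype,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> DistanceResult:
    """GTR mutation rate between two sample-specific MSP genotypes."""
    if a.msp_id != b.msp_id:
        raise StrainError(f"genotypes of different MSPs: {a.msp_id} vs {b.msp_id}")
    genes = sorted(set(a.sequences) & set(b.sequences))
    F, n_inf = _divergence_matrix(
        "".join(a.sequences[g] for g in genes),
        "".join(b.sequences[g] for g in genes),
    )
    if n_inf < min_informative:
        return DistanceResult(
            a.msp_id, a.sample_id, b.sample_id, n_inf, None, "insufficient_informative_sites"
        )
    d = gtr_distance(F)
    if d is None:
        return DistanceResult(a.msp_id, a.sample_id, b.sample_id, n_inf, None, "saturated")
    return DistanceResult(a.msp_id, a.sample_id, b.sample_id, n_inf, d)


def distance_matrix(
    genotypes: Mapping[str, ConsensusGenotype],
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> tuple[pd.DataFrame, list[DistanceResult]]:
    """Symmetric mutation-rate matrix across passing samples of one MSP.

    Missing pairwise rates (too few informative sites, saturation) appear
    as NaN.  Fewer than two passing samples yields an empty matrix.
    """
    passing = {s: g for s, g in genotypes.items() if g.passed_filter}
    samples = sorted(passing)
    results: list[DistanceResult] = []
    if len(samples) < 2:
        return pd.DataFrame(dtype=float), results
    mat = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, sa in enumerate(samples):
        for sb in samples[i + 1:]:
            res = pairwise_mutation_rate(passing[sa], passing[sb], min_informative)
            results.append(res)
            val = np.nan if res.mutation_rate is None else res.mutation_rate
            mat.loc[sa, sb] = val
            mat.loc[sb, sa] = val
    return mat, results


def strain_clusters(
    matrix: pd.DataFrame,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    linkage: str = "complete",
) -> tuple[dict[str, int], list[str]]:
    """Agglomerative clustering of samples cut at a mutation-rate height.

    Samples with any missing pairwise rate are removed (worst offender
    first) and reported unclustered.  Returns (sample -> cluster id,
    unclustered samples).
    """
    if matrix.empty:
        return {}, []
    sub = matrix.copy()
    unclustered: list[str] = []
    while sub.isna().to_numpy().any():
        worst = sub.isna().sum(axis=1).idxmax()
        unclustered.append(str(worst))
        sub = sub.drop(index=worst, columns=worst)
    samples = [str(s) for s in sub.index]
    if len(samples) == 0:
        return {}, sorted(unclustered)
    if len(samples) == 1:
        return {samples[0]: 1}, sorted(unclustered)
    condensed = squareform(sub.to_numpy(), checks=False)
    Z = sch.linkage(condensed, method=linkage)
    labels = sch.fcluster(Z, t=cutoff, criterion="distance")
    return dict(zip(samples, (int(x) for x in labels))), sorted(unclustered)


def engraftment_rate(
    distances: Iterable[DistanceResult],
    pairs: Iterable[tuple[str, str]],
    identical_cutoff: float = DEFAULT_IDENTICAL_CUTOFF,
) -> float | None:
    """Fraction of donor/recipient conspecific strain pairs that are identical.

    ``pairs`` maps donor samples to recipient samples; every MSP with a
    computed mutation rate between the two samples is a conspecific strain
    pair, classified identical when its rate is <= the cutoff.  Returns
    None when no eligible pair exists.
    """
    by_pair: dict[tuple[str, str], list[float]] = {}
    for res in distances:
        if res.mutation_rate is None:
            continue
        by_pair.setdefault((res.sample_a, res.sample_b), []).append(res.mutation_rate)
        by_pair.setdefault((res.sample_b, res.sample_a), []).append(res.mutation_rate)
    n_total = 0
    n_identical = 0
    for donor, recipient in pairs:
        for rate in by_pair.get((donor, recipient), ()):
            n_total += 1
            if rate <= identical_cutoff:
                n_identical += 1
    if n_total == 0:
        return None
    return n_identical / n_total


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_consensus_fasta(
    genotypes: Mapping[str, ConsensusGenotype], path: str | Path
) -> None:
    """Multi-FASTA of concatenated signature-gene consensus, one record/sample."""
    with open(path, "w") as fh:
        for sample in sorted(genotypes):
            g = genotypes[sample]
            fh.write(f">{sample} msp={g.msp_id} passed={g.passed_filter}\n")
            seq = g.concatenated()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_distances(
    results: Iterable[DistanceResult], path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("msp_id\tsample_a\tsample_b\tinformative_sites\tmutation_rate\treason\n")
        for r in results:
            rate = "" if r.mutation_rate is None else f"{r.mutation_rate:.6g}"
            fh.write(
                f"{r.msp_id}\t{r.sample_a}\t{r.sample_b}\t{r.informative_sites}"
                f"\t{rate}\t{r.reason or ''}\n"
            )
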