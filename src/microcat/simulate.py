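"""Synthetic catalogues, communities and alignments with known truth.

Everything the profiler consumes can be generated here deterministically
from a seed: a random gene catalogue (MSPs, signature ranks, functional
annotations, module definitions, near-duplicate gene copies that create
honest multi-mapping), shotgun samples as name-sorted SAM with NM tags,
and strain variants at controlled substitution rates.  The returned truth
objects (true relative abundances, per-read gene of origin, per-sample
strain variant) back every recovery test, and :func:`evaluate_profile`
provides the standard detection/abundance metrics.

The read simulator draws single-end reads from genes proportional to
MSP abundance x gene length, injects strain substitutions before uniform
sequencing errors (no indels — the strain model is substitution-only),
and writes alignments against the catalogue reference with exact edit
distances.  A controlled fraction of reads from duplicated genes also
reports a secondary alignment on the homologous copy, exercising shared
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pysam
from scipy.spatial.distance import braycurtis

from .catalogue import Catalogue, Gene, MSP, parse_module_definition, write_catalogue
from .taxonomy import MSPProfile

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_KO_POOL = [f"K{i:05d}" for i in range(1, 41)]
_CAZYME_POOL = [f"GH{i}" for i in range(1, 11)]
_ARG_POOL = ["blaZ", "tetM", "ermB", "vanA", "aacA"]
_MODULE_DEFS = [
    ("module_001", "KEGG", "K00001 (K00002,K00003)"),
    ("module_002", "KEGG", "K00004+K00005 K00006 K00007"),
    ("module_003", "GMM", "(K00001,K00008) (K00009,K00010+K00011) K00012"),
]


@dataclass
class CatalogueTruth:
    seed: int
    homolog_map: dict[str, str] = field(default_factory=dict)  # gene <-> near-copy


@dataclass
class SampleTruth:
    sample_id: str
    seed: int
    msp_relative_abundance: dict[str, float]
    read_gene: dict[str, str]  # read_id -> gene of origin
    gene_read_counts: dict[str, int]
    strain_divergence: dict[str, float]
    strain_seeds: dict[str, int]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` (never to itself)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_catalogue(
    directory: str | Path | None = None,
    n_msps: int = 5,
    genes_per_msp: int = 120,
    gene_length_range: tuple[int, int] = (300, 1500),
    n_unclustered: int = 20,
    annotation_density: float = 0.5,
    n_signature: int = 100,
    homolog_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[Catalogue, CatalogueTruth]:
    """Random catalogue with MSPs, annotations, modules and homolog pairs.

    Non-signature genes are paired up and, with probability
    ``homolog_fraction`` per pair, the second member becomes a 1%-diverged
    copy of the first — the realistic source of multi-mapped reads.
    Signature genes are never duplicated, keeping the strain stage clean.
    If ``directory`` is given the catalogue is also written to disk.
    """
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    genes: dict[str, Gene] = {}
    msps: dict[str, MSP] = {}
    truth = CatalogueTruth(seed=seed)

    k = 0
    for i in range(n_msps):
        msp_id = f"msp_{i + 1:04d}"
        gene_ids = []
        for _ in range(genes_per_msp):
            gid = f"gene_{k:06d}"
            k += 1
            length = int(rng.integers(lo, hi + 1))
            genes[gid] = Gene(gid, length, _random_seq(rng, length))
            gene_ids.append(gid)
        sig = gene_ids[: min(n_signature, genes_per_msp)]
        nonsig = gene_ids[len(sig):]
        for a, b in zip(nonsig[::2], nonsig[1::2]):
            if rng.random() < homolog_fraction:
                src = genes[a]
                genes[b] = Gene(b, src.length, _mutate(src.sequence, 0.01, rng))
                truth.homolog_map[a] = b
                truth.homolog_map[b] = a
        msps[msp_id] = MSP(msp_id, gene_ids, sig)

    for _ in range(n_unclustered):
        gid = f"gene_{k:06d}"
        k += 1
        length = int(rng.integers(lo, hi + 1))
        genes[gid] = Gene(gid, length, _random_seq(rng, length))

    annotations: dict[str, dict[str, set[str]]] = {"KO": {}, "CAZyme": {}, "ARG_resfinder": {}}
    for gid in genes:
        if rng.random() < annotation_density:
            annotations["KO"][gid] = {str(rng.choice(_KO_POOL))}
        if rng.random() < 0.1:
            annotations["CAZyme"][gid] = {str(rng.choice(_CAZYME_POOL))}
        if rng.random() < 0.05:
            annotations["ARG_resfinder"][gid] = {str(rng.choice(_ARG_POOL))}

    modules = {
        mid: parse_module_definition(expr, module_id=mid, source=src)
        for mid, src, expr in _MODULE_DEFS
    }
    cat = Catalogue(genes=genes, msps=msps, annotations=annotations, modules=modules)
    if directory is not None:
        write_catalogue(cat, directory)
    return cat, truth


def strain_variant(
    catalogue: Catalogue, msp_id: str, divergence: float, strain_seed: int
) -> dict[str, str]:
    """Mutated copies of an MSP's genes at the given substitution rate.

    The variant is a pure function of (catalogue, msp, divergence, seed):
    two samples given the same strain_seed and divergence carry the
    identical strain.
    """
    rng = np.random.default_rng(strain_seed)
    out = {}
    for g in catalogue.msps[msp_id].gene_ids:
        out[g] = _mutate(catalogue.genes[g].sequence, divergence, rng)
    return out


def simulate_sample(
    catalogue: Catalogue,
    msp_abundances: Mapping[str, float],
    out_sam: str | Path,
    sample_id: str | None = None,
    n_reads: int = 10_000,
    read_length: int = 80,
    error_rate: float = 0.01,
    multimap_fraction: float = 0.05,
    strain_divergence: Mapping[str, float] | None = None,
    strain_seeds: Mapping[str, int] | None = None,
    homolog_map: Mapping[str, str] | None = None,
    quality_high: int = 40,
    quality_low: int = 10,
    seed: int = 0,
) -> SampleTruth:
    """Simulate one shotgun sample and write it as a name-sorted SAM.

    Reads are drawn from genes with probability proportional to
    MSP abundance x gene length.  ``strain_divergence`` substitutes the
    sampled MSPs' genomes before sequencing; ``strain_seeds`` pins the
    variant so that samples can share (or not share) a strain.  With
    probability ``multimap_fraction`` a read from a gene that has a
    homologous copy also reports a secondary alignment on the copy.

    Sequencing error follows the base-caller model real instruments
    implement: each base gets a quality from a two-tier mixture of
    ``quality_high`` and ``quality_low`` and is miscalled with
    probability 10^(-Q/10), so miscalls concentrate on low-quality
    bases (which a quality-aware pileup then excludes).  The mixture
    weight is chosen so the raw per-base error rate equals
    ``error_rate`` (default 1%, typical for unfiltered short reads).
    """
    rng = np.random.default_rng(seed)
    sid = Path(out_sam).stem if sample_id is None else sample_id
    total = sum(msp_abundances.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"MSP abundances must sum to 1 (got {total})")
    strain_divergence = dict(strain_divergence or {})
    strain_seeds = dict(strain_seeds or {})
    homolog_map = dict(homolog_map or {})

    # per-MSP strain template (reference unless diverged)
    templates: dict[str, str] = {}
    divergence_used: dict[str, float] = {}
    seeds_used: dict[str, int] = {}
    for msp_id in msp_abundances:
        rate = strain_divergence.get(msp_id, 0.0)
        divergence_used[msp_id] = rate
        if rate > 0:
            sseed = int(strain_seeds.get(msp_id, rng.integers(0, 2**31 - 1)))
            seeds_used[msp_id] = sseed
            templates.update(strain_variant(catalogue, msp_id, rate, sseed))

    gene_list: list[str] = []
    weights: list[float] = []
    for msp_id, ab in msp_abundances.items():
        if ab <= 0:
            continue
        for g in catalogue.msps[msp_id].gene_ids:
            gene_list.append(g)
            weights.append(ab * catalogue.genes[g].length)
    p = np.asarray(weights) / np.sum(weights)
    per_gene = rng.multinomial(n_reads, p)

    dropped = [m for m, ab in msp_abundances.items() if ab > 0]
    sampled_msps = {catalogue.msp_of(g) for g, n in zip(gene_list, per_gene) if n > 0}
    dropped = [m for m in dropped if m not in sampled_msps]
    if dropped:
        import warnings

        warnings.warn(f"n_reads too small to represent MSPs: {dropped}")

    records = []  # (read_id, gene_id, pos, seq, nm, secondary:(gene,pos,nm)|None)
    truth = SampleTruth(sid, seed, dict(msp_abundances), {}, {}, divergence_used, seeds_used)
    read_no = 0
    for g, n in zip(gene_list, per_gene):
        if n == 0:
            continue
        gene = catalogue.genes[g]
        template = templates.get(g, gene.sequence)
        L = gene.length
        rl = min(read_length, L)
        ref = np.frombuffer(gene.sequence.encode(), dtype=np.uint8)
        tem = np.frombuffer(template.encode(), dtype=np.uint8)
        partner = homolog_map.get(g)
        pref = (
            np.frombuffer(catalogue.genes[partner].sequence.encode(), dtype=np.uint8)
            if partner is not None
            else None
        )
        p_hi = 10.0 ** (-quality_high / 10.0)
        p_lo = 10.0 ** (-quality_low / 10.0)
        low_frac = 0.0 if error_rate <= p_hi else min(
            (error_rate - p_hi) / (p_lo - p_hi), 1.0
        )
        starts = rng.integers(0, L - rl + 1, size=n)
        for start in starts:
            read = tem[start : start + rl].copy()
            low = rng.random(rl) < low_frac
            quals = np.where(low, quality_low, quality_high).astype(np.uint8)
            err_p = np.where(low, p_lo, p_hi if error_rate > 0 else 0.0)
            errs = np.nonzero(rng.random(rl) < err_p)[0]
            for pos in errs:
                read[pos] = rng.choice(_BASES[_BASES != read[pos]])
            nm = int(np.count_nonzero(read != ref[start : start + rl]))
            read_id = f"read_{read_no:07d}"
            read_no += 1
            secondary = None
            if partner is not None and rng.random() < multimap_fraction:
                nm2 = int(np.count_nonzero(read != pref[start : start + rl]))
                secondary = (partner, int(start), nm2)
            records.append(
                (read_id, g, int(start), read.tobytes().decode(), quals, nm, secondary)
            )
            truth.read_gene[read_id] = g
            truth.gene_read_counts[g] = truth.gene_read_counts.get(g, 0) + 1

    records.sort(key=lambda r: r[0])
    header = {
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": gid, "LN": catalogue.genes[gid].length} for gid in sorted(catalogue.genes)],
    }
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as fh:
        for read_id, g, pos, seq, quals, nm, secondary in records:
            for gene_id, rpos, nm_i, flag in (
                [(g, pos, nm, 0)]
                + ([(*secondary, 256)] if secondary is not None else [])
            ):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = read_id
                a.flag = flag
                a.reference_id = fh.get_tid(gene_id)
                a.reference_start = rpos
                a.mapping_quality = 40
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = seq
                a.query_qualities = list(quals)
                a.set_tag("NM", nm_i)
                fh.write(a)
    return truth


def evaluate_profile(
    estimated: MSPProfile, truth: Mapping[str, float], pseudocount: float | None = None
) -> dict[str, float]:
    """Detection and abundance metrics of an estimated profile vs truth.

    Presence/absence over the catalogue MSP space gives sensitivity,
    specificity and F1; ``richness_delta`` is estimated minus true
    richness; ``bray_curtis_log10`` compares log10-transformed relative
    abundances (pseudocount: 0.1 x the smallest positive abundance seen,
    unless given).
    """
    ids = sorted(estimated.abundances)
    est = np.array([estimated.abundances[m] for m in ids], dtype=float)
    tru = np.array([truth.get(m, 0.0) for m in ids], dtype=float)
    tp = int(np.sum((est > 0) & (tru > 0)))
    fp = int(np.sum((est > 0) & (tru == 0)))
    fn = int(np.sum((est == 0) & (tru > 0)))
    tn = int(np.sum((est == 0) & (tru == 0)))
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")

    est_rel = est / est.sum() if est.sum() > 0 else est
    tru_rel = tru / tru.sum() if tru.sum() > 0 else tru
    positives = np.concatenate([est_rel[est_rel > 0], tru_rel[tru_rel > 0]])
    if pseudocount is None:
        pseudocount = 0.1 * positives.min() if len(positives) else 1e-6
    bc = float(braycurtis(np.log10(est_rel + pseudocount), np.log10(tru_rel + pseudocount)))
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "richness_delta": int(np.sum(est > 0)) - int(np.sum(tru > 0)),
        "bray_curtis_log10": bc,
    }
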