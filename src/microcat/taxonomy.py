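"""Normalization of gene counts and reduction to MSP abundance profiles.

Gene counts are normalized to depth coverage (count / effective gene
length x 100) or FPKM, then reduced to species-level profiles by averaging
the normalized abundance of each MSP's signature genes.  An MSP is zeroed
when fewer than ``detection_fraction`` of its signature genes are detected
(default 10%; 20% in fast mode, where the reduced catalogue makes spurious
alignments more likely).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .catalogue import Catalogue
from .counting import GeneCounts

DEFAULT_DETECTION_FRACTION = 0.10
FAST_DETECTION_FRACTION = 0.20
DEFAULT_N_SIGNATURE = 100
_EPS = 1e-9


class ProfileError(Exception):
    pass


@dataclass
class GeneProfile:
    sample_id: str
    values: dict[str, float]  # gene_id -> normalized abundance (absent => 0)
    normalization: str


@dataclass
class MSPProfile:
    sample_id: str
    abundances: dict[str, float]  # every catalogue MSP id, 0 if undetected
    detection_fraction_used: float
    n_signature_used: int


def normalize_coverage(
    counts: GeneCounts,
    catalogue: Catalogue,
    read_length: int = 80,
    correction: str = "effective",
) -> GeneProfile:
    """Depth-coverage normalization: count / L_eff x 100.

    ``correction='effective'`` uses L_eff = L - read_length + 1, the number
    of distinct start positions a read of that length can occupy, which
    compensates the read-loss rate of short genes; genes shorter than the
    read length fall back to their raw length with a warning.
    ``correction='none'`` divides by the raw length.
    """
    if read_length <= 0:
        raise ProfileError("read_length must be positive")
    if correction not in ("effective", "none"):
        raise ProfileError(f"unknown correction {correction!r}")
    values: dict[str, float] = {}
    for g, c in counts.counts.items():
        gene = catalogue.genes.get(g)
        if gene is None:
            raise ProfileError(f"count for unknown gene {g!r}")
        length = gene.length
        if correction == "effective":
            eff = length - read_length + 1
            if eff <= 0:
                warnings.warn(
                    f"gene {g}: length {length} <= read length; using raw length"
                )
                eff = length
        else:
            eff = length
        values[g] = c / eff * 100.0
    return GeneProfile(counts.sample_id, values, "coverage")


def normalize_fpkm(
    counts: GeneCounts, catalogue: Catalogue, total_fragments: int | None = None
) -> GeneProfile:
    """Fragments per kilobase of gene per million retained fragments."""
    total = counts.n_reads_retained if total_fragments is None else total_fragments
    if total <= 0:
        raise ProfileError("FPKM requires a positive total fragment count")
    values: dict[str, float] = {}
    for g, c in counts.counts.items():
        gene = catalogue.genes.get(g)
        if gene is None:
            raise ProfileError(f"count for unknown gene {g!r}")
        values[g] = c / ((gene.length / 1000.0) * (total / 1e6))
    return GeneProfile(counts.sample_id, values, "fpkm")


def msp_abundance(
    profile: GeneProfile,
    catalogue: Catalogue,
    n_signature: int = DEFAULT_N_SIGNATURE,
    detection_fraction: float = DEFAULT_DETECTION_FRACTION,
    include_zeros: bool = True,
) -> MSPProfile:
    """Reduce a gene profile to MSP abundances via signature genes.

    For each MSP the top ``n_signature`` signature genes (centrality rank
    order) are taken; the MSP abundance is their arithmetic mean — over
    all of them when ``include_zeros`` (default), over detected ones
    otherwise.  The abundance is forced to 0 when fewer than
    ``detection_fraction`` of the used signature genes carry signal.
    """
    abundances: dict[str, float] = {}
    for msp_id, msp in catalogue.msps.items():
        sig = msp.signature_gene_ids[:n_signature]
        if not sig:
            warnings.warn(f"MSP {msp_id} has no signature genes; abundance set to 0")
            abundances[msp_id] = 0.0
            continue
        vals = [profile.values.get(g, 0.0) for g in sig]
        detected = sum(1 for v in vals if v > 0)
        # slack so that exactly the threshold fraction counts as detected
        if detected < detection_fraction * len(sig) - _EPS:
            abundances[msp_id] = 0.0
        elif include_zeros:
            abundances[msp_id] = sum(vals) / len(vals)
        else:
            abundances[msp_id] = sum(v for v in vals if v > 0) / detected
    return MSPProfile(
        sample_id=profile.sample_id,
        abundances=abundances,
        detection_fraction_used=detection_fraction,
        n_signature_used=n_signature,
    )


def relative_abundance(msp: MSPProfile) -> MSPProfile:
    """Scale abundances to sum to 1, preserving zeros."""
    total = sum(msp.abundances.values())
    if total <= 0:
        raise ProfileError("cannot compute relative abundance of an all-zero profile")
    return MSPProfile(
        sample_id=msp.sample_id,
        abundances={k: v / total for k, v in msp.abundances.items()},
        detection_fraction_used=msp.detection_fraction_used,
        n_signature_used=msp.n_signature_used,
    )


def richness(msp: MSPProfile) -> int:
    """Alpha-diversity as the number of detected MSPs."""
    return sum(1 for v in msp.abundances.values() if v > 0)


def write_msp_profile(msp: MSPProfile, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("msp_id\tabundance\n")
        for m in sorted(msp.abundances):
            fh.write(f"{m}\t{msp.abundances[m]:.6g}\n")


def merge_profiles(profiles: list[MSPProfile]):
    """Cohort matrix (samples x MSPs) from per-sample profiles."""
    import pandas as pd

    ids = sorted({m for p in profiles for m in p.abundances})
    return pd.DataFrame(
        [[p.abundances.get(m, 0.0) for m in ids] for p in profiles],
        index=[p.sample_id for p in profiles],
        columns=ids,
    )
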