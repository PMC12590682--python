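"""Run configuration and sample-set orchestration.

``RunConfig`` collects every tunable of the pipeline with its default.
Fast mode tightens the alignment identity threshold to 0.98 and the MSP
detection fraction to 0.20 unless either is overridden explicitly.
``run_profile`` takes a sample set through counting, normalization,
taxonomic and functional profiling; ``run_strain`` builds consensus
genotypes, pairwise mutation rates, strain clusters and (given
donor/recipient metadata) engraftment rates.  Per-sample failures are
isolated: the remaining samples still complete and the summary reports
which failed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalogue import ARG_NAMESPACES, Catalogue, load_catalogue
from .counting import (
    DEFAULT_MIN_IDENTITY,
    FAST_MIN_IDENTITY,
    count_sam,
    write_counts,
)
from .functions import (
    arg_ratio,
    gene_level_function_abundance,
    module_report,
    msp_level_function_abundance,
    write_function_profile,
    write_module_reports,
)
from .strains import (
    consensus_genotypes,
    distance_matrix,
    engraftment_rate,
    strain_clusters,
    write_consensus_fasta,
    write_distances,
)
from .taxonomy import (
    DEFAULT_DETECTION_FRACTION,
    FAST_DETECTION_FRACTION,
    msp_abundance,
    normalize_coverage,
    normalize_fpkm,
    write_msp_profile,
)

logger = logging.getLogger("microcat")


class ConfigError(Exception):
    pass


@dataclass
class RunConfig:
    catalogue: str
    output_dir: str = "microcat_out"
    mode: str = "complete"  # complete | fast
    counting: str = "shared"  # unique | total | shared
    normalization: str = "coverage"  # coverage | fpkm
    identity_threshold: float | None = None  # None -> 0.95 complete / 0.98 fast
    detection_fraction: float | None = None  # None -> 0.10 complete / 0.20 fast
    read_length: int = 80
    length_correction: str = "effective"
    n_signature: int = 100
    strain_f: float = 0.1
    min_depth: int = 3
    min_base_quality: int = 13
    min_informative: int = 10
    min_genes: int = 80
    of_genes: int = 100
    min_breadth: float = 0.5
    cluster_cutoff: float = 5e-3
    identical_cutoff: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("complete", "fast"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.counting not in ("unique", "total", "shared"):
            raise ConfigError(f"unknown counting mode {self.counting!r}")
        if self.normalization not in ("coverage", "fpkm"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")

    @property
    def resolved_identity(self) -> float:
        if self.identity_threshold is not None:
            return self.identity_threshold
        return FAST_MIN_IDENTITY if self.mode == "fast" else DEFAULT_MIN_IDENTITY

    @property
    def resolved_detection(self) -> float:
        if self.detection_fraction is not None:
            return self.detection_fraction
        return FAST_DETECTION_FRACTION if self.mode == "fast" else DEFAULT_DETECTION_FRACTION

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        # analytical parameters only: where outputs land must not change
        # what they contain
        params = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def output_header(self) -> str:
        return f"microcat {__version__} config={self.config_hash()} seed={self.seed}"


def _load(config: RunConfig) -> Catalogue:
    return load_catalogue(config.catalogue, mode=config.mode)


def profile_sample(
    config: RunConfig, catalogue: Catalogue, sam_path: str | Path, outdir: Path
) -> dict:
    """Full taxonomic + functional profile of one sample; returns a summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.output_header()
    sample_id = Path(sam_path).stem

    counts, stats = count_sam(
        sam_path, mode=config.counting, min_identity=config.resolved_identity,
        sample_id=sample_id,
    )
    write_counts(counts, outdir / "gene_counts.tsv", header)

    if config.normalization == "coverage":
        profile = normalize_coverage(
            counts, catalogue, read_length=config.read_length,
            correction=config.length_correction,
        )
    else:
        profile = normalize_fpkm(counts, catalogue)

    msp = msp_abundance(
        profile, catalogue, n_signature=config.n_signature,
        detection_fraction=config.resolved_detection,
    )
    write_msp_profile(msp, outdir / "msp_profile.tsv", header)

    for ns in sorted(catalogue.annotations):
        fp = gene_level_function_abundance(profile, catalogue, ns)
        write_function_profile(fp, outdir / f"functions_{ns}_gene.tsv", header)
        fp_msp = msp_level_function_abundance(msp, counts, catalogue, ns)
        write_function_profile(fp_msp, outdir / f"functions_{ns}_msp.tsv", header)

    if catalogue.modules:
        write_module_reports(
            module_report(msp, counts, catalogue), outdir, header
        )

    summary = {
        "sample_id": sample_id,
        "n_read_units": stats.n_read_units,
        "n_retained": stats.n_retained,
        "mapping_rate": stats.mapping_rate(),
        "n_missing_nm": stats.n_missing_nm,
    }
    arg_ns = [ns for ns in catalogue.annotations if ns in ARG_NAMESPACES]
    if arg_ns and counts.detected_genes():
        ratio = arg_ratio(counts, catalogue, frozenset(arg_ns))
        summary["arg_ratio"] = ratio
        with open(outdir / "arg_ratio.tsv", "w") as fh:
            fh.write(f"# {header}\nsample_id\targ_ratio\n{sample_id}\t{ratio:.6g}\n")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"header": header, **summary}, fh, indent=1)
    return summary


def run_profile(config: RunConfig, sam_paths: list[str | Path]) -> dict:
    """Profile a sample set; per-sample failures are isolated."""
    catalogue = _load(config)
    outroot = Path(config.output_dir)
    results: dict[str, dict] = {}
    failures: dict[str, str] = {}
    for sam in sam_paths:
        sample_id = Path(sam).stem
        try:
            results[sample_id] = profile_sample(
                config, catalogue, sam, outroot / sample_id
            )
        except Exception as exc:  # isolate per-sample failures
            logger.error("sample %s failed: %s", sample_id, exc)
            failures[sample_id] = str(exc)
    return {"samples": results, "failures": failures}


def run_strain(
    config: RunConfig,
    sam_paths: list[str | Path],
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Strain stage over a sample set.

    ``metadata`` (optional) columns: sample_id, individual, role
    (donor/recipient), donor_individual, timepoint.  When donor links are
    present, the engraftment rate is computed per timepoint.
    """
    catalogue = _load(config)
    outroot = Path(config.output_dir) / "strain"
    outroot.mkdir(parents=True, exist_ok=True)
    header = config.output_header()

    per_msp: dict[str, dict] = {m: {} for m in catalogue.msps}
    for sam in sam_paths:
        sample_id = Path(sam).stem
        genos = consensus_genotypes(
            sam, catalogue, sample_id=sample_id,
            f=config.strain_f, min_depth=config.min_depth,
            min_identity=config.resolved_identity,
            min_base_quality=config.min_base_quality,
            n_signature=config.n_signature, min_genes=config.min_genes,
            of_genes=config.of_genes, min_breadth=config.min_breadth,
        )
        for msp_id, g in genos.items():
            per_msp[msp_id][sample_id] = g

    all_results = []
    clusters_rows = []
    for msp_id, genos in sorted(per_msp.items()):
        passing = {s: g for s, g in genos.items() if g.passed_filter}
        if not passing:
            continue
        write_consensus_fasta(passing, outroot / f"consensus_{msp_id}.fasta")
        if len(passing) < 2:
            logger.info("MSP %s present in <2 samples; no distances", msp_id)
            continue
        mat, results = distance_matrix(genos, min_informative=config.min_informative)
        all_results.extend(results)
        mat.to_csv(outroot / f"distances_{msp_id}.tsv", sep="\t")
        labels, unclustered = strain_clusters(mat, cutoff=config.cluster_cutoff)
        for s, c in sorted(labels.items()):
            clusters_rows.append((msp_id, s, c))
        for s in unclustered:
            clusters_rows.append((msp_id, s, ""))

    write_distances(all_results, outroot / "distances.tsv", header)
    pd.DataFrame(clusters_rows, columns=["msp_id", "sample_id", "cluster"]).to_csv(
        outroot / "clusters.tsv", sep="\t", index=False
    )

    out = {"n_distances": sum(1 for r in all_results if r.mutation_rate is not None)}
    if metadata is not None and "donor_individual" in metadata.columns:
        rows = []
        donors = metadata[metadata["role"] == "donor"]
        recipients = metadata[metadata["role"] == "recipient"]
        for tp, grp in recipients.groupby("timepoint"):
            pairs = []
            for r in grp.itertuples(index=False):
                dsamples = donors[donors["individual"] == r.donor_individual]["sample_id"]
                pairs.extend((d, r.sample_id) for d in dsamples)
            rate = engraftment_rate(all_results, pairs, config.identical_cutoff)
            rows.append((tp, "" if rate is None else rate, len(pairs)))
        pd.DataFrame(rows, columns=["timepoint", "engraftment_rate", "n_donor_recipient_pairs"]).to_csv(
            outroot / "engraftment.tsv", sep="\t", index=False
        )
        out["engraftment"] = {str(tp): r for tp, r, _ in rows}
    elif metadata is not None:
        logger.info("metadata has no donor links; engraftment skipped")
    return out
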