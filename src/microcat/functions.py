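"""Functional profiling: term abundances, module completeness, ARG ratio.

Function abundance is computed at two levels: gene level (sum of the
normalized abundances of genes carrying the term) and MSP level (sum of
the abundances of MSPs that harbor at least one *detected* gene with the
term — detection meaning >= 1 mapped read in the sample).

A functional module (KEGG / GMM / GBM definition) is scored by
completeness: the fraction of its mandatory steps satisfied, maximized
over alternative step configurations.  MSPs with completeness strictly
above 90% are module carriers; the sum of carrier abundances is the
module's potential in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .catalogue import ARG_NAMESPACES, Catalogue, ModuleDefinition
from .counting import GeneCounts
from .taxonomy import MSPProfile

DEFAULT_CARRIER_THRESHOLD = 0.9


class FunctionError(Exception):
    pass


@dataclass
class FunctionProfile:
    sample_id: str
    namespace: str
    values: dict[str, float]
    level: str  # 'gene' or 'msp'


@dataclass
class ModuleReport:
    sample_id: str
    module_id: str
    carriers: list[tuple[str, float]]  # (msp_id, completeness), completeness > threshold
    potential: float


def _require_namespace(catalogue: Catalogue, namespace: str) -> dict[str, set[str]]:
    if namespace not in catalogue.annotations:
        raise FunctionError(
            f"namespace {namespace!r} not annotated; available: "
            f"{sorted(catalogue.annotations)}"
        )
    return catalogue.annotations[namespace]


def gene_level_function_abundance(
    profile, catalogue: Catalogue, namespace: str
) -> FunctionProfile:
    """Sum gene abundances per annotation term.

    A gene with several terms contributes its full abundance to each.
    """
    ann = _require_namespace(catalogue, namespace)
    values: dict[str, float] = {}
    for g, v in profile.values.items():
        for term in ann.get(g, ()):
            values[term] = values.get(term, 0.0) + v
    return FunctionProfile(profile.sample_id, namespace, values, "gene")


def msp_level_function_abundance(
    msp: MSPProfile, detection: GeneCounts, catalogue: Catalogue, namespace: str
) -> FunctionProfile:
    """Sum MSP abundances per term over MSPs with a detected carrier gene."""
    ann = _require_namespace(catalogue, namespace)
    detected = detection.detected_genes()
    values: dict[str, float] = {}
    for msp_id, msp_obj in catalogue.msps.items():
        abundance = msp.abundances.get(msp_id, 0.0)
        if abundance <= 0:
            continue
        terms: set[str] = set()
        for g in msp_obj.gene_ids:
            if g in detected:
                terms |= ann.get(g, set())
        for term in terms:
            values[term] = values.get(term, 0.0) + abundance
    return FunctionProfile(msp.sample_id, namespace, values, "msp")


def module_completeness(m: ModuleDefinition, present_terms: set[str]) -> float:
    """Fraction of steps satisfied, maximized over configurations.

    A step is satisfied when every term of at least one of its
    alternatives is present.  Because steps choose their alternatives
    independently, the maximum over full configurations decomposes into a
    per-step maximum — no enumeration needed.
    """
    satisfied = sum(
        1
        for alternatives in m.steps
        if any(unit <= present_terms for unit in alternatives)
    )
    return satisfied / len(m.steps)


def msp_present_terms(
    msp_id: str,
    detection: GeneCounts,
    catalogue: Catalogue,
    namespaces: tuple[str, ...] | None = None,
) -> set[str]:
    """Terms carried by an MSP's detected genes in this sample."""
    detected = detection.detected_genes()
    terms: set[str] = set()
    for g in catalogue.msps[msp_id].gene_ids:
        if g not in detected:
            continue
        if namespaces is None:
            terms |= catalogue.terms_of(g)
        else:
            for ns in namespaces:
                terms |= catalogue.annotations.get(ns, {}).get(g, set())
    return terms


def module_report(
    msp: MSPProfile,
    detection: GeneCounts,
    catalogue: Catalogue,
    carrier_threshold: float = DEFAULT_CARRIER_THRESHOLD,
    namespaces: tuple[str, ...] | None = None,
) -> list[ModuleReport]:
    """Per-module carriers and potential for one sample.

    Carrier status requires completeness strictly greater than the
    threshold (a completeness of exactly 0.90 is not enough); the module
    potential is the cumulative abundance of its carriers, yielding the
    list of species contributing the function in this sample.
    """
    detected_msps = [m for m, a in msp.abundances.items() if a > 0]
    terms_by_msp = {
        m: msp_present_terms(m, detection, catalogue, namespaces) for m in detected_msps
    }
    reports = []
    for module_id in sorted(catalogue.modules):
        module = catalogue.modules[module_id]
        carriers = []
        for m in detected_msps:
            comp = module_completeness(module, terms_by_msp[m])
            if comp > carrier_threshold:
                carriers.append((m, comp))
        potential = sum(msp.abundances[m] for m, _ in carriers)
        reports.append(ModuleReport(msp.sample_id, module_id, carriers, potential))
    return reports


def arg_ratio(
    detection: GeneCounts,
    catalogue: Catalogue,
    arg_namespaces: frozenset[str] | set[str] = ARG_NAMESPACES,
) -> float:
    """Fraction of detected genes annotated as antibiotic-resistance genes.

    The default pools every ARG namespace (union); pass a singleton set to
    score one repertoire at a time.
    """
    detected = detection.detected_genes()
    if not detected:
        raise FunctionError("no detected genes: ARG ratio undefined")
    n_arg = sum(
        1
        for g in detected
        if any(catalogue.annotations.get(ns, {}).get(g) for ns in arg_namespaces)
    )
    return n_arg / len(detected)


def write_function_profile(fp: FunctionProfile, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("term\tabundance\tlevel\n")
        for t in sorted(fp.values):
            fh.write(f"{t}\t{fp.values[t]:.6g}\t{fp.level}\n")


def write_module_reports(reports: list[ModuleReport], directory: str | Path, header: str | None = None) -> None:
    directory = Path(directory)
    with open(directory / "modules.tsv", "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("module_id\tpotential\tn_carriers\n")
        for r in reports:
            fh.write(f"{r.module_id}\t{r.potential:.6g}\t{len(r.carriers)}\n")
    with open(directory / "module_carriers.tsv", "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("module_id\tmsp_id\tcompleteness\n")
        for r in reports:
            for m, c in r.carriers:
                fh.write(f"{r.module_id}\t{m}\t{c:.6g}\n")
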