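"""Gene-catalogue data model.

A catalogue bundles the reference objects every profiling stage consumes:
genes (id, length, optional sequence), metagenomic species pangenomes
(MSPs) with their ranked signature genes, functional annotations
(KO / CAZyme / ARG namespaces), and functional-module definitions written
in a KEGG-style boolean grammar.

On disk a catalogue is a directory of plain-text tables::

    genes.tsv                 gene_id, length
    msps.tsv                  msp_id, gene_id, signature_rank ('' if none)
    annotations/<ns>.tsv      gene_id, term
    modules.tsv               module_id, source, definition
    genes.fasta               optional nucleotide sequences
    manifest.yaml             mode, counts, format version

Loading cross-references everything and rejects dangling ids, duplicate
genes, and genes claimed by more than one MSP.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FORMAT_VERSION = "1.0"

#: Annotation namespaces understood by the functional profiler.
NAMESPACES = ("KO", "CAZyme", "ARG_resfinder", "ARG_resfinderFG", "ARG_pcm", "uniref90")

#: Namespaces pooled by default when computing the ARG gene ratio.
ARG_NAMESPACES = frozenset({"ARG_resfinder", "ARG_resfinderFG", "ARG_pcm"})


class CatalogueError(Exception):
    """Base class for catalogue problems."""


class CatalogueLoadError(CatalogueError):
    """A mandatory file is missing or unreadable."""


class CatalogueValidationError(CatalogueError):
    """Tables are inconsistent (duplicates, dangling references...)."""


class ModuleParseError(CatalogueError):
    """A module definition string is malformed."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass
class Gene:
    gene_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise CatalogueValidationError(f"gene {self.gene_id!r}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise CatalogueValidationError(
                f"gene {self.gene_id!r}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )


@dataclass
class MSP:
    """A metagenomic species pangenome: a co-abundance gene cluster.

    ``signature_gene_ids`` is ordered by centrality rank — index 0 is the
    most central gene.  Signature genes are the detection and
    quantification markers of the species.
    """

    msp_id: str
    gene_ids: list[str]
    signature_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.signature_gene_ids) - set(self.gene_ids)
        if missing:
            raise CatalogueValidationError(
                f"MSP {self.msp_id!r}: signature genes not members: {sorted(missing)}"
            )


@dataclass
class ModuleDefinition:
    """A functional module as ordered mandatory steps with alternatives.

    ``steps[i]`` is a tuple of alternative units for step *i*; each unit is
    a frozenset of jointly-required terms.  A step is satisfied when all
    terms of at least one of its alternatives are present.
    """

    module_id: str
    steps: list[tuple[frozenset[str], ...]]
    source: str = "KEGG"
    definition: str | None = None

    def __post_init__(self) -> None:
        if not self.steps or any(not alts for alts in self.steps) or any(
            not unit for alts in self.steps for unit in alts
        ):
            raise CatalogueValidationError(
                f"module {self.module_id!r}: empty step or alternative"
            )


@dataclass
class Catalogue:
    genes: dict[str, Gene]
    msps: dict[str, MSP]
    annotations: dict[str, dict[str, set[str]]]  # namespace -> gene_id -> terms
    modules: dict[str, ModuleDefinition] = field(default_factory=dict)
    mode: str = "complete"

    def __post_init__(self) -> None:
        self._gene_msp: dict[str, str] = {}
        for msp in self.msps.values():
            for g in msp.gene_ids:
                if g in self._gene_msp:
                    raise CatalogueValidationError(
                        f"gene {g!r} assigned to both MSP {self._gene_msp[g]!r} "
                        f"and {msp.msp_id!r}"
                    )
                self._gene_msp[g] = msp.msp_id

    def msp_of(self, gene_id: str) -> str | None:
        """MSP id of a gene, or None for unclustered genes."""
        return self._gene_msp.get(gene_id)

    def terms_of(self, gene_id: str, namespace: str | None = None) -> set[str]:
        """Annotation terms of a gene, in one namespace or pooled."""
        if namespace is not None:
            return set(self.annotations.get(namespace, {}).get(gene_id, ()))
        out: set[str] = set()
        for mapping in self.annotations.values():
            out |= mapping.get(gene_id, set())
        return out

    def signature_genes(self, msp_id: str, n: int | None = None) -> list[str]:
        sig = self.msps[msp_id].signature_gene_ids
        return list(sig) if n is None else list(sig[:n])


# ---------------------------------------------------------------------------
# Module-definition grammar
# ---------------------------------------------------------------------------
#
# KEGG-module-like notation:
#   * top-level whitespace separates mandatory steps;
#   * within a step, comma separates alternatives;
#   * '+' joins jointly-required terms (a complex);
#   * parentheses group; nested whitespace acts as conjunction.
#
# "K1 (K2,K3)" therefore has two steps, the second offering {K2} or {K3}.

_TOKEN_RE = re.compile(r"\s+|[(),+]|[^\s(),+]+")


def _tokenize(expr: str) -> list[tuple[str, str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(expr):
        text = m.group(0)
        if text.isspace():
            kind = "WS"
        elif text == "(":
            kind = "LP"
        elif text == ")":
            kind = "RP"
        elif text == ",":
            kind = "COMMA"
        elif text == "+":
            kind = "PLUS"
        else:
            kind = "TERM"
        tokens.append((kind, text, m.start()))
    return tokens


def _check_balance(tokens: list[tuple[str, str, int]], expr: str) -> None:
    depth = 0
    last_open = 0
    for kind, _, pos in tokens:
        if kind == "LP":
            depth += 1
            last_open = pos
        elif kind == "RP":
            depth -= 1
            if depth < 0:
                raise ModuleParseError("unbalanced ')'", pos)
    if depth > 0:
        raise ModuleParseError("unbalanced '('", last_open)


class _StepParser:
    """Recursive-descent parser for one step's token slice."""

    def __init__(self, tokens: list[tuple[str, str, int]], end_pos: int):
        self.tokens = tokens
        self.i = 0
        self.end_pos = end_pos

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        return self.tokens[self.i][2] if self.i < len(self.tokens) else self.end_pos

    def parse(self) -> list[frozenset[str]]:
        alts = self._alt_expr()
        if self.i < len(self.tokens):
            raise ModuleParseError("unexpected token", self._pos())
        return alts

    def _alt_expr(self) -> list[frozenset[str]]:
        alts = self._conj()
        while self._peek() == "COMMA":
            self.i += 1
            while self._peek() == "WS":
                self.i += 1
            alts.extend(self._conj())
        # order-preserving de-duplication
        seen: set[frozenset[str]] = set()
        return [a for a in alts if not (a in seen or seen.add(a))]

    def _conj(self) -> list[frozenset[str]]:
        result = self._unit()
        while True:
            if self._peek() == "PLUS":
                self.i += 1
            elif self._peek() == "WS":
                self.i += 1
                if self._peek() not in ("TERM", "LP"):
                    break
            elif self._peek() in ("TERM", "LP"):
                pass
            else:
                break
            rhs = self._unit()
            result = [a | b for a in result for b in rhs]
        return result

    def _unit(self) -> list[frozenset[str]]:
        kind = self._peek()
        if kind == "TERM":
            term = self.tokens[self.i][1]
            self.i += 1
            return [frozenset({term})]
        if kind == "LP":
            self.i += 1
            while self._peek() == "WS":
                self.i += 1
            inner = self._alt_expr()
            while self._peek() == "WS":
                self.i += 1
            if self._peek() != "RP":
                raise ModuleParseError("expected ')'", self._pos())
            self.i += 1
            return inner
        raise ModuleParseError("empty alternative", self._pos())


def parse_module_definition(
    expr: str, module_id: str = "", source: str = "KEGG"
) -> ModuleDefinition:
    """Parse a module definition string into steps and alternatives."""
    tokens = _tokenize(expr)
    _check_balance(tokens, expr)

    # split into steps at depth-0 whitespace
    steps_tokens: list[list[tuple[str, str, int]]] = [[]]
    depth = 0
    for tok in tokens:
        kind = tok[0]
        if kind == "LP":
            depth += 1
        elif kind == "RP":
            depth -= 1
        if kind == "WS" and depth == 0:
            if steps_tokens[-1]:
                steps_tokens.append([])
            continue
        steps_tokens[-1].append(tok)
    if steps_tokens and not steps_tokens[-1]:
        steps_tokens.pop()
    if not steps_tokens:
        raise ModuleParseError("empty module definition", 0)

    steps = []
    for toks in steps_tokens:
        alts = _StepParser(toks, len(expr)).parse()
        steps.append(tuple(alts))
    return ModuleDefinition(module_id=module_id, steps=steps, source=source, definition=expr)


def enumerate_configurations(
    m: ModuleDefinition, limit: int = 10_000
) -> list[frozenset[str]]:
    """All alternative configurations of a module.

    Each configuration picks one alternative per step and takes the union
    of their terms.  Guarded against combinatorial blow-up: per-step
    evaluation (see the functional profiler) never needs the full product.
    """
    n = 1
    for alts in m.steps:
        n *= len(alts)
        if n > limit:
            raise CatalogueError(
                f"module {m.module_id!r}: {n}+ configurations exceed limit {limit}; "
                "evaluate per step instead"
            )
    return [frozenset().union(*choice) for choice in itertools.product(*m.steps)]


# ---------------------------------------------------------------------------
# Directory I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CatalogueLoadError(f"{path.name}: missing columns {missing}")
    return df


def load_catalogue(directory: str | Path, mode: str = "complete") -> Catalogue:
    """Load and cross-validate a catalogue directory.

    In ``fast`` mode the catalogue is restricted to signature genes only,
    giving the lightweight reference used for rapid profiling.
    """
    directory = Path(directory)
    if mode not in ("complete", "fast"):
        raise CatalogueError(f"unknown mode {mode!r}")
    for name in ("genes.tsv", "msps.tsv"):
        if not (directory / name).exists():
            raise CatalogueLoadError(f"missing mandatory file: {name} in {directory}")

    gdf = _read_tsv(directory / "genes.tsv", ["gene_id", "length"])
    dup = gdf["gene_id"][gdf["gene_id"].duplicated()]
    if len(dup):
        raise CatalogueValidationError(f"duplicate gene_id: {sorted(set(dup))}")
    genes = {
        r.gene_id: Gene(r.gene_id, int(r.length)) for r in gdf.itertuples(index=False)
    }

    fasta = directory / "genes.fasta"
    if fasta.exists():
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if rec.id not in genes:
                raise CatalogueValidationError(f"genes.fasta: unknown gene {rec.id!r}")
            g = genes[rec.id]
            genes[rec.id] = Gene(g.gene_id, g.length, str(rec.seq).upper())

    mdf = _read_tsv(directory / "msps.tsv", ["msp_id", "gene_id", "signature_rank"])
    unknown = sorted(set(mdf["gene_id"]) - set(genes))
    if unknown:
        raise CatalogueValidationError(f"msps.tsv references unknown genes: {unknown}")
    msps: dict[str, MSP] = {}
    for msp_id, grp in mdf.groupby("msp_id", sort=True):
        sig = grp[grp["signature_rank"] != ""].copy()
        sig["rank"] = sig["signature_rank"].astype(int)
        # rank ties broken lexicographically for reproducibility
        sig = sig.sort_values(["rank", "gene_id"])
        msps[str(msp_id)] = MSP(
            msp_id=str(msp_id),
            gene_ids=list(grp["gene_id"]),
            signature_gene_ids=list(sig["gene_id"]),
        )

    annotations: dict[str, dict[str, set[str]]] = {}
    anndir = directory / "annotations"
    if anndir.is_dir():
        for path in sorted(anndir.glob("*.tsv")):
            ns = path.stem
            adf = _read_tsv(path, ["gene_id", "term"])
            unknown = sorted(set(adf["gene_id"]) - set(genes))
            if unknown:
                raise CatalogueValidationError(
                    f"annotations/{path.name}: unknown genes: {unknown}"
                )
            mapping: dict[str, set[str]] = {}
            for r in adf.itertuples(index=False):
                mapping.setdefault(r.gene_id, set()).add(r.term)
            annotations[ns] = mapping

    modules: dict[str, ModuleDefinition] = {}
    modpath = directory / "modules.tsv"
    if modpath.exists():
        for r in _read_tsv(modpath, ["module_id", "source", "definition"]).itertuples(
            index=False
        ):
            modules[r.module_id] = parse_module_definition(
                r.definition, module_id=r.module_id, source=r.source
            )

    if mode == "fast":
        keep = {g for m in msps.values() for g in m.signature_gene_ids}
        genes = {g: v for g, v in genes.items() if g in keep}
        msps = {
            mid: MSP(mid, [g for g in m.gene_ids if g in keep], m.signature_gene_ids)
            for mid, m in msps.items()
        }
        annotations = {
            ns: {g: t for g, t in mapping.items() if g in keep}
            for ns, mapping in annotations.items()
        }

    return Catalogue(genes=genes, msps=msps, annotations=annotations, modules=modules, mode=mode)


def write_catalogue(cat: Catalogue, directory: str | Path) -> Path:
    """Write a catalogue directory (inverse of :func:`load_catalogue`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"gene_id": list(cat.genes), "length": [g.length for g in cat.genes.values()]}
    ).to_csv(directory / "genes.tsv", sep="\t", index=False)

    rows = []
    for msp in cat.msps.values():
        rank = {g: i + 1 for i, g in enumerate(msp.signature_gene_ids)}
        for g in msp.gene_ids:
            rows.append((msp.msp_id, g, rank.get(g, "")))
    pd.DataFrame(rows, columns=["msp_id", "gene_id", "signature_rank"]).to_csv(
        directory / "msps.tsv", sep="\t", index=False
    )

    if cat.annotations:
        anndir = directory / "annotations"
        anndir.mkdir(exist_ok=True)
        for ns, mapping in cat.annotations.items():
            rows = [(g, t) for g in sorted(mapping) for t in sorted(mapping[g])]
            pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(
                anndir / f"{ns}.tsv", sep="\t", index=False
            )

    if cat.modules:
        pd.DataFrame(
            [(m.module_id, m.source, m.definition) for m in cat.modules.values()],
            columns=["module_id", "source", "definition"],
        ).to_csv(directory / "modules.tsv", sep="\t", index=False)

    seqs = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
        for g in cat.genes.values()
        if g.sequence is not None
    ]
    if seqs:
        SeqIO.write(seqs, str(directory / "genes.fasta"), "fasta")

    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "format_version": FORMAT_VERSION,
                "mode": cat.mode,
                "n_genes": len(cat.genes),
                "n_msps": len(cat.msps),
                "n_modules": len(cat.modules),
            },
            fh,
        )
    return directory
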