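"""Readers and writers for the plain tab-separated input and result tables.

Five input tables are consumed:

* ``catalog.tsv`` — one row per gene: id, protein length (aa), essential /
  dubious / subtelomeric flags, and pipe-separated annotation-term lists for
  the process / function / component aspects.
* ``edges.tsv`` — physical-interaction pairs with an optional source tag
  (``small_scale`` / ``high_throughput``).
* ``families.tsv`` — gene to homologous-family assignments.
* ``reconstruction.tsv`` — ancestral loci with descendant tracks (A/B).
* ``orthologs.tsv`` — per-gene ortholog occurrences with a flag marking
  species that diverged before the whole-genome duplication.

All files are UTF-8 TSV with a mandatory header row; lines starting with
``#`` are comments.  Gene identifiers are case-sensitive opaque strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

ASPECTS = ("process", "function", "component")
EDGE_SOURCES = ("small_scale", "high_throughput", "unknown")

_CATALOG_COLUMNS = (
    "gene_id",
    "length_aa",
    "essential",
    "dubious",
    "subtelomeric",
    "go_process",
    "go_function",
    "go_component",
)


class DataError(ValueError):
    """Raised on malformed or invariant-violating input tables."""


# ---------------------------------------------------------------------------
# gene catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identity, protein length, flags, and annotation terms."""

    gene_id: str
    length_aa: int
    essential: bool = False
    dubious: bool = False
    subtelomeric: bool = False
    terms: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise DataError(
                f"gene {self.gene_id!r}: length_aa must be >= 1, got {self.length_aa}"
            )
        # normalize so records compare equal regardless of omitted aspects
        normalized = {a: frozenset(self.terms.get(a, frozenset())) for a in ASPECTS}
        object.__setattr__(self, "terms", normalized)

    def terms_for(self, aspect: str) -> frozenset:
        return self.terms.get(aspect, frozenset())


class GeneCatalog:
    """Ordered, id-unique collection of :class:`GeneRecord`."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: tuple[GeneRecord, ...] = tuple(records)
        self._index: dict[str, GeneRecord] = {}
        for rec in self.records:
            if rec.gene_id in self._index:
                raise DataError(f"duplicate gene_id {rec.gene_id!r} in catalog")
            self._index[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._index[gene_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneCatalog) and self.records == other.records

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(r.gene_id for r in self.records)

    @property
    def n_dubious(self) -> int:
        return sum(r.dubious for r in self.records)

    def non_dubious(self) -> tuple[GeneRecord, ...]:
        return tuple(r for r in self.records if not r.dubious)


def _iter_table(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _read_header(path: str | Path, required: tuple[str, ...]) -> tuple[dict[str, int], Iterator]:
    rows = _iter_table(path)
    try:
        lineno, fields = next(rows)
    except StopIteration:
        raise DataError(f"{path}: empty file, header row required") from None
    header = {name: i for i, name in enumerate(fields)}
    missing = [c for c in required if c not in header]
    if missing:
        raise DataError(f"{path}: header missing required columns {missing}")
    return header, rows


def _parse_flag(value: str, path: str | Path, lineno: int, column: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise DataError(f"{path}:{lineno}: column {column!r} must be 0 or 1, got {value!r}")


def _parse_terms(value: str) -> frozenset:
    value = value.strip()
    if not value:
        return frozenset()
    return frozenset(t for t in value.split("|") if t)


def parse_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read ``catalog.tsv`` into a :class:`GeneCatalog`, preserving row order.

    Raises :class:`DataError` naming the offending gene/line on duplicate ids
    or non-integer lengths.
    """
    header, rows = _read_header(path, _CATALOG_COLUMNS)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, fields in rows:
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))
        gene_id = fields[header["gene_id"]]
        if gene_id in seen:
            raise DataError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        raw_len = fields[header["length_aa"]]
        try:
            length = int(raw_len)
        except ValueError:
            raise DataError(
                f"{path}:{lineno}: non-integer length_aa {raw_len!r} for gene {gene_id!r}"
            ) from None
        terms = {
            "process": _parse_terms(fields[header["go_process"]]),
            "function": _parse_terms(fields[header["go_function"]]),
            "component": _parse_terms(fields[header["go_component"]]),
        }
        records.append(
            GeneRecord(
                gene_id=gene_id,
                length_aa=length,
                essential=_parse_flag(fields[header["essential"]], path, lineno, "essential"),
                dubious=_parse_flag(fields[header["dubious"]], path, lineno, "dubious"),
                subtelomeric=_parse_flag(
                    fields[header["subtelomeric"]], path, lineno, "subtelomeric"
                ),
                terms=terms,
            )
        )
    catalog = GeneCatalog(records)
    logger.info("parsed %d genes (%d dubious) from %s", len(catalog), catalog.n_dubious, path)
    return catalog


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for rec in catalog:
            fh.write(
                "\t".join(
                    [
                        rec.gene_id,
                        str(rec.length_aa),
                        str(int(rec.essential)),
                        str(int(rec.dubious)),
                        str(int(rec.subtelomeric)),
                        "|".join(sorted(rec.terms_for("process"))),
                        "|".join(sorted(rec.terms_for("function"))),
                        "|".join(sorted(rec.terms_for("component"))),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# edge table
# ---------------------------------------------------------------------------


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeTable:
    """Canonicalized simple edge list with per-edge source tags.

    Self-pairs and duplicate pairs are removed at parse time and counted in
    the log fields so their handling can be audited.
    """

    edges: list[tuple[str, str, str]] = field(default_factory=list)
    n_duplicates_collapsed: int = 0
    n_self_dropped: int = 0
    n_unknown_dropped: int = 0
    unknown_ids: set = field(default_factory=set)

    def pairs(self) -> set:
        return {(a, b) for a, b, _ in self.edges}

    def __len__(self) -> int:
        return len(self.edges)


def parse_edge_list(
    path: str | Path,
    catalog: GeneCatalog | None = None,
    unknown_policy: str = "drop",
    strict: bool = True,
) -> EdgeTable:
    """Read a two-or-three-column edge TSV into a canonical :class:`EdgeTable`.

    Pairs are lexicographically canonicalized; duplicates collapse to the
    first-seen row (counted); self-pairs are dropped (counted).  Ids absent
    from *catalog* are dropped with a warning or, with
    ``unknown_policy="error"``, raise.
    """
    if unknown_policy not in ("drop", "error"):
        raise ValueError(f"unknown_policy must be 'drop' or 'error', got {unknown_policy!r}")
    header, rows = _read_header(path, ("gene_a", "gene_b"))
    has_source = "source" in header
    table = EdgeTable()
    seen: dict[tuple[str, str], str] = {}
    for lineno, fields in rows:
        if len(fields) < 2:
            if strict:
                raise DataError(f"{path}:{lineno}: expected at least 2 columns")
            continue
        a, b = fields[header["gene_a"]], fields[header["gene_b"]]
        source = "unknown"
        if has_source and len(fields) > header["source"] and fields[header["source"]]:
            source = fields[header["source"]]
            if source not in EDGE_SOURCES:
                raise DataError(f"{path}:{lineno}: unknown source tag {source!r}")
        if catalog is not None:
            absent = [g for g in (a, b) if g not in catalog]
            if absent:
                if unknown_policy == "error":
                    raise DataError(f"{path}:{lineno}: gene id(s) {absent} not in catalog")
                table.unknown_ids.update(absent)
                table.n_unknown_dropped += 1
                continue
        if a == b:
            table.n_self_dropped += 1
            continue
        pair = canonical_pair(a, b)
        if pair in seen:
            table.n_duplicates_collapsed += 1
            continue
        seen[pair] = source
        table.edges.append((pair[0], pair[1], source))
    if table.n_self_dropped or table.n_duplicates_collapsed or table.n_unknown_dropped:
        logger.warning(
            "%s: dropped %d self-pairs, collapsed %d duplicate pairs, "
            "dropped %d edges with unknown ids",
            path,
            table.n_self_dropped,
            table.n_duplicates_collapsed,
            table.n_unknown_dropped,
        )
    return table


def write_edge_list(table: EdgeTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for a, b, source in table.edges:
            fh.write(f"{a}\t{b}\t{source}\n")


# ---------------------------------------------------------------------------
# evolution evidence
# ---------------------------------------------------------------------------

TRACKS = ("A", "B")


@dataclass
class EvolutionEvidence:
    """Evolutionary evidence backing the age/origin classification.

    ``family_map`` maps gene to homologous-family id (genes absent are
    implicit singletons).  ``reconstruction`` lists (ancestor locus, track,
    descendant gene) rows; a locus with descendants on both tracks marks a
    WGD-retained pair.  ``ortholog_profile`` maps gene to a set of
    (species_id, diverged_pre_wgd) occurrences.
    """

    family_map: dict = field(default_factory=dict)
    reconstruction: list = field(default_factory=list)
    ortholog_profile: dict = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvolutionEvidence):
            return NotImplemented
        return (
            self.family_map == other.family_map
            and sorted(self.reconstruction) == sorted(other.reconstruction)
            and self.ortholog_profile == other.ortholog_profile
        )


def parse_evolution_inputs(
    family_path: str | Path,
    reconstruction_path: str | Path,
    ortholog_path: str | Path,
) -> EvolutionEvidence:
    """Read families / reconstruction / orthologs TSVs into one structure.

    Track values outside {A, B} and duplicate (gene, species) ortholog rows
    are hard errors.
    """
    evidence = EvolutionEvidence()

    header, rows = _read_header(family_path, ("gene_id", "family_id"))
    for lineno, fields in rows:
        gene, family = fields[header["gene_id"]], fields[header["family_id"]]
        if gene in evidence.family_map:
            raise DataError(f"{family_path}:{lineno}: gene {gene!r} listed twice")
        evidence.family_map[gene] = family

    header, rows = _read_header(reconstruction_path, ("ancestor_locus", "track", "gene_id"))
    for lineno, fields in rows:
        locus = fields[header["ancestor_locus"]]
        track = fields[header["track"]]
        gene = fields[header["gene_id"]]
        if track not in TRACKS:
            raise DataError(
                f"{reconstruction_path}:{lineno}: track must be one of {TRACKS}, got {track!r}"
            )
        evidence.reconstruction.append((locus, track, gene))

    header, rows = _read_header(ortholog_path, ("gene_id", "species_id", "diverged_pre_wgd"))
    for lineno, fields in rows:
        gene = fields[header["gene_id"]]
        species = fields[header["species_id"]]
        flag = _parse_flag(fields[header["diverged_pre_wgd"]], ortholog_path, lineno,
                           "diverged_pre_wgd")
        profile = evidence.ortholog_profile.setdefault(gene, set())
        if any(sp == species for sp, _ in profile):
            raise DataError(
                f"{ortholog_path}:{lineno}: duplicate ortholog row for ({gene!r}, {species!r})"
            )
        profile.add((species, flag))

    return evidence


def write_evolution_inputs(
    evidence: EvolutionEvidence,
    family_path: str | Path,
    reconstruction_path: str | Path,
    ortholog_path: str | Path,
) -> None:
    with open(family_path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tfamily_id\n")
        for gene, family in evidence.family_map.items():
            fh.write(f"{gene}\t{family}\n")
    with open(reconstruction_path, "w", encoding="utf-8") as fh:
        fh.write("ancestor_locus\ttrack\tgene_id\n")
        for locus, track, gene in evidence.reconstruction:
            fh.write(f"{locus}\t{track}\t{gene}\n")
    with open(ortholog_path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tspecies_id\tdiverged_pre_wgd\n")
        for gene in evidence.ortholog_profile:
            for species, flag in sorted(evidence.ortholog_profile[gene]):
                fh.write(f"{gene}\t{species}\t{int(flag)}\n")


# ---------------------------------------------------------------------------
# classification table
# ---------------------------------------------------------------------------


def write_classification(rows: Iterable[tuple[str, str, str, str]], path: str | Path) -> None:
    """Write (gene_id, age, origin, evidence) rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tage\torigin\tevidence\n")
        for gene, age, origin, evidence in rows:
            fh.write(f"{gene}\t{age}\t{origin}\t{evidence}\n")


def read_classification(path: str | Path) -> dict:
    """Read a classification TSV back into gene -> (age, origin)."""
    header, rows = _read_header(path, ("gene_id", "age", "origin"))
    result: dict[str, tuple[str, str]] = {}
    for lineno, fields in rows:
        gene = fields[header["gene_id"]]
        if gene in result:
            raise DataError(f"{path}:{lineno}: duplicate gene {gene!r}")
        result[gene] = (fields[header["age"]], fields[header["origin"]])
    return result
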