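"""Readers and writers for the pipeline's external formats.

All tabular formats are TSV with a header row. Writers emit canonical,
lexicographically sorted output so that read ∘ write is the identity on
canonicalized content and output files are byte-reproducible.

In-memory containers are deliberately thin: expression matrices are pandas
DataFrames (genes × samples), interaction networks are ``networkx.Graph``
objects, TF→target maps are plain dicts of frozensets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

HRM = "HRM"
LRM = "LRM"

#: canonical variant classes
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice_site",
    "synonymous",
    "unknown",
    "other",
)

REGIONS = ("exon", "splice_site", "other")

# MAF-style aliases accepted on input; canonical token on the left.
_CLASS_ALIASES = {
    "missense": "missense",
    "missense_mutation": "missense",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "frameshift_indel": "frameshift_indel",
    "frame_shift_del": "frameshift_indel",
    "frame_shift_ins": "frameshift_indel",
    "frameshift": "frameshift_indel",
    "inframe_indel": "inframe_indel",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "splice_site": "splice_site",
    "synonymous": "synonymous",
    "silent": "synonymous",
    "unknown": "unknown",
    "other": "other",
}

_REGION_ALIASES = {
    "exon": "exon",
    "exonic": "exon",
    "splice_site": "splice_site",
    "splicing": "splice_site",
    "other": "other",
}

_COLUMN_ALIASES = {
    "sample": "sample",
    "tumor_sample_barcode": "sample",
    "sample_id": "sample",
    "gene": "gene",
    "hugo_symbol": "gene",
    "protein_change": "protein_change",
    "hgvsp_short": "protein_change",
    "class": "class",
    "variant_classification": "class",
    "region": "region",
    "af": "af",
    "population_af": "af",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class VariantRecord:
    """A single somatic variant call.

    Mutation identity throughout the pipeline is the pair
    ``(gene, protein_change)``: the position and type of the alteration
    matter, not just the gene symbol.
    """

    sample_id: str
    gene: str
    protein_change: str
    variant_class: str = "unknown"
    region: str = "exon"
    population_af: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        """Mutation identity key ``(gene, protein_change)``."""
        return (self.gene, self.protein_change)


class CohortLabels:
    """Mapping sample_id → group, where group is ``"HRM"`` or ``"LRM"``."""

    def __init__(self, mapping: Mapping[str, str]):
        mapping = dict(mapping)
        bad = {g for g in mapping.values() if g not in (HRM, LRM)}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not any(g == HRM for g in mapping.values()) or not any(
            g == LRM for g in mapping.values()
        ):
            raise ValueError("both HRM and LRM groups must be nonempty")
        self._map = mapping

    def __getitem__(self, sample: str) -> str:
        return self._map[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CohortLabels) and self._map == other._map

    @property
    def samples(self) -> list[str]:
        return sorted(self._map)

    def group(self, name: str) -> list[str]:
        """Sorted sample ids belonging to group *name*."""
        return sorted(s for s, g in self._map.items() if g == name)

    def as_dict(self) -> dict[str, str]:
        return dict(self._map)


def _canonical_header(fieldnames: Iterable[str]) -> dict[str, str]:
    mapping = {}
    for name in fieldnames:
        canon = _COLUMN_ALIASES.get(name.strip().lower())
        if canon is not None:
            mapping[canon] = name
    return mapping


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV (columns sample, gene, protein_change, class, region, af).

    MAF-compatible column aliases are accepted. Unrecognized class or region
    tokens map to ``other`` and are logged, never dropped.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("%s: empty variant file", path)
            return []
        header = _canonical_header(reader.fieldnames)
        for col in ("sample", "gene", "protein_change", "class", "region", "af"):
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        records = []
        for row in reader:
            cls_token = (row[header["class"]] or "").strip().lower()
            cls = _CLASS_ALIASES.get(cls_token)
            if cls is None:
                logger.warning("%s: unknown variant class %r mapped to 'other'", path, cls_token)
                cls = "other"
            region_token = (row[header["region"]] or "").strip().lower()
            region = _REGION_ALIASES.get(region_token)
            if region is None:
                logger.warning("%s: unknown region %r mapped to 'other'", path, region_token)
                region = "other"
            af_token = (row[header["af"]] or "").strip()
            af = float(af_token) if af_token not in ("", "NA", ".") else None
            records.append(
                VariantRecord(
                    sample_id=row[header["sample"]].strip(),
                    gene=row[header["gene"]].strip(),
                    protein_change=row[header["protein_change"]].strip(),
                    variant_class=cls,
                    region=region,
                    population_af=af,
                )
            )
    if not records:
        logger.warning("%s: variant file contains a header but no rows", path)
    return records


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "gene", "protein_change", "class", "region", "af"])
        for r in records:
            af = "" if r.population_af is None else repr(r.population_af)
            writer.writerow(
                [r.sample_id, r.gene, r.protein_change, r.variant_class, r.region, af]
            )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples FPKM matrix (first column = gene symbol)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene row {dup!r}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample column")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative FPKM value")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr = expr.sort_index(axis=0).sort_index(axis=1)
    expr.index.name = "gene"
    expr.to_csv(Path(path), sep="\t", lineterminator="\n")


def read_labels(path: str | Path) -> CohortLabels:
    """Read a labels TSV with columns sample, group."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for col in ("sample", "group"):
        if col not in cols:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df[cols["sample"]].duplicated().any():
        raise FormatError(f"{path}: duplicate sample in labels")
    return CohortLabels(dict(zip(df[cols["sample"]], df[cols["group"]])))


def write_labels(labels: CohortLabels, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "group"])
        for s in labels.samples:
            writer.writerow([s, labels[s]])


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected edge list (geneA, geneB[, weight]).

    Reversed duplicates collapse to a single undirected edge; self-loops are
    skipped with a warning.
    """
    path = Path(path)
    graph = nx.Graph()
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            return graph
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 fields")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                logger.warning("%s:%d: self-loop %s skipped", path, lineno, a)
                continue
            attrs = {}
            if len(fields) >= 3 and fields[2].strip():
                attrs["weight"] = float(fields[2])
            graph.add_edge(a, b, **attrs)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["geneA", "geneB", "weight"])
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            w = graph.edges[a, b].get("weight")
            writer.writerow([a, b, "" if w is None else repr(w)])


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read TF → target-gene sets from a GMT file (name, description, genes...)."""
    path = Path(path)
    tfmap: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0].strip()
            if name in tfmap:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            targets = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not targets:
                raise FormatError(f"{path}:{lineno}: empty target set for {name!r}")
            tfmap[name] = targets
    return tfmap


def write_gmt(tfmap: Mapping[str, frozenset[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(tfmap):
            targets = "\t".join(sorted(tfmap[name]))
            fh.write(f"{name}\tna\t{targets}\n")
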