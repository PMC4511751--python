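"""Alignment and population-map containers plus file I/O.

The pipeline works on phased haplotype alignments (FASTA) together with a
tab-separated map assigning each chromosome (haplotype sequence) to a local
population.  Result tables are written as TSV with a JSON manifest recording
run parameters, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGT-N")

#: per-column classification labels
INVARIANT = "invariant"
SUBSTITUTION = "substitution"
INDEL = "indel"
MISSING = "missing"


class AlignmentError(ValueError):
    """Malformed alignment (unequal lengths, bad characters, empty input)."""


class PopulationMapError(ValueError):
    """Malformed population map (unknown or duplicate chromosome ids)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned haplotype: an id and a gapped sequence over {A,C,G,T,-,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("sequence record with empty id")
        if not self.sequence:
            raise AlignmentError(f"record {self.id!r} has an empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_CHARS
        if bad:
            raise AlignmentError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


def classify_column(column: str) -> str:
    """Classify one alignment column as invariant/substitution/indel/missing.

    A column containing any gap is an indel column; an 'N' column (and no gap)
    is missing and is excluded from site counting downstream.
    """
    if "-" in column:
        return INDEL
    if "N" in column:
        return MISSING
    return SUBSTITUTION if len(set(column)) > 1 else INVARIANT


@dataclass
class HaplotypeAlignment:
    """Equal-length haplotype sequences with per-column site classes.

    Parameters
    ----------
    records:
        Ordered aligned sequences; ids must be unique.
    anchors:
        Optional 1-based genomic coordinate for each alignment column
        (e.g. rheMac2 chr3 positions), used only for labelling.
    """

    records: list[SequenceRecord]
    anchors: list[int] | None = None
    site_classes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment with no records")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record ids: {dup}")
        length = len(self.records[0].sequence)
        for r in self.records[1:]:
            if len(r.sequence) != length:
                raise AlignmentError(
                    f"record {r.id!r} has length {len(r.sequence)}, "
                    f"expected {length}"
                )
        if self.anchors is not None and len(self.anchors) != length:
            raise AlignmentError("anchors length does not match alignment length")
        self.site_classes = [classify_column(col) for col in zip(*(r.sequence for r in self.records))]

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequence(self, record_id: str) -> str:
        for r in self.records:
            if r.id == record_id:
                return r.sequence
        raise KeyError(record_id)

    def subset(self, ids: Iterable[str]) -> "HaplotypeAlignment":
        """Alignment restricted to the given chromosome ids (order preserved)."""
        wanted = list(ids)
        missing = set(wanted) - set(self.ids)
        if missing:
            raise KeyError(f"unknown chromosome ids: {sorted(missing)}")
        by_id = {r.id: r for r in self.records}
        return HaplotypeAlignment([by_id[i] for i in wanted], anchors=self.anchors)

    def column(self, index: int) -> str:
        """0-based column as a string over records."""
        return "".join(r.sequence[index] for r in self.records)


@dataclass
class PopulationMap:
    """Assignment of chromosome ids to population labels (file order kept)."""

    assignments: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.assignments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PopulationMapError(f"duplicate chromosome ids: {dup}")
        if not self.populations:
            raise PopulationMapError("population map with no populations")

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for _, pop in self.assignments:
            if pop not in seen:
                seen.append(pop)
        return seen

    def chromosomes(self, population: str) -> list[str]:
        ids = [c for c, p in self.assignments if p == population]
        if not ids:
            raise KeyError(f"unknown population {population!r}")
        return ids

    def population_of(self, chromosome_id: str) -> str:
        for c, p in self.assignments:
            if c == chromosome_id:
                return p
        raise KeyError(chromosome_id)

    def __len__(self) -> int:
        return len(self.assignments)


def read_fasta_alignment(path: str | Path, anchors: Sequence[int] | None = None) -> HaplotypeAlignment:
    """Read an aligned FASTA file into a :class:`HaplotypeAlignment`.

    Lowercase input is uppercased; characters outside {A,C,G,T,-,N} are
    rejected.  Unequal record lengths raise :class:`AlignmentError` naming the
    offending record; an empty file raises :class:`AlignmentError`.
    """
    path = Path(path)
    records = [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return HaplotypeAlignment(records, anchors=list(anchors) if anchors is not None else None)


def write_fasta_alignment(alignment: HaplotypeAlignment, path: str | Path) -> Path:
    """Write the alignment back out as FASTA (round-trips exactly)."""
    path = Path(path)
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in alignment.records]
    SeqIO.write(bio, str(path), "fasta-2line")
    return path


def read_population_map(path: str | Path, alignment: HaplotypeAlignment) -> PopulationMap:
    """Read a TSV (header ``chromosome_id<TAB>population``) and validate it.

    Every chromosome id must match a record in the companion alignment.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chromosome_id", "population"}
    if not required.issubset(df.columns):
        raise PopulationMapError(
            f"population map must have columns {sorted(required)}, got {list(df.columns)}"
        )
    known = set(alignment.ids)
    unknown = [c for c in df["chromosome_id"] if c not in known]
    if unknown:
        raise PopulationMapError(
            f"population map references unknown chromosome ids: {sorted(set(unknown))}"
        )
    return PopulationMap(list(zip(df["chromosome_id"], df["population"])))


def write_population_map(pop_map: PopulationMap, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(pop_map.assignments, columns=["chromosome_id", "population"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_summary(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    *,
    parameters: Mapping[str, object] | None = None,
    seed: int | None = None,
    networks: Mapping[str, nx.Graph] | None = None,
) -> list[Path]:
    """Write result tables (TSV), optional networks (GraphML) and a manifest.

    The manifest always records the RNG seed and the parameters used, so the
    same seed reproduces byte-identical TSV outputs.  Returns the list of
    written files (manifest last).
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not tables and not networks:
        warnings.warn("write_summary called with no tables; writing manifest only")
    for name, df in tables.items():
        dest = outdir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False)
        written.append(dest)
    for name, graph in (networks or {}).items():
        dest = outdir / f"{name}.graphml"
        safe = _stringify_attrs(graph)
        nx.write_graphml(safe, str(dest))
        written.append(dest)
    manifest = {
        "seed": seed,
        "parameters": dict(parameters or {}),
        "tables": sorted(t.name for t in written if t.suffix == ".tsv"),
        "networks": sorted(t.name for t in written if t.suffix == ".graphml"),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def _stringify_attrs(graph: nx.Graph) -> nx.Graph:
    """Copy with list/tuple attributes serialized for GraphML."""
    g = graph.copy()
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (list, tuple, set)):
                data[k] = ",".join(str(x) for x in v)
    for _, _, data in g.edges(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (list, tuple, set)):
                data[k] = ",".join(str(x) for x in v)
    return g
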