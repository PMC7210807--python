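"""Tabular I/O: genotype and frequency CSVs, GenePop export, packaged fixtures.

CSV dialects are UTF-8 and comma-separated; screening annotation/call tables
are tab-separated (see :mod:`strpanel.screening`).  Lines starting with ``#``
are comments.  All numeric output uses period decimal separators regardless of
locale, so golden files are bit-stable.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .genotypes import (
    AlleleName,
    FrequencyTable,
    Genotype,
    Individual,
    Locus,
    Population,
    StrPanelError,
)

PathLike = Union[str, Path]

#: Panel order of the packaged reference fixture (report rows follow it).
REFERENCE_PANEL_ORDER = [
    "DA3S1123", "DA2S1059", "DB1S1259", "DD3S86", "DE1S613", "DF1S579",
    "DA2S1575", "DF2S497", "DA3S1145", "DD2S793", "DD4S705", "DB1S542",
    "DA1S1290", "DA1S1470", "DC1S1364",
]


class CsvFormatError(StrPanelError):
    """Malformed tabular input, with the offending line number."""


def _rows(path: PathLike, delimiter: str = ",") -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            yield lineno, [cell.strip() for cell in row]


def read_genotypes_csv(path: PathLike) -> Population:
    """Read a genotype table (columns ``id,locus,allele1,allele2``).

    Empty allele cells mean the individual is untyped at that locus.
    """
    individuals: dict[str, Individual] = {}
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen:
            if [c.lower() for c in row[:4]] != ["id", "locus", "allele1", "allele2"]:
                raise CsvFormatError(
                    f"{path}:{lineno}: expected header id,locus,allele1,allele2"
                )
            header_seen = True
            continue
        if len(row) < 4:
            raise CsvFormatError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
        ind_id, locus, a1, a2 = row[:4]
        ind = individuals.setdefault(ind_id, Individual(ind_id))
        if not a1 and not a2:
            continue  # explicit missing call
        if bool(a1) != bool(a2):
            raise CsvFormatError(f"{path}:{lineno}: half-missing genotype for {ind_id}")
        try:
            g = Genotype(locus, AlleleName.parse(a1), AlleleName.parse(a2))
        except ValueError as exc:
            raise CsvFormatError(f"{path}:{lineno}: {exc}") from exc
        ind.set_genotype(g)
    return Population(list(individuals.values()))


def write_genotypes_csv(
    population: Population, path: PathLike, loci: Optional[list[str]] = None
) -> None:
    locus_names = loci if loci is not None else population.locus_names()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "locus", "allele1", "allele2"])
        for ind in population.individuals:
            for name in locus_names:
                g = ind.genotypes.get(name)
                if g is None:
                    w.writerow([ind.id, name, "", ""])
                else:
                    w.writerow([ind.id, name, str(g.a1), str(g.a2)])


def read_frequency_csv(
    path: PathLike, loci: Optional[Mapping[str, Locus]] = None
) -> dict[str, FrequencyTable]:
    """Read per-locus allele frequencies (``locus,allele,frequency`` with an
    optional ``count`` column).

    When integer counts are present the table is rebuilt from them, so the
    frequencies are exact rather than the rounded published values.  ``loci``
    supplies marker metadata; unknown loci get a metadata-free :class:`Locus`.
    """
    freqs: dict[str, dict[AlleleName, float]] = {}
    counts: dict[str, dict[AlleleName, int]] = {}
    header: Optional[list[str]] = None
    for lineno, row in _rows(path):
        if header is None:
            header = [c.lower() for c in row]
            if header[:2] != ["locus", "allele"] or "frequency" not in header:
                raise CsvFormatError(f"{path}:{lineno}: expected locus,allele[,count],frequency")
            continue
        rec = dict(zip(header, row))
        try:
            allele = AlleleName.parse(rec["allele"])
            freqs.setdefault(rec["locus"], {})[allele] = float(rec["frequency"])
            if rec.get("count"):
                counts.setdefault(rec["locus"], {})[allele] = int(rec["count"])
        except (KeyError, ValueError) as exc:
            raise CsvFormatError(f"{path}:{lineno}: {exc}") from exc
    tables: dict[str, FrequencyTable] = {}
    for name, fmap in freqs.items():
        locus = loci[name] if loci and name in loci else Locus(name)
        if name in counts and len(counts[name]) == len(fmap):
            tables[name] = FrequencyTable.from_counts(locus, counts[name])
        else:
            tables[name] = FrequencyTable(locus, dict(sorted(fmap.items())))
    return tables


def write_frequency_csv(tables: Iterable[FrequencyTable], path: PathLike) -> None:
    tables = list(tables)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        has_counts = all(t.counts is not None for t in tables)
        w.writerow(["locus", "allele", "count", "frequency"] if has_counts
                   else ["locus", "allele", "frequency"])
        for t in tables:
            for a in t.alleles:
                if has_counts:
                    w.writerow([t.locus.name, str(a), t.counts[a], f"{t.freqs[a]:.6f}"])
                else:
                    w.writerow([t.locus.name, str(a), f"{t.freqs[a]:.6f}"])


def genepop_code(allele: AlleleName) -> str:
    """Three-digit GenePop allele code: ``repeats * 10 + microvariant``.

    Invertible for repeat counts below 100, which covers tetra/penta STR
    panels; e.g. allele ``22.3`` encodes as ``223``.
    """
    code = allele.repeats * 10 + allele.microvariant
    if code > 999:
        raise ValueError(f"allele {allele} does not fit a 3-digit GenePop code")
    return f"{code:03d}"


def write_genepop(
    population: Population,
    path: PathLike,
    loci: Optional[list[str]] = None,
    title: str = "strpanel export",
) -> None:
    """Write a GenePop-format snapshot for cross-checking with external tools.

    Missing genotypes are encoded as ``000000`` per GenePop convention.
    """
    locus_names = loci if loci is not None else population.locus_names()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for name in locus_names:
            fh.write(name + "\n")
        fh.write("Pop\n")
        for ind in population.individuals:
            cells = []
            for name in locus_names:
                g = ind.genotypes.get(name)
                cells.append("000000" if g is None
                             else genepop_code(g.a1) + genepop_code(g.a2))
            fh.write(f"{ind.id} , " + " ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference fixture (15-locus captive tiger panel, n = 31)

def _data_path(name: str):
    return resources.files("strpanel.data").joinpath(name)


def load_reference_loci() -> dict[str, Locus]:
    """Marker metadata for the packaged 15-locus reference panel."""
    loci: dict[str, Locus] = {}
    with resources.as_file(_data_path("reference_loci.csv")) as p:
        header = None
        for _, row in _rows(p):
            if header is None:
                header = row
                continue
            rec = dict(zip(header, row))
            loci[rec["name"]] = Locus(
                rec["name"],
                motif=rec["motif"],
                chromosome_label=rec["scaffold"],
                size_range=(int(rec["size_min"]), int(rec["size_max"])),
            )
    return loci


def load_reference_frequencies() -> dict[str, FrequencyTable]:
    """Allele-frequency tables of the reference captive tiger population.

    Tables are backed by the integer chromosome counts (out of 62), so derived
    statistics reproduce the published panel characterization exactly; the
    rounded 4-decimal frequencies are what the count/62 ratios print as.
    """
    loci = load_reference_loci()
    with resources.as_file(_data_path("reference_frequencies.csv")) as p:
        return read_frequency_csv(p, loci=loci)


def reference_panel_tables() -> list[FrequencyTable]:
    tables = load_reference_frequencies()
    return [tables[name] for name in REFERENCE_PANEL_ORDER]
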