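"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA reference amplicons (record id = marker name with optional
``|species`` suffix), a tab-separated primer table, a sample sheet, and
diploid genotype tables in either a "long" dialect (one row per
individual x locus) or a STRUCTURE-like dialect (two rows per individual,
one column per locus).  Missing genotypes are coded -9 (blanks accepted on
read).  All writers emit a '#'-prefixed header line carrying the format
version; emitted coordinates are 1-based inclusive.
"""
from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .types import MISSING, GenotypeDataset, PopulationDistance, PrimerPair, _check_dna

FORMAT_VERSION = "orthosat/1"

_MOD_FLAGS = {"none": 0, "P": 7, "M": 1}


def _open_rows(path):
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or (row[0].startswith("#")):
                continue
            yield row


def read_primer_table(path) -> list[PrimerPair]:
    """Read a TSV primer table.

    Columns: marker, forward, reverse, mod_flag, mod_primer, merge_offset.
    ``mod_flag`` is ``none``, ``P`` (7-bp pig-tail) or ``M`` (single extra
    adenine); ``mod_primer`` says which primer carries it (``forward`` /
    ``reverse``; ignored when flag is ``none``).
    """
    rows = iter(_open_rows(path))
    try:
        header = next(rows)
    except StopIteration:
        raise ValueError(f"empty primer table: {path}")
    cols = {name: i for i, name in enumerate(header)}
    required = {"marker", "forward", "reverse", "mod_flag", "mod_primer", "merge_offset"}
    if not required <= set(cols):
        raise ValueError(f"primer table missing columns: {sorted(required - set(cols))}")
    pairs, seen = [], set()
    for row in rows:
        marker = row[cols["marker"]]
        if marker in seen:
            raise ValueError(f"duplicate marker in primer table: {marker}")
        seen.add(marker)
        flag = row[cols["mod_flag"]]
        if flag not in _MOD_FLAGS:
            raise ValueError(f"{marker}: unknown modification flag {flag!r}")
        extra = _MOD_FLAGS[flag]
        which = row[cols["mod_primer"]].strip().lower()
        fwd_extra = extra if (extra and which == "forward") else 0
        rev_extra = extra if (extra and which == "reverse") else 0
        if extra and which not in ("forward", "reverse"):
            raise ValueError(f"{marker}: mod_primer must be forward or reverse when flagged")
        pairs.append(PrimerPair(
            marker_name=marker,
            forward=row[cols["forward"]],
            reverse=row[cols["reverse"]],
            forward_extra_bp=fwd_extra,
            reverse_extra_bp=rev_extra,
            merge_offset=int(row[cols["merge_offset"]] or 0),
        ))
    return pairs


def write_primer_table(pairs: list[PrimerPair], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} primer table\n")
        fh.write("marker\tforward\treverse\tmod_flag\tmod_primer\tmerge_offset\n")
        for p in pairs:
            if p.forward_extra_bp:
                flag = "P" if p.forward_extra_bp == 7 else "M"
                which = "forward"
            elif p.reverse_extra_bp:
                flag = "P" if p.reverse_extra_bp == 7 else "M"
                which = "reverse"
            else:
                flag, which = "none", "none"
            fh.write(f"{p.marker_name}\t{p.forward}\t{p.reverse}\t{flag}\t{which}\t{p.merge_offset}\n")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {record id: upper-cased ACGT sequence}.

    Record ids may carry an optional ``|species`` suffix which is preserved
    in the key (use :func:`split_fasta_id` to separate it).
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = _check_dna(str(rec.seq), f"FASTA record {rec.id}")
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    return records


def split_fasta_id(record_id: str) -> tuple[str, str | None]:
    """Split ``marker|species`` record ids; species is None when absent."""
    if "|" in record_id:
        marker, species = record_id.split("|", 1)
        return marker, species
    return record_id, None


def read_samples(path):
    """Read the sample sheet: individual, population, species[, distance_km].

    Returns (individuals, populations, species, distances) where distances is
    a dict population -> PopulationDistance (empty if no distance column).
    """
    rows = iter(_open_rows(path))
    header = next(rows)
    cols = {name: i for i, name in enumerate(header)}
    for c in ("individual", "population", "species"):
        if c not in cols:
            raise ValueError(f"sample sheet missing column {c!r}")
    inds, pops, specs, distances = [], [], [], {}
    for row in rows:
        inds.append(row[cols["individual"]])
        pops.append(row[cols["population"]])
        specs.append(row[cols["species"]])
        if "distance_km" in cols and row[cols["distance_km"]] != "":
            distances[row[cols["population"]]] = PopulationDistance(
                row[cols["population"]], float(row[cols["distance_km"]]))
    return inds, pops, specs, distances


def _parse_allele(token: str) -> float:
    token = token.strip()
    if token == "" or float(token) == MISSING:
        return math.nan
    v = float(token)
    if v <= 0:
        raise ValueError(f"allele value must be positive or the missing code: {token}")
    return v


def read_genotypes(path, samples_path, dialect: str = "long",
                   representation: str = "length") -> GenotypeDataset:
    """Read a genotype TSV plus its companion sample sheet.

    dialect "long": header ``individual population locus allele1 allele2``,
    one row per individual x locus.  dialect "structure-like": header
    ``individual`` + one column per locus; two rows per individual (one per
    allele copy).
    """
    inds, pops, specs, _ = read_samples(samples_path)
    ind_index = {ind: i for i, ind in enumerate(inds)}
    if len(ind_index) != len(inds):
        raise ValueError("duplicate individual ids in sample sheet")

    if dialect == "long":
        rows = iter(_open_rows(path))
        header = next(rows)
        cols = {name: i for i, name in enumerate(header)}
        loci, loci_index = [], {}
        cells = {}
        for row in rows:
            ind = row[cols["individual"]]
            locus = row[cols["locus"]]
            if locus not in loci_index:
                loci_index[locus] = len(loci)
                loci.append(locus)
            a1 = _parse_allele(row[cols["allele1"]])
            a2 = _parse_allele(row[cols["allele2"]])
            cells[(ind_index[ind], loci_index[locus])] = (a1, a2)
        alleles = np.full((len(inds), len(loci), 2), np.nan)
        for (i, j), (a1, a2) in cells.items():
            alleles[i, j] = (a1, a2)
    elif dialect == "structure-like":
        rows = list(_open_rows(path))
        header, body = rows[0], rows[1:]
        loci = header[1:]
        if len(body) % 2 != 0:
            raise ValueError("structure-like dialect requires an even number of data rows")
        alleles = np.full((len(inds), len(loci), 2), np.nan)
        for k in range(0, len(body), 2):
            r1, r2 = body[k], body[k + 1]
            if r1[0] != r2[0]:
                raise ValueError(f"allele rows for {r1[0]} and {r2[0]} are not paired")
            i = ind_index[r1[0]]
            for j in range(len(loci)):
                alleles[i, j] = (_parse_allele(r1[1 + j]), _parse_allele(r2[1 + j]))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    return GenotypeDataset(inds, pops, specs, loci, alleles, representation)


def write_genotypes(dataset: GenotypeDataset, path, dialect: str = "long") -> None:
    def fmt(v: float) -> str:
        if math.isnan(v):
            return str(MISSING)
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} genotypes representation={dataset.representation} "
                 f"dialect={dialect}\n")
        if dialect == "long":
            fh.write("individual\tpopulation\tlocus\tallele1\tallele2\n")
            for i, ind in enumerate(dataset.individuals):
                for j, locus in enumerate(dataset.loci):
                    a1, a2 = dataset.alleles[i, j]
                    fh.write(f"{ind}\t{dataset.populations[i]}\t{locus}\t{fmt(a1)}\t{fmt(a2)}\n")
        elif dialect == "structure-like":
            fh.write("individual\t" + "\t".join(dataset.loci) + "\n")
            for i, ind in enumerate(dataset.individuals):
                for copy in range(2):
                    vals = "\t".join(fmt(dataset.alleles[i, j, copy])
                                     for j in range(dataset.n_loci))
                    fh.write(f"{ind}\t{vals}\n")
        else:
            raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_samples(dataset: GenotypeDataset, path, distances=None) -> None:
    distances = distances or {}
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION} sample sheet\n")
        fh.write("individual\tpopulation\tspecies\tdistance_km\n")
        for ind, pop, sp in zip(dataset.individuals, dataset.populations, dataset.species):
            d = distances.get(pop)
            fh.write(f"{ind}\t{pop}\t{sp}\t{'' if d is None else d.distance_km}\n")


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
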