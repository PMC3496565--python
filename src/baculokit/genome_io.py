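"""Genome and feature I/O with circular-coordinate arithmetic.

Coordinates throughout the package are 1-based inclusive (GenBank
convention).  A feature on a circular genome may wrap the origin, in
which case ``start > end`` and the span runs start..length,1..end.
BED output converts to 0-based half-open on emission.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Genome",
    "FeatureInterval",
    "Feature",
    "GenomeFormatError",
    "TopologyError",
    "read_fasta",
    "write_fasta",
    "at_fraction",
    "subsequence",
    "translate",
    "reverse_complement",
    "write_outputs",
    "read_gff3",
]

# IUPAC nucleotide one-letter codes (upper case)
_IUPAC_NT = set("ACGTNRYSWKMBDHV")


class GenomeFormatError(ValueError):
    """Raised for malformed sequence input (bad alphabet, empty file)."""


class TopologyError(ValueError):
    """Raised when a circular operation is requested on a linear genome."""


@dataclass(frozen=True)
class FeatureInterval:
    """A 1-based inclusive interval on a genome, optionally wrapping the origin.

    ``start > end`` denotes a feature that wraps the origin of a circular
    genome (spanning start..L then 1..end).
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"interval positions must be >= 1, got {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def span(self, genome_length: int | None = None) -> int:
        """Length in bp; wrapping intervals need the genome length."""
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome_length required for a wrapping interval")
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int | None = None) -> range | list[int]:
        """All genome positions covered (1-based), in clockwise order."""
        if not self.wraps_origin:
            return range(self.start, self.end + 1)
        if genome_length is None:
            raise ValueError("genome_length required for a wrapping interval")
        return list(range(self.start, genome_length + 1)) + list(
            range(1, self.end + 1)
        )


@dataclass
class Genome:
    """A nucleotide sequence with topology.

    The sequence is upper-cased on construction.  ``topology`` is either
    ``"circular"`` or ``"linear"``; circular genomes admit features and
    windows that wrap the origin.
    """

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        for i, c in enumerate(self.sequence):
            if c not in _IUPAC_NT:
                raise GenomeFormatError(
                    f"non-IUPAC nucleotide {c!r} at position {i + 1} in {self.id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass
class Feature:
    """A typed, attributed interval — the unit GFF3/BED emission works on."""

    id: str
    interval: FeatureInterval
    type: str = "misc_feature"
    attributes: dict = field(default_factory=dict)


def read_fasta(path: str | Path, record_id: str | None = None,
               topology: str = "circular") -> Genome:
    """Read one genome record from a (possibly multi-record) FASTA file.

    When the file holds several records, ``record_id`` selects one;
    otherwise the single record is returned.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeFormatError(f"no FASTA records in {path}")
    if record_id is None:
        if len(records) > 1:
            raise GenomeFormatError(
                f"{path} holds {len(records)} records; pass record_id"
            )
        rec = records[0]
    else:
        by_id = {r.id: r for r in records}
        if record_id not in by_id:
            raise GenomeFormatError(f"record {record_id!r} not in {path}")
        rec = by_id[record_id]
    return Genome(id=rec.id, sequence=str(rec.seq), topology=topology)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        s = genome.sequence
        for i in range(0, len(s), width):
            fh.write(s[i : i + width] + "\n")
    return path


def at_fraction(genome: Genome | str) -> float:
    """(#A + #T) / (#A + #C + #G + #T); ambiguity codes excluded from both."""
    s = genome.sequence if isinstance(genome, Genome) else genome.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise GenomeFormatError("AT content undefined: no unambiguous bases")
    return (a + t) / denom


def reverse_complement(s: str) -> str:
    return str(Seq(s).reverse_complement())


def subsequence(genome: Genome, interval: FeatureInterval) -> str:
    """Strand-oriented sequence of an interval; wraps allowed on circles only."""
    if interval.wraps_origin and not genome.is_circular:
        raise TopologyError(
            f"interval {interval.start}-{interval.end} wraps the origin of "
            f"linear genome {genome.id!r}"
        )
    L = genome.length
    if interval.start > L or interval.end > L:
        raise ValueError(f"interval {interval} outside genome of length {L}")
    if interval.wraps_origin:
        s = genome.sequence[interval.start - 1 :] + genome.sequence[: interval.end]
    else:
        s = genome.sequence[interval.start - 1 : interval.end]
    if interval.strand == "-":
        s = reverse_complement(s)
    return s


def translate(cds: str, strict: bool = True) -> str:
    """Translate a CDS with the standard code, stopping at the first stop.

    The terminal stop is not part of the returned protein.  In strict
    mode an internal (premature) stop raises instead of truncating
    silently.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    first_stop = aa.find("*")
    if first_stop == -1:
        return aa
    if strict and first_stop != len(aa) - 1:
        raise ValueError(
            f"internal stop codon at amino-acid position {first_stop + 1}"
        )
    return aa[:first_stop]


# ---------------------------------------------------------------------------
# feature table output
# ---------------------------------------------------------------------------

def _split_wrap(feat: Feature, genome_length: int) -> list[FeatureInterval]:
    iv = feat.interval
    if not iv.wraps_origin:
        return [iv]
    return [
        FeatureInterval(iv.start, genome_length, iv.strand),
        FeatureInterval(1, iv.end, iv.strand),
    ]


def write_outputs(features: Sequence[Feature], genome: Genome,
                  path: str | Path, kind: str = "gff3",
                  source: str = "baculokit") -> Path:
    """Write features as GFF3, BED or TSV.

    GFF3 is 1-based inclusive; BED is 0-based half-open.  Features that
    wrap the circular origin are split into two parts sharing the same
    ``ID`` attribute (GFF3) or name (BED) so the record round-trips.
    """
    path = Path(path)
    L = genome.length
    for f in features:
        if f.interval.start > L or f.interval.end > L:
            raise ValueError(f"feature {f.id} outside genome of length {L}")
    if kind == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.id} 1 {L}\n")
            for f in features:
                parts = _split_wrap(f, L)
                attrs = ";".join(
                    [f"ID={f.id}"]
                    + [f"{k}={v}" for k, v in sorted(f.attributes.items())]
                )
                for p in parts:
                    fh.write(
                        "\t".join(
                            [genome.id, source, f.type, str(p.start),
                             str(p.end), ".", p.strand, ".", attrs]
                        )
                        + "\n"
                    )
    elif kind == "bed":
        with open(path, "w") as fh:
            for f in features:
                for p in _split_wrap(f, L):
                    fh.write(
                        f"{genome.id}\t{p.start - 1}\t{p.end}\t{f.id}\t0\t{p.strand}\n"
                    )
    elif kind == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id", "type", "start", "end", "strand", "wraps_origin",
                        "attributes"])
            for f in features:
                iv = f.interval
                w.writerow([f.id, f.type, iv.start, iv.end, iv.strand,
                            int(iv.wraps_origin),
                            ";".join(f"{k}={v}" for k, v in sorted(f.attributes.items()))])
    else:
        raise ValueError(f"unknown output kind {kind!r}")
    return path


def read_gff3(path: str | Path, genome_length: int | None = None) -> list[Feature]:
    """Read GFF3 features, reassembling origin-wrapping parts by shared ID.

    Two parts with the same ID where one ends at ``genome_length`` and the
    other starts at 1 are merged back into a single wrapping feature.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, int, str, str, dict]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"bad GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, _, attr_s = cols
            attrs = {}
            for kv in attr_s.split(";"):
                if kv and "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            fid = attrs.pop("ID", f"feat{len(order) + 1}")
            if fid not in raw:
                order.append(fid)
                raw[fid] = []
            raw[fid].append((int(start), int(end), strand, ftype, attrs))
    out: list[Feature] = []
    for fid in order:
        parts = raw[fid]
        if len(parts) == 1:
            s, e, strand, ftype, attrs = parts[0]
            out.append(Feature(fid, FeatureInterval(s, e, strand), ftype, attrs))
        elif len(parts) == 2 and genome_length is not None:
            parts = sorted(parts)
            (s1, e1, strand, ftype, attrs), (s2, e2, _, _, _) = parts
            if s1 == 1 and e2 == genome_length:
                out.append(
                    Feature(fid, FeatureInterval(s2, e1, strand), ftype, attrs)
                )
            else:
                raise GenomeFormatError(
                    f"feature {fid} has 2 parts that do not wrap the origin"
                )
        else:
            raise GenomeFormatError(f"feature {fid} has {len(parts)} parts")
    return out
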