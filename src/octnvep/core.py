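"""Domain types for protein sequences, membrane topology and missense variants.

Coordinates are 1-based throughout; topology regions are closed intervals
``[start, end]``, matching the convention of protein variant nomenclature
(p.V216L refers to residue 216 of the mature sequence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .chemistry import CANONICAL_AA

REGION_CLASSES = ("N-term", "TM", "EL", "IL", "C-term")

_HGVS_P_RE = re.compile(r"^p\.([A-Za-z])(\d+)([A-Za-z])$")


class HgvsParseError(ValueError):
    """Label does not match the one-letter p.<Ref><Pos><Alt> short form."""


class SynonymousVariantError(ValueError):
    """Reference and alternate residues are identical."""


class AlphabetError(ValueError):
    """Residue code outside the 20 canonical amino acids."""


class ReferenceMismatchError(ValueError):
    """Variant reference residue disagrees with the bound sequence."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based residue addressing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues) - set(CANONICAL_AA)
        if bad:
            raise AlphabetError(
                f"non-canonical residue code(s) {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self):
            raise IndexError(f"position {pos} outside 1..{len(self)}")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class Region:
    name: str
    cls: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.cls not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.cls!r}")
        if self.end < self.start or self.start < 1:
            raise ValueError(f"bad region bounds [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


class TopologyMap:
    """Ordered, contiguous partition of positions 1..L into membrane regions.

    Regions must tile the sequence exactly: region i+1 starts at end(i)+1 and
    the first region starts at 1.
    """

    def __init__(self, regions: Iterable[Region]):
        self.regions = tuple(regions)
        if not self.regions:
            raise ValueError("topology needs at least one region")
        expect = 1
        for r in self.regions:
            if r.start != expect:
                raise ValueError(
                    f"region {r.name!r} starts at {r.start}, expected {expect}: "
                    "regions must be contiguous and cover 1..L"
                )
            expect = r.end + 1
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names")

    @property
    def length(self) -> int:
        return self.regions[-1].end

    def region_of(self, pos: int) -> Region:
        """The unique region containing 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        # 25 regions at most in practice; linear scan is fine.
        for r in self.regions:
            if pos in r:
                return r
        raise AssertionError("unreachable: contiguous coverage")

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in REGION_CLASSES}
        for r in self.regions:
            out[r.cls] += 1
        return out


@dataclass(frozen=True, order=True)
class MissenseVariant:
    """A single amino-acid substitution, e.g. p.V216L."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for aa in (self.ref, self.alt):
            if aa not in CANONICAL_AA:
                raise AlphabetError(f"non-canonical amino acid {aa!r}")
        if self.ref == self.alt:
            raise SynonymousVariantError(
                f"ref and alt are both {self.ref!r} at position {self.pos}"
            )
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def label(self) -> str:
        return f"p.{self.ref}{self.pos}{self.alt}"

    def __str__(self) -> str:
        return self.label


def parse_hgvs_p(label: str) -> MissenseVariant:
    """Parse a one-letter protein substitution label like ``p.V216L``.

    Raises :class:`HgvsParseError` on malformed labels,
    :class:`SynonymousVariantError` if ref == alt, and
    :class:`AlphabetError` for non-canonical residue codes.
    """
    m = _HGVS_P_RE.match(label.strip())
    if m is None:
        raise HgvsParseError(f"cannot parse variant label {label!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return MissenseVariant(pos=pos, ref=ref, alt=alt)


def validate_against_sequence(
    v: MissenseVariant, seq: ProteinSequence
) -> MissenseVariant:
    """Check that the variant's reference residue matches the sequence."""
    if v.pos > len(seq):
        raise ReferenceMismatchError(
            f"{v.label}: position {v.pos} beyond sequence length {len(seq)}"
        )
    observed = seq[v.pos]
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v.label}: expected {v.ref} at position {v.pos}, sequence has {observed}"
        )
    return v


def region_density(
    variants: Iterable[MissenseVariant], topo: TopologyMap
) -> tuple[pd.Series, float]:
    """Per-region variant density and the overall density.

    Density of a region is the number of variants falling in it divided by
    its residue count; the overall density is n_variants / L.  Multiple
    substitutions at one position each count (variants are counted, not
    positions); duplicate variant labels are rejected.
    """
    vs = list(variants)
    labels = [v.label for v in vs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate variant labels: {dupes}")
    counts = {r.name: 0 for r in topo.regions}
    for v in vs:
        counts[topo.region_of(v.pos).name] += 1
    dens = pd.Series(
        {r.name: counts[r.name] / len(r) for r in topo.regions}, name="density"
    )
    return dens, len(vs) / topo.length


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path, record_id: str | None = None) -> ProteinSequence:
    """Read a single protein record from a FASTA file.

    A multi-record file is an error unless ``record_id`` selects one record.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    elif len(records) > 1:
        raise ValueError(
            f"{path} holds {len(records)} records; pass record_id to choose one"
        )
    else:
        rec = records[0]
    return ProteinSequence(id=rec.id, residues=str(rec.seq).upper())


def read_topology_tsv(path: str | Path) -> TopologyMap:
    """Read a topology region table (columns: name, class, start, end)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "class", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"topology TSV needs columns {sorted(required)}")
    return TopologyMap(
        Region(row["name"], row["class"], int(row["start"]), int(row["end"]))
        for _, row in df.iterrows()
    )


def write_topology_tsv(topo: TopologyMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [r.name for r in topo.regions],
            "class": [r.cls for r in topo.regions],
            "start": [r.start for r in topo.regions],
            "end": [r.end for r in topo.regions],
        }
    ).to_csv(path, sep="\t", index=False)
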