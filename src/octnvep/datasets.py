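"""Packaged fixtures.

The bundled OCTN2 stand-ins are synthetic: they reproduce the canonical
dimensions of the transporter — 557 residues partitioned into 25 topological
regions (intracellular N-terminus, 12 transmembrane domains, 6 extracellular
loops, 5 intracellular loops, intracellular C-terminus) — but the residue
identities and exact region boundaries are generated, not the UniProt O76082
entry.  Every quantity that depends only on the dimensions (19 x 557 = 10,583
possible missense variants; 150 / 557 = 0.27 characterization density)
carries over exactly; replace the files with the real sequence and an
annotation-derived region table for production use.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import ProteinSequence, TopologyMap, read_fasta, read_topology_tsv

#: Canonical OCTN2 length (UniProt O76082).
OCTN2_LENGTH = 557


def _data_path(name: str) -> Path:
    return Path(resources.files("octnvep").joinpath("data", name))


def load_octn2_sequence() -> ProteinSequence:
    """The packaged 557-residue synthetic OCTN2 stand-in sequence."""
    return read_fasta(_data_path("octn2_synthetic.fasta"))


def load_octn2_topology() -> TopologyMap:
    """The packaged synthetic 25-region OCTN2 topology table."""
    return read_topology_tsv(_data_path("octn2_topology_synthetic.tsv"))


def load_published_variants():
    """The published 150-variant characterization table, if transcribed.

    The per-variant functional measurements (%WT function, SEM, localization
    class, ancestry group, per-population allele frequencies) live in the
    study's supplementary datasets, which are not redistributed with this
    package.  To reproduce the published summary statistics, transcribe the
    table to ``octnvep/data/published_variants.tsv`` (characterized-variant
    TSV schema) and reinstall.
    """
    path = _data_path("published_variants.tsv")
    if not path.exists():
        raise FileNotFoundError(
            "published per-variant measurements are not bundled with this "
            "package; transcribe the supplementary characterization table to "
            f"{path} to enable replication checks"
        )
    from .assay import read_characterized_tsv

    return read_characterized_tsv(path)
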