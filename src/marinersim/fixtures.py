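"""Packaged sequence fixtures.

The two linear transposon-end fragments used for gel-shift assays (a
96 bp XmaI fragment and a 162 bp SacII/AccI fragment, each carrying one
Hsmar1 end with its flanking TA dinucleotide) ship as a FASTA file so
length bookkeeping and any sequence-level checks run without downloads.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = ["load_emsa_fragments", "emsa_fragment_lengths"]


def load_emsa_fragments() -> Dict[str, SeqRecord]:
    """Parse the packaged transposon-end fragment FASTA, keyed by record id."""
    ref = resources.files("marinersim").joinpath("data/emsa_fragments.fasta")
    with ref.open("r") as handle:
        return {rec.id: rec for rec in SeqIO.parse(handle, "fasta")}


def emsa_fragment_lengths() -> Dict[str, int]:
    """Lengths (nt) of the short and long gel-shift fragments."""
    return {rid: len(rec.seq) for rid, rec in load_emsa_fragments().items()}
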