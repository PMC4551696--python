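"""Reference genome access with 1-based inclusive coordinates."""

from __future__ import annotations

import os
from typing import Mapping

from pyfaidx import Fasta


class ReferenceGenome:
    """Random access to an uppercase reference genome.

    Coordinates are 1-based and inclusive throughout, matching VCF and the
    c./g. nomenclature. Contig names are resolved tolerantly with respect to
    a leading ``chr`` prefix, the commonest FASTA/VCF/GTF mismatch.
    """

    def __init__(self, contigs: Mapping[str, str] | Fasta):
        self._fasta: Fasta | None = None
        self._dict: dict[str, str] | None = None
        if isinstance(contigs, Fasta):
            self._fasta = contigs
            names = list(contigs.keys())
        else:
            self._dict = {name: seq.upper() for name, seq in contigs.items()}
            names = list(self._dict)
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig name in reference")
        self._names = names
        # alias map: both with and without "chr" prefix
        self._alias: dict[str, str] = {}
        for name in names:
            self._alias[name] = name
            stripped = name[3:] if name.startswith("chr") else "chr" + name
            self._alias.setdefault(stripped, name)

    @classmethod
    def from_dict(cls, contigs: Mapping[str, str]) -> "ReferenceGenome":
        return cls(contigs)

    @property
    def contig_names(self) -> list[str]:
        return list(self._names)

    def has_contig(self, name: str) -> bool:
        return name in self._alias

    def resolve(self, name: str) -> str:
        """Map a query contig name onto the stored one (chr-prefix tolerant)."""
        try:
            return self._alias[name]
        except KeyError:
            raise KeyError(f"unknown contig {name!r}") from None

    def length(self, name: str) -> int:
        name = self.resolve(name)
        if self._dict is not None:
            return len(self._dict[name])
        return len(self._fasta[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {name: self.length(name) for name in self._names}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive), uppercased."""
        if start < 1 or end < start:
            raise ValueError(f"invalid interval {start}-{end}")
        name = self.resolve(chrom)
        if end > self.length(name):
            raise ValueError(f"interval {start}-{end} beyond contig {name}")
        if self._dict is not None:
            return self._dict[name][start - 1 : end]
        return str(self._fasta[name][start - 1 : end]).upper()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def load_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Open an (indexed) FASTA file as a :class:`ReferenceGenome`.

    A missing file is fatal; pyfaidx builds the ``.fai`` index on demand.
    Duplicate contig names raise ``ValueError``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        fasta = Fasta(path, sequence_always_upper=True)
    except ValueError as exc:  # pyfaidx signals duplicate keys this way
        raise ValueError(f"cannot index {path}: {exc}") from exc
    return ReferenceGenome(fasta)
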