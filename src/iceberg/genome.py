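"""Genome model: an ordered table of chromosome names and lengths.

Coordinates throughout the package are 0-based, half-open (BED
convention). The genome table fixes both the coordinate bounds and the
chromosome sort order used by every interval container; order is the
order of appearance in the chrom.sizes file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class GenomeError(ValueError):
    """Invalid genome table or coordinate outside chromosome bounds."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome table.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs. Names must be unique and
        lengths positive. The sequence order is the canonical sort order
        for all interval containers bound to this genome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _rank: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, chromosomes) -> None:
        chroms = tuple((str(name), int(length)) for name, length in chromosomes)
        names = [name for name, _ in chroms]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names in genome table")
        for name, length in chroms:
            if length <= 0:
                raise GenomeError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_rank", {name: i for i, name in enumerate(names)})

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._rank

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length(self, name: str) -> int:
        try:
            return self.chromosomes[self._rank[name]][1]
        except KeyError:
            raise GenomeError(f"unknown chromosome {name!r}") from None

    def rank(self, name: str) -> int:
        try:
            return self._rank[name]
        except KeyError:
            raise GenomeError(f"unknown chromosome {name!r}") from None

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeModel":
        """Read a two-column TSV of chromosome name and length."""
        path = Path(path)
        rows: list[tuple[str, int]] = []
        with path.open() as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise GenomeError(f"{path}:{lineno}: expected 'name<TAB>length'")
                try:
                    length = int(fields[1])
                except ValueError:
                    raise GenomeError(
                        f"{path}:{lineno}: length {fields[1]!r} is not an integer"
                    ) from None
                rows.append((fields[0], length))
        if not rows:
            raise GenomeError(f"{path}: empty genome table")
        return cls(rows)

    def to_chrom_sizes(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            for name, length in self.chromosomes:
                handle.write(f"{name}\t{length}\n")
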