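"""Core data model: contigs, scaffold layouts and Hi-C contact stores.

Coordinates are 0-based half-open in each contig's *native* forward frame
throughout the package; AGP input/output converts from its 1-based inclusive
convention at the boundary.  A contact between two contigs is a pair of
native offsets ``(x, y)`` with ``0 <= x < L_i`` and ``0 <= y < L_j`` where
the i-th contig precedes the j-th in its super-scaffold.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping

import numpy as np

#: orientation codes: a contig is either placed forward (+) or
#: reverse-complemented (-) in the super-scaffold.
FORWARD: int = 0
REVERSE: int = 1

_CHAR_TO_CODE = {"+": FORWARD, "-": REVERSE}
_CODE_TO_CHAR = {FORWARD: "+", REVERSE: "-"}


class LayoutError(ValueError):
    """A scaffold layout violates a structural invariant or format rule."""


class ContactError(ValueError):
    """Hi-C contact input is malformed or unusable."""


def parse_orientation(symbol: str) -> int:
    """Map an orientation character to its internal code (``+`` -> 0, ``-`` -> 1)."""
    try:
        return _CHAR_TO_CODE[symbol]
    except KeyError:
        raise LayoutError(f"unknown orientation symbol {symbol!r}") from None


def orientation_char(code: int) -> str:
    return _CODE_TO_CHAR[int(code)]


def orientation_chars(codes: Iterable[int]) -> list[str]:
    return [orientation_char(c) for c in codes]


@dataclasses.dataclass(frozen=True)
class Contig:
    """A contiguous assembled sequence placed in a super-scaffold.

    ``index`` is the 1-based position of the contig within its
    super-scaffold; ``length`` is its size in base pairs.
    """

    name: str
    length: int
    index: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise LayoutError(f"contig {self.name!r} has length {self.length} < 1")
        if self.index < 1:
            raise LayoutError(f"contig {self.name!r} has index {self.index} < 1")


@dataclasses.dataclass
class Scaffold:
    """An ordered run of oriented contigs forming one super-scaffold."""

    name: str
    contigs: list[Contig]
    orientations: np.ndarray  # uint8 codes, one per contig

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=np.uint8)
        if len(self.contigs) != len(self.orientations):
            raise LayoutError(
                f"scaffold {self.name!r}: {len(self.contigs)} contigs but "
                f"{len(self.orientations)} orientations"
            )
        if len(self.contigs) == 0:
            raise LayoutError(f"scaffold {self.name!r} has no contigs")
        for pos, contig in enumerate(self.contigs):
            if contig.index != pos + 1:
                raise LayoutError(
                    f"scaffold {self.name!r}: contig {contig.name!r} carries "
                    f"index {contig.index}, expected {pos + 1}"
                )

    @property
    def n(self) -> int:
        return len(self.contigs)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.contigs], dtype=np.int64)

    def gap_before(self, i: int, j: int) -> int:
        """Total length of contigs strictly between positions ``i < j`` (0-based).

        This is the inter-contig distance D of the likelihood model; AGP gap
        records never contribute (the model assumes no gap between adjacent
        contigs).
        """
        if not 0 <= i < j < self.n:
            raise IndexError(f"invalid pair positions ({i}, {j}) for n={self.n}")
        return int(sum(c.length for c in self.contigs[i + 1 : j]))


@dataclasses.dataclass
class ScaffoldLayout:
    """An ordered collection of super-scaffolds.

    ``gap_length`` is only used when emitting sequence or AGP gap records;
    it never enters likelihood distances.
    """

    scaffolds: list[Scaffold]
    gap_length: int = 100

    def __post_init__(self) -> None:
        if self.gap_length < 0:
            raise LayoutError("gap_length must be non-negative")
        seen: dict[str, str] = {}
        for scaf in self.scaffolds:
            for contig in scaf.contigs:
                if contig.name in seen:
                    raise LayoutError(
                        f"contig {contig.name!r} appears in both "
                        f"{seen[contig.name]!r} and {scaf.name!r}"
                    )
                seen[contig.name] = scaf.name
        self._locations = {
            contig.name: (si, pi)
            for si, scaf in enumerate(self.scaffolds)
            for pi, contig in enumerate(scaf.contigs)
        }

    @property
    def n_contigs(self) -> int:
        return sum(s.n for s in self.scaffolds)

    def locate(self, name: str) -> tuple[int, int] | None:
        """Return ``(scaffold_index, position)`` of a contig, or None."""
        return self._locations.get(name)

    def contig(self, name: str) -> Contig:
        si, pi = self._locations[name]
        return self.scaffolds[si].contigs[pi]

    def iter_contigs(self) -> Iterator[tuple[int, int, Contig, int]]:
        """Yield ``(scaffold_index, position, contig, orientation)``."""
        for si, scaf in enumerate(self.scaffolds):
            for pi, contig in enumerate(scaf.contigs):
                yield si, pi, contig, int(scaf.orientations[pi])

    def all_orientations(self) -> np.ndarray:
        """Concatenated orientation codes, scaffold-major order."""
        if not self.scaffolds:
            return np.zeros(0, dtype=np.uint8)
        return np.concatenate([s.orientations for s in self.scaffolds])

    def split_vector(self, vector: np.ndarray) -> list[np.ndarray]:
        """Split a concatenated per-contig vector back into per-scaffold pieces."""
        vector = np.asarray(vector)
        if vector.shape[0] != self.n_contigs:
            raise LayoutError(
                f"vector of length {vector.shape[0]} does not match "
                f"{self.n_contigs} contigs"
            )
        out, start = [], 0
        for scaf in self.scaffolds:
            out.append(vector[start : start + scaf.n])
            start += scaf.n
        return out

    def with_orientations(self, orientations: np.ndarray) -> "ScaffoldLayout":
        """Copy of the layout with a new concatenated orientation vector."""
        pieces = self.split_vector(np.asarray(orientations, dtype=np.uint8))
        scaffolds = [
            Scaffold(s.name, list(s.contigs), piece.copy())
            for s, piece in zip(self.scaffolds, pieces)
        ]
        return ScaffoldLayout(scaffolds, gap_length=self.gap_length)

    def layout_equal(self, other: "ScaffoldLayout", scaffold_names: bool = False) -> bool:
        """Equality of contig order, names, lengths and orientations.

        ``gap_length`` is presentation metadata and never compared;
        super-scaffold names are format metadata (the ``.assembly`` dialect
        does not carry them) and compared only on request.
        """
        if len(self.scaffolds) != len(other.scaffolds):
            return False
        for a, b in zip(self.scaffolds, other.scaffolds):
            if (scaffold_names and a.name != b.name) or a.n != b.n:
                return False
            if not np.array_equal(a.orientations, b.orientations):
                return False
            for ca, cb in zip(a.contigs, b.contigs):
                if (ca.name, ca.length) != (cb.name, cb.length):
                    return False
        return True


def make_layout(
    scaffold_specs: Mapping[str, Iterable[tuple[str, int, str]]],
    gap_length: int = 100,
) -> ScaffoldLayout:
    """Convenience constructor from ``{scaffold: [(name, length, '+'/'-'), ...]}``."""
    scaffolds = []
    for scaf_name, entries in scaffold_specs.items():
        entries = list(entries)
        contigs = [
            Contig(name, length, i + 1) for i, (name, length, _) in enumerate(entries)
        ]
        orients = np.array(
            [parse_orientation(sym) for _, _, sym in entries], dtype=np.uint8
        )
        scaffolds.append(Scaffold(scaf_name, contigs, orients))
    return ScaffoldLayout(scaffolds, gap_length=gap_length)


@dataclasses.dataclass
class ContactStore:
    """Hi-C contacts in native contig coordinates.

    ``inter`` maps ``(scaffold_index, i, j)`` with 0-based positions
    ``i < j`` to an ``(m, 2)`` int64 array of ``(x, y)`` offsets: the contact
    sets R_ij.  ``intra`` maps a contig name to the separation distances
    ``|pos1 - pos2|`` of read pairs that landed inside that single contig.
    Arrays are kept lexicographically sorted so that the store is a pure
    function of the contact *multiset*, insensitive to input line order.
    """

    inter: dict[tuple[int, int, int], np.ndarray]
    intra: dict[str, np.ndarray]
    filters_applied: dict = dataclasses.field(default_factory=dict)
    n_dropped: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, arr in list(self.inter.items()):
            si, i, j = key
            if not i < j:
                raise ContactError(f"inter key {key} must have i < j")
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            self.inter[key] = arr[order]
        for name, arr in list(self.intra.items()):
            arr = np.sort(np.asarray(arr, dtype=np.int64))
            if arr.size and arr[0] < 0:
                raise ContactError(f"negative intra distance for contig {name!r}")
            self.intra[name] = arr

    @property
    def n_inter(self) -> int:
        return sum(a.shape[0] for a in self.inter.values())

    @property
    def n_intra(self) -> int:
        return sum(a.size for a in self.intra.values())

    def pair(self, scaffold: int, i: int, j: int) -> np.ndarray:
        """Contacts of pair (i, j) in a scaffold; empty (0, 2) array if none."""
        return self.inter.get((scaffold, i, j), _EMPTY_PAIR)

    def pooled_intra(self) -> np.ndarray:
        """All intra-contig separation distances, pooled across contigs."""
        if not self.intra:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(list(self.intra.values()))

    def same_contents(self, other: "ContactStore") -> bool:
        if set(self.inter) != set(other.inter) or set(self.intra) != set(other.intra):
            return False
        return all(
            np.array_equal(self.inter[k], other.inter[k]) for k in self.inter
        ) and all(np.array_equal(self.intra[k], other.intra[k]) for k in self.intra)

    def validate_against(self, layout: ScaffoldLayout) -> None:
        """Assert every stored contact satisfies its coordinate invariants."""
        for (si, i, j), arr in self.inter.items():
            scaf = layout.scaffolds[si]
            li = scaf.contigs[i].length
            lj = scaf.contigs[j].length
            if arr.size and not (
                (arr[:, 0] >= 0).all()
                and (arr[:, 0] < li).all()
                and (arr[:, 1] >= 0).all()
                and (arr[:, 1] < lj).all()
            ):
                raise ContactError(
                    f"contact offsets out of range for pair {(si, i, j)}"
                )


_EMPTY_PAIR = np.zeros((0, 2), dtype=np.int64)
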