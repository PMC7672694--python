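"""Readers and writers for the standard scaffolding formats.

Supported formats:

* AGP v2.1 — tab-separated, 1-based inclusive coordinates; one object per
  super-scaffold.
* 3D-DNA ``.assembly`` — header lines ``>name index length`` followed by
  whitespace-separated signed-index body lines, one super-scaffold per line
  (a negative index means the contig is reverse-complemented).
* Hi-C contacts as Juicer ``merged_nodups.txt``, a generic whitespace
  ``name1 pos1 name2 pos2 [mapq1 mapq2]`` dialect ("pairs4", 0-based), or
  paired-end SAM/BAM alignments to the contigs (via pysam).
* FASTA for contig sequences and scaffold sequence output (via Biopython).

Everything is converted to the internal 0-based native-frame coordinate
model of :mod:`hicorient.core` at the boundary.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ContactError,
    ContactStore,
    Contig,
    LayoutError,
    Scaffold,
    ScaffoldLayout,
    orientation_char,
    parse_orientation,
)

logger = logging.getLogger(__name__)

#: default MAPQ threshold; duplicates are assumed to have been removed by
#: the upstream aligner/Juicer pipeline and are not re-deduplicated here.
DEFAULT_MIN_MAPQ = 30

#: 0-based column indices into a whitespace-split merged_nodups line
#: (Juicer 16-column long form).  ``mapq1``/``mapq2`` may be omitted from a
#: custom map for the short form, in which case the MAPQ filter passes.
MERGED_NODUPS_COLUMNS = {"chr1": 1, "pos1": 2, "chr2": 5, "pos2": 6, "mapq1": 8, "mapq2": 11}


# ---------------------------------------------------------------------------
# layout readers
# ---------------------------------------------------------------------------

def read_agp(
    path: str | Path,
    names_to_lengths: Mapping[str, int] | None = None,
    min_contig_length: int = 0,
) -> ScaffoldLayout:
    """Read an AGP v2.1 file into a :class:`ScaffoldLayout`.

    One super-scaffold is created per AGP object.  Gap (N/U) lines are
    recorded only through ``gap_length``; they contribute nothing to the
    inter-contig distances used by the likelihood model.  Component lengths
    are taken from ``component_end - component_beg + 1`` and cross-checked
    against ``names_to_lengths`` when given.  Orientations ``?``/``0``/``na``
    are mapped to ``+`` with a warning.  Contigs shorter than
    ``min_contig_length`` are kept but flagged with a warning.
    """
    path = Path(path)
    per_object: dict[str, list[tuple[str, int, int]]] = {}
    object_order: list[str] = []
    last_end: dict[str, int] = {}
    gap_length: int | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise LayoutError(f"{path}:{lineno}: expected >= 8 AGP columns")
            obj, beg_s, end_s, _part, ctype = fields[:5]
            try:
                beg, end = int(beg_s), int(end_s)
            except ValueError as exc:
                raise LayoutError(f"{path}:{lineno}: bad object coordinates") from exc
            if end < beg:
                raise LayoutError(f"{path}:{lineno}: object_end < object_beg")
            if obj not in per_object:
                per_object[obj] = []
                object_order.append(obj)
                last_end[obj] = 0
            if beg != last_end[obj] + 1:
                raise LayoutError(
                    f"{path}:{lineno}: object coordinates overlap or are "
                    f"non-monotone (beg={beg}, previous end={last_end[obj]})"
                )
            last_end[obj] = end

            if ctype in ("N", "U"):
                if gap_length is None:
                    gap_length = int(fields[5])
                continue
            if len(fields) < 9:
                raise LayoutError(f"{path}:{lineno}: component line needs 9 columns")
            comp_name, comp_beg, comp_end, orient = fields[5], fields[6], fields[7], fields[8]
            length = int(comp_end) - int(comp_beg) + 1
            if length != end - beg + 1:
                raise LayoutError(
                    f"{path}:{lineno}: component span does not match object span"
                )
            if names_to_lengths is not None:
                if comp_name not in names_to_lengths:
                    raise LayoutError(
                        f"{path}:{lineno}: unknown component {comp_name!r}"
                    )
                if names_to_lengths[comp_name] != length:
                    raise LayoutError(
                        f"{path}:{lineno}: component {comp_name!r} length {length} "
                        f"!= expected {names_to_lengths[comp_name]}"
                    )
            if orient not in ("+", "-"):
                logger.warning(
                    "%s:%d: orientation %r mapped to '+'", path, lineno, orient
                )
                orient = "+"
            if min_contig_length and length < min_contig_length:
                logger.warning(
                    "%s:%d: contig %s is shorter than %d bp (kept)",
                    path, lineno, comp_name, min_contig_length,
                )
            per_object[obj].append((comp_name, length, parse_orientation(orient)))

    scaffolds = []
    for obj in object_order:
        entries = per_object[obj]
        if not entries:
            continue
        contigs = [Contig(n, ln, i + 1) for i, (n, ln, _) in enumerate(entries)]
        orients = np.array([o for _, _, o in entries], dtype=np.uint8)
        scaffolds.append(Scaffold(obj, contigs, orients))
    return ScaffoldLayout(scaffolds, gap_length=100 if gap_length is None else gap_length)


def read_assembly(path: str | Path) -> ScaffoldLayout:
    """Read a 3D-DNA ``.assembly`` file.

    Fragments split by 3D-DNA (``:::fragment_*`` name suffixes) are treated
    as independent contigs; nothing special is required beyond keeping their
    names verbatim.
    """
    path = Path(path)
    declared: dict[int, tuple[str, int]] = {}
    body: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                if len(parts) != 3:
                    raise LayoutError(f"{path}:{lineno}: bad assembly header")
                name, idx_s, len_s = parts
                declared[int(idx_s)] = (name, int(len_s))
            else:
                try:
                    body.append([int(tok) for tok in line.split()])
                except ValueError as exc:
                    raise LayoutError(f"{path}:{lineno}: bad body line") from exc
    scaffolds = []
    for snum, indices in enumerate(body, start=1):
        contigs, orients = [], []
        for pos, signed in enumerate(indices):
            idx = abs(signed)
            if idx not in declared:
                raise LayoutError(
                    f"{path}: body references undeclared contig index {idx}"
                )
            name, length = declared[idx]
            contigs.append(Contig(name, length, pos + 1))
            orients.append(1 if signed < 0 else 0)
        scaffolds.append(
            Scaffold(f"scaffold_{snum}", contigs, np.array(orients, dtype=np.uint8))
        )
    return ScaffoldLayout(scaffolds)


# ---------------------------------------------------------------------------
# layout writer
# ---------------------------------------------------------------------------

def write_layout(
    layout: ScaffoldLayout,
    orientations: np.ndarray | None,
    path: str | Path,
    format: str = "agp",
) -> None:
    """Write a layout (optionally with replacement orientations) to disk.

    Output is deterministic for fixed input.  AGP coordinates are 1-based
    inclusive with sequential part numbers and ``layout.gap_length`` N-gap
    lines between components; ``.assembly`` output uses signed indices.
    """
    if orientations is not None:
        layout = layout.with_orientations(orientations)
    path = Path(path)
    if format == "agp":
        _write_agp(layout, path)
    elif format == "assembly":
        _write_assembly(layout, path)
    else:
        raise LayoutError(f"unknown layout format {format!r}")


def _write_agp(layout: ScaffoldLayout, path: Path) -> None:
    lines = ["##agp-version\t2.1"]
    for scaf in layout.scaffolds:
        pos = 1
        part = 1
        for pi, contig in enumerate(scaf.contigs):
            if pi > 0 and layout.gap_length > 0:
                lines.append(
                    "\t".join(
                        [
                            scaf.name,
                            str(pos),
                            str(pos + layout.gap_length - 1),
                            str(part),
                            "N",
                            str(layout.gap_length),
                            "scaffold",
                            "yes",
                            "proximity_ligation",
                        ]
                    )
                )
                pos += layout.gap_length
                part += 1
            lines.append(
                "\t".join(
                    [
                        scaf.name,
                        str(pos),
                        str(pos + contig.length - 1),
                        str(part),
                        "W",
                        contig.name,
                        "1",
                        str(contig.length),
                        orientation_char(scaf.orientations[pi]),
                    ]
                )
            )
            pos += contig.length
            part += 1
    path.write_text("\n".join(lines) + "\n")


def _write_assembly(layout: ScaffoldLayout, path: Path) -> None:
    lines = []
    index_of: dict[str, int] = {}
    for si, scaf in enumerate(layout.scaffolds):
        for contig in scaf.contigs:
            index_of[contig.name] = len(index_of) + 1
            lines.append(f">{contig.name} {index_of[contig.name]} {contig.length}")
    for scaf in layout.scaffolds:
        toks = []
        for pi, contig in enumerate(scaf.contigs):
            idx = index_of[contig.name]
            toks.append(str(-idx if scaf.orientations[pi] else idx))
        lines.append(" ".join(toks))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# contact readers
# ---------------------------------------------------------------------------

def read_contacts(
    path: str | Path,
    layout: ScaffoldLayout,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    dialect: str = "pairs4",
    column_map: Mapping[str, int] | None = None,
) -> ContactStore:
    """Read Hi-C contacts into a :class:`ContactStore`.

    Pairs with either MAPQ below ``min_mapq`` are dropped; pairs whose two
    sides land on the same contig are routed to the intra-contig distance
    pool; pairs on contigs in different super-scaffolds, or on contigs
    absent from the layout, are dropped with a counted warning.  The
    resulting store is insensitive to input line order.
    """
    if dialect == "sambam":
        records = _iter_sambam(Path(path))
    elif dialect == "merged_nodups":
        records = _iter_merged_nodups(Path(path), column_map)
    elif dialect == "pairs4":
        records = _iter_pairs4(Path(path))
    else:
        raise ContactError(f"unknown contacts dialect {dialect!r}")

    inter: dict[tuple[int, int, int], list[tuple[int, int]]] = defaultdict(list)
    intra: dict[str, list[int]] = defaultdict(list)
    dropped = {"mapq": 0, "unplaced": 0, "cross_scaffold": 0}
    n_kept = 0

    for lineno, name1, pos1, name2, pos2, mq1, mq2 in records:
        if mq1 < min_mapq or mq2 < min_mapq:
            dropped["mapq"] += 1
            continue
        loc1 = layout.locate(name1)
        loc2 = layout.locate(name2)
        if loc1 is None or loc2 is None:
            dropped["unplaced"] += 1
            continue
        if name1 == name2:
            _check_offset(layout, name1, pos1, path, lineno)
            _check_offset(layout, name2, pos2, path, lineno)
            intra[name1].append(abs(pos1 - pos2))
            n_kept += 1
            continue
        if loc1[0] != loc2[0]:
            dropped["cross_scaffold"] += 1
            continue
        _check_offset(layout, name1, pos1, path, lineno)
        _check_offset(layout, name2, pos2, path, lineno)
        si = loc1[0]
        if loc1[1] < loc2[1]:
            key, xy = (si, loc1[1], loc2[1]), (pos1, pos2)
        else:
            key, xy = (si, loc2[1], loc1[1]), (pos2, pos1)
        inter[key].append(xy)
        n_kept += 1

    if any(dropped.values()):
        logger.warning("dropped contacts: %s", dropped)
    if n_kept == 0:
        raise ContactError(f"{path}: no usable contacts after filtering")
    return ContactStore(
        inter={k: np.array(v, dtype=np.int64) for k, v in inter.items()},
        intra={k: np.array(v, dtype=np.int64) for k, v in intra.items()},
        filters_applied={"min_mapq": min_mapq, "dialect": dialect, "dedup": "upstream"},
        n_dropped=dropped,
    )


def _check_offset(layout: ScaffoldLayout, name: str, pos: int, path, lineno) -> None:
    length = layout.contig(name).length
    if not 0 <= pos < length:
        raise ContactError(
            f"{path}:{lineno}: position {pos} out of range [0, {length}) "
            f"for contig {name!r}"
        )


def _iter_pairs4(path: Path):
    """Generic whitespace dialect: ``name1 pos1 name2 pos2 [mapq1 mapq2]``.

    Positions are 0-based native-frame offsets; MAPQ columns are optional
    (treated as passing when absent).
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) not in (4, 6):
                raise ContactError(f"{path}:{lineno}: expected 4 or 6 columns")
            try:
                pos1, pos2 = int(toks[1]), int(toks[3])
                mq1 = int(toks[4]) if len(toks) == 6 else 255
                mq2 = int(toks[5]) if len(toks) == 6 else 255
            except ValueError as exc:
                raise ContactError(f"{path}:{lineno}: malformed line") from exc
            yield lineno, toks[0], pos1, toks[2], pos2, mq1, mq2


def _iter_merged_nodups(path: Path, column_map: Mapping[str, int] | None):
    """Juicer merged_nodups: whitespace-separated, positions 1-based."""
    cmap = dict(MERGED_NODUPS_COLUMNS if column_map is None else column_map)
    need = max(cmap.values()) + 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < need:
                raise ContactError(
                    f"{path}:{lineno}: expected >= {need} columns, got {len(toks)}"
                )
            try:
                pos1 = int(toks[cmap["pos1"]]) - 1
                pos2 = int(toks[cmap["pos2"]]) - 1
                mq1 = int(toks[cmap["mapq1"]]) if "mapq1" in cmap else 255
                mq2 = int(toks[cmap["mapq2"]]) if "mapq2" in cmap else 255
            except ValueError as exc:
                raise ContactError(f"{path}:{lineno}: malformed line") from exc
            yield lineno, toks[cmap["chr1"]], pos1, toks[cmap["chr2"]], pos2, mq1, mq2


def _iter_sambam(path: Path):
    """Paired-end SAM/BAM: primary alignments, leftmost mapping coordinate.

    Mates are paired by query name so that both MAPQ values are available.
    """
    import pysam

    pending: dict[str, tuple[str, int, int]] = {}
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for lineno, aln in enumerate(fh, start=1):
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or not aln.is_paired
                or aln.mate_is_unmapped
            ):
                continue
            rec = (aln.reference_name, aln.reference_start, aln.mapping_quality)
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = rec
            else:
                yield lineno, mate[0], mate[1], rec[0], rec[1], mate[2], rec[2]


# ---------------------------------------------------------------------------
# sequence output
# ---------------------------------------------------------------------------

def write_scaffold_fasta(
    contig_fasta: str | Path,
    layout: ScaffoldLayout,
    orientations: np.ndarray | None,
    path: str | Path,
) -> None:
    """Emit super-scaffold sequences: contigs concatenated in layout order,
    reverse-complemented where the orientation is ``-``, separated by
    ``layout.gap_length`` Ns, wrapped at 80 columns."""
    from Bio import SeqIO
    from Bio.Seq import Seq

    if orientations is not None:
        layout = layout.with_orientations(orientations)
    records = SeqIO.to_dict(SeqIO.parse(str(contig_fasta), "fasta"))
    for _, _, contig, _ in layout.iter_contigs():
        if contig.name not in records:
            raise LayoutError(f"contig {contig.name!r} missing from FASTA")
        if len(records[contig.name].seq) != contig.length:
            raise LayoutError(
                f"contig {contig.name!r}: FASTA length "
                f"{len(records[contig.name].seq)} != layout length {contig.length}"
            )
    gap = "N" * layout.gap_length
    with open(path, "w") as out:
        for scaf in layout.scaffolds:
            parts = []
            for pi, contig in enumerate(scaf.contigs):
                seq = str(records[contig.name].seq)
                if scaf.orientations[pi]:
                    seq = str(Seq(seq).reverse_complement())
                parts.append(seq)
            full = gap.join(parts)
            out.write(f">{scaf.name}\n")
            for start in range(0, len(full), 80):
                out.write(full[start : start + 80] + "\n")
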