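"""Readers and writers for the formats the pipeline touches.

Formats
-------
* multi-locus PHYLIP, BPP dialect: blank-line-separated blocks, each with a
  ``n_seq  n_sites`` header and relaxed labels (up to 50 chars, whitespace
  separated) — the dialect produced when RADseq FASTA partitions are
  concatenated for coalescent analysis;
* FASTA, one file per locus;
* two-column Imap text (individual label, candidate-species label);
* rooted Newick guide/species trees, with optional ``[&theta=,tau=]`` node
  comments (see :mod:`mscdelim.trees`).

Sequences are case-folded to uppercase on load and ``?`` is normalized to
``N`` so that downstream site-pattern counting is deterministic.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

from .trees import SpeciesTree

__all__ = [
    "LocusAlignment",
    "IndividualMap",
    "FormatError",
    "load_multilocus",
    "write_multilocus",
    "load_imap",
    "write_imap",
    "load_guide_tree",
    "write_guide_tree",
    "export_bpp_style",
]

_VALID = set("ACGTN-")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class LocusAlignment:
    """One locus: equal-length haploid sequences keyed by individual label."""

    locus_id: str
    rows: dict  # individual label -> sequence over {A,C,G,T,N,-}

    def __post_init__(self):
        if not self.rows:
            raise FormatError(f"locus {self.locus_id!r}: no sequences")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            bad = self._ragged_label()
            raise FormatError(
                f"locus {self.locus_id!r}: ragged sequence lengths "
                f"(offending individual {bad!r})"
            )
        if self.length < 1:
            raise FormatError(f"locus {self.locus_id!r}: empty sequences")
        for lab, seq in self.rows.items():
            extra = set(seq) - _VALID
            if extra:
                raise FormatError(
                    f"locus {self.locus_id!r}, individual {lab!r}: "
                    f"invalid symbols {sorted(extra)}"
                )

    def _ragged_label(self):
        from collections import Counter

        counts = Counter(len(s) for s in self.rows.values())
        majority = counts.most_common(1)[0][0]
        for lab, s in self.rows.items():
            if len(s) != majority:
                return lab
        return next(iter(self.rows))

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def labels(self):
        return list(self.rows.keys())


@dataclass
class IndividualMap:
    """Assignment of every sequenced individual to a candidate species."""

    assignments: dict  # individual label -> species label

    @property
    def species(self):
        """Species labels, in first-appearance order."""
        seen = []
        for sp in self.assignments.values():
            if sp not in seen:
                seen.append(sp)
        return seen

    def individuals_of(self, species_label: str):
        return [i for i, s in self.assignments.items() if s == species_label]

    def validate_against(self, loci) -> None:
        """Every individual in any locus must be mapped; no empty species."""
        for loc in loci:
            for lab in loc.rows:
                if lab not in self.assignments:
                    raise ValueError(
                        f"individual {lab!r} (locus {loc.locus_id!r}) "
                        "is absent from the individual map"
                    )
        if not self.assignments:
            raise ValueError("individual map is empty")

    def merged(self, groups) -> "IndividualMap":
        """Return a new map with each listed group of species merged.

        ``groups`` maps new label -> iterable of old labels.
        """
        relabel = {}
        for new, olds in groups.items():
            for old in olds:
                relabel[old] = new
        return IndividualMap(
            {ind: relabel.get(sp, sp) for ind, sp in self.assignments.items()}
        )


def _clean_seq(seq: str) -> str:
    return seq.upper().replace("?", "N")


# ---------------------------------------------------------------------------
# multi-locus PHYLIP (BPP dialect) and FASTA-per-locus


def load_multilocus(path, format: str = "phylip-multilocus"):
    """Load a multi-locus dataset as a list of :class:`LocusAlignment`.

    ``format`` is ``"phylip-multilocus"`` (one file, blank-line-separated
    blocks) or ``"fasta-per-locus"`` (a directory of ``*.fa``/``*.fasta``
    files, one per locus, sorted by filename).
    """
    path = Path(path)
    if format == "phylip-multilocus":
        return _load_phylip(path)
    if format == "fasta-per-locus":
        return _load_fasta_dir(path)
    raise ValueError(f"unknown format {format!r}")


def _load_phylip(path: Path):
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    lines = text.splitlines()
    loci = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        header = lines[i].split()
        if len(header) < 2 or not header[0].isdigit() or not header[1].isdigit():
            raise FormatError(
                f"{path}: expected 'n_seq n_sites' header at line {i + 1}, "
                f"got {lines[i]!r}"
            )
        n_seq, n_sites = int(header[0]), int(header[1])
        i += 1
        rows = {}
        while len(rows) < n_seq:
            if i >= len(lines) or not lines[i].strip():
                raise FormatError(
                    f"{path}: locus block {len(loci) + 1} declares {n_seq} "
                    f"sequences but contains {len(rows)}"
                )
            parts = lines[i].split(None, 1)
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: malformed sequence line {i + 1}: {lines[i]!r}"
                )
            label = parts[0].strip().lstrip("^")
            seq = _clean_seq(re.sub(r"\s+", "", parts[1]))
            if label in rows:
                raise FormatError(
                    f"{path}: duplicate individual {label!r} in locus block "
                    f"{len(loci) + 1}"
                )
            rows[label] = seq
            i += 1
        locus_id = f"L{len(loci) + 1:05d}"
        aln = LocusAlignment(locus_id, rows)
        if aln.length != n_sites:
            raise FormatError(
                f"{path}: locus block {len(loci) + 1} declares {n_sites} sites "
                f"but sequences have {aln.length}"
            )
        loci.append(aln)
    if not loci:
        raise FormatError(f"{path}: no locus blocks found")
    return loci


def _load_fasta_dir(path: Path):
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".fa", ".fasta", ".fna"}
    )
    if not files:
        raise FormatError(f"{path}: no FASTA files found")
    loci = []
    for p in files:
        rows = dict(_iter_fasta(p))
        loci.append(LocusAlignment(p.stem, rows))
    return loci


def _iter_fasta(path: Path):
    label, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if label is not None:
                    yield label, _clean_seq("".join(chunks))
                label, chunks = line[1:].split()[0].strip(), []
            elif line:
                chunks.append(line)
    if label is not None:
        yield label, _clean_seq("".join(chunks))
    elif not chunks:
        raise FormatError(f"{path}: empty FASTA")


def write_multilocus(loci, path) -> None:
    """Write loci as blank-line-separated relaxed PHYLIP blocks."""
    with open(path, "w") as fh:
        for k, loc in enumerate(loci):
            if k:
                fh.write("\n")
            fh.write(f"{loc.n_seqs} {loc.length}\n")
            for lab, seq in loc.rows.items():
                fh.write(f"{lab}  {seq}\n")


# ---------------------------------------------------------------------------
# Imap


def load_imap(path) -> IndividualMap:
    """Load a two-column individual→species map."""
    assignments = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {ln}: expected two columns, got {line!r}"
                )
            ind, sp = parts
            if ind in assignments and assignments[ind] != sp:
                raise FormatError(
                    f"{path}: individual {ind!r} mapped to both "
                    f"{assignments[ind]!r} and {sp!r}"
                )
            assignments[ind] = sp
    if not assignments:
        raise FormatError(f"{path}: empty individual map")
    return IndividualMap(assignments)


def write_imap(imap: IndividualMap, path) -> None:
    with open(path, "w") as fh:
        for ind, sp in imap.assignments.items():
            fh.write(f"{ind} {sp}\n")


# ---------------------------------------------------------------------------
# guide tree


def load_guide_tree(path) -> SpeciesTree:
    """Load a rooted binary Newick guide tree (tau/theta comments optional)."""
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty tree file")
    return SpeciesTree.from_newick(text)


def write_guide_tree(tree: SpeciesTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# FASTA + partition table -> BPP-style multilocus PHYLIP


def export_bpp_style(fasta_path, partition_names, partition_file, out_phylip, out_names):
    """Cut named partitions out of a concatenated FASTA and write PHYLIP blocks.

    ``partition_file`` has lines ``name start end`` with 1-based inclusive
    coordinates into the concatenated alignment.  For each requested name a
    PHYLIP block is written (individuals with only missing data in the
    partition are dropped from that block) plus a companion file listing the
    exported partition names, one per line.

    Returns the list of exported :class:`LocusAlignment`.
    """
    seqs = dict(_iter_fasta(Path(fasta_path)))
    if not seqs:
        raise FormatError(f"{fasta_path}: no sequences")
    total_len = len(next(iter(seqs.values())))
    parts = {}
    with open(partition_file) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            bits = line.split()
            if len(bits) != 3:
                raise FormatError(
                    f"{partition_file}: line {ln}: expected 'name start end'"
                )
            parts[bits[0]] = (int(bits[1]), int(bits[2]))
    unknown = [n for n in partition_names if n not in parts]
    if unknown:
        raise ValueError(
            f"unknown partition(s) {unknown}; valid names: {sorted(parts)}"
        )
    loci = []
    for name in partition_names:
        start, end = parts[name]
        if not (1 <= start <= end <= total_len):
            raise ValueError(
                f"partition {name!r} coordinates [{start},{end}] outside "
                f"sequence bounds [1,{total_len}]"
            )
        rows = {}
        for lab, seq in seqs.items():
            sub = seq[start - 1 : end]
            if set(sub) <= {"N", "-"}:
                continue  # individual absent at this locus
            rows[lab] = sub
        loci.append(LocusAlignment(name, rows))
    write_multilocus(loci, out_phylip)
    with open(out_names, "w") as fh:
        for name in partition_names:
            fh.write(name + "\n")
    return loci
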