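"""Fragment libraries: domain types and Rosetta-style file I/O.

A fragment library is the discrete choice space of the assembly method: for
every contiguous sequence window it lists candidate backbone fragments, each
given as per-residue (phi, psi, omega) torsions excised from known
structures.  The on-disk format is a documented subset of the Rosetta
fragment-file layout:

    position:            1 neighbors:           25

     1xyz A    42 A H  -61.500  -44.200  179.100
     ... one line per fragment residue ...
                                  <blank line between fragments>

Columns per residue line: source PDB code, chain, source residue number,
amino acid, secondary-structure letter, phi, psi, omega.  Trailing columns
are ignored.  Fragment order within a window is significant: it defines the
fragment index that probability vectors refer to.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conformation import canonicalize_torsions

__all__ = [
    "Fragment",
    "FragmentWindow",
    "FragmentLibrary",
    "FragmentFileError",
    "read_fragment_file",
    "write_fragment_file",
    "read_sequence",
    "write_sequence",
]

PAPER_FRAGMENT_LENGTHS = (3, 9)


class FragmentFileError(ValueError):
    """Malformed fragment file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class Fragment:
    """One candidate backbone fragment: (L, 3) torsions in degrees."""

    torsions: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.torsions, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("fragment torsions must have shape (L, 3)")
        if np.any(t < -180.0) or np.any(t > 180.0):
            raise ValueError(
                f"fragment '{self.source_tag}': torsion outside [-180, 180]"
            )
        # -180 and +180 are the same angle; keep the canonical representative
        # so that serialization round-trips are exact.
        t = t.copy()
        t[t == -180.0] = 180.0
        self.torsions = t

    @property
    def length(self) -> int:
        return self.torsions.shape[0]


@dataclass
class FragmentWindow:
    """Candidate fragments for one window of the target sequence."""

    start: int  # 1-based residue index of the first window position
    fragments: list[Fragment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"window start {self.start} < 1")
        if not self.fragments:
            raise ValueError(f"window {self.start} has no fragments")
        lengths = {f.length for f in self.fragments}
        if len(lengths) != 1:
            raise ValueError(
                f"window {self.start}: mixed fragment lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return self.fragments[0].length

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class FragmentLibrary:
    """9-mer and 3-mer fragment windows for one target sequence."""

    target_length: int
    windows9: list[FragmentWindow] = field(default_factory=list)
    windows3: list[FragmentWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        for length, windows in ((9, self.windows9), (3, self.windows3)):
            starts = [w.start for w in windows]
            if starts != sorted(starts):
                raise ValueError(f"{length}-mer windows not sorted by start")
            if len(set(starts)) != len(starts):
                raise ValueError(f"duplicate {length}-mer window starts")
            for w in windows:
                if w.length != length:
                    raise ValueError(
                        f"window at {w.start}: fragment length {w.length}, "
                        f"expected {length}"
                    )
                if w.start + length - 1 > self.target_length:
                    raise ValueError(
                        f"window at {w.start} exceeds target length "
                        f"{self.target_length}"
                    )

    def windows(self, frag_length: int) -> list[FragmentWindow]:
        if frag_length == 9:
            return self.windows9
        if frag_length == 3:
            return self.windows3
        raise ValueError(f"no windows of fragment length {frag_length}")

    def coverage(self, frag_length: int) -> float:
        """Fraction of possible window starts present (1.0 = dense)."""
        possible = self.target_length - frag_length + 1
        if possible <= 0:
            return 0.0
        return len(self.windows(frag_length)) / possible


_POSITION_RE = re.compile(r"^\s*position:\s*(\d+)\s+neighbors:\s*(\d+)\s*$")


def read_fragment_file(path, frag_length: int) -> list[FragmentWindow]:
    """Parse a Rosetta-style fragment file into windows of ``frag_length``.

    Raises :class:`FragmentFileError` (with line number) on malformed input
    and ``ValueError`` on out-of-range torsions or wrong fragment lengths.
    """
    if frag_length not in PAPER_FRAGMENT_LENGTHS:
        raise ValueError(f"frag_length must be 3 or 9, got {frag_length}")
    windows: list[FragmentWindow] = []
    cur_start: int | None = None
    cur_frags: list[Fragment] = []
    cur_rows: list[tuple[float, float, float]] = []
    cur_tag = ""

    def close_fragment(lineno: int) -> None:
        nonlocal cur_rows, cur_tag
        if not cur_rows:
            return
        if len(cur_rows) != frag_length:
            raise FragmentFileError(
                f"fragment '{cur_tag}' in window {cur_start} has "
                f"{len(cur_rows)} residues, expected {frag_length}",
                lineno,
            )
        try:
            cur_frags.append(Fragment(np.array(cur_rows), source_tag=cur_tag))
        except ValueError as exc:
            raise FragmentFileError(str(exc), lineno) from exc
        cur_rows = []
        cur_tag = ""

    def close_window(lineno: int) -> None:
        nonlocal cur_start, cur_frags
        close_fragment(lineno)
        if cur_start is not None:
            if not cur_frags:
                raise FragmentFileError(
                    f"window {cur_start} has no fragments", lineno
                )
            windows.append(FragmentWindow(start=cur_start, fragments=cur_frags))
        cur_start = None
        cur_frags = []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            m = _POSITION_RE.match(line)
            if m:
                close_window(lineno)
                cur_start = int(m.group(1))
                continue
            if not line.strip():
                close_fragment(lineno)
                continue
            if cur_start is None:
                raise FragmentFileError(
                    "residue line before any 'position:' header", lineno
                )
            tokens = line.split()
            if len(tokens) < 8:
                raise FragmentFileError(
                    f"expected >= 8 columns, got {len(tokens)}", lineno
                )
            try:
                phi, psi, omega = (float(x) for x in tokens[5:8])
            except ValueError as exc:
                raise FragmentFileError(
                    f"unparseable torsion in {tokens[5:8]}", lineno
                ) from exc
            if not cur_rows:
                cur_tag = " ".join(tokens[:3])
            cur_rows.append((phi, psi, omega))
    close_window(lineno)
    return windows


def write_fragment_file(windows: list[FragmentWindow], path) -> None:
    """Serialize windows to the fragment-file dialect read by this package.

    Torsions are written with three decimals, so a read/write round trip is
    the identity up to 5e-4 degrees.
    """
    lines: list[str] = []
    for w in windows:
        lines.append(f"position: {w.start:12d} neighbors: {w.n_fragments:12d}")
        lines.append("")
        for frag in w.fragments:
            tag = frag.source_tag.split()
            pdb = tag[0] if tag else "xxxx"
            chain = tag[1] if len(tag) > 1 else "A"
            try:
                resnum = int(tag[2]) if len(tag) > 2 else 1
            except ValueError:
                resnum = 1
            for j, (phi, psi, omega) in enumerate(frag.torsions):
                lines.append(
                    f" {pdb:>4s} {chain:1s} {resnum + j:5d} A L "
                    f"{phi:9.3f} {psi:9.3f} {omega:9.3f}"
                )
            lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def round_trip_torsions(windows: list[FragmentWindow]) -> list[FragmentWindow]:
    """Windows with torsions quantized to the on-disk precision (3 decimals)."""
    out = []
    for w in windows:
        frags = [
            Fragment(
                canonicalize_torsions(np.round(f.torsions, 3)),
                source_tag=f.source_tag,
            )
            for f in w.fragments
        ]
        out.append(FragmentWindow(start=w.start, fragments=frags))
    return out


VALID_AA = "ACDEFGHIKLMNPQRSTVWY"


def read_sequence(path) -> str:
    """Read a single-record FASTA; returns the uppercase sequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    seq = str(records[0].seq).upper()
    bad = sorted(set(seq) - set(VALID_AA))
    if bad:
        raise ValueError(f"{path}: non-standard amino-acid letters {''.join(bad)}")
    if len(seq) < 9:
        raise ValueError(
            f"{path}: sequence length {len(seq)} is shorter than one 9-mer"
        )
    return seq


def write_sequence(sequence: str, path, name: str = "target") -> None:
    """Write a sequence as single-record FASTA (60-column wrap)."""
    chunks = [sequence[i : i + 60] for i in range(0, len(sequence), 60)]
    Path(path).write_text(f">{name}\n" + "\n".join(chunks) + "\n")
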